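"""Quantify dosage compensation from male/female FPKM tables.

The chain mirrors the coverage analysis but on expression: derive a
per-sample FPKM cutoff from intron/intergenic background, keep genes
expressed above the cutoff in every compared sample, compute per-gene
normalized log2 male/female ratios (centered on the median ratio of genes
on putatively autosomal reference chromosomes), rank-test each chromosome
against the pooled autosomes with FDR control, and translate the median
ratio into a compensation call and an estimated compensation fraction.

The compensation fraction ``c`` inverts the male X expression factor
``0.5 + 0.5 c``: a median normalized log2(M/F) ratio ``m`` on a chromosome
gives ``c_hat = 2 * 2**m - 1``, so -1 maps to c = 0 (no compensation) and
0 to c = 1 (full compensation).

An ancestral-expression comparison contrasts each sex's normalized
expression in the focal species against a related species used as a proxy
for the pre-sex-linkage state, distinguishing compensation achieved by
male upregulation (male-only deficit vs the proxy) from shared
downregulation (deficit in both sexes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .sex_linkage import AMBIGUOUS, AUTOSOMAL, LinkageCall, X_LINKED
from .windows_stats import bh_adjust, mann_whitney_u

__all__ = [
    "CompensationReport",
    "AncestralComparison",
    "fpkm_cutoff",
    "filter_expressed",
    "gene_linkage_labels",
    "normalized_expression_ratio",
    "per_chromosome_tests",
    "call_compensation",
    "ancestral_comparison",
]

logger = logging.getLogger(__name__)

BACKGROUND_CLASSES = ("intron", "intergenic")

FULL, PARTIAL, NONE, OTHER = "FULL", "PARTIAL", "NONE", "OTHER"

DEFAULT_FULL_BAND = 0.15
DEFAULT_NONE_CUT = -0.85
DEFAULT_ALPHA = 0.05


@dataclass
class CompensationReport:
    unit: str
    n_genes: int
    median_norm_ratio: float
    u_stat: float
    p_raw: float
    p_adj: float
    call: str
    c_hat: float
    notch: tuple[float, float, float]


@dataclass
class AncestralComparison:
    unit: str
    sex: str
    n_genes: int
    median_focal_vs_proxy: float
    p_raw: float
    p_adj: float
    stars: str


def fpkm_cutoff(expr: pd.DataFrame, quantile_q: float = 0.95) -> dict[str, float]:
    """Per-sample expression cutoff from pooled intron + intergenic background.

    The cutoff is the ``quantile_q`` quantile (linear-interpolation
    convention) of a sample's background FPKM values; genes must exceed it
    to count as expressed.
    """
    if not 0.0 <= quantile_q <= 1.0:
        raise ConfigError(f"quantile_q must be in [0, 1], got {quantile_q}")
    bg = expr[expr["feature_class"].isin(BACKGROUND_CLASSES)]
    if len(bg) == 0:
        raise ValidationError("no background (intron/intergenic) rows in the table")
    cutoffs = {}
    for sample, sub in bg.groupby("sample_id"):
        cutoffs[str(sample)] = float(np.quantile(sub["fpkm"].to_numpy(), quantile_q))
    return cutoffs


def filter_expressed(expr: pd.DataFrame, cutoffs: Mapping[str, float]) -> pd.DataFrame:
    """Keep genes with FPKM strictly above the cutoff in *all* compared samples.

    Only ``feature_class == 'gene'`` rows are returned, restricted to the
    samples named in ``cutoffs``; requiring every sample keeps male/female
    ratios defined downstream.
    """
    genes = expr[(expr["feature_class"] == "gene") & expr["sample_id"].isin(cutoffs)]
    missing = set(cutoffs) - set(genes["sample_id"])
    if missing:
        raise ValidationError(f"cutoff samples absent from expression table: {sorted(missing)}")
    wide = genes.pivot_table(index="gene_id", columns="sample_id", values="fpkm", aggfunc="first")
    keep = pd.Series(True, index=wide.index)
    for sample, cut in cutoffs.items():
        keep &= wide[sample].notna() & (wide[sample] > cut)
    kept_ids = set(wide.index[keep])
    return genes[genes["gene_id"].isin(kept_ids)].reset_index(drop=True)


def gene_linkage_labels(
    approach: Literal["rbh", "scaffold_coverage"],
    rbh_pairs: Sequence[tuple[str, str]] | None = None,
    gene_map: Mapping[str, str] | None = None,
    x_chromosomes: set[str] | None = None,
    linkage_calls: Sequence[LinkageCall] | None = None,
    gene_to_scaffold: Mapping[str, str] | None = None,
    genes: Sequence[str] | None = None,
) -> tuple[dict[str, str], int]:
    """Label genes X-linked / autosomal by one of two classification approaches.

    ``rbh``: a gene is X-linked when its reciprocal-best-hit partner in the
    reference species lies on a chromosome of ``x_chromosomes``
    (``gene_map`` maps reference genes to chromosomes). ``scaffold_coverage``:
    a gene inherits the coverage-based linkage label of its host scaffold.
    Genes missing from the needed mapping are labeled ambiguous and counted
    in the returned warning count.
    """
    labels: dict[str, str] = {}
    warnings = 0
    if approach == "rbh":
        if rbh_pairs is None or gene_map is None or x_chromosomes is None:
            raise ConfigError("rbh approach requires rbh_pairs, gene_map and x_chromosomes")
        partner = {q: g for q, g in rbh_pairs}
        universe = genes if genes is not None else sorted(partner)
        for gene in universe:
            ref = partner.get(gene)
            chrom = gene_map.get(ref) if ref is not None else None
            if chrom is None:
                labels[gene] = AMBIGUOUS
                warnings += 1
            else:
                labels[gene] = X_LINKED if chrom in x_chromosomes else AUTOSOMAL
    elif approach == "scaffold_coverage":
        if linkage_calls is None or gene_to_scaffold is None:
            raise ConfigError(
                "scaffold_coverage approach requires linkage_calls and gene_to_scaffold"
            )
        call_of = {c.scaffold_id: c.label for c in linkage_calls}
        universe = genes if genes is not None else sorted(gene_to_scaffold)
        for gene in universe:
            scaf = gene_to_scaffold.get(gene)
            label = call_of.get(scaf) if scaf is not None else None
            if label is None:
                labels[gene] = AMBIGUOUS
                warnings += 1
            else:
                labels[gene] = label
    else:
        raise ConfigError(f"unknown approach {approach!r}")
    if warnings:
        logger.warning("%d genes lacked a mapping and were labeled AMBIGUOUS", warnings)
    return labels, warnings


def _normalized_sample_values(
    expr: pd.DataFrame, sample_id: str, reference_chromosomes: set[str]
) -> dict[str, float]:
    sub = expr[(expr["feature_class"] == "gene") & (expr["sample_id"] == sample_id)]
    if len(sub) == 0:
        raise ValidationError(f"sample {sample_id!r} absent from expression table")
    ref = sub[sub["chromosome"].isin(reference_chromosomes) & (sub["fpkm"] > 0)]
    if len(ref) == 0:
        raise ValidationError("no positive-FPKM genes on the reference chromosomes")
    med = float(np.median(ref["fpkm"]))
    if med <= 0:
        raise ValidationError("reference median FPKM is zero")
    return {
        str(g): float(v) / med for g, v in zip(sub["gene_id"], sub["fpkm"]) if v > 0
    }


def normalized_expression_ratio(
    expr: pd.DataFrame,
    male_id: str,
    female_id: str,
    reference_chromosomes: set[str],
) -> dict[str, float]:
    """Per-gene log2 male/female FPKM ratio, centered on the reference genes.

    ``r_g = fpkm_male / fpkm_female``; the returned value is
    ``log2(r_g / median{r_h})`` over genes on ``reference_chromosomes``.
    Genes with zero female FPKM are excluded (logged with a count).
    """
    if not reference_chromosomes:
        raise ConfigError("reference chromosome set is empty")
    genes = expr[expr["feature_class"] == "gene"]
    wide = genes.pivot_table(index="gene_id", columns="sample_id", values="fpkm", aggfunc="first")
    for sample in (male_id, female_id):
        if sample not in wide.columns:
            raise ValidationError(f"sample {sample!r} absent from expression table")
    chrom_of = genes.drop_duplicates("gene_id").set_index("gene_id")["chromosome"]
    wide = wide[[male_id, female_id]].dropna()
    zero_f = int((wide[female_id] <= 0).sum())
    if zero_f:
        logger.info("excluding %d genes with zero female FPKM", zero_f)
    wide = wide[wide[female_id] > 0]
    ratios = wide[male_id] / wide[female_id]
    ref = ratios[chrom_of.reindex(ratios.index).isin(reference_chromosomes) & (ratios > 0)]
    if len(ref) == 0:
        raise ValidationError("no genes with defined ratios on the reference chromosomes")
    med = float(np.median(ref))
    return {str(g): math.log2(r / med) for g, r in ratios.items() if r > 0}


def per_chromosome_tests(
    norm_ratios: Mapping[str, float],
    unit_of: Mapping[str, str],
    reference_units: set[str],
) -> list[tuple[str, int, float, float, float]]:
    """Rank-test each unit's normalized ratios against the pooled reference units.

    Returns ``(unit, n_genes, u, p_raw, p_adj)`` per unit with >= 2 genes
    (smaller units are skipped with a warning); the comparison pool is
    every reference-unit gene outside the tested unit; adjustment is
    Benjamini-Hochberg across the tested units.
    """
    values_by_unit: dict[str, list[float]] = {}
    for gene, value in norm_ratios.items():
        unit = unit_of.get(gene)
        if unit is None:
            continue
        values_by_unit.setdefault(str(unit), []).append(float(value))
    results = []
    for unit in sorted(values_by_unit):
        vals = values_by_unit[unit]
        if len(vals) < 2:
            logger.warning("unit %s has < 2 genes; skipped", unit)
            continue
        pool = [
            v
            for ref_unit in reference_units
            if ref_unit != unit
            for v in values_by_unit.get(ref_unit, [])
        ]
        if len(pool) < 2:
            logger.warning("reference pool for unit %s has < 2 genes; skipped", unit)
            continue
        u, p = mann_whitney_u(vals, pool)
        results.append((unit, len(vals), u, p))
    adj = bh_adjust([r[3] for r in results])
    return [(unit, n, u, p, pa) for (unit, n, u, p), pa in zip(results, adj)]


def call_compensation(
    median_norm_ratio: float,
    p_adj: float,
    full_band: float = DEFAULT_FULL_BAND,
    none_cut: float = DEFAULT_NONE_CUT,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[str, float]:
    """Translate a unit's median normalized log2(M/F) ratio into a call and c_hat.

    FULL when the unit is not significantly different from the autosomes or
    its median lies within ``full_band`` of 0; NONE when significant and at
    or below ``none_cut`` (near the uncompensated -1); PARTIAL when
    significant and between; OTHER for significant shifts in other
    directions (e.g. male-biased units). ``c_hat = 2 * 2**median - 1``,
    clipped to [-1, 1].
    """
    if not 0 < full_band < -none_cut:
        raise ConfigError(f"need 0 < full_band < {-none_cut}, got {full_band}")
    c_hat = float(np.clip(2.0 * 2.0 ** median_norm_ratio - 1.0, -1.0, 1.0))
    if p_adj >= alpha or abs(median_norm_ratio) <= full_band:
        return FULL, c_hat
    if median_norm_ratio <= none_cut:
        return NONE, c_hat
    if median_norm_ratio <= -full_band:
        return PARTIAL, c_hat
    return OTHER, c_hat


def _stars(p_adj: float) -> str:
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return "ns"


def ancestral_comparison(
    expr_focal: pd.DataFrame,
    expr_proxy: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    sample_focal: str,
    sample_proxy: str,
    sex: str,
    reference_chromosomes: set[str],
    unit_of: Mapping[str, str] | None = None,
) -> list[AncestralComparison]:
    """Compare one sex's focal expression against a proxy for ancestral levels.

    Each species' FPKM is first normalized by the median over its own
    reference-chromosome genes (within the given sex/sample); per paired
    gene the statistic is ``log2(norm_focal / norm_proxy)``. Units default
    to the proxy gene's chromosome. Each unit's values are rank-tested
    against the pooled reference-unit values (centered at 0 by
    construction); stars mark BH-adjusted significance at 0.05 / 0.01 /
    0.001.
    """
    focal_norm = _normalized_sample_values(expr_focal, sample_focal, reference_chromosomes)
    proxy_norm = _normalized_sample_values(expr_proxy, sample_proxy, reference_chromosomes)
    proxy_chrom = (
        expr_proxy[expr_proxy["feature_class"] == "gene"]
        .drop_duplicates("gene_id")
        .set_index("gene_id")["chromosome"]
        .to_dict()
    )
    values_by_unit: dict[str, list[float]] = {}
    for focal_gene, proxy_gene in pairs:
        if focal_gene not in focal_norm or proxy_gene not in proxy_norm:
            continue
        unit = (
            unit_of.get(focal_gene) if unit_of is not None else proxy_chrom.get(proxy_gene)
        )
        if unit is None:
            continue
        v = math.log2(focal_norm[focal_gene] / proxy_norm[proxy_gene])
        values_by_unit.setdefault(str(unit), []).append(v)
    results = []
    for unit in sorted(values_by_unit):
        vals = values_by_unit[unit]
        if len(vals) < 2:
            logger.warning("ancestral comparison: unit %s has < 2 paired genes; skipped", unit)
            continue
        pool = [
            v
            for ref_unit in reference_chromosomes
            if ref_unit != unit
            for v in values_by_unit.get(ref_unit, [])
        ]
        if len(pool) < 2:
            logger.warning("ancestral comparison: no reference pool for unit %s; skipped", unit)
            continue
        u, p = mann_whitney_u(vals, pool)
        results.append((unit, len(vals), float(np.median(vals)), p))
    adj = bh_adjust([r[3] for r in results])
    return [
        AncestralComparison(
            unit=unit,
            sex=sex,
            n_genes=n,
            median_focal_vs_proxy=med,
            p_raw=p,
            p_adj=pa,
            stars=_stars(pa),
        )
        for (unit, n, med, p), pa in zip(results, adj)
    ]
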