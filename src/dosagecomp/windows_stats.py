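"""Shared statistics: sliding-window medians, Mann-Whitney U, BH adjustment, notch intervals.

These primitives back both the coverage-based sex-linkage analysis (window
tracks along reference chromosomes) and the dosage-compensation tests
(rank test of each chromosome's normalized male/female ratios against the
autosomal pool, with false-discovery-rate control across chromosomes).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "Window",
    "WindowTrack",
    "sliding_window_median",
    "mann_whitney_u",
    "bh_adjust",
    "notch_interval",
]

#: combined sample size at or below which the exact U null is enumerated
EXACT_ENUMERATION_LIMIT = 20


@dataclass(frozen=True)
class Window:
    start_gene_index: int
    member_gene_ids: tuple[str, ...]
    median_value: float


@dataclass
class WindowTrack:
    """Ordered sliding windows of gene-level values along one chromosome."""

    chromosome: str
    window_size: int
    step: int
    windows: list[Window] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosome,
                "start_gene_index": [w.start_gene_index for w in self.windows],
                "n_genes": [len(w.member_gene_ids) for w in self.windows],
                "median_value": [w.median_value for w in self.windows],
            }
        )


def sliding_window_median(
    values: Mapping[str, float],
    gene_map: pd.DataFrame,
    window_size: int = 10,
    step: int = 1,
) -> list[WindowTrack]:
    """Median of ``values`` over sliding windows of consecutive genes.

    Parameters
    ----------
    values
        Mapping ``gene_id -> value`` (e.g. a normalized log2 expression or
        coverage ratio). Genes missing from the mapping are skipped.
    gene_map
        DataFrame with columns ``gene_id, chromosome, position`` giving the
        ordering of genes along each reference chromosome.
    window_size
        Number of consecutive genes per window (default 10). Chromosomes
        with fewer genes than ``window_size`` yield no windows; partial
        windows are never emitted.
    step
        Number of genes the window advances between successive windows.
    """
    if window_size < 1:
        raise ValidationError(f"window_size must be >= 1, got {window_size}")
    if step < 1:
        raise ValidationError(f"step must be >= 1, got {step}")
    required = {"gene_id", "chromosome", "position"}
    if not required.issubset(gene_map.columns):
        raise ValidationError(f"gene_map must have columns {sorted(required)}")

    tracks: list[WindowTrack] = []
    ordered = gene_map.sort_values(["chromosome", "position"], kind="mergesort")
    for chrom, sub in ordered.groupby("chromosome", sort=True):
        genes = [g for g in sub["gene_id"] if g in values]
        track = WindowTrack(chromosome=str(chrom), window_size=window_size, step=step)
        for start in range(0, len(genes) - window_size + 1, step):
            members = tuple(genes[start : start + window_size])
            med = float(np.median([values[g] for g in members]))
            track.windows.append(Window(start, members, med))
        tracks.append(track)
    return tracks


def _u_statistic(ranks_x: np.ndarray, n: int) -> float:
    # U of the first sample from its mid-ranks in the pooled ranking
    return float(ranks_x.sum() - n * (n + 1) / 2.0)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (rank-sum) test of ``x`` vs ``y``.

    Returns ``(u, p)`` where ``u`` is the U statistic of ``x`` computed from
    mid-ranks. For combined sample sizes up to 20 the null distribution of U
    is enumerated exactly over all C(n+m, n) labelings of the pooled values
    (mid-ranks handle ties); the two-sided p-value is the null probability of
    a deviation ``|U - nm/2|`` at least as large as observed. Larger samples
    use the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney_u requires non-empty samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("mann_whitney_u requires finite values")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n], n)

    if n + m <= EXACT_ENUMERATION_LIMIT:
        mu = n * m / 2.0
        dev_obs = abs(u_obs - mu)
        # Enumerate which pooled positions are labeled "x"; ranks are fixed.
        idx = np.array(list(itertools.combinations(range(n + m), n)), dtype=np.intp)
        u_all = ranks[idx].sum(axis=1) - n * (n + 1) / 2.0
        p = float(np.mean(np.abs(u_all - mu) >= dev_obs - 1e-12))
    else:
        res = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
    return u_obs, min(float(p), 1.0)


def bh_adjust(p: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(arr, method="fdr_bh")
    return [float(v) for v in adj]


def notch_interval(values: Sequence[float]) -> tuple[float, float, float]:
    """Approximate confidence interval for the median: median +/- 1.57*IQR/sqrt(n).

    IQR is Q3 - Q1 under the linear-interpolation quantile convention. This
    is the notch size of a boxplot and is used to annotate per-chromosome
    medians in the ancestral-expression comparison.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError("notch_interval requires at least 2 values")
    if not np.isfinite(arr).all():
        raise ValidationError("notch_interval requires finite values")
    med = float(np.median(arr))
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    half = 1.57 * float(q3 - q1) / math.sqrt(arr.size)
    return med - half, med, med + half
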