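"""End-to-end orchestration: simulate/load -> assign -> linkage -> compensation -> windows.

A single structured config (a nested mapping, typically loaded from YAML)
drives all stages in dependency order. Each stage writes its table under
the output directory and contributes to a machine-readable ``report.json``;
re-running with an identical config reproduces the report byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import dosage, io_formats, sex_linkage, synthetic_data, windows_stats
from .errors import ConfigError
from .homology_map import ScaffoldAssignment, assign_scaffolds, filter_best_hits

__all__ = ["load_config", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

_LINKAGE_METHODS = ("threshold", "mixture")


def load_config(path: str | Path) -> dict:
    """Load a pipeline config from a YAML file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ConfigError(f"{path}: config must be a mapping")
    return dict(cfg)


def _simulation_config(block: Mapping[str, Any]) -> synthetic_data.SimulationConfig:
    kwargs = dict(block)
    kwargs.pop("proxy_compensation", None)
    if "compensation" in kwargs:
        kwargs["compensation"] = {
            chrom: synthetic_data.Scenario.parse(s)
            for chrom, s in kwargs["compensation"].items()
        }
    if "x_chromosomes" in kwargs:
        kwargs["x_chromosomes"] = frozenset(kwargs["x_chromosomes"])
    if "scaffold_length_range" in kwargs:
        kwargs["scaffold_length_range"] = tuple(kwargs["scaffold_length_range"])
    return synthetic_data.SimulationConfig(**kwargs)


def validate_config(config: Mapping[str, Any]) -> list[str]:
    """Return a list of problems (empty iff the config is runnable)."""
    problems: list[str] = []
    has_sim = "simulate" in config
    has_inputs = "inputs" in config
    if has_sim == has_inputs:
        problems.append("exactly one of 'simulate' and 'inputs' must be present")
    if has_inputs:
        inputs = config.get("inputs") or {}
        samples = config.get("samples") or {}
        single_sex = "female" in samples and samples["female"] is None
        required = ("coverage",) if single_sex else ("coverage", "expression")
        for key in required:
            if key not in inputs:
                problems.append(f"inputs.{key}: required path is missing")
        for key, path in inputs.items():
            if not Path(path).exists():
                problems.append(f"inputs.{key}: file {path!r} does not exist")
    if has_sim:
        try:
            _simulation_config(config["simulate"] or {})
        except (ConfigError, TypeError, ValueError) as exc:
            problems.append(f"simulate: {exc}")
    ref = config.get("reference_chromosomes")
    if not ref:
        problems.append("reference_chromosomes: must be a non-empty list")
    xset = set(config.get("x_chromosomes") or [])
    if ref and xset & set(ref):
        problems.append("x_chromosomes and reference_chromosomes overlap")
    linkage = config.get("linkage") or {}
    method = linkage.get("method", "threshold")
    if method not in _LINKAGE_METHODS:
        problems.append(f"linkage.method: must be one of {_LINKAGE_METHODS}, got {method!r}")
    x_max = linkage.get("x_max", sex_linkage.DEFAULT_X_MAX)
    auto_min = linkage.get("auto_min", sex_linkage.DEFAULT_AUTO_MIN)
    if not x_max < auto_min:
        problems.append(f"linkage.x_max ({x_max}) must be < linkage.auto_min ({auto_min})")
    cutoff = (config.get("expression") or {}).get("cutoff", "auto")
    if cutoff != "auto" and not isinstance(cutoff, (int, float)):
        problems.append(f"expression.cutoff: must be 'auto' or a number, got {cutoff!r}")
    ws = (config.get("windows") or {}).get("size", 10)
    if not (isinstance(ws, int) and ws >= 1):
        problems.append(f"windows.size: must be a positive integer, got {ws!r}")
    return problems


def _assignments_from_truth(truth: pd.DataFrame) -> list[ScaffoldAssignment]:
    return [
        ScaffoldAssignment(
            scaffold_id=str(r.scaffold_id),
            chromosome=str(r.true_chromosome),
            n_genes=1,
            vote_counts={str(r.true_chromosome): 1},
        )
        for r in truth.itertuples(index=False)
    ]


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-14s %.2fs", name, t1 - t0)
    return t1


def run_pipeline(config: Mapping[str, Any], output_dir: str | Path | None = None) -> dict:
    """Run every stage defined by ``config`` and write tables + report.json.

    Fails fast on config problems before any stage executes. Returns the
    report dictionary (also written to ``<output_dir>/report.json``).
    """
    problems = validate_config(config)
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))
    out = Path(output_dir if output_dir is not None else config.get("output_dir", "."))
    out.mkdir(parents=True, exist_ok=True)

    samples = config.get("samples") or {}
    male_id = samples.get("male", "male")
    female_id = samples.get("female", "female")
    reference = set(config.get("reference_chromosomes"))
    x_set = set(config.get("x_chromosomes") or [])
    report: dict[str, Any] = {"stages": {}, "config_seed": None}
    t0 = time.perf_counter()

    # ---- inputs -----------------------------------------------------------
    truth = None
    proxy_expr = None
    pairs = None
    if "simulate" in config:
        sim_cfg = _simulation_config(config["simulate"] or {})
        report["config_seed"] = sim_cfg.seed
        layout = synthetic_data.simulate_layout(sim_cfg)
        cov, truth = synthetic_data.simulate_coverage(layout, sim_cfg)
        expr = synthetic_data.simulate_expression(layout, sim_cfg)
        assignments = _assignments_from_truth(truth)
        gene_to_scaffold = dict(zip(layout.genes["gene_id"], layout.genes["host_scaffold"]))
        layout.scaffolds.to_csv(out / "layout_scaffolds.tsv", sep="\t", index=False)
        layout.genes.to_csv(out / "layout_genes.tsv", sep="\t", index=False)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        io_formats.write_coverage_table(cov, out / "coverage.tsv")
        io_formats.write_expression_table(expr, out / "expression.tsv")
        proxy_block = (config["simulate"] or {}).get("proxy_compensation")
        if proxy_block is not None:
            # proxy species: same layout/baselines model but independent
            # measurement noise (its own seed) and its own scenarios
            sim_block = dict(config["simulate"] or {})
            proxy_seed = sim_block.pop("proxy_seed", sim_cfg.seed + 1)
            proxy_cfg = _simulation_config(
                {
                    **sim_block,
                    "compensation": proxy_block,
                    "seed": proxy_seed,
                    # conserved ortholog baselines, independent measurement noise
                    "baseline_seed": sim_cfg.seed,
                }
            )
            proxy_expr = synthetic_data.simulate_expression(layout, proxy_cfg)
            io_formats.write_expression_table(proxy_expr, out / "proxy_expression.tsv")
            pairs = [(g, g) for g in layout.genes["gene_id"]]
    else:
        inputs = config["inputs"]
        cov = io_formats.read_coverage_table(inputs["coverage"])
        expr = io_formats.read_expression_table(inputs["expression"])
        if "hits" in inputs and "transcript_map" in inputs:
            hits = io_formats.read_hits_tsv(inputs["hits"])
            tmap = pd.read_csv(inputs["transcript_map"], sep="\t")
            transcript_to_scaffold = dict(zip(tmap["transcript_id"], tmap["scaffold_id"]))
            lengths = dict(
                zip(cov.drop_duplicates("scaffold_id")["scaffold_id"],
                    cov.drop_duplicates("scaffold_id")["length"])
            )
            min_len = (config.get("linkage") or {}).get("min_length", 1000)
            assignments = assign_scaffolds(
                filter_best_hits(hits, by="query"),
                transcript_to_scaffold,
                scaffold_lengths=lengths,
                min_scaffold_len=min_len,
            )
        elif "assignments" in inputs:
            adf = pd.read_csv(inputs["assignments"], sep="\t")
            assignments = [
                ScaffoldAssignment(str(r.scaffold_id), str(r.chromosome), 1,
                                   {str(r.chromosome): 1})
                for r in adf.itertuples(index=False)
            ]
        else:
            raise ConfigError(
                "inputs must provide either hits+transcript_map or an assignments table"
            )
        gene_to_scaffold = None
        if "proxy_expression" in inputs:
            proxy_expr = io_formats.read_expression_table(inputs["proxy_expression"])
            pairs = None  # requires rbh pairs input
            if "rbh_pairs" in inputs:
                pdf = pd.read_csv(inputs["rbh_pairs"], sep="\t")
                pairs = list(zip(pdf["query_id"], pdf["gene_id"]))
    t0 = _stage("inputs", t0)

    # ---- sex linkage ------------------------------------------------------
    lk = config.get("linkage") or {}
    single_sex = female_id is None or samples.get("female", "female") is None
    if single_sex:
        ratios = sex_linkage.normalized_log2_single_sex(
            cov, male_id, reference, assignments, min_length=lk.get("min_length", 1000)
        )
    else:
        ratios = sex_linkage.normalized_log2_ratio(
            cov, male_id, female_id, reference, assignments,
            pseudo=lk.get("pseudo", 0.0), min_length=lk.get("min_length", 1000),
        )
    method = lk.get("method", "threshold")
    mixture_fit = None
    if method == "mixture":
        mixture_fit = sex_linkage.fit_two_component_mixture(list(ratios.values()))
        calls = sex_linkage.classify_mixture(
            ratios, mixture_fit, posterior_cut=lk.get("posterior_cut", 0.95)
        )
    else:
        calls = sex_linkage.classify_threshold(
            ratios,
            x_max=lk.get("x_max", sex_linkage.DEFAULT_X_MAX),
            auto_min=lk.get("auto_min", sex_linkage.DEFAULT_AUTO_MIN),
        )
    calls_df = pd.DataFrame(
        {
            "scaffold_id": [c.scaffold_id for c in calls],
            "log2_ratio": [c.log2_ratio for c in calls],
            "label": [c.label for c in calls],
            "posterior_x": [c.posterior_x if c.posterior_x is not None else "." for c in calls],
        }
    )
    calls_df.to_csv(out / "linkage_calls.tsv", sep="\t", index=False, float_format="%.12g")
    lengths = dict(zip(cov["scaffold_id"], cov["length"]))
    with open(out / "x_linked.bed", "w") as fh:
        for c in calls:
            if c.label == sex_linkage.X_LINKED:
                fh.write(f"{c.scaffold_id}\t0\t{lengths.get(c.scaffold_id, 0)}\t{c.label}\n")
    label_counts = calls_df["label"].value_counts().to_dict()
    linkage_summary: dict[str, Any] = {
        "method": method,
        "n_scaffolds": len(calls),
        "label_counts": {k: int(v) for k, v in sorted(label_counts.items())},
    }
    if mixture_fit is not None:
        linkage_summary["mixture"] = {
            "means": list(mixture_fit.means),
            "sds": list(mixture_fit.sds),
            "weight_x": mixture_fit.weight_x,
            "n_iter": mixture_fit.n_iter,
        }
    if truth is not None:
        truth_x = dict(zip(truth["scaffold_id"], truth["is_x"]))
        correct = sum(
            1
            for c in calls
            if (c.label == sex_linkage.X_LINKED) == bool(truth_x.get(c.scaffold_id, False))
            and c.label != sex_linkage.AMBIGUOUS
        )
        linkage_summary["accuracy_vs_truth"] = round(correct / len(calls), 6)
    report["stages"]["linkage"] = linkage_summary
    t0 = _stage("linkage", t0)

    if single_sex:
        # coverage-only analysis (one sequenced sex): no expression stages
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report

    # ---- dosage compensation ---------------------------------------------
    expr_block = config.get("expression") or {}
    cutoff_setting = expr_block.get("cutoff", "auto")
    compared = {male_id: 0.0, female_id: 0.0}
    if cutoff_setting == "auto":
        cutoffs = dosage.fpkm_cutoff(expr, quantile_q=expr_block.get("quantile", 0.95))
        cutoffs = {s: cutoffs.get(s, 0.0) for s in compared}
    else:
        cutoffs = {s: float(cutoff_setting) for s in compared}
    expressed = dosage.filter_expressed(expr, cutoffs)
    norm = dosage.normalized_expression_ratio(expressed, male_id, female_id, reference)
    chrom_of = (
        expressed.drop_duplicates("gene_id").set_index("gene_id")["chromosome"].to_dict()
    )
    tests = dosage.per_chromosome_tests(norm, chrom_of, reference)
    comp_rows = []
    for unit, n_genes, u, p_raw, p_adj in tests:
        vals = [v for g, v in norm.items() if chrom_of.get(g) == unit]
        med = float(np.median(vals))
        call, c_hat = dosage.call_compensation(med, p_adj)
        notch = windows_stats.notch_interval(vals)
        comp_rows.append(
            dosage.CompensationReport(
                unit=unit, n_genes=n_genes, median_norm_ratio=med, u_stat=u,
                p_raw=p_raw, p_adj=p_adj, call=call, c_hat=c_hat, notch=notch,
            )
        )
    comp_df = pd.DataFrame([asdict(r) for r in comp_rows])
    comp_df.to_csv(out / "compensation.tsv", sep="\t", index=False, float_format="%.12g")
    report["stages"]["compensation"] = {
        "cutoffs": {s: round(v, 6) for s, v in sorted(cutoffs.items())},
        "n_expressed_genes": int(expressed["gene_id"].nunique()),
        "units": {
            r.unit: {
                "n_genes": r.n_genes,
                "median_norm_ratio": round(r.median_norm_ratio, 6),
                "p_adj": float(f"{r.p_adj:.6g}"),
                "call": r.call,
                "c_hat": round(r.c_hat, 6),
                "notch": [round(v, 6) for v in r.notch],
            }
            for r in comp_rows
        },
    }
    t0 = _stage("compensation", t0)

    # ---- sliding windows --------------------------------------------------
    win = config.get("windows") or {}
    gene_map = (
        expressed.drop_duplicates("gene_id")[["gene_id", "chromosome", "position"]]
    )
    tracks = windows_stats.sliding_window_median(
        norm, gene_map, window_size=win.get("size", 10), step=win.get("step", 1)
    )
    if tracks:
        pd.concat([t.to_frame() for t in tracks], ignore_index=True).to_csv(
            out / "windows.tsv", sep="\t", index=False, float_format="%.12g"
        )
    report["stages"]["windows"] = {
        t.chromosome: len(t.windows) for t in tracks if t.windows
    }
    t0 = _stage("windows", t0)

    # ---- ancestral comparison --------------------------------------------
    if proxy_expr is not None and pairs is not None:
        anc_rows = []
        for sex, sample in (("male", male_id), ("female", female_id)):
            anc_rows.extend(
                dosage.ancestral_comparison(
                    expr, proxy_expr, pairs, sample, sample, sex, reference
                )
            )
        anc_df = pd.DataFrame([asdict(r) for r in anc_rows])
        anc_df.to_csv(out / "ancestral.tsv", sep="\t", index=False, float_format="%.12g")
        report["stages"]["ancestral"] = {
            f"{r.unit}/{r.sex}": {
                "n_genes": r.n_genes,
                "median_focal_vs_proxy": round(r.median_focal_vs_proxy, 6),
                "p_adj": float(f"{r.p_adj:.6g}"),
                "stars": r.stars,
            }
            for r in anc_rows
        }
        t0 = _stage("ancestral", t0)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
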