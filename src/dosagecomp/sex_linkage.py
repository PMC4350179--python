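"""Classify scaffolds as X-linked or autosomal from sequencing depth.

In an XY (or X0) system the X is present in one copy in males and two in
females, so X-linked scaffolds show about half the male read depth of
autosomal scaffolds. The statistic used here is the per-scaffold log2 of
the male/female depth ratio, normalized by the median ratio over scaffolds
assigned to a putatively autosomal reference-chromosome set, so autosomal
scaffolds center at 0 and X-linked scaffolds at -1. A single-sex variant
normalizes one sample's depth by the reference median, for data sets where
only male reads exist.

Classification is either by fixed thresholds on the normalized ratio or by
fitting a two-component Gaussian mixture (EM) to the — typically bimodal —
ratio distribution and thresholding the posterior of the low-coverage
component.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateFitError, ValidationError
from .homology_map import ScaffoldAssignment

__all__ = [
    "X_LINKED",
    "AUTOSOMAL",
    "AMBIGUOUS",
    "LinkageCall",
    "MixtureFit",
    "normalized_log2_ratio",
    "normalized_log2_single_sex",
    "classify_threshold",
    "fit_two_component_mixture",
    "classify_mixture",
]

logger = logging.getLogger(__name__)

X_LINKED = "X_LINKED"
AUTOSOMAL = "AUTOSOMAL"
AMBIGUOUS = "AMBIGUOUS"

# Expected peaks sit at 0 (diploid) and -1 (haploid-in-males). The default
# thresholds bracket the midpoint and leave an explicit ambiguous band:
# ratios at or below log2(2/3) are called X-linked, at or above log2(0.8)
# autosomal.
DEFAULT_X_MAX = math.log2(2.0 / 3.0)  # ~ -0.585
DEFAULT_AUTO_MIN = math.log2(0.8)  # ~ -0.322

_VARIANCE_FLOOR = 1e-6


@dataclass(frozen=True)
class LinkageCall:
    scaffold_id: str
    log2_ratio: float
    label: str
    posterior_x: float | None = None  # present only for mixture classification


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture fit of normalized log2 ratios.

    Component ``x`` is the lower-mean (X-linked) component; ``auto`` the
    higher-mean (autosomal) one. ``weight_x`` is the mixing proportion of
    the X component.
    """

    means: tuple[float, float]  # (m_auto, m_x), with m_x < m_auto
    sds: tuple[float, float]  # (s_auto, s_x)
    weight_x: float
    loglik: float
    n_iter: int
    converged: bool


def _reference_median(
    ratios: Mapping[str, float],
    assignments: Sequence[ScaffoldAssignment],
    reference_chromosomes: set[str],
) -> float:
    if not reference_chromosomes:
        raise ConfigError("reference chromosome set is empty")
    ref_ids = [
        a.scaffold_id
        for a in assignments
        if a.chromosome in reference_chromosomes and a.scaffold_id in ratios
    ]
    if not ref_ids:
        raise ValidationError(
            "no scaffolds assigned to the reference chromosomes have a depth ratio"
        )
    return float(np.median([ratios[s] for s in ref_ids]))


def _depth_frame(cov: pd.DataFrame, sample_ids: list[str]) -> pd.DataFrame:
    wide = cov.pivot_table(
        index="scaffold_id", columns="sample_id", values="mean_depth", aggfunc="first"
    )
    missing = [s for s in sample_ids if s not in wide.columns]
    if missing:
        raise ValidationError(f"samples absent from coverage table: {missing}")
    wide = wide[sample_ids].dropna()
    lengths = cov.drop_duplicates("scaffold_id").set_index("scaffold_id")["length"]
    wide = wide.join(lengths)
    return wide


def normalized_log2_ratio(
    cov: pd.DataFrame,
    male_id: str,
    female_id: str,
    reference_chromosomes: set[str],
    assignments: Sequence[ScaffoldAssignment],
    pseudo: float = 0.0,
    min_length: int = 1000,
) -> dict[str, float]:
    """Per-scaffold log2 male/female depth ratio, centered on the reference set.

    For each scaffold ``s`` present in both samples and strictly longer than
    ``min_length``, ``r_s = (male + pseudo) / (female + pseudo)``; the
    returned value is ``log2(r_s / median{r_t})`` over scaffolds assigned to
    ``reference_chromosomes``. Scaffolds with zero female depth (at
    ``pseudo = 0``) are excluded and counted in a log message; if every
    female depth is zero the call fails instead.
    """
    if pseudo < 0:
        raise ConfigError(f"pseudo-count must be >= 0, got {pseudo}")
    wide = _depth_frame(cov, [male_id, female_id])
    wide = wide[wide["length"] > min_length]
    if len(wide) == 0:
        raise ValidationError("no scaffolds pass the length filter in both samples")
    if (wide[female_id] + pseudo <= 0).all():
        raise ValidationError("all female depths are zero and pseudo-count is 0")
    denom = wide[female_id] + pseudo
    excluded = int((denom <= 0).sum())
    if excluded:
        logger.info("excluding %d scaffolds with zero female depth", excluded)
    wide = wide[denom > 0]
    ratios = {
        str(s): float(r)
        for s, r in ((wide[male_id] + pseudo) / (wide[female_id] + pseudo)).items()
    }
    ref_med = _reference_median(ratios, assignments, reference_chromosomes)
    if ref_med <= 0:
        raise ValidationError("reference median ratio is zero")
    return {s: math.log2(r / ref_med) for s, r in ratios.items() if r > 0}


def normalized_log2_single_sex(
    cov: pd.DataFrame,
    male_id: str,
    reference_chromosomes: set[str],
    assignments: Sequence[ScaffoldAssignment],
    min_length: int = 1000,
) -> dict[str, float]:
    """Single-sample variant: log2 of male depth over the reference median depth.

    Used when only one sex was sequenced; X-linked scaffolds are expected
    near -1 because mean depth is already per-bp (length-standardized).
    """
    wide = _depth_frame(cov, [male_id])
    wide = wide[wide["length"] > min_length]
    if len(wide) == 0:
        raise ValidationError("no scaffolds pass the length filter")
    depths = {str(s): float(d) for s, d in wide[male_id].items()}
    ref_med = _reference_median(depths, assignments, reference_chromosomes)
    if ref_med <= 0:
        raise ValidationError("reference median depth is zero")
    excluded = sum(1 for d in depths.values() if d <= 0)
    if excluded:
        logger.info("excluding %d scaffolds with zero depth", excluded)
    return {s: math.log2(d / ref_med) for s, d in depths.items() if d > 0}


def classify_threshold(
    ratios: Mapping[str, float],
    x_max: float = DEFAULT_X_MAX,
    auto_min: float = DEFAULT_AUTO_MIN,
) -> list[LinkageCall]:
    """Label scaffolds by fixed cuts: <= x_max X-linked, >= auto_min autosomal."""
    if not x_max < auto_min:
        raise ConfigError(f"x_max ({x_max}) must be < auto_min ({auto_min})")
    calls = []
    for scaf in sorted(ratios):
        v = ratios[scaf]
        if v <= x_max:
            label = X_LINKED
        elif v >= auto_min:
            label = AUTOSOMAL
        else:
            label = AMBIGUOUS
        calls.append(LinkageCall(scaffold_id=scaf, log2_ratio=float(v), label=label))
    return calls


def _loglik(values: np.ndarray, params: tuple) -> tuple[float, np.ndarray]:
    (m0, m1), (s0, s1), w1 = params
    from scipy.stats import norm

    d0 = (1.0 - w1) * norm.pdf(values, m0, s0)
    d1 = w1 * norm.pdf(values, m1, s1)
    tot = d0 + d1
    tot = np.maximum(tot, 1e-300)
    return float(np.log(tot).sum()), d1 / tot


def fit_two_component_mixture(
    values: Sequence[float],
    init_means: tuple[float, float] = (0.0, -1.0),
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureFit:
    """EM fit of a two-Gaussian mixture to normalized log2 depth ratios.

    Initialized at the diploid/haploid expectation (means 0 and -1) and
    deterministic given the data. The log-likelihood is non-decreasing
    across iterations; convergence is declared when its absolute change
    drops below ``tol``. A component variance falling under 1e-6 aborts
    with :class:`DegenerateFitError`.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 10:
        raise ValidationError(f"mixture fit requires >= 10 values, got {arr.size}")
    if not np.isfinite(arr).all():
        raise ValidationError("mixture fit requires finite values")
    if float(np.var(arr)) < _VARIANCE_FLOOR:
        raise DegenerateFitError("input values are (nearly) constant")

    m0, m1 = float(init_means[0]), float(init_means[1])
    s0 = s1 = max(float(np.std(arr)) / 2.0, 0.05)
    w1 = 0.5
    ll_prev = -np.inf
    ll = ll_prev
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, resp = _loglik(arr, ((m0, m1), (s0, s1), w1))
        if ll + 1e-12 < ll_prev:  # EM guarantee; violation means a numeric bug
            raise DegenerateFitError("log-likelihood decreased during EM")
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
        n1 = resp.sum()
        n0 = arr.size - n1
        if n0 < 1e-10 or n1 < 1e-10:
            raise DegenerateFitError("a mixture component became empty")
        w1 = n1 / arr.size
        m0 = float(((1 - resp) * arr).sum() / n0)
        m1 = float((resp * arr).sum() / n1)
        v0 = float(((1 - resp) * (arr - m0) ** 2).sum() / n0)
        v1 = float((resp * (arr - m1) ** 2).sum() / n1)
        if v0 < _VARIANCE_FLOOR or v1 < _VARIANCE_FLOOR:
            raise DegenerateFitError("mixture component variance underflow")
        s0, s1 = math.sqrt(v0), math.sqrt(v1)

    if m1 > m0:  # ensure component 1 is the low-mean (X) component
        m0, m1, s0, s1, w1 = m1, m0, s1, s0, 1.0 - w1
    return MixtureFit(
        means=(m0, m1), sds=(s0, s1), weight_x=float(w1),
        loglik=float(ll), n_iter=it, converged=converged,
    )


def classify_mixture(
    ratios: Mapping[str, float],
    fit: MixtureFit,
    posterior_cut: float = 0.95,
) -> list[LinkageCall]:
    """Label scaffolds by the posterior probability of the X component.

    ``posterior_x >= posterior_cut`` is X-linked, ``<= 1 - posterior_cut``
    autosomal, anything between ambiguous.
    """
    if not fit.converged:
        raise ValidationError("mixture fit did not converge")
    if not 0.5 < posterior_cut <= 1.0:
        raise ConfigError(f"posterior_cut must be in (0.5, 1], got {posterior_cut}")
    scafs = sorted(ratios)
    arr = np.asarray([ratios[s] for s in scafs], dtype=float)
    (m0, m1), (s0, s1), w1 = fit.means, fit.sds, fit.weight_x
    _, post_x = _loglik(arr, ((m0, m1), (s0, s1), w1))
    calls = []
    for scaf, v, p in zip(scafs, arr, post_x):
        if p >= posterior_cut:
            label = X_LINKED
        elif p <= 1.0 - posterior_cut:
            label = AUTOSOMAL
        else:
            label = AMBIGUOUS
        calls.append(
            LinkageCall(scaffold_id=scaf, log2_ratio=float(v), label=label, posterior_x=float(p))
        )
    return calls
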