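"""Normalized coverage ratios and X-linked vs autosomal classification."""

import math

import numpy as np
import pandas as pd
import pytest

from dosagecomp.errors import ConfigError, DegenerateFitError, ValidationError
from dosagecomp.homology_map import ScaffoldAssignment
from dosagecomp.sex_linkage import (
    AMBIGUOUS,
    AUTOSOMAL,
    X_LINKED,
    classify_mixture,
    classify_threshold,
    fit_two_component_mixture,
    normalized_log2_ratio,
    normalized_log2_single_sex,
)


def make_coverage(depths: dict[str, tuple[float, float]], length: int = 5000) -> pd.DataFrame:
    """depths: scaffold -> (male, female)."""
    rows = []
    for scaf, (m, f) in depths.items():
        rows.append((scaf, length, "male", m))
        rows.append((scaf, length, "female", f))
    return pd.DataFrame(rows, columns=["scaffold_id", "length", "sample_id", "mean_depth"])


def assigns(chrom_of: dict[str, str]) -> list[ScaffoldAssignment]:
    return [ScaffoldAssignment(s, c, 1, {c: 1}) for s, c in chrom_of.items()]


class TestNormalizedRatio:
    def test_half_coverage_scores_minus_one(self):
        cov = make_coverage({"r1": (30, 30), "r2": (30, 30), "t": (15, 30)})
        ratios = normalized_log2_ratio(
            cov, "male", "female", {"chrA"},
            assigns({"r1": "chrA", "r2": "chrA", "t": "chrX"}),
        )
        assert ratios["t"] == pytest.approx(-1.0)
        assert ratios["r1"] == pytest.approx(0.0)

    def test_hand_computed_reference_median(self):
        # reference raw ratios {1.0, 1.1}: median 1.05; test ratio 0.5
        cov = make_coverage({"r1": (30, 30), "r2": (33, 30), "t": (15, 30)})
        ratios = normalized_log2_ratio(
            cov, "male", "female", {"chrA"},
            assigns({"r1": "chrA", "r2": "chrA", "t": "chrX"}),
        )
        assert ratios["t"] == pytest.approx(math.log2(0.5 / 1.05), abs=1e-9)

    def test_equal_coverage_everywhere_gives_zero(self):
        cov = make_coverage({f"s{i}": (25, 25) for i in range(5)})
        ratios = normalized_log2_ratio(
            cov, "male", "female", {"chrA"}, assigns({f"s{i}": "chrA" for i in range(5)})
        )
        assert all(v == pytest.approx(0.0) for v in ratios.values())

    def test_invariant_to_common_depth_rescaling(self):
        chrom_of = {"r1": "chrA", "r2": "chrA", "t1": "chrX", "t2": "chrX"}
        base = {"r1": (28, 30), "r2": (31, 29), "t1": (14, 30), "t2": (16, 31)}
        cov1 = make_coverage(base)
        cov2 = make_coverage({s: (3.7 * m, 3.7 * f) for s, (m, f) in base.items()})
        r1 = normalized_log2_ratio(cov1, "male", "female", {"chrA"}, assigns(chrom_of))
        r2 = normalized_log2_ratio(cov2, "male", "female", {"chrA"}, assigns(chrom_of))
        for s in r1:
            assert r1[s] == pytest.approx(r2[s], abs=1e-12)

    def test_reference_median_centered_at_zero(self):
        rng = np.random.default_rng(1)
        depths = {f"s{i}": (rng.uniform(20, 40), rng.uniform(20, 40)) for i in range(21)}
        cov = make_coverage(depths)
        ratios = normalized_log2_ratio(
            cov, "male", "female", {"chrA"}, assigns({s: "chrA" for s in depths})
        )
        assert float(np.median(list(ratios.values()))) == pytest.approx(0.0, abs=1e-12)

    def test_empty_reference_set_rejected(self):
        cov = make_coverage({"s": (30, 30)})
        with pytest.raises(ConfigError):
            normalized_log2_ratio(cov, "male", "female", set(), assigns({"s": "chrA"}))

    def test_all_zero_female_depths_rejected(self):
        cov = make_coverage({"s1": (30, 0), "s2": (30, 0)})
        with pytest.raises(ValidationError):
            normalized_log2_ratio(
                cov, "male", "female", {"chrA"}, assigns({"s1": "chrA", "s2": "chrA"})
            )

    def test_short_scaffolds_excluded(self):
        cov = pd.concat(
            [
                make_coverage({"r": (30, 30), "t": (15, 30)}, length=5000),
                make_coverage({"tiny": (15, 30)}, length=800),
            ],
            ignore_index=True,
        )
        ratios = normalized_log2_ratio(
            cov, "male", "female", {"chrA"},
            assigns({"r": "chrA", "t": "chrX", "tiny": "chrX"}),
        )
        assert "tiny" not in ratios


class TestSingleSexMode:
    def test_half_depth_scores_minus_one(self):
        cov = make_coverage({"r1": (30, 1), "r2": (30, 1), "t": (15, 1)})
        ratios = normalized_log2_single_sex(
            cov, "male", {"chrA"}, assigns({"r1": "chrA", "r2": "chrA", "t": "chrX"})
        )
        assert ratios["t"] == pytest.approx(-1.0)
        assert ratios["r1"] == pytest.approx(0.0)

    def test_hand_computed_example(self):
        cov = make_coverage({"r1": (28, 1), "r2": (30, 1), "r3": (32, 1), "t": (20, 1)})
        ratios = normalized_log2_single_sex(
            cov, "male", {"chrA"},
            assigns({"r1": "chrA", "r2": "chrA", "r3": "chrA", "t": "chrX"}),
        )
        assert ratios["t"] == pytest.approx(math.log2(20 / 30), abs=1e-9)


class TestThresholdClassification:
    @pytest.mark.parametrize(
        "value,label",
        [(-1.0, X_LINKED), (0.0, AUTOSOMAL), (-0.45, AMBIGUOUS)],
    )
    def test_default_bands(self, value, label):
        (call,) = classify_threshold({"s": value})
        assert call.label == label
        assert call.posterior_x is None

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ConfigError):
            classify_threshold({"s": 0.0}, x_max=-0.3, auto_min=-0.6)


class TestMixture:
    @staticmethod
    def _bimodal(seed=123, n0=500, n1=250, sd=0.1):
        rng = np.random.default_rng(seed)
        return np.concatenate([rng.normal(0, sd, n0), rng.normal(-1, sd, n1)])

    def test_parameter_recovery_on_generating_model(self):
        values = self._bimodal()
        fit = fit_two_component_mixture(values)
        assert fit.converged
        m_auto, m_x = fit.means
        assert m_auto == pytest.approx(0.0, abs=0.05)
        assert m_x == pytest.approx(-1.0, abs=0.05)
        assert fit.weight_x == pytest.approx(1 / 3, abs=0.05)
        assert m_x < m_auto

    def test_constant_values_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_two_component_mixture([0.5] * 50)

    def test_loglik_is_finite_and_fit_deterministic(self):
        values = self._bimodal(seed=9)
        fit1 = fit_two_component_mixture(values)
        fit2 = fit_two_component_mixture(values)
        assert fit1 == fit2
        assert math.isfinite(fit1.loglik)

    def test_posterior_classification_recovers_truth(self):
        rng = np.random.default_rng(77)
        truth = {}
        values = {}
        for i in range(600):
            is_x = i % 3 == 0
            truth[f"s{i}"] = is_x
            values[f"s{i}"] = float(rng.normal(-1.0 if is_x else 0.0, 0.1))
        fit = fit_two_component_mixture(list(values.values()))
        calls = classify_mixture(values, fit)
        correct = sum(
            1 for c in calls
            if c.label != AMBIGUOUS and (c.label == X_LINKED) == truth[c.scaffold_id]
        )
        assert correct / len(calls) >= 0.98
        for c in calls:
            assert 0.0 <= c.posterior_x <= 1.0

    def test_midpoint_value_is_ambiguous(self):
        from dosagecomp.sex_linkage import MixtureFit

        fit = MixtureFit(means=(0.0, -1.0), sds=(0.1, 0.1), weight_x=0.5,
                         loglik=0.0, n_iter=1, converged=True)
        (call,) = classify_mixture({"s": -0.5}, fit)
        assert call.label == AMBIGUOUS
        assert call.posterior_x == pytest.approx(0.5, abs=1e-9)

    def test_value_at_x_mean_is_x_linked(self):
        from dosagecomp.sex_linkage import MixtureFit

        fit = MixtureFit(means=(0.0, -1.0), sds=(0.05, 0.05), weight_x=0.4,
                         loglik=0.0, n_iter=1, converged=True)
        (call,) = classify_mixture({"s": -1.0}, fit)
        assert call.label == X_LINKED
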