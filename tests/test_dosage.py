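"""Expression cutoffs, normalized ratios, rank tests and compensation calls."""

import math

import numpy as np
import pandas as pd
import pytest

from dosagecomp import dosage
from dosagecomp.errors import ValidationError
from dosagecomp.sex_linkage import AMBIGUOUS, AUTOSOMAL, LinkageCall, X_LINKED
from dosagecomp.synthetic_data import Scenario, SimulationConfig, simulate_expression, simulate_layout


def expr_table(rows):
    """rows: (gene_id, chromosome, sample_id, fpkm[, feature_class])."""
    return pd.DataFrame(
        [
            (r[0], r[1], 0, r[2], r[3], r[4] if len(r) > 4 else "gene")
            for r in rows
        ],
        columns=["gene_id", "chromosome", "position", "sample_id", "fpkm", "feature_class"],
    )


class TestFpkmCutoff:
    def test_all_zero_background_gives_zero(self):
        table = expr_table([(f"b{i}", ".", "male", 0.0, "intron") for i in range(10)])
        assert dosage.fpkm_cutoff(table) == {"male": 0.0}

    def test_hand_computed_quantile(self):
        # 19 zeros and one 1.0: the 0.95 quantile interpolates to 0.05
        rows = [(f"b{i}", ".", "male", 0.0, "intron") for i in range(19)]
        rows.append(("b19", ".", "male", 1.0, "intergenic"))
        assert dosage.fpkm_cutoff(expr_table(rows))["male"] == pytest.approx(0.05)

    def test_empty_background_rejected(self):
        with pytest.raises(ValidationError):
            dosage.fpkm_cutoff(expr_table([("g", "chr1", "male", 2.0)]))


class TestFilterExpressed:
    @staticmethod
    def _table():
        return expr_table(
            [
                ("g1", "chr1", "male", 0.1), ("g1", "chr1", "female", 0.2),
                ("g2", "chr1", "male", 0.5), ("g2", "chr1", "female", 3.0),
                ("g3", "chr2", "male", 12.0), ("g3", "chr2", "female", 15.0),
            ]
        )

    def test_zero_cutoff_keeps_low_expression(self):
        kept = dosage.filter_expressed(self._table(), {"male": 0.0, "female": 0.0})
        assert set(kept["gene_id"]) == {"g1", "g2", "g3"}

    def test_gene_must_pass_in_all_samples(self):
        kept = dosage.filter_expressed(self._table(), {"male": 1.0, "female": 1.0})
        assert set(kept["gene_id"]) == {"g3"}  # g2 fails in male

    def test_cutoff_monotonicity(self):
        table = self._table()
        survivors = [
            set(dosage.filter_expressed(table, {"male": c, "female": c})["gene_id"])
            for c in (0.0, 1.0, 10.0)
        ]
        assert survivors[2] <= survivors[1] <= survivors[0]


class TestGeneLinkageLabels:
    def test_rbh_partner_chromosome_decides(self):
        labels, warn = dosage.gene_linkage_labels(
            "rbh",
            rbh_pairs=[("x1", "TC1"), ("a1", "TC2")],
            gene_map={"TC1": "chr1", "TC2": "chr7"},
            x_chromosomes={"chr1", "chr4"},
        )
        assert labels == {"x1": X_LINKED, "a1": AUTOSOMAL}
        assert warn == 0

    def test_gene_inherits_scaffold_call(self):
        calls = [LinkageCall("s1", -1.0, X_LINKED), LinkageCall("s2", 0.0, AUTOSOMAL)]
        labels, warn = dosage.gene_linkage_labels(
            "scaffold_coverage",
            linkage_calls=calls,
            gene_to_scaffold={"g1": "s1", "g2": "s2", "g3": "s9"},
        )
        assert labels == {"g1": X_LINKED, "g2": AUTOSOMAL, "g3": AMBIGUOUS}
        assert warn == 1

    def test_approaches_agree_on_noise_free_synthetic_data(self):
        cfg = SimulationConfig(
            n_chromosomes=3, x_chromosomes=frozenset({"chr1"}),
            scaffolds_per_chromosome=5, genes_per_chromosome=30,
            measurement_sd=0.0, seed=4, compensation={"chr1": Scenario("NONE")},
        )
        layout = simulate_layout(cfg)
        # coverage-approach labels from truth; rbh partner = the gene's own chromosome
        calls = [
            LinkageCall(s, -1.0 if c == "chr1" else 0.0,
                        X_LINKED if c == "chr1" else AUTOSOMAL)
            for s, c in zip(layout.scaffolds.scaffold_id, layout.scaffolds.true_chromosome)
        ]
        by_cov, _ = dosage.gene_linkage_labels(
            "scaffold_coverage",
            linkage_calls=calls,
            gene_to_scaffold=dict(zip(layout.genes.gene_id, layout.genes.host_scaffold)),
        )
        by_rbh, _ = dosage.gene_linkage_labels(
            "rbh",
            rbh_pairs=[(g, f"ref_{g}") for g in layout.genes.gene_id],
            gene_map={f"ref_{g}": c for g, c in zip(layout.genes.gene_id, layout.genes.chromosome)},
            x_chromosomes={"chr1"},
        )
        assert by_cov == by_rbh


class TestNormalizedExpressionRatio:
    def test_noise_free_scenarios(self):
        rows = []
        for i in range(4):
            rows += [(f"a{i}", "chr2", "male", 10.0), (f"a{i}", "chr2", "female", 10.0)]
        rows += [("x1", "chr1", "male", 5.0), ("x1", "chr1", "female", 10.0)]
        rows += [("x2", "chr1", "male", 7.5), ("x2", "chr1", "female", 10.0)]
        norm = dosage.normalized_expression_ratio(expr_table(rows), "male", "female", {"chr2"})
        assert norm["x1"] == pytest.approx(-1.0)
        assert norm["x2"] == pytest.approx(math.log2(0.75))
        assert norm["a0"] == pytest.approx(0.0)

    def test_symmetric_reference_centers_at_zero(self):
        rows = []
        for i, r in enumerate([0.5, 0.8, 1.0, 1.25, 2.0]):
            rows += [(f"a{i}", "chr2", "male", 10.0 * r), (f"a{i}", "chr2", "female", 10.0)]
        norm = dosage.normalized_expression_ratio(expr_table(rows), "male", "female", {"chr2"})
        ref_vals = [norm[f"a{i}"] for i in range(5)]
        assert float(np.median(ref_vals)) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_sample_rescaling(self):
        rows = [("a1", "chr2", "male", 10.0), ("a1", "chr2", "female", 8.0),
                ("a2", "chr2", "male", 4.0), ("a2", "chr2", "female", 9.0),
                ("x1", "chr1", "male", 5.0), ("x1", "chr1", "female", 10.0)]
        t1 = expr_table(rows)
        t2 = t1.copy()
        t2.loc[t2.sample_id == "male", "fpkm"] *= 17.0
        n1 = dosage.normalized_expression_ratio(t1, "male", "female", {"chr2"})
        n2 = dosage.normalized_expression_ratio(t2, "male", "female", {"chr2"})
        for g in n1:
            assert n1[g] == pytest.approx(n2[g], abs=1e-12)

    def test_zero_female_gene_excluded(self):
        rows = [("a1", "chr2", "male", 10.0), ("a1", "chr2", "female", 8.0),
                ("a2", "chr2", "male", 4.0), ("a2", "chr2", "female", 9.0),
                ("z", "chr1", "male", 5.0), ("z", "chr1", "female", 0.0)]
        norm = dosage.normalized_expression_ratio(expr_table(rows), "male", "female", {"chr2"})
        assert "z" not in norm


class TestPerChromosomeTests:
    def test_identical_unit_and_reference_gives_p_one(self):
        vals = {"u1": -0.1, "u2": 0.1, "r1": -0.1, "r2": 0.1}
        unit_of = {"u1": "chrT", "u2": "chrT", "r1": "chrR", "r2": "chrR"}
        results = dosage.per_chromosome_tests(vals, unit_of, {"chrR"})
        by_unit = {r[0]: r for r in results}
        assert by_unit["chrT"][3] == 1.0  # p_raw

    def test_matches_exact_enumeration(self):
        from dosagecomp.windows_stats import mann_whitney_u

        x = [-1.1, -0.9, -1.0]
        y = [0.1, -0.1, 0.0, 0.05]
        vals = {f"x{i}": v for i, v in enumerate(x)}
        vals.update({f"r{i}": v for i, v in enumerate(y)})
        unit_of = {**{f"x{i}": "chrX" for i in range(3)}, **{f"r{i}": "chrR" for i in range(4)}}
        results = {r[0]: r for r in dosage.per_chromosome_tests(vals, unit_of, {"chrR"})}
        _, p_expected = mann_whitney_u(x, y)
        assert results["chrX"][3] == pytest.approx(p_expected, abs=1e-12)
        assert results["chrX"][4] >= results["chrX"][3]  # BH never lowers

    def test_null_units_control_false_discoveries(self):
        rng = np.random.default_rng(314)
        n_rep, n_units, genes_per_unit = 200, 10, 20
        false_rates = []
        for _ in range(n_rep):
            vals, unit_of = {}, {}
            for u in range(n_units):
                for g in range(genes_per_unit):
                    key = f"u{u}_g{g}"
                    vals[key] = float(rng.normal())
                    unit_of[key] = f"chr{u}"
            reference = {f"chr{u}" for u in range(n_units)}
            results = dosage.per_chromosome_tests(vals, unit_of, reference)
            false_rates.append(np.mean([r[4] < 0.05 for r in results]))
        assert float(np.mean(false_rates)) <= 0.05


class TestCallCompensation:
    @pytest.mark.parametrize(
        "median,p_adj,call,c_hat",
        [
            (-1.0, 1e-12, "NONE", 0.0),
            (0.0, 0.5, "FULL", 1.0),
            (math.log2(0.75), 1e-6, "PARTIAL", 0.5),
            (-1.8, 1e-9, "NONE", 2 * 2**-1.8 - 1),
            (0.7, 1e-9, "OTHER", 1.0),  # male-biased unit; c_hat clipped
        ],
    )
    def test_calls_and_fraction(self, median, p_adj, call, c_hat):
        got_call, got_c = dosage.call_compensation(median, p_adj)
        assert got_call == call
        assert got_c == pytest.approx(c_hat, abs=1e-9)

    def test_insignificant_unit_is_full(self):
        assert dosage.call_compensation(-1.0, 0.5)[0] == "FULL"


class TestAncestralComparison:
    @staticmethod
    def _species(ratios_by_chrom, n_ref=6, level=10.0, sample="male"):
        rows = []
        for i in range(n_ref):
            rows.append((f"r{i}", "chrR", sample, level))
        for chrom, (ratio, n) in ratios_by_chrom.items():
            for i in range(n):
                rows.append((f"{chrom}_g{i}", chrom, sample, level * ratio))
        return expr_table(rows)

    def test_identical_tables_give_zero_median_ns(self):
        focal = self._species({"chrX": (1.0, 6)})
        pairs = [(g, g) for g in focal["gene_id"]]
        results = dosage.ancestral_comparison(
            focal, focal.copy(), pairs, "male", "male", "male", {"chrR"}
        )
        by_unit = {r.unit: r for r in results}
        assert by_unit["chrX"].median_focal_vs_proxy == pytest.approx(0.0)
        assert by_unit["chrX"].stars == "ns"

    def test_shared_downregulation_shows_in_both_sexes(self):
        # focal X at half level in both sexes; proxy X at the ancestral level
        for sex in ("male", "female"):
            focal = self._species({"chrX": (0.5, 8)}, sample=sex)
            proxy = self._species({"chrX": (1.0, 8)}, sample=sex)
            pairs = [(g, g) for g in focal["gene_id"]]
            results = dosage.ancestral_comparison(
                focal, proxy, pairs, sex, sex, sex, {"chrR"}
            )
            by_unit = {r.unit: r for r in results}
            assert by_unit["chrX"].median_focal_vs_proxy == pytest.approx(-1.0)

    def test_uncompensated_x_down_in_males_only(self):
        focal_m = self._species({"chrX": (0.5, 8)}, sample="male")
        focal_f = self._species({"chrX": (1.0, 8)}, sample="female")
        proxy_m = self._species({"chrX": (1.0, 8)}, sample="male")
        proxy_f = self._species({"chrX": (1.0, 8)}, sample="female")
        pairs = [(g, g) for g in focal_m["gene_id"]]
        male = {r.unit: r for r in dosage.ancestral_comparison(
            focal_m, proxy_m, pairs, "male", "male", "male", {"chrR"})}
        female = {r.unit: r for r in dosage.ancestral_comparison(
            focal_f, proxy_f, pairs, "female", "female", "female", {"chrR"})}
        assert male["chrX"].median_focal_vs_proxy == pytest.approx(-1.0)
        assert female["chrX"].median_focal_vs_proxy == pytest.approx(0.0)
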