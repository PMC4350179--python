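"""Quantify dosage compensation per chromosome from male/female FPKM.

Per-sample expression cutoffs come from intron/intergenic background; each
chromosome's normalized log2(M/F) ratios are rank-tested against the
pooled autosomes (BH-corrected), and the median ratio is inverted into a
compensation fraction c_hat (0 = none, 1 = full).
"""

import numpy as np

from dosagecomp import dosage
from dosagecomp.synthetic_data import (
    Scenario,
    SimulationConfig,
    simulate_expression,
    simulate_layout,
)
from dosagecomp.windows_stats import notch_interval

config = SimulationConfig(
    n_chromosomes=6,
    x_chromosomes=frozenset({"chr1", "chr4"}),
    scaffolds_per_chromosome=20,
    genes_per_chromosome=300,
    measurement_sd=0.4,
    compensation={
        "chr1": Scenario("FULL_BOTH_DOWN", d=0.5),
        "chr4": Scenario("PARTIAL", c=0.5),
    },
    seed=17,
)
layout = simulate_layout(config)
expression = simulate_expression(layout, config)

cutoffs = dosage.fpkm_cutoff(expression, quantile_q=0.95)
print("FPKM cutoffs (95th background percentile):",
      {s: round(v, 3) for s, v in sorted(cutoffs.items())})
expressed = dosage.filter_expressed(
    expression, {s: cutoffs[s] for s in ("male", "female")}
)
print(f"{expressed['gene_id'].nunique()} of {len(layout.genes)} genes expressed "
      "above cutoff in both sexes")

reference = {"chr2", "chr3", "chr5", "chr6"}
norm = dosage.normalized_expression_ratio(expressed, "male", "female", reference)
chrom_of = expressed.drop_duplicates("gene_id").set_index("gene_id")["chromosome"].to_dict()

print(f"\n{'unit':>6} {'n':>4} {'median':>8} {'p_adj':>10} {'call':>8} {'c_hat':>6}  notch")
for unit, n, u, p_raw, p_adj in dosage.per_chromosome_tests(norm, chrom_of, reference):
    vals = [v for g, v in norm.items() if chrom_of.get(g) == unit]
    med = float(np.median(vals))
    call, c_hat = dosage.call_compensation(med, p_adj)
    lo, _, hi = notch_interval(vals)
    print(f"{unit:>6} {n:>4} {med:>8.3f} {p_adj:>10.2e} {call:>8} {c_hat:>6.2f}"
          f"  [{lo:+.3f}, {hi:+.3f}]")
print(
    "\nchr1 (shared downregulation) shows M/F ~ 1 -> FULL; chr4 shows the\n"
    "partial male deficit (median ~ log2 0.75 = -0.415) -> PARTIAL, c_hat ~ 0.5."
)
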