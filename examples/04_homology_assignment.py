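"""Assign scaffolds to reference chromosomes from translated-alignment hits.

Toy hit sets demonstrate the homology chain: best-hit filtering, consensus
(majority-vote) scaffold assignment, the 20-bp transcript merge rule, and
reciprocal best hits.
"""

from dosagecomp.homology_map import (
    assign_scaffolds,
    filter_best_hits,
    merge_transcripts,
    reciprocal_best_hits,
)
from dosagecomp.io_formats import HomologyHit


def hit(q, g, chrom, score, t=(0, 100)):
    return HomologyHit(q, g, chrom, 0, float(score), (0, 100), t)


# Three transcripts from scaffold s1, one from s2; t1 has two candidate hits.
hits = [
    hit("t1", "TC000101", "chr1", 95),
    hit("t1", "TC000999", "chr7", 60),  # weaker hit, dropped by best-hit filter
    hit("t2", "TC000102", "chr1", 88),
    hit("t3", "TC000407", "chr4", 91),
    hit("t4", "TC000705", "chr7", 77),
]
best = filter_best_hits(hits, by="query")
print(f"best hits kept: {[(h.query_id, h.gene_id) for h in best]}")

assignments = assign_scaffolds(
    best, {"t1": "s1", "t2": "s1", "t3": "s1", "t4": "s2"}
)
for a in assignments:
    print(f"scaffold {a.scaffold_id}: {a.chromosome} "
          f"(votes {a.vote_counts}, {a.n_genes} genes)")
print("s1 takes chr1 by majority (2 of 3 votes); s2 has a single gene on chr7.")

# Transcript merging on one reference gene: >20 bp overlap drops the weaker
# transcript, exactly 20 bp (or less) concatenates.
gene_hits = [
    hit("T1", "G", "chr1", 90, t=(100, 400)),
    hit("T2", "G", "chr1", 80, t=(380, 600)),  # 20-bp overlap with T1: kept
    hit("T3", "G", "chr1", 70, t=(150, 300)),  # 150-bp overlap with T1: dropped
]
(model,) = merge_transcripts(gene_hits)
print(f"\nmerged model for G: transcripts {model.retained_transcripts}, "
      f"covered {model.covered_intervals}")

pairs = reciprocal_best_hits(
    hits_fwd=[hit("t1", "TC000101", "chr1", 95)],
    hits_rev=[hit("TC000101", "t1", "chr1", 93)],
)
print(f"reciprocal best hits: {pairs}")
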