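"""Homology-based chromosome assignment and transcript-to-gene merging.

Raw translated-alignment hits from a focal species (scaffolds or assembled
transcripts) onto a well-assembled reference genome are turned into:

* best hits per query (or per reference gene);
* scaffold -> reference-chromosome assignments by consensus over the genes
  hitting each scaffold (a scaffold with a single mapped gene takes that
  gene's chromosome; with several, the chromosome supported by a strict
  majority of gene votes — plurality optionally — and unassigned on a tie);
* merged gene models: per reference gene, transcripts are retained greedily
  by descending alignment score, dropping any candidate whose footprint on
  the gene overlaps an already-retained transcript by more than
  ``overlap_bp`` (default 20 bp); the survivors' intervals are concatenated;
* reciprocal best hits, the ortholog proxy used to label focal genes as
  X-linked from their reference partner's chromosome.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from .errors import ConfigError, ValidationError
from .io_formats import HomologyHit

__all__ = [
    "UNASSIGNED",
    "ScaffoldAssignment",
    "MergedGeneModel",
    "filter_best_hits",
    "assign_scaffolds",
    "merge_transcripts",
    "reciprocal_best_hits",
]

logger = logging.getLogger(__name__)

#: sentinel chromosome for scaffolds whose gene votes tie
UNASSIGNED = "UNASSIGNED"

#: scaffolds must be strictly longer than this to enter the assignment (bp)
DEFAULT_MIN_SCAFFOLD_LEN = 1000

#: transcripts overlapping a retained one by more than this many bp are dropped
DEFAULT_OVERLAP_BP = 20


@dataclass(frozen=True)
class ScaffoldAssignment:
    scaffold_id: str
    chromosome: str  # a chromosome name or UNASSIGNED
    n_genes: int
    vote_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.n_genes != sum(self.vote_counts.values()):
            raise ValidationError(
                f"{self.scaffold_id}: n_genes {self.n_genes} != sum of votes"
            )


@dataclass
class MergedGeneModel:
    gene_id: str
    retained_transcripts: list[str] = field(default_factory=list)
    covered_intervals: list[tuple[int, int]] = field(default_factory=list)


def _best_key(hit: HomologyHit, by: str) -> tuple:
    other = hit.gene_id if by == "query" else hit.query_id
    # max score; ties -> longer matched interval, then lexicographically
    # smaller partner id (deterministic, order-independent)
    return (-hit.score, -hit.t_length, other)


def filter_best_hits(
    hits: Iterable[HomologyHit], by: Literal["query", "gene"] = "query"
) -> list[HomologyHit]:
    """Keep exactly one hit per query (or per reference gene): the best-scoring one.

    Ties on score are broken by the longer matched interval on the reference
    gene, then by the lexicographically smaller partner id; ties are logged.
    Output is sorted by key for order independence.
    """
    if by not in ("query", "gene"):
        raise ConfigError(f"by must be 'query' or 'gene', got {by!r}")
    groups: dict[str, list[HomologyHit]] = {}
    for hit in hits:
        key = hit.query_id if by == "query" else hit.gene_id
        groups.setdefault(key, []).append(hit)
    best: list[HomologyHit] = []
    for key in sorted(groups):
        ranked = sorted(groups[key], key=lambda h: _best_key(h, by))
        if len(ranked) > 1 and ranked[0].score == ranked[1].score:
            logger.debug("best-hit tie for %s %r broken deterministically", by, key)
        best.append(ranked[0])
    return best


def _consensus(votes: Counter, mode: str) -> str:
    ranked = votes.most_common()
    top_chrom, top_count = ranked[0]
    if len(ranked) > 1 and ranked[1][1] == top_count:
        return UNASSIGNED  # exact tie for the top
    if mode == "majority" and top_count * 2 <= sum(votes.values()):
        return UNASSIGNED  # plurality winner but no strict majority
    return top_chrom


def assign_scaffolds(
    best_hits: Sequence[HomologyHit],
    transcript_to_scaffold: Mapping[str, str],
    scaffold_lengths: Mapping[str, int] | None = None,
    min_scaffold_len: int = DEFAULT_MIN_SCAFFOLD_LEN,
    mode: Literal["majority", "plurality"] = "majority",
) -> list[ScaffoldAssignment]:
    """Assign each scaffold to the consensus reference chromosome of its genes.

    Every hit's query must map to a scaffold through
    ``transcript_to_scaffold`` (queries that already are scaffold ids may map
    to themselves). One gene vote is cast per hit; a scaffold with a single
    vote takes that chromosome, otherwise the consensus rule applies
    (``majority``: strict majority of votes, else UNASSIGNED; ``plurality``:
    unique top count, else UNASSIGNED). When ``scaffold_lengths`` is given,
    scaffolds not strictly longer than ``min_scaffold_len`` are dropped
    before voting. Scaffolds with zero hits are omitted.
    """
    if mode not in ("majority", "plurality"):
        raise ConfigError(f"mode must be 'majority' or 'plurality', got {mode!r}")
    votes: dict[str, Counter] = {}
    for hit in best_hits:
        if hit.query_id not in transcript_to_scaffold:
            raise ValidationError(f"query {hit.query_id!r} has no scaffold mapping")
        scaf = transcript_to_scaffold[hit.query_id]
        if scaffold_lengths is not None:
            if scaf not in scaffold_lengths:
                raise ValidationError(f"scaffold {scaf!r} has no declared length")
            if scaffold_lengths[scaf] <= min_scaffold_len:
                continue
        votes.setdefault(scaf, Counter())[hit.chromosome] += 1
    out = []
    for scaf in sorted(votes):
        v = votes[scaf]
        total = sum(v.values())
        if total == 1:
            chrom = next(iter(v))  # single mapped gene: its chromosome
        else:
            chrom = _consensus(v, mode)
        out.append(
            ScaffoldAssignment(
                scaffold_id=scaf,
                chromosome=chrom,
                n_genes=sum(v.values()),
                vote_counts=dict(v),
            )
        )
    return out


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(a, b) for a, b in merged]


def merge_transcripts(
    best_hits_per_gene: Sequence[HomologyHit],
    overlap_bp: int = DEFAULT_OVERLAP_BP,
) -> list[MergedGeneModel]:
    """Build one merged gene model per reference gene from best-match hits.

    Input hits must already be best-match-filtered per transcript, with
    ``t_interval`` on the reference gene's coordinate system. Per gene,
    candidates are visited by descending score (ties: longer interval, then
    smaller query id); a candidate overlapping any retained transcript's
    interval by strictly more than ``overlap_bp`` is dropped, otherwise it is
    retained and its interval concatenated into the model. An overlap of
    exactly ``overlap_bp`` therefore concatenates.
    """
    if overlap_bp < 0:
        raise ConfigError(f"overlap_bp must be >= 0, got {overlap_bp}")
    by_gene: dict[str, list[HomologyHit]] = {}
    for hit in best_hits_per_gene:
        by_gene.setdefault(hit.gene_id, []).append(hit)
    models = []
    for gene in sorted(by_gene):
        ranked = sorted(by_gene[gene], key=lambda h: (-h.score, -h.t_length, h.query_id))
        retained: list[HomologyHit] = []
        for cand in ranked:
            if any(_overlap(cand.t_interval, r.t_interval) > overlap_bp for r in retained):
                continue
            retained.append(cand)
        models.append(
            MergedGeneModel(
                gene_id=gene,
                retained_transcripts=[h.query_id for h in retained],
                covered_intervals=_merge_intervals([h.t_interval for h in retained]),
            )
        )
    return models


def reciprocal_best_hits(
    hits_fwd: Sequence[HomologyHit], hits_rev: Sequence[HomologyHit]
) -> list[tuple[str, str]]:
    """Pairs (query, gene) where each is the other's best hit.

    ``hits_fwd`` maps focal queries onto reference genes; ``hits_rev`` maps
    reference genes (as queries) back onto focal sequences. Both directions
    are best-hit-filtered here (idempotent if already filtered).
    """
    fwd_best = {h.query_id: h.gene_id for h in filter_best_hits(hits_fwd, by="query")}
    rev_best = {h.query_id: h.gene_id for h in filter_best_hits(hits_rev, by="query")}
    return sorted((q, g) for q, g in fwd_best.items() if rev_best.get(g) == q)
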