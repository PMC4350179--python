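"""Readers and writers for the tabular formats the pipeline consumes.

Three kinds of input are handled:

* homology hits — BLAT PSL (21-column) or a simplified hit TSV, parsed into
  :class:`HomologyHit` records;
* per-scaffold coverage tables (scaffold, length, sample, mean depth),
  optionally derived from a per-base depth dump;
* per-gene expression tables (FPKM) with a background partition of intron /
  intergenic features used to derive expression cutoffs.

All internal coordinates are 0-based half-open (the PSL convention);
per-base depth input is 1-based and converted on read. Readers validate and
reject rather than coerce; reals are serialized with 12 significant digits
so that write-then-read round-trips are stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "HomologyHit",
    "FEATURE_CLASSES",
    "read_psl",
    "read_hits_tsv",
    "write_hits_tsv",
    "read_coverage_table",
    "write_coverage_table",
    "mean_depth_from_base_depths",
    "read_expression_table",
    "write_expression_table",
]

#: allowed values of the expression-table feature_class column
FEATURE_CLASSES = ("gene", "intron", "intergenic")

_FLOAT_FMT = "%.12g"

COVERAGE_COLUMNS = ["scaffold_id", "length", "sample_id", "mean_depth"]
EXPRESSION_COLUMNS = ["gene_id", "chromosome", "position", "sample_id", "fpkm", "feature_class"]
HIT_COLUMNS = [
    "query_id", "gene_id", "chromosome", "gene_start", "score",
    "q_start", "q_end", "t_start", "t_end", "strand",
]


@dataclass(frozen=True)
class HomologyHit:
    """One translated-alignment hit of a focal-species query onto a reference gene.

    ``chromosome`` / ``gene_start`` locate the reference gene on the
    reference genome; intervals are 0-based half-open. ``strand`` is stored
    but not used by downstream logic.
    """

    query_id: str
    gene_id: str
    chromosome: str
    gene_start: int
    score: float
    q_interval: tuple[int, int]
    t_interval: tuple[int, int]
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValidationError(f"hit {self.query_id}->{self.gene_id}: empty chromosome")
        if not math.isfinite(self.score):
            raise ValidationError(f"hit {self.query_id}->{self.gene_id}: non-finite score")
        for name, (a, b) in (("q_interval", self.q_interval), ("t_interval", self.t_interval)):
            if a < 0 or b < 0:
                raise ValidationError(
                    f"hit {self.query_id}->{self.gene_id}: negative coordinate in {name}"
                )
            if not a < b:
                raise ValidationError(
                    f"hit {self.query_id}->{self.gene_id}: {name} start {a} >= end {b}"
                )

    @property
    def t_length(self) -> int:
        return self.t_interval[1] - self.t_interval[0]


# ---------------------------------------------------------------------------
# PSL
# ---------------------------------------------------------------------------

_PSL_NCOLS = 21


def read_psl(
    path: str | Path,
    gene_map: Mapping[str, tuple[str, int]] | None = None,
) -> list[HomologyHit]:
    """Parse a 21-column BLAT PSL file into :class:`HomologyHit` records.

    The score of each hit is ``matches - misMatches - qNumInsert -
    tNumInsert``. PSL itself does not carry the reference chromosome, so an
    optional ``gene_map`` (``gene_id -> (chromosome, gene_start)``) may be
    supplied; without it the PSL target name doubles as the chromosome and
    ``tStart`` as the gene start. A standard 5-line psLayout header is
    skipped when present.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    start = 0
    if lines and lines[0].startswith("psLayout"):
        start = 5  # psLayout vN, blank, two column-name lines, dash ruler
    hits: list[HomologyHit] = []
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        if not raw.strip() or raw.startswith("---"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) != _PSL_NCOLS:
            raise ParseError(
                f"{path}:{lineno}: expected {_PSL_NCOLS} PSL columns, got {len(fields)}"
            )
        try:
            matches = int(fields[0])
            mismatches = int(fields[1])
            q_num_insert = int(fields[4])
            t_num_insert = int(fields[6])
            strand = fields[8]
            q_name = fields[9]
            q_start, q_end = int(fields[11]), int(fields[12])
            t_name = fields[13]
            t_start, t_end = int(fields[15]), int(fields[16])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed PSL field: {exc}") from None
        if min(q_start, q_end, t_start, t_end) < 0:
            raise ParseError(f"{path}:{lineno}: negative coordinate")
        score = float(matches - mismatches - q_num_insert - t_num_insert)
        if gene_map is not None:
            if t_name not in gene_map:
                raise ValidationError(f"{path}:{lineno}: target {t_name!r} absent from gene map")
            chrom, gene_start = gene_map[t_name]
        else:
            chrom, gene_start = t_name, t_start
        try:
            hits.append(
                HomologyHit(
                    query_id=q_name,
                    gene_id=t_name,
                    chromosome=str(chrom),
                    gene_start=int(gene_start),
                    score=score,
                    q_interval=(q_start, q_end),
                    t_interval=(t_start, t_end),
                    strand=strand,
                )
            )
        except ValidationError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return hits


def read_hits_tsv(path: str | Path) -> list[HomologyHit]:
    """Read the simplified hit TSV dialect (see ``HIT_COLUMNS`` for the header)."""
    df = _read_tsv(path, HIT_COLUMNS, dtypes={"score": float})
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            HomologyHit(
                query_id=str(row.query_id),
                gene_id=str(row.gene_id),
                chromosome=str(row.chromosome),
                gene_start=int(row.gene_start),
                score=float(row.score),
                q_interval=(int(row.q_start), int(row.q_end)),
                t_interval=(int(row.t_start), int(row.t_end)),
                strand=str(row.strand),
            )
        )
    return hits


def write_hits_tsv(hits: Iterable[HomologyHit], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "query_id": [h.query_id for h in hits],
            "gene_id": [h.gene_id for h in hits],
            "chromosome": [h.chromosome for h in hits],
            "gene_start": [h.gene_start for h in hits],
            "score": [h.score for h in hits],
            "q_start": [h.q_interval[0] for h in hits],
            "q_end": [h.q_interval[1] for h in hits],
            "t_start": [h.t_interval[0] for h in hits],
            "t_end": [h.t_interval[1] for h in hits],
            "strand": [h.strand for h in hits],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep=".")


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, columns: list[str], dtypes: Mapping | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file (header mandatory)") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col, dtype in (dtypes or {}).items():
        try:
            df[col] = df[col].astype(dtype)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: column {col!r} not parseable as {dtype}: {exc}") from None
    return df[columns]


def validate_coverage_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check CoverageTable invariants; returns the (unchanged) table."""
    if list(df.columns) != COVERAGE_COLUMNS:
        raise ValidationError(f"coverage table must have columns {COVERAGE_COLUMNS}")
    dup = df.duplicated(subset=["scaffold_id", "sample_id"])
    if dup.any():
        first = df.loc[dup, ["scaffold_id", "sample_id"]].iloc[0]
        raise ValidationError(
            f"duplicate (scaffold_id, sample_id) key: ({first.scaffold_id}, {first.sample_id})"
        )
    if (df["length"] <= 0).any():
        raise ValidationError("scaffold length must be > 0")
    if (df["mean_depth"] < 0).any() or not np.isfinite(df["mean_depth"]).all():
        raise ValidationError("mean_depth must be finite and >= 0")
    return df


def read_coverage_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a coverage TSV (``scaffold_id  length  sample_id  mean_depth``)."""
    df = _read_tsv(path, COVERAGE_COLUMNS, dtypes={"length": np.int64, "mean_depth": float})
    return validate_coverage_table(df)


def write_coverage_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_coverage_table(df)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep=".")


def mean_depth_from_base_depths(
    path: str | Path,
    sample_id: str,
    lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Aggregate a per-base depth dump into a CoverageTable.

    The input is a TSV of ``scaffold  pos  depth`` rows with 1-based
    positions (the convention of common depth dumps); positions absent from
    the file count as depth 0. Scaffold lengths are taken from ``lengths``
    when given and inferred as the maximum observed position otherwise. A
    position beyond a declared length is a validation error.
    """
    path = Path(path)
    rows: dict[str, float] = {}
    maxpos: dict[str, int] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            if lineno == 1 and not fields[1].lstrip("-").isdigit():
                continue  # optional header
            scaf = fields[0]
            try:
                pos, depth = int(fields[1]), float(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if pos < 1:
                raise ParseError(f"{path}:{lineno}: positions are 1-based, got {pos}")
            if depth < 0:
                raise ValidationError(f"{path}:{lineno}: negative depth")
            if lengths is not None and scaf in lengths and pos > lengths[scaf]:
                raise ValidationError(
                    f"{path}:{lineno}: position {pos} exceeds declared length "
                    f"{lengths[scaf]} of {scaf}"
                )
            rows[scaf] = rows.get(scaf, 0.0) + depth
            maxpos[scaf] = max(maxpos.get(scaf, 0), pos)
    scaffolds = sorted(set(rows) | set(lengths or {}))
    out = pd.DataFrame(
        {
            "scaffold_id": scaffolds,
            "length": [
                int(lengths[s]) if lengths is not None and s in lengths else maxpos[s]
                for s in scaffolds
            ],
            "sample_id": sample_id,
            "mean_depth": [0.0] * len(scaffolds),
        }
    )
    out["mean_depth"] = [rows.get(s, 0.0) / L for s, L in zip(out["scaffold_id"], out["length"])]
    return validate_coverage_table(out[COVERAGE_COLUMNS])


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def validate_expression_table(df: pd.DataFrame) -> pd.DataFrame:
    if list(df.columns) != EXPRESSION_COLUMNS:
        raise ValidationError(f"expression table must have columns {EXPRESSION_COLUMNS}")
    bad = set(df["feature_class"]) - set(FEATURE_CLASSES)
    if bad:
        raise ValidationError(f"unknown feature_class values: {sorted(bad)}")
    if (df["fpkm"] < 0).any() or not np.isfinite(df["fpkm"]).all():
        raise ValidationError("fpkm must be finite and >= 0")
    dup = df.duplicated(subset=["gene_id", "sample_id", "feature_class"])
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise ValidationError(
            f"duplicate (gene_id, sample_id) within feature_class "
            f"{first.feature_class!r}: ({first.gene_id}, {first.sample_id})"
        )
    return df


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read and validate an expression TSV (FPKM per gene and sample plus background rows)."""
    df = _read_tsv(
        path, EXPRESSION_COLUMNS, dtypes={"position": np.int64, "fpkm": float}
    )
    return validate_expression_table(df)


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_expression_table(df)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep=".")
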