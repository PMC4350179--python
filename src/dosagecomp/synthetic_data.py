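"""Synthetic genomes, coverage tables and expression tables with known truth.

The generator emulates the statistical structure the inference assumes: a
genome partitioned into autosomal and X-linked scaffolds, male read depth
halved on the X relative to females (overdispersed negative-binomial
counts), and per-gene FPKM under configurable dosage-compensation
scenarios, plus low-level intron/intergenic background expression. Ground
truth labels accompany every table so recovery can be scored.

Compensation scenarios (female factor, male factor applied to an X-linked
gene's baseline):

* ``NONE`` — (1, 0.5): no compensation, males express half;
* ``PARTIAL(c)`` — (1, 0.5 + 0.5 c): male expression partially restored,
  c in [0, 1] is the compensation fraction;
* ``FULL_MALE_UP`` — (1, 1): the single male X is upregulated two-fold;
* ``FULL_BOTH_DOWN(d)`` — (d, d): both sexes express the X at a reduced
  level d, equalizing the sexes while lowering X:autosome ratios.

A single master seed drives independent substreams per stage (layout,
coverage, expression), so any stage can be regenerated on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "Scenario",
    "SimulationConfig",
    "GenomeLayout",
    "simulate_layout",
    "simulate_coverage",
    "simulate_expression",
]

_SCENARIO_KINDS = ("NONE", "PARTIAL", "FULL_MALE_UP", "FULL_BOTH_DOWN")


@dataclass(frozen=True)
class Scenario:
    """A dosage-compensation scenario for one chromosome."""

    kind: str
    c: float = 0.0  # compensation fraction, PARTIAL only
    d: float = 1.0  # shared downregulation level, FULL_BOTH_DOWN only

    def __post_init__(self) -> None:
        if self.kind not in _SCENARIO_KINDS:
            raise ConfigError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "PARTIAL" and not 0.0 <= self.c <= 1.0:
            raise ConfigError(f"PARTIAL compensation fraction must be in [0, 1], got {self.c}")
        if self.kind == "FULL_BOTH_DOWN" and not 0.0 < self.d <= 1.0:
            raise ConfigError(f"FULL_BOTH_DOWN level must be in (0, 1], got {self.d}")

    def factors(self) -> tuple[float, float]:
        """(female, male) multiplicative expression factors."""
        if self.kind == "NONE":
            return 1.0, 0.5
        if self.kind == "PARTIAL":
            return 1.0, 0.5 + 0.5 * self.c
        if self.kind == "FULL_MALE_UP":
            return 1.0, 1.0
        return self.d, self.d  # FULL_BOTH_DOWN

    @classmethod
    def parse(cls, text: str) -> "Scenario":
        """Parse 'NONE', 'PARTIAL:0.5', 'FULL_MALE_UP', 'FULL_BOTH_DOWN:0.5'."""
        kind, _, arg = str(text).partition(":")
        kind = kind.strip().upper()
        if kind == "PARTIAL":
            return cls("PARTIAL", c=float(arg) if arg else 0.5)
        if kind == "FULL_BOTH_DOWN":
            return cls("FULL_BOTH_DOWN", d=float(arg) if arg else 0.5)
        return cls(kind)


def _default_compensation() -> dict[str, Scenario]:
    # ancestral X fully compensated by shared downregulation, neo-X partially
    return {"chr1": Scenario("FULL_BOTH_DOWN", d=0.5), "chr4": Scenario("PARTIAL", c=0.5)}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe a beetle-like reference karyotype of ten chromosomes
    of which two (chr1 = ancestral X, chr4 = recently added X) are X-linked
    in the focal species, ~30x female depth with negative-binomial
    overdispersion (size ``dispersion``; variance mu + mu^2/k; ``inf``
    selects Poisson), log-normal FPKM baselines with multiplicative
    log2-scale measurement noise, and exponential low-level background
    expression for introns and intergenic regions.
    """

    n_chromosomes: int = 10
    x_chromosomes: frozenset[str] = frozenset({"chr1", "chr4"})
    scaffolds_per_chromosome: int = 150
    genes_per_chromosome: int = 200
    scaffold_length_range: tuple[int, int] = (2000, 20000)
    depth_female: float = 30.0
    dispersion: float = 10.0
    fpkm_log_mean: float = 2.0
    fpkm_log_sd: float = 1.0
    measurement_sd: float = 0.4
    compensation: dict[str, Scenario] = field(default_factory=_default_compensation)
    background_n: int = 200
    background_scale: float = 0.3
    seed: int = 0
    baseline_seed: int | None = None  # share gene baselines across species when set

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i}" for i in range(1, self.n_chromosomes + 1)]

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        if self.scaffolds_per_chromosome < 1:
            raise ConfigError("scaffolds_per_chromosome must be >= 1")
        if self.genes_per_chromosome < 1:
            raise ConfigError("genes_per_chromosome must be >= 1")
        unknown = set(self.x_chromosomes) - set(self.chromosomes)
        if unknown:
            raise ConfigError(f"x_chromosomes not in the genome: {sorted(unknown)}")
        lo, hi = self.scaffold_length_range
        if not 0 < lo <= hi:
            raise ConfigError(f"invalid scaffold_length_range {self.scaffold_length_range}")
        for name, val in (
            ("depth_female", self.depth_female),
            ("dispersion", self.dispersion),
            ("fpkm_log_sd", self.fpkm_log_sd),
            ("background_scale", self.background_scale),
        ):
            if not val > 0:
                raise ConfigError(f"{name} must be > 0, got {val}")
        if self.measurement_sd < 0:
            raise ConfigError("measurement_sd must be >= 0")
        if self.background_n < 0:
            raise ConfigError("background_n must be >= 0")
        unknown = set(self.compensation) - set(self.chromosomes)
        if unknown:
            raise ConfigError(f"compensation scenarios for unknown chromosomes: {sorted(unknown)}")

    def scenario_for(self, chromosome: str) -> Scenario:
        """Scenario applied to a chromosome; autosomes are unmodified (1, 1)."""
        if chromosome in self.compensation:
            return self.compensation[chromosome]
        if chromosome in self.x_chromosomes:
            return Scenario("NONE")
        return Scenario("FULL_MALE_UP")  # factors (1, 1): an ordinary autosome


@dataclass
class GenomeLayout:
    """Scaffold and gene coordinates with ground-truth chromosome labels."""

    scaffolds: pd.DataFrame  # scaffold_id, length, true_chromosome
    genes: pd.DataFrame  # gene_id, chromosome, position, host_scaffold


_STAGE_LAYOUT, _STAGE_COVERAGE, _STAGE_EXPRESSION = 0, 1, 2


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((config.seed, stage))))


def simulate_layout(config: SimulationConfig) -> GenomeLayout:
    """Draw scaffold lengths and place genes on scaffolds, deterministically per seed.

    Scaffold lengths are uniform over ``scaffold_length_range``; genes are
    assigned round-robin to their chromosome's scaffolds with strictly
    increasing positions along the chromosome.
    """
    config.validate()
    rng = _rng(config, _STAGE_LAYOUT)
    scaf_rows = []
    gene_rows = []
    lo, hi = config.scaffold_length_range
    for chrom in config.chromosomes:
        lengths = rng.integers(lo, hi + 1, size=config.scaffolds_per_chromosome)
        scaf_ids = [f"{chrom}_s{i:04d}" for i in range(config.scaffolds_per_chromosome)]
        for sid, length in zip(scaf_ids, lengths):
            scaf_rows.append((sid, int(length), chrom))
        for j in range(config.genes_per_chromosome):
            gene_rows.append(
                (
                    f"{chrom}_g{j:04d}",
                    chrom,
                    (j + 1) * 1000,  # strictly increasing along the chromosome
                    scaf_ids[j % len(scaf_ids)],
                )
            )
    return GenomeLayout(
        scaffolds=pd.DataFrame(scaf_rows, columns=["scaffold_id", "length", "true_chromosome"]),
        genes=pd.DataFrame(gene_rows, columns=["gene_id", "chromosome", "position", "host_scaffold"]),
    )


def _draw_counts(
    rng: np.random.Generator, mean_depth: np.ndarray, lengths: np.ndarray, k: float
) -> np.ndarray:
    """Per-scaffold read-base counts: sum over the scaffold of per-base NB depths.

    Per-base depth is NB with mean ``mean_depth`` and size ``k`` (variance
    mu + mu^2/k); summing L independent bases gives NB(mean*L, k*L), so a
    scaffold's mean depth is the length-standardized NB average. ``k = inf``
    selects Poisson.
    """
    if math.isinf(k):
        return rng.poisson(mean_depth * lengths).astype(float)
    size = k * lengths
    p = size / (size + mean_depth * lengths)  # = k / (k + mean_depth)
    return rng.negative_binomial(size, p).astype(float)


def simulate_coverage(
    layout: GenomeLayout, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate male and female per-scaffold mean depths.

    Per-base depth is negative binomial with size ``dispersion`` (variance
    mu + mu^2/k); a scaffold's read-base count sums its bases and is divided
    by the scaffold length, so mean depth is the length-standardized NB
    average. Female per-base mean depth is ``depth_female`` everywhere; male
    mean depth is halved on true-X scaffolds. Returns ``(coverage_table,
    truth)`` where truth has columns ``scaffold_id, true_chromosome, is_x``.
    """
    config.validate()
    rng = _rng(config, _STAGE_COVERAGE)
    scaf = layout.scaffolds
    lengths = scaf["length"].to_numpy(dtype=float)
    is_x = scaf["true_chromosome"].isin(config.x_chromosomes).to_numpy()
    rows = []
    for sample, depth_factor in (("male", np.where(is_x, 0.5, 1.0)), ("female", 1.0)):
        mean_depth = config.depth_female * depth_factor * np.ones_like(lengths)
        counts = _draw_counts(rng, mean_depth, lengths, config.dispersion)
        rows.append(
            pd.DataFrame(
                {
                    "scaffold_id": scaf["scaffold_id"],
                    "length": scaf["length"],
                    "sample_id": sample,
                    "mean_depth": counts / lengths,
                }
            )
        )
    cov = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(
        {
            "scaffold_id": scaf["scaffold_id"],
            "true_chromosome": scaf["true_chromosome"],
            "is_x": is_x,
        }
    )
    return cov, truth


def simulate_expression(layout: GenomeLayout, config: SimulationConfig) -> pd.DataFrame:
    """Simulate male/female FPKM per gene plus background rows.

    Each gene's baseline is log-normal (``fpkm_log_mean``, ``fpkm_log_sd``
    on the natural-log scale); the chromosome's scenario multiplies it by
    the (female, male) factors; multiplicative measurement noise of
    standard deviation ``measurement_sd`` on the log2 scale (the scale the
    analysis works on) is applied per gene and sample (none when the scale
    is 0, so noise-free ratios equal the scenario factors exactly). Background rows are ``background_n`` exponential draws of
    scale ``background_scale`` per feature class (intron, intergenic) and
    sample.
    """
    config.validate()
    base_seed = config.baseline_seed if config.baseline_seed is not None else config.seed
    rng_base = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence((base_seed, _STAGE_EXPRESSION, 0)))
    )
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence((config.seed, _STAGE_EXPRESSION, 1)))
    )
    genes = layout.genes
    n = len(genes)
    baseline = rng_base.lognormal(config.fpkm_log_mean, config.fpkm_log_sd, size=n)
    factors = np.array(
        [config.scenario_for(c).factors() for c in genes["chromosome"]], dtype=float
    )  # columns: female, male
    rows = []
    for sample, col in (("male", 1), ("female", 0)):
        fpkm = baseline * factors[:, col]
        if config.measurement_sd > 0:
            # multiplicative noise on the log2 scale (the scale the whole
            # analysis works on): factor 2**N(0, sd)
            fpkm = fpkm * np.exp2(rng.normal(0.0, config.measurement_sd, size=n))
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": genes["gene_id"],
                    "chromosome": genes["chromosome"],
                    "position": genes["position"],
                    "sample_id": sample,
                    "fpkm": fpkm,
                    "feature_class": "gene",
                }
            )
        )
    for sample in ("male", "female"):
        for feature_class in ("intron", "intergenic"):
            bg = rng.exponential(config.background_scale, size=config.background_n)
            rows.append(
                pd.DataFrame(
                    {
                        "gene_id": [
                            f"bg_{feature_class}_{i:04d}" for i in range(config.background_n)
                        ],
                        "chromosome": ".",
                        "position": 0,
                        "sample_id": sample,
                        "fpkm": bg,
                        "feature_class": feature_class,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
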