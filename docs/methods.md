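# Methods

## Coverage-based sex-linkage inference

The depth statistic for scaffold *s* is the male/female ratio of mean
per-bp depths, divided by the median ratio over scaffolds assigned to a
user-chosen reference (putatively autosomal) chromosome set, in log2.
Dividing by the reference median makes the statistic invariant to library
size: rescaling either sample's depths by any positive constant leaves
every value unchanged, and the median over reference scaffolds is exactly 0
by construction. X-linked scaffolds are expected at −1 (one copy in males,
two in females); this assumes the Y homolog is degenerate enough that male
reads no longer cross-map, which also holds for a long-established neo-X.
The single-sex variant (for data sets with only male reads) divides male
mean depth by the reference-median male depth; X scaffolds again land near
−1. Scaffolds must be strictly longer than `min_length` (default 1,000 bp),
short scaffolds having unstable depth estimates; scaffolds with zero female
depth are excluded rather than imputed (`pseudo` defaults to 0 — a
pseudo-count would fabricate ratios for missing data).

Classification is either by fixed cuts — X at or below log2(2/3) ≈ −0.585,
autosomal at or above log2(0.8) ≈ −0.322, an explicit ambiguous band
between, bracketing the midpoint of the expected 0/−1 peaks — or by a
two-component Gaussian mixture fitted by EM. The EM is deterministic given
the data: means initialized at the diploid/haploid expectation (0, −1),
both standard deviations at half the sample standard deviation (floored at
0.05), weights at ½. Convergence is an absolute log-likelihood change
below `tol` (1e−8); a component variance under 1e−6 aborts as degenerate
(a tighter floor would let a component collapse onto repeated values); the
log-likelihood is asserted non-decreasing, a decrease indicating a numeric
defect rather than a data property. Components are ordered afterwards so
the low-mean component is "X". Posterior thresholding at
`posterior_cut = 0.95` leaves values with intermediate posteriors
ambiguous rather than forcing a call.

## Homology layer

Hits from translated alignment (PSL 21-column, score = matches −
mismatches − qNumInsert − tNumInsert, or an equivalent simplified TSV) are
reduced to one best hit per query (or per reference gene); score ties
break by longer matched interval, then lexicographically smaller partner
id, making all downstream results independent of input order. Scaffolds
take the chromosome supported by a strict majority of their genes' hits;
a single mapped gene decides alone; exact ties — and, under the default,
plurality-without-majority — are left unassigned (conservative; a
plurality mode is available). Transcript models per reference gene are
built greedily by descending score: a candidate whose footprint on the
gene overlaps any retained transcript by strictly more than 20 bp is
dropped, otherwise concatenated — so an overlap of exactly 20 bp
concatenates, and the top-scoring transcript always survives. Overlap is
measured on reference-gene coordinates. Reciprocal best hits require
mutual best-hit status in both alignment directions and serve as the
ortholog proxy for gene-level X-linkage labels.

## Expression analysis

Per-sample FPKM cutoffs are the 0.95 quantile (linear interpolation) of
that sample's pooled intron + intergenic FPKM — background transcription
defines what "expressed" means; fixed cutoffs (e.g. 0, 1, 10) can be
supplied instead for sensitivity analysis. A gene is kept only if it
exceeds the cutoff in **all** compared samples, which keeps male/female
ratios defined; the expressed set is therefore monotone non-increasing in
any cutoff. Gene ratios are normalized by the median ratio of
reference-chromosome genes, mirroring the coverage normalization and its
invariances. Each chromosome (≥ 2 genes) is tested two-sided against the
pooled reference genes — a reference chromosome is tested against the
*other* reference chromosomes, avoiding self-comparison — and p-values are
Benjamini–Hochberg adjusted across chromosomes (Bonferroni would also be
defensible; BH is the field default for per-chromosome screens).

Calls translate the median normalized log2(M/F) ratio *m* and adjusted
p-value into: FULL when not significant at 0.05 or |*m*| ≤ 0.15; NONE when
significant and *m* ≤ −0.85 (near the uncompensated −1); PARTIAL when
significant and between; OTHER for significant shifts elsewhere
(male-biased or strongly female-deficient units). The compensation
fraction ĉ = 2·2^*m* − 1 inverts the male X expression factor 0.5 + 0.5c
and is clipped to [−1, 1] (*m* > 0 would push it above 1; such units are
male-biased and reported as OTHER). The 0.15/−0.85 bands are artifact
conventions — the underlying biology is a continuum, and ĉ, not the call,
is the quantitative output.

The ancestral comparison normalizes each species' FPKM by its own
reference-chromosome median within the given sex, then takes
log2(norm_focal / norm_proxy) per orthologous gene pair. A unit's values
are rank-tested against the pooled reference-unit values (centered at 0 by
construction); significance stars follow 0.05/0.01/0.001 on adjusted
p-values. Medians are annotated with the notch interval
median ± 1.57·IQR/√n (linear-interpolation quartiles; plotting systems
using Tukey hinges will differ slightly — the 1.57 constant is kept
verbatim). A compensated X that sits below the proxy in both sexes
indicates shared downregulation; a male-only deficit indicates absent or
partial compensation; equality in both sexes with FULL status indicates
male upregulation.

## Rank test

The Mann–Whitney U is computed from mid-ranks. For combined samples of at
most 20 the null is enumerated exactly over all C(n+m, n) labelings of the
pooled values; the two-sided p-value is the null probability of a
deviation |U − nm/2| at least the observed one, which handles ties without
approximation. Larger samples use the tie-corrected normal approximation
with continuity correction. The cutover at 20 keeps enumeration ≤ 184,756
labelings — effectively free — while the approximation is standard above.
Calibration is verified empirically: at n = m = 15 the null rejection rate
at α = 0.05 stays within [0.035, 0.065] over 2,000 replicates.

## Synthetic data generator

The generator emulates the study design the pipeline targets: a genome of
`n_chromosomes` reference chromosomes (default 10, with chr1 the ancestral
X and chr4 the recently added X), scaffolds with uniform lengths
(2–20 kb), genes placed round-robin on their chromosome's scaffolds at
strictly increasing positions.

**Coverage.** Per-base depth is negative binomial with mean
`depth_female` (default 30, a routine resequencing depth) and size
`dispersion` (default 10, variance μ + μ²/k; ∞ selects Poisson),
reflecting Illumina overdispersion. A scaffold's read-base count sums its
bases — NB(μL, kL) — and is divided by length, so a scaffold's mean depth
is the length-standardized NB average and longer scaffolds are less noisy,
as in real data. Males get half the female mean on true-X scaffolds.

**Expression.** Gene baselines are log-normal (natural-log mean 2, sd 1 —
a typical several-decades FPKM spread). Each chromosome's compensation
scenario multiplies the baseline by (female, male) factors: NONE (1, 0.5),
PARTIAL(c) (1, 0.5 + 0.5c), FULL_MALE_UP (1, 1), FULL_BOTH_DOWN(d) (d, d).
Measurement noise is multiplicative, 2^N(0, `measurement_sd`) per gene and
sample — the noise scale is defined in log2 units because the entire
analysis operates on log2 ratios (default 0.4, i.e. ~32% CV). With
`measurement_sd = 0`, male/female ratios equal the scenario factors
exactly, which the tests exploit. Background rows are exponential with
scale 0.3 per feature class and sample — low-level transcriptional noise
well below genic FPKM. A second species sharing `baseline_seed` reuses the
same gene baselines with independent noise, modeling conserved ortholog
expression for the ancestral-proxy analysis.

A master seed drives independent, tagged PCG64 substreams per stage
(layout / coverage / expression baseline / expression noise), so any stage
regenerates independently and identical configs are byte-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: mapping artifacts and repeat-driven coverage
spikes, GC bias, partially degenerate Y homologs inflating male X
coverage, gene-length and count-noise dependence of FPKM uncertainty,
correlated expression within co-regulated blocks, biological variation
between female samples of different stages, and assembly chimerism that
would put genes of different true chromosomes on one scaffold. Recovery
rates on synthetic data are upper bounds on real-data performance.

## Problem sizes and determinism

The test suite and acceptance script run study-scale-but-desk-sized
problems chosen to leave comfortable statistical margins: 1,500 scaffolds
for the coverage study, 400 X + 1,600 autosomal genes per compensation
replicate with 20 replicates per scenario, 200 random instances for
exact-test equivalence, and 2,000 replicates for calibration checks. All
stochastic checks fix their seeds; `scripts/acceptance.py` derives every
seed from its `--seed` argument.

## Known limitations

Consensus assignment cannot separate genuinely chimeric scaffolds from
noise (both look like mixed votes); the coverage classifier cannot detect
Y-linked scaffolds (absent in the female sample, not halved); FPKM is
consumed as given — no attempt is made to model count-level uncertainty,
so very low-expressed genes passing a cutoff of 0 contribute noisy ratios;
and ĉ inverts the median only, saying nothing about gene-level
heterogeneity of compensation, for which the sliding-window tracks are the
intended view.
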