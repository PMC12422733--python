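# Methods

This note documents the statistical models, default parameters, and
numerical choices behind `teconet`, and what the synthetic-data tests
do and do not establish about real data.

## Cross-species scaling by type-I-error calibration

**Model.** Let a conserved feature (a one-to-one orthologous gene, or a
TE subfamily with homologs in both species) have counts x_A, x_B summed
over each species' replicate samples.  If expression per unit length
and per sequenced read is equal in both species up to a species-level
composition factor f, then conditional on the pooled total x_A + x_B
the species-B count is binomial with success probability

    p(f) = f · N_B · L_B / (N_A · L_A + f · N_B · L_B),

where N are library sizes (total mapped reads) and L the per-species
feature lengths (ortholog lengths for genes; consensus lengths for
TEs).  For each candidate f on a grid, every conserved feature is
tested with an exact two-sided binomial test at level α (default 0.05)
and the empirical type-I error t1(f) is the rejected fraction.  The
estimate f* minimizes |t1(f) − α|: at the correct factor, conserved
features should be rejected at exactly the nominal rate.

**Grid.** 401 log2-spaced values spanning 2^±2 around the moment
estimate median(x_B/x_A · L_A/L_B · N_A/N_B) — a 16-fold range with
<0.7% spacing.

**Selection rule.** The deviation curve is minimized on a *set* of grid
values: a flat plateau when counts are small (the exact test cannot
reject anywhere near the truth), or two shoulder points flanking the
truth when counts are large (t1 crosses α on both sides).  Both shapes
are symmetric around the underlying factor, so f* is the grid value
nearest the log-scale midpoint of the near-minimal set (deviation
within 1/n of the minimum, n = conserved features); residual ties break
toward 1.0 (no-change prior).  This reproduces the intuitive answers on
degenerate inputs (identical matrices → 1.0; exactly doubled counts →
2.0) and is more accurate than a raw argmin on stochastic data.

**Exact binomial p-values.** The two-sided p-value follows the
"minlike" convention (sum of all point probabilities not exceeding
that of the observed count), evaluated by a vectorized binary search
on the unimodal pmf.  The implementation agrees with
`scipy.stats.binomtest` to machine precision (tested); the scipy
routine is three orders of magnitude too slow for a 401-point grid
over hundreds of features.

**Library sizes.** `CountMatrix.library_sizes()` uses a `lib_size`
metadata column (total mapped reads, known from alignment) when
present, else column sums.  The distinction matters: the factor is a
*composition* effect of the measured features relative to the whole
library, and is unidentifiable from a matrix whose column sums are
themselves dominated by the measured features.

**Limits.** The binomial null assumes counting noise only.  Replicate-
level biological variability overdisperses the summed counts, inflates
t1 everywhere, and flattens the objective; with log-normal replicate
noise of SD 0.8 (a realistic brain-expression figure) recovery error
grows to ~10–20%.  The recovery and calibration tests therefore run in
the regime the estimator is designed for — Poisson/NB counting noise
with mild (SD 0.2) replicate noise, 500 conserved genes — where
recovery is within ±10% and the rejection rate at f* sits within two
binomial standard errors of α.

## Differential expression

A self-contained negative-binomial Wald test (no external DE package):
median-of-ratios size factors over all-positive features; per-feature
method-of-moments dispersion (floored at 1e-8) from pooled within-group
variances, shrunk 50% toward a fitted a1/μ + a0 mean–dispersion trend;
Wald statistic on ln(μ_B/μ_A) with delta-method variance
(1/μ + φ)/n per group; BH adjustment within each contrast.  A 0.5
pseudo-count keeps fold changes finite when one group is all-zero.
Status calls require |log2FC| ≥ T and adjusted p < 0.05, with T = 1.5
for cross-species contrasts and T = 0.5 for within-species condition
contrasts, where expression differences are smaller.  The test is
antisymmetric under group swap and controls type-I error on null NB
simulations (tested); exact numerical parity with any particular
third-party DE estimator is not claimed.

## Correlation discovery

Pearson correlations are computed on log2(1 + x) of size-factor-
normalized expression — the log transform symmetrizes the attainable
range of negative correlations, which for raw log-normal counts is
bounded well above −1.  BH adjustment pools all gene × TE pairs of one
sample group (positives and negatives together); significance requires
adjusted p < 0.01 and |r| > 0.4 (strict inequalities; |r| = 1 reports
p = 0 exactly).  Features present (> 0) in fewer than 80% of the
group's samples are excluded up front; zero-variance features are
dropped with a warning.

The leave-one-out consensus removes one biological individual (all its
region samples) at a time and retains a pair only if it is significant
*with the same sign* in every subset; r, p, and adjusted p are reported
from the full-sample run.  Matching sign is stricter than significance
alone and is the intended behavior: a link whose direction depends on
one individual is not a reproducible link.

## Permutation nulls and binding evidence

Empirical p-values use the plus-one rule, p = (1 + #{null ≥ obs}) /
(1 + B), one-sided "greater" — the claim under test is an *excess* of
correlations (or overlap).  `random_geneset_null` redraws gene sets of
the focal size from an expressed-gene pool (focal genes excluded) and
recomputes the full correlation pipeline each iteration; all, positive,
and negative significant counts are summarized separately.  Evidence
overlap is Jaccard similarity between the significant pair set and the
binding-evidence pairs restricted to the analyzed universe, against
random pair sets of the same size.  Evidence pairs are compared at
(gene symbol, TE subfamily) granularity; genomic loci are not used.

## Age classes and link classes

Features at or below the age split are young; above it, old.  The
default split of 44.2 Mya corresponds to the emergence of Simiiformes,
the clade restriction of the youngest Alu/SVA subfamilies; the boundary
value itself is young (≤).  A link is young if *either* endpoint is
young, old only if both are old; with the correlation sign this gives
the four classes P-O, P-Y, N-O, N-Y.  Features without an age (elements
that cannot be placed on a branch) are excluded from age-classified
analyses with a warning.  Per-family composition tests compare each TE
family's 4-class counts against all other families pooled (2 × 4
chi-squared); when any expected cell is below 5 the asymptotic p is
replaced by a Monte-Carlo p from 1e5 fixed-margin tables (flag at
p < 0.001).

## Bipartite network analysis

Edges are significant correlations weighted by |r| — Barber's bipartite
configuration null requires nonnegative weights, so the sign lives in
edge metadata and link classes instead.  Barber modularity is

    Q_b = (1/m) Σ_{g,t} (A_gt − k_g d_t / m) δ(c_g, c_t).

Module detection refines several initial partitions by greedy
single-node moves (strict Q_b increase, lexicographic node order,
including detachment to a fresh module) alternated with best-pair
module merges until a full pass changes nothing.  Initializations:
Newman leading-eigenvector communities on the unipartite projection
(nodes sharing a neighbor, weight Σ min(|r|, |r|) over shared
neighbors), all-singletons, one-module, and seeded random partitions.
The leading-eigenvector step uses a dense symmetric eigendecomposition,
so the whole procedure is deterministic given the seed.  The random-
restart budget is size-adaptive (48 restarts for ≤16 nodes, where the
greedy landscape is roughest and restarts are cheap; fewer for larger
networks); on random ≤10-node graphs the detected Q_b equals the
exhaustive maximum over all set partitions (tested on 100 graphs).
Q_b ties are resolved toward partitions that place more nodes in
proper (two-class) modules; modules lacking either class are
meaningless under Q_b and their nodes are flagged unassigned.

Hubs are the intersection of the top-5% lists by degree and by strength
(Σ|r|), ties at the cutoff included — stricter than either list alone.
Module enrichment tests each module × category 2 × 2 table with a
Monte-Carlo Fisher exact test (1e6 fixed-margin tables by default,
two-sided by point-probability ordering, plus-one rule; within ±0.005
of the exact hypergeometric p at 1e5 simulations, tested).

## Species and condition contrasts

Links are compared on the feature universe expressed in *all* species
(presence-filtered per species, then intersected).  Relative to a
reference group, a pair significant in the reference is categorized
with precedence sign_flip (significant with opposite sign in some
comparison group) → conserved (same sign somewhere) → reference-
specific (ns everywhere else); pairs significant only outside the
reference are "other".  Condition-lost links are significant in
control, not in disease, intersected with an externally supplied
reference-specific set — the construction behind "present in healthy
brains of only this species, absent in disease".  Raw sign agreement
without significance is deliberately not merged into these categories.

## Synthetic data

The generator emulates the two study shapes end to end: several species
with few biological individuals each (default 4 + 3 + 3 + 3), grouped
brain regions with a handful of samples per individual and group, or a
single species with control/disease conditions.  Per feature, a
log-normal baseline (SD 1.0 across features) plus per-sample latent
noise (SD 0.8) sets the expression; counts are negative binomial
(dispersion 0.05) with mean ∝ exp(latent) × length/kb × depth ×
species factor, with ±10% per-sample depth jitter; the nominal depth
is recorded as `lib_size` metadata.  Planted gene-TE pairs share a
Gaussian-copula latent factor whose correlation is tuned analytically
so the *observed* log-scale Pearson correlation matches the requested
target after attenuation by counting noise (targets near ±0.9 remain
attainable; the tuning clips at |ρ| = 0.995).  Links can be restricted
to chosen species or conditions; everywhere else the pair is
independent.  Optional low-rank background factors induce the broad
co-expression of real transcriptomes — without them the significant-
correlation count of *any* gene set is essentially zero and
permutation p-values are degenerate at 1.

What the simulations do not model: subfamily copy-number differences
between individuals, mappability artifacts, shared genomic loci between
TEs and genes (which correlate counts mechanically rather than
regulatorily), and batch structure beyond the low-rank factors.
Passing recovery tests therefore demonstrates the statistical machinery
is correct and calibrated, not that real-data discoveries are free of
those confounders.

## Benchmark scenario

`pipeline.planted_benchmark` pairs a four-species dataset (60 genes of
which 30 KRAB-ZNFs, 90 TE subfamilies, 4 + 3 + 3 + 3 individuals, 8
cortex samples each, species factors 1.0/0.9/1.1/1.4) with a
single-species control/disease dataset (23 samples per arm, the shape
of a typical post-mortem cohort).  Thirty links are planted: 20
conserved across species (also present in both condition arms), 6
reference-specific, and 4 reference-specific links additionally absent
from the disease arm.  The full pipeline recovers the planted links
with recall ≥ 0.9 and precision ≥ 0.9, and the reference-specific and
condition-lost sets exactly up to at most one sampling failure
(verified across seeds).  Problem sizes throughout the test suite are
scaled-down versions of the realistic shapes (hundreds rather than
tens of thousands of correlation pairs) chosen to keep the full suite
around a minute; the statistics are size-calibrated, so the bounds
tested are the same ones that apply at scale.
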