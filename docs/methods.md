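# Methods

`nucleotype` implements the computational chain of a comparative study
linking haploid genome size in diatoms to cell size, growth rate, and
global ocean abundance. This note documents the models, the numerical
choices, and what the synthetic-data generators do and do not emulate.

## Genome-size estimation

Two estimators operate on sequencing-depth spectra.

**k-mer spectrum.** A k-mer frequency histogram (count of distinct k-mers
at each depth) has a low-depth error spike (k-mers created by sequencing
errors, concentrated at depths 1–3) and a genomic peak at the per-copy
coverage `C`. The haploid genome size is

    GS = N / (C · p)

with `N` the total number of genomic k-mers (histogram mass `Σ d·count(d)`
at or above the error cutoff) and `p` the ploidy. Estimates are averaged
over k ∈ {17, 19, 21, 23, 25, 27, 29, 31} because longer k-mers collapse
fewer repeats and shift the estimate.

*Error cutoff.* The cutoff is the valley floor before the first strict rise
of a 3-bin moving average of the histogram — smoothing suppresses cutoff
placement at single-bin noise dips, and the plateau-tolerant "first rise"
rule copes with long zero-count stretches between spike and peak. A
spectrum that never rises has no detectable genomic peak and is an error;
one that rises from the first bin has no error spike and the cutoff is the
smallest depth. The cutoff (and thereby the peak) can be overridden, which
stands in for manual peak verification. `N` excludes sub-cutoff k-mers;
whether error k-mers should count toward `N` is a genuine convention choice
and excluding them is standard practice.

*Peak under diploidy.* The peak is the highest-count depth at or above the
cutoff; the homozygous peak is assumed dominant. Heterozygous-peak
disambiguation is out of scope (ploidy is an input).

**Coverage (Lander–Waterman).** With reads mapped to a draft assembly,

    GS = L · N / C

where `L` is read length, `N` mapped reads (or `L·N` supplied directly as
total mapped bases) and `C` the mode of the per-contig mean-coverage
distribution. Transcriptome-derived contig tables go through the same code
path. The mode is the **half-sample mode**: repeatedly keep the narrowest
contiguous window of distinct values carrying at least half the current
mass, resolving a final pair to the heavier value (midpoint on ties). The
mass-based formulation makes the estimate exactly invariant to duplicating
every observation and robust to the right skew that collapsed repeats
impose on coverage distributions.

## Trait construction

**Biovolume.** Cylinder `V = π(d/2)²h`, sphere `V = (π/6)d³`, prolate
spheroid `V = (π/6)d²h`. Cell height is rarely reported; the fallback rules
are `h = d/2` (the standard database convention) or `h = d` (chain-forming
centric genera such as *Skeletonema*).

**Growth.** The maximum specific growth rate µ (h⁻¹) comes from the linear
method: ordinary least-squares slope of ln(RF) against time over every
contiguous window of the fluorescence series, taking the steepest slope
among windows with R² at or above a threshold. Defaults are window = 5
points and R² ≥ 0.95; the method names no tuning, and these values accept
clean exponential phases while rejecting lag and saturation. Windows with a
zero-variance response are assigned R² = 0 (so a flat curve raises a
"no exponential phase" error rather than returning slope 0). Ties go to the
earliest window for determinism. Doubling time is `T_d = ln 2 / µ`, and
replicate doubling times are averaged per strain. (A literal reading of the
source protocol — µ divided by ln 2 — has units of h⁻¹ and cannot be a time
in hours; the dimensionally correct form is implemented.)

**Transformations.** Genome size, doubling time and cell volumes are
log₁₀-transformed; repeat content enters as arcsin(√proportion), the
standard variance stabiliser for proportions (plain arcsin of a percentage
above 1 is undefined); GC percent, temperature and latitude are left
untransformed.

## Phylogenetic comparative statistics

The Brownian covariance of tips `i, j` is the root-to-MRCA shared path
length; Pagel's λ multiplies the off-diagonal, interpolating between a star
phylogeny (λ = 0) and pure Brownian structure (λ = 1). Matrices are built
in sorted-tip-label order and all joins align to that order. Polytomies are
handled naturally by the shared-path definition. Ultrametricity is checked
with relative tolerance 1e-6 (dating software rounds branch lengths).

**PGLS.** `β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y` with `V = λ-scaled covariance`. λ is
profiled by maximum likelihood (not REML, so signal-test likelihoods are
comparable) with bounded Brent search on [0, 1] (tolerance 1e-6, endpoints
checked). Standard errors use `s² = RSS_V/(n−k)`; p-values are two-sided t
with `n−k` df. `r² = 1 − RSS_V/TSS_V`, both computed against the GLS
intercept-only fit in the V-whitened space. Species with missing data are
dropped listwise with a logged warning and the tree pruned before the
covariance is built.

*Numerics.* For an ultrametric tree, `V(λ) = D^{1/2}(λR + (1−λ)I)D^{1/2}`
with `R` the phylogenetic correlation matrix. One eigendecomposition of `R`
makes each λ evaluation O(nk²) instead of O(n³), which is what lets the
calibration studies below run thousands of PGLS fits in seconds. Eigenvalues
are floored at 1e-12.

**Signal.** Pagel's λ signal for one trait profiles λ in the intercept-only
model; the p-value is the χ²₁ likelihood-ratio test of λ = 0 versus λ̂.

**Rank statistics.** Spearman's ρ is the Pearson correlation of average
ranks, with an exact permutation p-value for n ≤ 10 (vectorised full
enumeration; handles ties) and the t approximation above. The Wilcoxon
rank-sum test enumerates all rank assignments exactly for n ≤ 12 (two-sided
p = twice the smaller tail, capped at 1) and otherwise uses the normal
approximation with tie correction and continuity correction.

## Phylogenetic path analysis

Candidate causal structures are DAGs over genome size (GS), minimum cell
volume (CV), doubling time (DT), temperature (TEMP) and GC content (GC).
The shipped registry holds 14 models in three families — null (no GS
effect on DT), direct (a GS→DT edge) and indirect (GS reaches DT only
through CV) — satisfying the documented constraints (direct4: GS→CV,
GS→DT, TEMP→GS, TEMP→DT with GC→GS; direct2 swaps GS→CV for CV→GS;
direct1/direct2 omit GC→GS). Exact published edge lists beyond those
constraints are not recoverable from text, so the remaining models are
reconstructions following the same logic; the registry is a plain-text DAG
file users can replace.

**Basis set.** For every non-adjacent pair (x, y): x ⊥ y given
parents(x) ∪ parents(y). The regression response ("child") is the vertex
that is not an ancestor of the other; when neither is an ancestor, the
later vertex in (lexicographic) topological order responds. Each claim is
tested by PGLS of the child on the other variable plus the conditioning
set, with λ re-estimated per regression; the claim p-value is the two-sided
p of the other variable's slope.

**Fisher's C and CICc.** `C = −2 Σ ln p_i` is χ² with `2k` df under the
model (an empty basis set gives C = 0, p = 1; a claim p of exactly 0 raises
rather than being clamped silently — an infinite C should be loud).
`CICc = C + 2qn/(n−q−1)` with `q` = edges + vertices, the parameter count
of the per-vertex regressions (one slope per edge, one intercept per
vertex); `q` is recorded in every result. Models are ranked by CICc with
weights `exp(−Δ/2)` normalised.

**Path fitting and averaging.** All variables are z-scored; each vertex
with parents is regressed on them by PGLS and the edge coefficient is that
parent's slope with its SE. "Full" averaging zero-fills coefficients of
absent edges; "conditional" renormalises weights over models containing the
edge. Averaged SEs use the unconditional-variance formula (weighted
within-model variance plus weighted squared deviation from the average).

*Calibration.* Simulating traits from a registry model and testing that
same model, Fisher's C at α = 0.05 rejects in ~6% of 1,000 replicates
(60-tip trees), and with standardized effects ≥ 0.5 the generating model
attains ΔCICc < 2 in ~90% of replicates; both are asserted by the
acceptance tests. The mild excess over the nominal 5% reflects per-claim
ML-λ estimation, which is the cited method's own convention.

## Gamma abundance model

Observational layer: OTU counts → per-sample proportions → species sums
per sample (unassigned OTUs dropped, with a logged count; proportions are
computed before dropping, so they remain fractions of the whole sample) →
prevalence filter keeping species detected in ≥ 10 samples (inclusive).

Model: for species i at station s,

    y_si ~ Gamma(α, mean µ_si),   log µ_si = x_s'β + u_i,
    u ~ MVN(0, φ² R),

with `R` the Brownian correlation matrix (λ fixed at 1; the source protocol
names only "a covariance matrix", and unit-diagonal scaling makes the
random-intercept scale φ interpretable). Zero abundances are dropped before
fitting — the gamma has positive support and the source's zero handling is
unstated; this is the package's documented choice. Continuous covariates
are centered except latitude and the response.

Three fixed-effect variants: **temperature** (intercept, centered
temperature, centered log₁₀ genome size g, temperature × g), **region**
(region dummies, g, region × g), **latitude** (cubic B-spline with 8
interior knots at latitude quantiles, g, and spline × g as a
varying-coefficient smooth; a unit-precision ridge prior on spline
coefficients replaces a penalised-GAM smoothness search, fixing the
complexity at an auditable value). Priors are weakly informative:
Normal(0, 5) on coefficients, Normal(0, 1) on spline coefficients,
half-Normal(0, 2) on φ, Exponential(1) on α.

**Sampler.** Adaptive random-walk Metropolis-within-Gibbs with a
non-centered parameterization `u = φ L z` (`L` = Cholesky factor of `R`).
Default run: 2 chains × 10,000 iterations, first half discarded as warmup,
no thinning; all proposal scales adapt only during warmup (Robbins–Monro
toward standard acceptance targets). Blocks per iteration:

1. joint adaptive multivariate RW over the non-ridge fixed effects
   (empirical proposal covariance, Haario-style);
2. per-coordinate RW sweep over all fixed effects via rank-1 updates of
   Xβ — necessary for the correlated region/spline designs;
3. z in sub-blocks of ≤ 10 species;
4. **translation moves**: fixed-effect columns constant within species
   (intercept, genome size) lie in the span of u, so the likelihood sees
   only their sum; the move shifts such a coefficient and compensates z
   along `L⁻¹f/φ`, leaving the likelihood exactly invariant and accepting
   on the prior ratio — this removes the ridge that otherwise freezes
   those coefficients;
5. RW on log φ (non-centered), then an interweaved centered-parameterization
   update of log φ holding `u` fixed — the standard two-parameterization
   remedy for the funnel between φ and z;
6. RW on log α.

Convergence is monitored with split-R̂ per parameter; any R̂ ≥ 1.1 flags the
fit with a prominent warning (the fit is still returned). Sampling is a
pure function of the seed: identical seeds give bit-identical posteriors.

**Summaries.** An effect is "significant" when its 2.5% and 97.5% posterior
quantiles share a sign. Predictions are population-level (u = 0) posterior
means and 95% intervals of µ over a grid — the default temperature grid is
{0, 10, 20, 30} °C crossed with the fitted genome-size range; grids outside
the fitted covariate ranges warn about extrapolation. Bayesian r² per draw
is `var(µ)/(var(µ) + mean(µ²)/α)` with µ including the species effects (the
expected gamma residual variance is µ²/α); the posterior mean is reported.

## Synthetic data

Generators are pure functions of their arguments including a mandatory
seed, and default to the study-scale conditions used throughout the tests.

- `sim_tree`: pure-birth trees rescaled to unit height below the root
  split.
- `sim_traits_dag`: vertices in topological order; each is the
  coefficient-weighted sum of its standardized parents plus a
  phylogenetically correlated Gaussian residual (covariance λ-scaled
  Brownian, unit diagonal) scaled so each vertex has unit variance — the
  coefficients are therefore standardized effects directly comparable to
  fitted path coefficients.
- `sim_kmer_histogram`: genomic peak of `GS·p` distinct k-mers with
  Poisson(depth) counts; errors contribute `error_rate·GS·depth` distinct
  k-mers split 80/15/5 over depths 1–3 (≈ one novel k-mer per errored
  base). Bin counts are Poisson-sampled around expectations.
- `sim_coverage_table`: lognormal contig-length partition of the genome;
  per-contig coverage from Poisson read sampling (tighter for longer
  contigs) with 3% lognormal mapping bias and 5% collapsed-repeat contigs
  at twice the depth.
- `sim_growth_curve`: lag, then logistic growth with multiplicative
  lognormal noise of a given CV.
- `sim_abundance_dataset`: stations with latitude ~ U(−80°, 80°),
  temperature = 28 − 0.3·|lat| + noise (so the latitude, region and
  temperature variants are mutually consistent, as in real ocean
  transects), regions by latitude band; abundances drawn from exactly the
  gamma model above (default truth: interaction −0.5, shape 5, φ = 0.5,
  30 species × 40 stations). With a negative interaction, large-genome
  species are more abundant at cold stations by construction.

What the generators do **not** emulate: read-level data (FASTQ, mapping
artifacts beyond the coverage noise model), OTU sequence content and
placement uncertainty, compositional coupling between species (each
species–station abundance is an independent gamma draw given the model),
spatial autocorrelation between stations, and measurement error in traits.
Passing tests therefore demonstrate correctness of the estimators and
calibration of the inference under the assumed models — not robustness to
violations such as compositionality or biased taxonomic assignment.

## Problem sizes

The test and acceptance workloads use 50–100-tip trees for comparative
statistics, 60 tips × 1,000 replicates for path-analysis calibration,
1 Mb genomes at 30–40× for genome-size recovery, and 30 species × 40
stations with 2 × 10,000 MCMC iterations for the abundance model — sizes
chosen so the full statistical battery (estimator error, type-I rate,
model selection, posterior coverage) runs on a desktop while keeping
Monte-Carlo error comfortably below the tested tolerances.

## Known limitations

- The k-mer peak is an integer depth, so estimates carry a quantisation
  error of order 1/C (≈ 2.5% at 40×); multi-k averaging reduces it.
- Heterozygous k-mer peaks are not modelled or detected.
- ML-λ claim tests make Fisher's C very slightly anticonservative at n = 60
  (see calibration above).
- The latitude variant's spline basis is fixed-complexity; it will
  oversmooth sharply localised latitude effects.
- The abundance model treats station observations as conditionally
  independent given species effects; station random effects are not
  implemented.
- Exact published edge lists of the 14 candidate DAGs are figure-only in
  the source; the registry reconstructs them from the stated constraints.
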