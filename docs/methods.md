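# Methods

## Model and procedure

### Phylogenetic covariance and the PGLS screen

Under Brownian motion with rate sigma^2 on a rooted tree with branch lengths,
the covariance of a trait between tips *i* and *j* is sigma^2 · C_ij, where
C_ij is the path length from the root to the most recent common ancestor of
*i* and *j* (C_ii is the root-to-tip depth). The screen treats each family's
per-species gene count as a continuous response and fits, per family,

    y = X beta + e,   cov(e) = sigma^2 C,
    X = [1, SSD, covariate],   covariate in {log10 mean mass, relative brain size}

by generalized least squares. Numerically, C = L Lᵀ (Cholesky) and OLS is run
on the whitened variables L⁻¹y, L⁻¹X; this equals
beta = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y without forming C⁻¹, and the whole screen is
vectorized across families because X is shared. Per predictor: t = beta/se
with df = n − k, two-sided p from the t distribution, effect size
r = t/√(t² + df), BH adjustment **across families, separately per predictor**
(joint correction across the two predictors is a defensible alternative; the
separate version keeps each predictor's FDR interpretable on its own).

Classification: a family is *expanding* (resp. *contracting*) for a predictor
when its BH-adjusted p < alpha and r > 0 (resp. r < 0). The |r| > 0.3
criterion sometimes used to define expansion is exposed as a secondary
`strong` label rather than a gate, since published effect-size ranges for
such screens extend below it (|r| ≈ 0.24 at n = 124); both readings are
recoverable from the output, and `use_raw_p` switches the gate to raw
p-values. A perfect fit (zero residual variance) is flagged degenerate and
called `ns` — t is undefined there, never infinite.

Missing trait values drop a species for the whole screen (not per family), so
every family is fit on the same species set and BH operates on exchangeable
tests.

### Trait derivation and Rensch's rule

SSD = log2(male mass / female mass); log2 rather than a natural or base-10
log because the ratio scale makes "twice as large" exactly 1. Mean mass is
the arithmetic mean of the sexes. Relative brain size is the residual from
OLS of log10 brain on log10 body mass; residuals sum to zero and are
invariant to rescaling body mass.

Rensch's rule is tested by **major-axis** regression of log10 male on log10
female mass: the slope of the first principal axis of the 2×2 covariance
matrix, which treats the axes symmetrically (swapping them inverts the
slope). The slope-vs-1 test is the standard rotation test: under H0 slope =
b, the residual axis y − b·x is uncorrelated with the fitted axis x + b·y,
so the Pearson correlation between them is tested with
F = r²(n−2)/(1−r²) ~ F(1, n−2). The SSD-vs-size association is additionally
reported as the Pearson (optionally Spearman) correlation of SSD with log10
mean mass. No phylogenetic correction is applied to this test.

### Family inclusion filters

Three rules, each reported per family: presence (count > 0) in at least
⌈threshold · n_species⌉ species (ceiling, because "at least 80%" bounds the
fraction from below); maximum count ≥ 3 somewhere; nonzero variance across
species. Filters run on the species set shared with the tree and trait table,
so prevalence refers to the analyzed species. The filter is idempotent.

### Randomization GO enrichment

Terms are lifted to families by existential linking (any member gene carries
the term). Terms with fewer than `small_go_min` = 50 families are pooled into
an excluded `small_GO` pseudo-term — kept in the map so no term-family edge
is lost, but never tested. The null draws `n_resamples` = 10,000 subsets of
size |focal| from the background **without replacement** (the natural reading
of "random samples from the background set", and the choice that makes each
term's null count exactly hypergeometric, giving an independent closed-form
check of the sampler). Z = (x_obs − null mean)/null SD; p is the upper normal
tail (enrichment only; a two-sided switch exists), BH across testable terms.
A term carried by (almost) every background family has null SD 0; it falls
back to the add-one empirical tail p and is flagged. The background should be
the universe the focal set was selected from — for screen hits, the families
that entered the screen, not all families in the genome.

### Brain expression statistics

Replicates at the same (gene, tissue, stage, sex) are averaged first; all
expression statistics use log2(x + 1) where a transform matters.

*Brain rank.* Per gene, the number of non-brain tissues whose (per-tissue
mean) expression **strictly** exceeds the brain's — ties do not count against
the brain. The statistic depends only on value order, so it is invariant to
monotone transforms. Significance: bootstrap sets of the same size drawn with
replacement from all genes with a brain value;
p = (1 + #{bootstrap mean ≤ observed})/(1 + R), lower tail because a low rank
means brain-biased, add-one so p is never zero.

*Temporal trajectories.* Per stage, mean log2(x+1) expression over a brain
structure group's regions (cortex/subcortex/cerebellum, BrainSpan-style
region codes), then over genes; the slope is OLS over stages. The stage axis
defaults to ordinal position, with a numeric-age option — slopes are only
comparable within one axis convention, and published slope units for such
trajectories are often unstated, so the package asserts nothing that ties the
two conventions together.

*Sex bias.* Per gene, log2((female mean + 1)/(male mean + 1)) at every
(region, stage) of the phase with both sexes; the pseudocount matches the
log2(x+1) convention and guards zero expression. Two-sided one-sample
Wilcoxon signed-rank against zero (exact null for small n without zeros,
normal approximation with continuity correction otherwise; Pratt's treatment
of zero differences), BH across genes within the phase. An all-zero
fold-change vector gets p = 1 by convention and a flag. Prenatal and adult
stages never share samples.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *statistical structure* the pipeline assumes,
with planted truth for scoring:

- `simulate_tree` — pure-birth (Yule) process, unit birth rate, rescaled to
  root depth 1; ultrametric like a time-calibrated tree. The process runs one
  extra exponential waiting time past the last speciation so every branch
  length is strictly positive.
- `simulate_traits` — correlated bivariate Brownian motion of (SSD, log10
  mass): branch increments are N(0, ℓΣ) with
  Σ = [[σ_ssd², ρσ_ssdσ_bm], [·, σ_bm²]]. Defaults σ_ssd = 0.5, σ_bm = 1.0,
  ρ = 0.4, root SSD 0.5, root log10 mass 3.5: on a depth-1 tree this puts
  SSD roughly in the −0.5..3 range observed in mammals, masses from grams to
  tonnes, and a positive SSD–size association of the reported magnitude.
  Male/female masses are back-derived by inverting the SSD and mean-mass
  definitions (f = 2·mean/(1 + 2^ssd), m = f·2^ssd), so the phenotype stage
  round-trips exactly.
- `simulate_family_counts` — latent a_j + b_j·SSD + u, u ~ N(0, σ²C),
  rounded and clipped at 0. Gaussian with phylogenetic covariance *by
  design*: it matches the model the screen fits, so parameter-recovery
  results measure the estimator, not generator mismatch. Defaults
  noise σ = 2 and base count 10 keep clipping rare and counts in a realistic
  single-digit-to-tens range. `effect_for_target_r` converts a desired true
  effect size r* into the coefficient to plant, using the whitened design:
  b = t*·σ·√[(XᵀC⁻¹X)⁻¹]₂₂ with t* = r*√(df/(1−r*²)).
- `simulate_go_annotations` — flat term sets (no DAG), uniform background
  terms, one planted term with controllable overlap with a focal set.
- `simulate_expression` — i.i.d. Gaussian latent log2 signal per
  gene×tissue×stage×sex, planted brain shift and female log2 fold change;
  values reported as 2^latent − 1 so log2(x+1) recovers the latent scale.

Not emulated: extinction, gene-tree/species-tree discordance, non-Gaussian
count processes (a Poisson option would probe robustness, not correctness),
GO DAG structure, expression correlation across tissues or genes, and
measurement error in body masses. Passing tests therefore demonstrate that
the *methods are implemented correctly and are calibrated under their own
assumptions* — not that real gene counts are Gaussian or real annotations
flat.

## Numerical choices

- GLS via Cholesky whitening; rank-deficient designs raise rather than
  pseudo-inverting. Degenerate (zero-residual) fits are flagged, with NaN
  statistics.
- Counts are integers, so screen residuals carry rounding noise
  (variance 1/12, i.i.d.) on top of the tree-structured component; at the
  default noise scale this inflates residual variance by ~2% and leaves null
  p-values uniform to the precision the calibration tests check.
- BH adjustment delegates to statsmodels' `fdr_bh`; tests verify it against a
  literal step-up implementation.
- Major-axis degeneracies: zero covariance with equal variances (circular
  scatter) yields a flagged NaN slope; with unequal variances the axis is
  horizontal/vertical and flagged.
- Enrichment output is made order-invariant by sorting families and terms
  before seeded sampling.
- All stages log input dimensions, filter outcomes and the seed in use, and
  identical (config, seed) runs produce byte-identical output files.

## Test problem sizes

The calibration and recovery checks run at the study's native width —
124 species, 1000 families, 10,000 resamples/bootstraps — which the
vectorized screen and samplers complete in seconds; replicate-based checks
(e.g. Brownian covariance convergence) use 500 replicates on small trees,
where Monte-Carlo error bands are explicit in the assertions.

## Known limitations

- The screen's Gaussian likelihood is an approximation for small counts; no
  phylogenetic Poisson or birth-death (gain/loss) model is provided.
- Brownian motion only: no Pagel's lambda or OU transformation of C.
- Species matching is exact string matching after normalization; no synonym
  resolution.
- The observed-data check of the SSD–size association (r = 0.378 across 124
  mammals) requires the published phenotype table at
  `data/species_phenotypes.tsv`; it is third-party data not shipped with the
  package, and the corresponding test fails with instructions until the file
  is supplied.
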