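# Methods

This note documents the statistical procedures, default parameter values and
numerical choices in quadbird. Module names in parentheses.

## Survey model (`quadbird.survey`)

A study consists of `n` square quadrats of fixed area (default 25 ha, i.e.
500 m × 500 m), each assigned to an urbanization zone (`urban`,
`peri_urban`, `extra_urban`) and described by the hectares of eight
land-cover categories: arable land, continuous urban fabric, discontinuous
urban fabric, green urban areas, inland waters, ligneous crops, road
networks and urban woodlands. Land-cover extents must be non-negative and
sum to the quadrat area within `1e-6` ha; violations raise
`SurveyValidationError` with the offending quadrat named.

Bird counts come from repeated survey sessions (species × quadrat count
matrices). Two derived responses feed the models: per-quadrat species
richness and total abundance, each taken as the **maximum across sessions**
so that both early residents and late-arriving migrants are represented.
Incidence (presence/absence) uses a count threshold of ≥ 1.

## Richness estimation and completeness (`quadbird.richness`)

Incidence frequencies `f1` (species in exactly one quadrat) and `f2` feed:

- **Chao1**: `S_obs + f1²/(2 f2)`; when `f2 = 0` the bias-corrected form
  `S_obs + f1 (f1 − 1) / 2` is used.
- **First-order jackknife**: `S_obs + f1 (n−1)/n`.
- **Second-order jackknife**:
  `S_obs + f1 (2n−3)/n − f2 (n−2)²/(n (n−1))`.
- **Michaelis–Menten**: the species-accumulation curve `S(t)` is averaged
  over 10,000 random quadrat orderings (endpoint pinned at `S_obs`), then
  `S_max` is the intercept of the Eadie–Hofstee linearization, an ordinary
  least-squares fit of `S` on `S/t`. A flat or degenerate curve raises
  `EstimationError` rather than returning a meaningless asymptote.

Completeness is `100 · S_obs / S_hat`, rounded to two decimals — the
rounding is part of the reported quantity, matching how such tables are
conventionally printed.

## Environmental-filtering test (`quadbird.filtering`)

The test statistic is the **C-score**: the mean over unordered species
pairs of `(r_i − s_ij)(r_j − s_ij)`, where `r_i` is species `i`'s quadrat
count and `s_ij` the number of shared quadrats. Environmental filtering
(species sorting into distinct habitats) inflates the C-score, so the test
is **one-sided upper-tail**.

The null model is **fixed–fixed equiprobable**: all 0/1 matrices with the
observed row and column totals, uniformly. Samplers:

- `curveball` (default): repeatedly pick two rows, shuffle the columns in
  their symmetric difference. Uniform on the margin class; implemented as a
  numba-compiled kernel (~0.4 µs/step) with a pure-Python fallback.
- `trial_swap`: classic 2×2 checkerboard swaps, made **lazy** (each step is
  skipped with probability ½) so the chain is aperiodic even on margin
  classes where every proposal succeeds.
- `enumeration`: exhaustive recursion over the margin class, used as an
  exact oracle for small matrices and in tests.

Chain settings: burn-in `10 × fill` steps and thinning `fill` steps, where
`fill` is the number of ones in the matrix — enough steps for every
occurrence to be proposed several times between retained samples, verified
against exhaustive enumeration by chi-square uniformity tests in the suite.

The p-value uses the **add-one (valid) Monte-Carlo estimator**
`(1 + #{C_null ≥ C_obs}) / (m + 1)` with `m = 10,000` null matrices by
default, accompanied by a Clopper–Pearson 95% binomial interval on the
exceedance probability. The default significance level is `alpha = 0.10`,
appropriate for a screening test whose failure is a caution rather than a
hard stop. Type-I calibration over 500 simulated unfiltered communities
gives a rejection rate of 0.10 (tested to ±0.03).

**Interacting-species variant.** To separate habitat filtering from
biotic interactions, a fraction `q` of species is excluded:
`ceil(q · S)` species (capped at `S − 2` so a C-score is still defined)
are removed uniformly at random in each of `n_subsets = 3` independent
draws, the test is run on each reduced matrix, and the **largest** p-value
is reported (the most conservative answer to "does filtering survive the
removal?"). The exclusion scheme and any cap are recorded in the result
metadata.

## Additive models (`quadbird.gam`)

Richness and abundance are modelled as identity-link Poisson additive
models: `E[y] = β0 + Σ_k f_k(x_k)` with `x_k` the hectares of land-cover
category `k`. The identity link keeps effects in "species per hectare"
units; the mean is clamped at `MU_EPS = 1e-6` to keep the Poisson deviance
defined, and the number of clamped observations is reported in the fit
diagnostics.

- **Smooths**: cubic B-splines, 9 basis functions, interior knots at
  quantiles of the predictor, sum-to-zero constrained (so the intercept is
  identified) with a second-difference penalty. `df = 1` reduces exactly to
  a centered linear term; the suite verifies agreement with an independent
  identity-link Poisson GLM to a relative tolerance of `1e-4`.
- **Fitting**: penalized iteratively reweighted least squares with
  step-halving on the penalized deviance. A ridge of `1e-9` on the normal
  equations handles the structural collinearity of compositional land-cover
  data (the eight categories sum exactly to the quadrat area, so with an
  intercept the design is rank-deficient by one; fitted means remain
  identified, individual slopes are identified up to that ridge).
- **Smoothness selection**: each term's penalty λ is tuned by bisection on
  `log10 λ ∈ [−8, 10]` until the term's effective degrees of freedom (trace
  of the corresponding block of the influence matrix) matches the requested
  df within `1e-3`.
- **df selection** (`select_df`): greedy forward search from all-linear,
  raising one term's df at a time (cap 4) while the criterion
  `deviance/φ̂ + 7.5 · total_edf` improves, where φ̂ is the Pearson
  dispersion of the most flexible candidate (floored at 1). The per-edf
  penalty of 7.5 sits between AIC (2) and strict BIC-like values, chosen
  design-stage to keep spurious curvature out of 30-observation fits; the
  suite checks it recovers curved terms and keeps linear worlds linear in
  ≥ 9 of 10 replicates.
- **Reported fit quality**: in-sample `R²` (percent of response variance
  explained) and Pearson dispersion `X² / (n − total_edf)`. On count sums
  of many near-independent Bernoulli detections the richness dispersion is
  typically below 1 (underdispersion), which is expected, not a defect.

Partial responses `f_k(grid) − mean(f_k)` are exported per predictor.
Models serialize to JSON and round-trip exactly.

## Scenarios (`quadbird.scenarios`)

A scenario rewrites the land cover of quadrats in target zones, either by

- **replacement** fractions summing to 1 (the whole quadrat becomes that
  mix), or
- a **delta** in hectares summing to 0 (area-conserving transfer).

Built-in variants, applied to peri- and extra-urban quadrats (expansion)
or urban quadrats (greening):

| variant | change |
|---|---|
| A | 100% continuous urban fabric |
| B | 90% continuous urban fabric + 10% road networks |
| C | 80% + 20% |
| D | 70% + 30% |
| E–H | +1…+4 ha green urban areas, taken from continuous urban fabric |

If a greening donor category has less area than the transfer, the transfer
is clipped to what is available and a warning is raised. Area conservation
is enforced by pinning the residue onto the largest component; a zero delta
short-circuits to the identical record, so identity scenarios produce
bit-exact zero predicted changes.

Predicted change is evaluated with the richness model on baseline and
rewritten land cover; the report gives per-quadrat deltas, their mean and
sample standard deviation (ddof = 1), and the most extreme quadrat. Under a
purely linear model the delta of a replacement scenario depends only on
each quadrat's baseline composition (closed form verified in tests), and
greening deltas are identical across unclipped quadrats — an SD near zero
there is the correct consequence, not a bug.

## Synthetic communities (`quadbird.synthetic`)

The generator produces ground-truthed survey bundles: 10 urban + 20
peri/extra-urban quadrats by default. Land cover is drawn from
zone-conditional Dirichlet distributions (urban quadrats > 60% built
cover) and pinned to sum exactly to the quadrat area. Each of 36 species
gets a response profile over 2–4 land-cover categories (linear, saturating
or unimodal effect shapes); occupancy is
`logit⁻¹(intercept + strength · Σ effects)` with
`filtering_strength = 3.0` by default — calibrated at design time so that
per-quadrat richness (~12 mean, ~19 max) and detected pool (~29/36) match
a realistic 25-ha survey, while `strength = 0` yields exchangeable
(unfiltered) communities for null calibration. Abundance given presence is
zero-truncated Poisson (or negative binomial), thinned by per-session
binomial detection with `p_detect = 0.9`; 15% of species are
second-session-only migrants. All randomness flows through
`numpy.random.SeedSequence` spawning, so communities are reproducible and
independent across seeds.

## Pipeline (`quadbird.pipeline`)

Stages run in scientific order: completeness → filtering → model fit →
partial responses → scenarios. Skipping the filtering stage is refused
unless `acknowledge_unfiltered_modelling` is set, because without evidence
of environmental filtering the land-cover models lack footing; a
non-rejection logs a warning but does not stop the run. The manifest
records a SHA-256 of the canonical configuration (excluding the output
directory, which affects no computed number), the seed and the package
version. Runs are byte-identical for identical configuration and seed.

All default sizes (30 quadrats, 10⁴ accumulation orderings, 10⁴ null
matrices) are desk-scale: the full pipeline runs in well under a minute on
one CPU core.
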