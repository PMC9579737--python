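# Methods

## Scope

`floradyn` implements the quantitative workflow of a multi-year flower-strip
experiment: designing seed assemblages that cross sown species richness
(9 / 14 / 29 species) with sown functional dispersion (low / high), measuring
trait-based diversity from annual percent-cover surveys, standardising
functional dispersion against a name-shuffling null, and relating the
temporal dynamics of the realized communities to their initial
characteristics by AIC-based multimodel inference. A mechanism-level
succession simulator supplies data with the statistical structure the
analysis assumes, so every stage is testable end to end.

## Trait space

Traits are mixed-type: numeric (with units — LDMC in mg·g⁻¹, SLA in
mm²·mg⁻¹, heights and nectar depth in length units, flowering onset as a
calendar week, duration in weeks, Grime C/R scores in percent), ordinal
(nectar amount 0/1/2), categorical (flower colour, UV pattern, leaf
distribution, Raunkiær life form, regeneration strategy) and binary
(extrafloral nectar). Three named presets select analysis subsets: the
plant–arthropod interaction set in a 10- and an 11-trait variant (the wider
one adds the Raunkiær life form; the 11-trait set is the default), and a
9-trait competition set (morphology, phenology, resource-use strategy, with
the Grime C and R scores counted separately).

Four numeric traits with skewed distributions (flowering height, duration
of flowering, flower/inflorescence diameter, nectar depth) are natural-log
transformed before distance computation. The base of the logarithm is a
documented constant; any monotone transform only rescales the trait before
range normalisation.

Pairwise dissimilarity is Gower's coefficient: numeric and ordinal traits
contribute |Δ|/range (ordinal traits are treated as numeric with range
normalisation rather than ranked scores — the simplest defensible reading
for a 0/1/2 scale), categorical and binary traits contribute 0/1 mismatch,
and weights are renormalised per species pair over traits where both
species are non-missing (Gower's original rule). This keeps distances
unbiased under partial missingness — relevant because nectar depth is
available for only ~81% of species. A zero-range numeric trait contributes
0 with a warning; a species pair sharing no measured trait is an error.

Centroid-based metrics need coordinates, so the Gower matrix is realised by
classical principal-coordinates analysis. Mixed-type Gower matrices are
usually non-Euclidean; by default the Cailliez correction (adding the
smallest constant that makes all off-diagonal dissimilarities Euclidean) is
applied and the decomposition redone, matching the reference-implementation
lineage of distance-based FD metrics. A square-root correction and no
correction are selectable; with `correction="none"` negative eigenvalues are
recorded as a warning on the embedding and axes with eigenvalues below
1e-10 of the maximum are dropped. One embedding of the full species pool is
shared by all communities, as in the standard dbFD workflow.

## Community metrics

For abundances `a_i` (percent cover, taken as given — totals above 100 are
legitimate because species cover overlaps; no capping) with `p_i = a_i/Σa`:
Gini–Simpson `D = 1 − Σp²`; Simpson's evenness `E = (1/Σp²)/S` (the
inverse-Simpson form is a configuration choice — the underlying study
screened correlated evenness variants and kept Simpson's); Rao's quadratic
entropy `Q = Σ d_ij p_i p_j`; functional redundancy `FR = D − Q`;
`FDis = Σ p_i ‖x_i − c‖` with `c = Σ p_i x_i` in the embedding; CWM over
species with non-missing values (abundances renormalised, never imputed).

Two Rao conventions are exposed. The default is the linear textbook form,
under which `Q = D` when all distances are 1 and `FR = D − Q ≥ 0` for
`d ∈ [0,1]`. `convention="divc"` uses `d²/2`, the convention of the ade4
`divc` function used by the redundancy framework the redundancy published
values derive from; reproducing those published redundancy magnitudes
(~0.84–0.92) requires this convention, since on Gower distances of the
magnitude implied by the published FDis (~0.2) the linear form would give
`D − Q` near 0.6–0.7.

A subtlety worth knowing: `Q` is exactly invariant to splitting a species
into identical-trait duplicates, but `FDis` computed through a corrected
embedding is only invariant when the dissimilarity matrix is Euclidean —
the Cailliez constant and the truncated negative axes depend on the full
species set. The test suite checks the exact invariance in the Euclidean
case only.

## Null models and SES

The null shuffles species names on the (prepared) trait matrix over a pool
— by default the study-wide species list, not the per-community list, since
the null conditions on observed richness while drawing names from the full
trait matrix; a per-community pool can be passed instead. Each of the
`n_iter = 1000` shuffles yields a null FDis;
`SES = (obs − mean_null)/sd_null`, flagged undefined (not ±∞) when the null
sd is 0. Because a name shuffle merely relabels which embedding row belongs
to which species, null FDis values are computed by permuting rows of the
one shared embedding; a naive implementation that redoes Gower + PCoA per
shuffle is kept in the package as the optimisation contract and the two are
asserted equal in tests. Every result records its seed; a table row can be
recomputed in isolation.

## Assemblage design

The original mixtures were hand-built; the module reproduces the design
logic rather than the species choices: for each of two disjoint dicot lists
(plus a mandatory grass backbone present in every mixture), a best-of-N
random subset search (N = 300 by default) maximises sown FDis for high-FD
cells and minimises it for the low-FD cell at each richness. The returned
set must pass the original verification criteria — every high-FD assemblage
out-disperses the low-FD assemblage of its list, and functional redundancy
increases strictly with richness within the high-FD series (with equal
proportions `D` is fixed by `S`, which makes this ordering reachable) — or
the search fails with the best achieved margin. Seed mixes follow the
equal-seed-number rule: `density/S` seeds·m⁻² per species (240 seeds·m⁻²
default), converted to mass by thousand-seed weight. Measured seed-batch
weights were never published, so fixtures carry synthetic placeholder
weights, flagged as such. Germination-rate correction is out of scope.

## Multimodel inference

Candidates are every marginality-respecting subset of {predictors, time,
predictor×time interactions}: `2^p + 3^p` models for `p` predictors with a
time term (13 for the standard two-predictor analyses), always including
the intercept-only model. Fits are maximum likelihood (never REML, so AICs
are comparable across fixed-effect structures) with plot nested in transect
as random intercepts. Gaussian responses use statsmodels `MixedLM`; its
gradient optimizers often stall at variance-boundary optima, so the fitter
falls back to derivative-free optimizers and keeps the best likelihood.
Poisson responses use an in-package Laplace-approximation fitter (Newton
inner loop for the conditional mode of the random effects, BFGS outer loop
over coefficients and log-standard-deviations, finite-difference observed
information for standard errors); it agrees with `lme4::glmer` to ~1e-2 in
log-likelihood on test fixtures. A flat-grouping option degrades to
OLS/GLM so closed-form oracles apply.

AIC is `−2ℓ + 2k` with `k` counting fixed effects plus variance components
(plus the residual variance for Gaussian fits); whether variance components
are counted is not universal, and this choice is applied consistently so
ΔAIC is unaffected within a family. AICc is available as a flag-free
alternative by computing it from the table. Models with ΔAIC < 4 (strict)
are selected; Akaike weights are renormalised over the selected set; ties
are broken by ascending parameter count then model id. Non-converged
candidates are dropped from ranking with a logged record.

Full (zero-substitution) averaging: each coefficient is averaged over all
selected models with 0 where absent; the averaged standard error is
`Σ w_i sqrt(se_i² + (b_i − b̄)²)` (between-model variance included); 95%
intervals use the normal 1.96 quantile, and the reported `abs_z` is
|estimate|/se of the averaged coefficient. Pseudo-R² for Gaussian mixed
fits is the variance-partition form: marginal
`var_f/(var_f + var_r + var_e)`, conditional adds `var_r` to the numerator;
the Poisson variant is deliberately not implemented (explicit
`NotImplementedError`).

## The succession simulator

The generator is mechanism-level, not distribution-matched: it encodes the
processes the analysis is meant to detect, with all parameters in
`SimConfig` and recorded in output metadata.

* **Layout.** 151-species pool; 8 assemblages × 6 replicate plots (two per
  block, blocks of two transects, 8 plots per transect, globally numbered
  1–48) × 4 annual surveys; equal initial seed proportions. An optional
  missing-year mode surveys only transects 4–6 in year 2, mirroring a
  half-surveyed season.
* **Pool.** Numeric traits from normal/lognormal families bracketing field
  scales (LDMC 100–400 mg·g⁻¹, SLA 5–45 mm²·mg⁻¹, heights in cm, flowering
  weeks), categorical traits with the field level sets, a five-level
  regeneration strategy consistent with the Raunkiær life form, ~19% of
  nectar-depth values missing, and pairwise numeric |r| ≤ 0.70 enforced by
  rejection sampling.
* **Survival.** Each species persists each year with probability
  `logistic(survival_base + redundancy_effect × FR)` where FR is its
  assemblage's sown functional redundancy; annuals (from year 2) and
  biennials (from year 3) receive lifespan penalties and unsown species a
  establishment penalty on the logit scale.
* **Dominance.** Surviving covers multiply by
  `exp(ldmc_dominance × z(LDMC) + N(0, growth_noise))`, shifting dominance
  toward resource-conservative (high-LDMC) species and concentrating
  abundance over time; annuals and biennials receive an early-year growth
  advantage that produces the first-season annual flush.
* **Invasion.** New unsown species arrive as
  `Poisson(μ0 · exp(−γ · FDis_sown))` draws from the pool (a plot's own
  design species cannot re-arrive as colonists), with FDis of the sown
  residents computed on the competition preset — invasion declines with
  realized sown dispersion.
* **Observation.** Latent covers are rescaled to a yearly total-cover
  trajectory, multiplied by lognormal observation noise plus transect and
  plot random intercepts on the log scale, rounded, and dropped below a
  detection threshold. Cover is generated on a latent log scale because it
  is positive and right-skewed. A plot that loses every species stays in
  the output as a zero-cover plot-year.

**Calibration.** Defaults were set against the two field anchors the
simulator is meant to reproduce — mean year-4 sown persistence inside
0.60–0.75, and roughly 60% of first-season cover held by annuals — and an
effect size for the richness-linked buffering of FDis comparable to the
field result (|z| ≈ 4 for the interaction). The interaction is carried
mainly by the dominance-concentration channel: concentration proceeds at
the same rate everywhere, but its effect on FDis depends on the effective
species number, which scales with richness; survival moderation by
redundancy alone cannot produce it, because randomly deleting species does
not change expected FDis. `SimConfig.null_effects()` defines the "no
effects" condition by zeroing the three effect slopes while holding
baseline survival and the invader load at the levels the defaults realize —
naively zeroing the slopes would collapse survival and flood plots with
invaders, changing the null's nuisance structure rather than removing the
signal.

**What the simulator does not emulate:** spatial dispersal and seed-bank
dynamics, weather forcing, interannual management variation, observer
drift, and trait-dependent competitive hierarchies beyond the single LDMC
gradient. Passing recovery tests therefore show that the pipeline detects
effects of the encoded mechanisms at the study's design size — not that the
field estimates themselves are reproduced; the two field-data tests that
would show that require the archived deposit (see README) and report or
skip accordingly.

## Pipeline analyses and problem sizes

The three analyses mirror the study: (1) dynamics of realized FDis
(Gaussian), richness (Poisson) and evenness (Gaussian) against initial
richness (3-level), initial FD (2-level) and time, with two robustness
subsets (medium-richness only; high-FD only); (2) SES of FDis modelled with
survey year as a categorical term (the SES trajectory is not linear in
time), excluding undefined-SES plot-years with a count report; (3) unsown
cover (Gaussian) and unsown richness (Poisson) against initial
characteristics and against realized sown richness and FDis (competition
preset), as two independent multimodel runs per response.

Default problem sizes keep the whole suite desk-scale: the benchmark is the
full study size (48 plots × 4 years, 151-species pool); null-model
calibration uses 200 random communities × 500 shuffles; parameter-recovery
checks use 100 replicate successions on a fixed pool/design set for each of
the effect and null conditions; unit tests use a 60-species pool with 2
replicates. The acceptance script reduces per-plot-year SES iterations to
300 (its calibration summary is a mean over ~190 plot-years, where 300
iterations give ample precision).

## Known limitations

* FDis through a corrected embedding is not exactly subset-consistent for
  non-Euclidean Gower matrices (see above); comparisons should share one
  embedding, as the pipeline does.
* The Poisson Laplace fitter supports random intercepts (nested or crossed
  one-level factors), not random slopes; standard errors come from
  finite-difference observed information and are approximate near variance
  boundaries.
* The design search is stochastic best-of-N; it reproduces the design
  criteria, not any particular species choice, and can fail (with a
  reported margin) on pools whose trait structure cannot separate the FD
  levels.
* Survey plot ids are globally unique (1–48) rather than positional within
  transect, so that (plot, year, species) uniquely keys a record.
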