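# Methods

This note documents the models implemented in `thermoflex`, the assumptions
behind them, what the synthetic-data generator does and does not emulate,
and the numerical choices that were genuinely open.

## Respirometry trace processing

A trace holds time (s, ~1 Hz), the excurrent O2 fraction FeO2, the
STP-corrected flow (ml min^-1), and index ranges flagging animal-absent
baseline segments before and after the animal segment.

**Drift correction.** The analyzer reading drifts with ambient temperature;
the drift is modeled as linear in time between the mean FeO2 of the pre- and
post-baseline segments (anchored at each segment's mean time, held constant
beyond the anchors). This is the simplest model consistent with bracketing
baselines; curvature in the drift is not modeled, so the residual error after
correction scales with the drift's nonlinearity, not its magnitude.

**VO2.** For a dry, CO2-scrubbed excurrent stream with flow metered
downstream, `VO2 = flow * (ref(t) - FeO2(t)) / (1 - FiO2)`, where `ref(t)` is
the drift-corrected reference and FiO2 the nominal incurrent fraction (0.21
for 21% O2 / 79% He). The denominator deliberately uses the nominal fraction:
analyzer drift is an offset in the *reading*, not a change in the supplied
gas, and this choice makes M_sum exactly invariant to any constant offset
applied to FeO2 and both baselines. Samples whose FeO2 exceeds the reference
beyond a small tolerance (1e-4) are flagged and excluded from windows.

**M_sum.** The highest mean over all contiguous windows of the configured
averaging period (default 300 s; window length in samples from the median
sampling interval). Ties break to the earliest window. No effective-volume
(washout) correction is applied by default because chamber volumes are a
rig-specific input; the steady-state value is the documented default.

**QC.** A measurement fails if the absolute baseline drift exceeds
`drift_max` (default 0.005 O2 fraction) or the flow's coefficient of
variation exceeds `flow_cv_max` (default 5%). Both thresholds are explicit
package defaults — the protocols this stage models publish no numbers — and
are echoed into every run log.

## Acclimatization windows and standardization

Window features average each daily weather variable over the k days
*strictly preceding* capture (k = 7..14); the capture day is excluded, taking
"preceding" literally. A missing day raises an error naming the gap — no
silent imputation. Continuous predictors throughout the package are
standardized by centering and dividing by **two** standard deviations (n−1
denominator), which puts them on a scale comparable to binary predictors;
the output has mean 0 and sd 0.5 exactly.

## Field models and reaction norms

For each candidate variable x window, an OLS fit of
`M_sum ~ mass + taxon + var + taxon:var` with the oreganus group as the
reference taxon and predictors standardized on the complete-case subset
actually fitted. AIC includes the Gaussian constant and counts the residual
variance as a parameter (the R convention), so differences match `AIC()`
output there; elevation enters once, window-free, and the null model is
`mass + taxon`. Model choice reports the ΔAIC of the winner against the same
model without the interaction and, when a season column exists, with a season
term added.

Raw-scale reaction norms divide the standardized slope (reference main
effect, plus the taxon's interaction coefficient for non-reference taxa) by
twice the raw variable's sd; the standard error combines the coefficient
covariances. A taxon's thermal-heterogeneity index is the unweighted mean of
the annual temperature range (BIO7) over that taxon's *individuals'* capture
sites — individuals, not unique sites, are the weighting unit. The
flexibility–heterogeneity relation is a simple linear regression of slope on
that index, with an optional leave-one-taxon-out.

## Genotype–environment association

**Filter cascade** (fixed order): mean depth in [5, 50]; minor-allele count
≥ 3; site missingness ≤ 50%; individuals with > 60% missing dropped; site
missingness ≤ 5%; Hardy–Weinberg exact test per species with a site removed
if p < 0.001 in *any* species (the conservative reading). The report counts
removals per step and satisfies input − output = sum of site-step counts.
The HWE test is the exact conditional test: the two-sided p sums the
probabilities of all heterozygote counts no more probable than the observed
one.

**Imputation and PCA.** Missing calls take the species' modal genotype at
the site, ties breaking to the lower dosage code (logged). PCA operates on
the column-centered (not variance-scaled) matrix via SVD; scaling is exposed
as a flag but off by default since centering-only is the common choice for
dosage matrices.

**Partial RDA.** Both the centered genotype matrix and the climate matrix
are residualized on [1, PC1, PC2]; the constrained axes are the SVD of the
fitted values of the multivariate regression of residual genotypes on
residual climate. Raw fractions (conditional, constrained, residual) are of
the total inertia and sum to 1. Adjusted fractions use the Ezekiel
correction applied semipartially — adjusted R² of condition+climate minus
adjusted R² of condition alone — which matches vegan's `RsquareAdj` for
partial ordinations (cross-checked against vegan in the test suite).
Variables are screened by VIF < 5 and greedy correlation pruning at
|r| ≥ 0.70 (the member of the worst pair with the larger mean |r| to all
others is dropped; deterministic).

**Permutation tests.** The model test permutes rows of the residualized
climate matrix, re-residualizes the permuted predictors on the conditioning
basis (without this the permuted predictors leave the reduced space and the
test is anti-conservative), and recomputes the pseudo-F
`(SS_fit/m) / (SS_res/df_res)`; p = (exceedances + 1)/(n_perm + 1). Axis k
is tested marginally by comparing its eigenvalue with the k-th ordered
eigenvalue of the permuted fits — a simplification of vegan's sequential
axis test that shares its null logic. Defaults: 999 model and 299 axis
permutations.

*Caveat (group-level predictors).* When predictors are constant within
populations and between-population structure remains beyond the conditioned
axes, individual-level permutation genuinely rejects: the predictor is
confounded with residual drift structure. This is a property of
genotype–environment association designs, not of the implementation; the
test's nominal size holds for predictors exchangeable at the permutation
unit, and the test suite calibrates it that way.

**Variance partitioning.** The default (marginal) mode reports, per climate
variable, the adjusted R² of a partial RDA constrained on that variable
alone, conditioned on the ancestry axes; under collinearity these do not sum
to the constrained total. A unique (leave-one-out) mode is available.

**Weir–Cockerham θ.** Per-site variance components a (among populations),
b (among individuals within populations), c (within individuals), with the
weighted multi-site estimator `θ = Σa / Σ(a+b+c)` over polymorphic sites,
computed pairwise. Sites monomorphic across a pair contribute nothing. Note
that the estimator's finite-sample correction makes θ slightly *negative*
when two samples are literally identical (the observed among-population
variance is zero while the correction subtracts its expected sampling
share); θ is exactly zero only when the heterozygote fraction equals
4p̄(1−p̄).

## Distances and the partial Mantel test

Genetic distance is F_ST/(1 − F_ST) (small negative θ estimates are clipped
to distance 0); geographic distance is the haversine great circle on a
sphere of radius 6371.0088 km (ellipsoidal effects are far below the
resolution any downstream test uses); environmental distance is the
Euclidean norm over 2-SD standardized, correlation-pruned bioclim variables.
The partial Mantel statistic is the Pearson correlation of the off-diagonal
residuals of A|C and B|C; the null permutes object labels of the first
matrix (rows and columns jointly), re-residualizes, and uses the one-sided
upper tail with the +1 convention. The statistic is symmetric in A and B.

## Acclimation mixed model

ΔM_sum (post − pre) is modeled as
`y = Xβ + Zu + ε`, `u ~ N(0, σ²_u S)`, `ε ~ N(0, σ²_e I)`, with fixed
effects intercept, pre-acclimation mass (2-SD standardized), treatment
(control = 0, cold = 1), T_range (2-SD standardized), and
treatment × T_range; Z maps individuals to populations.

**F_ST covariance.** How pairwise F_ST enters as a "random effect" is the
central modeling gap in this design. The default interpretation builds the
population correlation S from similarity 1 − θ (unit diagonal), projects to
the nearest positive semidefinite matrix by eigenvalue clipping, and
renormalizes the diagonal. An alternative kernel mode,
`exp(-(θ/(1−θ))/λ)`, is available behind a flag; both are labeled
interpretations, not reconstructions.

**Sampler.** A conjugate Gibbs sampler: normal updates for β (prior
N(0, 1e8)) and u, inverse-gamma(1e-3, 1e-3) updates for both variances
(divergent draws are capped at 1e8 and counted). S is inverted through its
eigendecomposition with eigenvalues floored at 1e-8, which keeps the
singular all-ones limit (θ → 0) usable. Defaults run 100,000 iterations with
10,000 burn-in and thinning 100; the full-length 1,000,000-iteration run is
a flag away (`n_iter`). pMCMC is twice the smaller tail probability of a
coefficient crossing zero, floored at 1/n_samples; effective sample sizes
come from the initial-positive-sequence autocorrelation sum. The sampler is
validated against the closed-form diffuse-prior regression posterior (mean
and t-marginal spread) and by credible-interval coverage of planted effects.

**Companion analyses.** Pre-treatment balance models (M_sum and mass against
treatment and against T_range, plus a season check with mass as covariate)
use the same machinery. The flexibility CV is `100 · sd(n−1)/mean` of ΔM_sum
across cold-acclimated individuals per population (undefined and flagged if
the mean is ~0), regressed on T_range separately for cold and control
groups. The control-group comparison is a paired two-sided t-test on
post − pre.

## Synthetic data: what it emulates, and what it does not

Every generator draws from its own deterministic stream derived from the
master seed, so identical configurations reproduce byte-identical outputs
and the generators do not perturb each other.

* **Traces** place a VO2 profile (ramp, plateau at the planted peak for at
  least one averaging window, partial recovery) between two baselines, then
  add linear drift (default 0.05 %O2 h^-1) and Gaussian instrument noise
  (default sd 0.001 %O2, i.e. 1e-5 in O2 fraction) to the O2 fraction. The
  noiseless round trip recovers the planted M_sum exactly; the defaults keep
  the mean recovery error well under 1%.
* **Weather** is a seasonal sinusoid midpoint ± half a daily range, with
  day-to-day Gaussian variation in both (range floored at 0.5 °C), plus
  plausible precipitation, vapor-pressure, radiation, and daylength series.
  It emulates marginal distributions, not weather autocorrelation or spatial
  covariance between sites.
* **Genotypes** draw population allele frequencies from the Balding–Nichols
  beta distribution at the target F_ST (the realized weighted θ calibrates
  to the target within [0.02, 0.08] at 0.05); missingness is
  missing-completely-at-random per site and per-site mean depth is
  gamma-distributed, so the depth/mac/missingness filters have material to
  act on. At adaptive loci the frequency is logit-linear in the standardized
  site environment (effect 2.0 at 200 of 2000 loci by default; frequencies
  clipped to (0.01, 0.99) with a warning). An optional hierarchical layer
  (`clades`, `clade_fst`) draws clade frequencies first and populations
  within clades: this plants deep background structure for the conditioning
  axes to absorb, which is the regime a conditioned ordination assumes — in
  a flat island model a strong cline *is* the leading structure and PC1/PC2
  would absorb the signal itself, making the planted variable unrecoverable
  by construction. Linkage disequilibrium and migration dynamics are not
  simulated.
* **Field data** place two sites per taxon differing in mean daily range,
  draw capture dates across the year, and build
  `M_sum = intercept_taxon + 0.39·(mass − 19 g) + slope_taxon · T_d_range(8-day) + ε`
  with residual sd 0.6 ml O2 min^-1 and planted slopes 0.03–0.30
  ml O2 min^-1 °C^-1 roughly collinear with per-taxon annual temperature
  range — signal sizes at which the 8-day window is identifiable against its
  neighbors (windows differing by one day share most of their days, so
  identifiability rests on the day-to-day variance of the daily range).
* **Acclimation data** plant, on the 2-SD standardized scale the analysis
  recovers, intercept 0 (controls centered on no change), mass effect 0.5,
  treatment effect 0.75, treatment × T_range interaction 0.6, a population
  effect (sd 0.1) drawn with the F_ST-derived covariance, and cold-group
  residual sd 0.35 − 0.3·z(T_range) — the declining-variance structure the
  CV analysis targets, with the mean cold response bounded away from zero so
  the CV stays well defined in every population.

Passing tests on these data demonstrate that each stage recovers the
structure it is built to detect at realistic effect sizes and desk-scale
problem sizes (traces of ~40 min at 1 Hz; 500 field individuals; 5
populations × 20 individuals × 2,000 loci; 95–100 acclimation records); they
do not demonstrate robustness to unmodeled features of real data —
autocorrelated weather, linkage, non-MCAR missingness, non-Gaussian
residuals, or migratory movement between sites.

## Numerical choices and degenerate inputs

* Permutation p-values always use (exceedances + 1)/(n_perm + 1) and are
  reproducible under a fixed seed.
* Window-mean ties break to the earliest start; imputation mode ties to the
  lower genotype code; correlation-pruning ties keep the earlier column.
* Single-population θ is NaN with a warning; monomorphic sites contribute
  zero components; constant vectors are rejected by the standardizer and by
  the Mantel test; a constant response collapses the Gibbs posterior onto
  the intercept.
* The all-ones similarity limit (all θ = 0) is handled by the jittered
  eigeninverse rather than by rejecting the model.
* Problem sizes in tests and the acceptance script (100 trace replicates, 50
  field/GEA replicates, 200 permutation-calibration replicates, 20 mixed-model
  replicates at 1e5 iterations) are the package's chosen desk-scale study
  conditions.

## Known limitations

* The drift and "instantaneous" corrections of the original acquisition
  scripts are not published; the linear-baseline steady-state contract here
  is the documented stand-in, with washout correction left as an explicit
  user input.
* The exact construction by which pairwise F_ST entered the original mixed
  models is unspecified; both implemented covariance modes are
  interpretations and are labeled as such.
* Marginal variance-partition fractions are one of several defensible
  decompositions under collinearity; the unique-fraction mode will disagree
  whenever predictors are correlated.
* Group-constant predictors inflate the permutation test's size whenever
  structure remains beyond the conditioned axes (see the GEA caveat above).
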