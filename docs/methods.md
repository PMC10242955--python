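# Methods

## The model

`riclpm` implements the random-intercept cross-lagged panel model (RI-CLPM)
for K traits measured at T waves, and a within-family extension
(wf-RI-CLPM) for twin pairs.

For person *i*, trait *k* and wave *t*, the observed score decomposes as

    x_ikt = mu_kt + kappa_ik + p_ikt

where `mu_kt` is a wave/trait group mean, `kappa_ik` is a time-invariant
random intercept (stable between-person differences, e.g. genetic and
family-environmental influences with constant effects), and `p_ikt` is the
within-person deviation.  Deviations follow a first-order vector
autoregression across waves,

    p_it = B_t p_i,t-1 + v_it,        v_it ~ N(0, Theta_t),

with carry-over (autoregressive) effects on the diagonal of `B_t` and
cross-lagged effects off it.  Wave-1 deviations are exogenous with free
covariance `Phi_1`; random intercepts have covariance `Psi` and are
uncorrelated with the wave-1 deviations; intercept loadings are fixed to 1
at every wave.  These are the standard identification conventions for the
model class.

In the within-family extension, both members of a twin pair are modelled
jointly.  The stacked deviation vector of the pair evolves as

    [p_i; p_j]_t = [[B_t, G_t], [G_t, B_t]] [p_i; p_j]_{t-1} + innovations,

where `G_t` holds between-sibling lagged paths, constrained equal across
zygosity and across the twin1→twin2 / twin2→twin1 direction (twins are
order-exchangeable).  Within-person parameters (means, `Psi`, `Phi_1`,
`B_t`, `Theta_t`) are shared across both twins and both zygosity groups.
Cross-twin covariance blocks of the intercepts, wave-1 deviations and
innovations are estimated separately for MZ and DZ pairs and constrained
symmetric under twin exchange.  Comparing those blocks across zygosity
identifies genetic and environmental contributions (see "Falconer
decomposition" below).

All implied moments are available in closed form because the latent
structure is acyclic over time; `model_builder` propagates the deviation
covariance recursively through the (stacked) lag matrices and adds the
intercept covariance to every wave-pair cell.

### Degrees of freedom

Model df = (distinct observed moments summed over groups) − (free
parameters, counted as equality groups).  For 4 traits and 3 waves the
unconstrained RI-CLPM has 84 free parameters against 90 moments (df 6); the
time-constrained variant (lags and innovation (co)variances equated across
waves) frees 26 fewer; the wf-RI-CLPM has 196 free parameters against 648
moments over the two zygosity groups (df 452).

## Estimation

Two multivariate-normal likelihood forms:

* **moment form** — the classical ML discrepancy computed from per-group
  sample means and (biased, ML) covariances; exact for complete data and
  also accepts externally supplied summary moments with declared n;
* **casewise FIML** — pattern-grouped full-information likelihood for data
  with missing entries; the saturated model (needed for a comparable
  chi-square) is fitted by an EM algorithm for the unstructured MVN.

Optimization is L-BFGS over the free-parameter vector (equality groups
resolved by substitution), followed by up to four Newton polishing steps
using a central finite-difference Hessian; the same Hessian provides
observed-information standard errors.  Convergence requires an
infinity-norm gradient below 1e-5 at termination (the L-BFGS inner
tolerances are ftol 1e-11 / gtol 1e-9).  Covariance blocks are not
constrained positive definite during optimization: steps yielding a
non-invertible implied covariance are rejected in the line search, but
Heywood-style solutions are permitted and surface in the estimates, which
is deliberate (overdominant variance decompositions, for example, should be
visible rather than bounded away).

Start values are moment-based: means from sample means, intercept variances
from average cross-wave covariances, wave-1 and innovation variances from
the residual variance split, carry-over lags at 0.1, all covariance
off-diagonals at 0 (which guarantees a positive-definite implied covariance
at the start), and cross-twin diagonals from cross-sibling covariances.

Robust (sandwich / scaled chi-square) corrections are not implemented:
chi-square values and standard errors are plain ML, which matters for
misspecified or non-normal data but not for point estimates.

Fit indices follow the usual definitions: AIC = −2ℓ + 2k,
BIC = −2ℓ + k·log N, RMSEA = √G · √(max(χ²−df, 0)/(df·N)) with G the
number of groups (0 when df = 0), CFI = 1 − max(χ²−df,0)/max(χ²_b−df_b,
χ²−df, 0) against the per-group independence baseline (free means and
variances, zero covariances — closed form in both likelihood modes), and
SRMR the n-weighted root mean square of correlation-metric covariance
residuals over the lower triangle including the diagonal, averaged across
groups (the EM-estimated saturated moments stand in for sample moments
under FIML).

## Inference workflow

The comparison pipeline mirrors standard practice for this model family:
fit the full model; Wald-test every lagged path in a declared scope
(within-person cross-lags, or all between-sibling paths); apply
Benjamini–Hochberg FDR (or a nominal threshold) jointly over that family;
fix the non-significant paths to zero in a single pass and refit; also fit
the null model with the whole scope removed; compare the three nested
models by chi-square difference tests.  Design choices worth making
explicit:

* path p-values come from Wald statistics of the full fit, not per-path LR
  tests (scalable, and the natural reading of pruning by path significance);
* the FDR family is all scoped paths of one model jointly, not subdivided
  by lag;
* pruning is a single pass, not iterated re-pruning;
* a negative chi-square difference (possible under separate refits) is
  floored at zero with a warning.

Sex differences are tested by a multi-group variant: every parameter split
by sex versus a nested model with the lag matrices equated across the
sexes (all other parameters still sex-specific), compared by LR test.

## Falconer decomposition

From a converged wf fit, each component's latent twin correlation is its
cross-twin covariance divided by the within-person variance (per random
intercept and per wave-specific residual).  With r_DZ ≥ r_MZ/2 an ACE
parameterization applies: a² = 2(r_MZ − r_DZ), c² = 2r_DZ − r_MZ; otherwise
ADE: a² = 4r_DZ − r_MZ, d² = 2r_MZ − 4r_DZ; e² = 1 − r_MZ in both branches,
which agree at the boundary.  Estimates are reported unclipped, with flags
for negative components and overdominance (d² > 1, typically produced by
near-zero DZ correlations).  The decomposition operates on model-estimated
latent correlations, not raw phenotypic twin correlations, so it applies to
intercepts and to each wave's residual separately.

## The simulator

`simulator` draws data from the wf-RI-CLPM generative process: per-family
intercepts and wave-1 deviations from the zygosity-specific joint Gaussian,
then the stacked autoregression with Gaussian innovations.  Cross-twin
blocks can be derived from biometric shares: for an ACE component the
implied correlations are r_MZ = a² + c², r_DZ = a²/2 + c²; for ADE,
r_MZ = a² + d², r_DZ = a²/2 + d²/4.

`default_parameters` encodes the study-like conditions used throughout the
tests: standardized (unit-variance) traits, random intercepts carrying
about half the variance with positive cross-trait intercept correlations,
carry-over effects 0.2, cross-lags 0.1, sibling paths 0.05, and an additive
ACE structure (a² = 0.6, c² = 0.1) for every component.  Missingness is
completely at random only — enough to exercise FIML, but not a model of any
real attrition mechanism.

What the generator does **not** emulate: ordinal/skewed questionnaire
scores (everything is Gaussian, matching the working model for
z-standardized residuals), rater contrast effects (a possible alternative
explanation for apparent overdominance), informative missingness, age
heterogeneity within waves, and selection effects.  Passing tests therefore
demonstrate correctness of the machinery under the model's own assumptions,
not robustness to their violation.

## Problem sizes in tests and the acceptance script

Chosen as the package's own trade-off between Monte-Carlo error and wall
time: the population-moment oracle uses 10 random parameter sets per model
family in the test suite (5 in the script); cohort-scale lag recovery uses
2 traits, 3 waves, 1,000 MZ + 1,000 DZ families with 20 replicates in the
suite and 15 in the script (mean absolute bias threshold 0.02, pooled 95%
CI coverage against exact binomial bounds); the Falconer round trip uses
50,000 pairs per zygosity with recovery tolerance 0.03 on each share,
averaged over the four components per trait that share generating values;
null-scope pruning uses 10–12 replicates of n = 1,000.  Monte-Carlo
comparisons against closed-form moments use 3.5 standard-error bands.

## Numerical notes and limitations

* Moment-map symmetry is exact by construction; implied covariances are
  symmetrized and checked to 1e-10.
* The wf reduction identity (zero sibling paths and cross-twin blocks
  reproduce the single-person model) holds to < 1e-12 and is tested.
* CSV round trips are bit-exact (floats written at 17 significant digits,
  read with correctly-rounded parsing).
* FIML cost grows with the number of distinct missingness patterns; panels
  with many waves/traits and heavy missingness fit noticeably slower than
  complete data, which uses the moment form automatically.
* Three waves is the minimum; random slopes / latent growth extensions
  would need at least four occasions and are out of scope, as are ordinal
  measurement models and robust (MLR) corrections.
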