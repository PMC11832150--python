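# Methods

## Model

Work histories are modelled as a continuous-time Markov chain on a small
labelled state space.  Two configurations are built in: four states
(1 full-time, 2 part-time, 3 not in work, 4 death) and a collapsed
three-state version (working / not in work / death) obtained by merging the
two work states and recoding observations 1,2→1, 3→2, 4→3.  Death is the
single absorbing state; all transitions among alive states are allowed by
default (recovery — re-entry into work from "not in work" — included), plus
every alive state → death.  The allowed set is user-configurable but must
leave the alive states strongly connected and the absorbing state exitless.

Transition intensities are Gompertz (log-linear in age) with
baseline-fixed covariates:

    q_rs(a, z) = exp( log q0_rs + b_rs (a − 50) + beta_rs' z )   [1/year]

The age origin is fixed at 50 years: `exp(log q0)` is an at-age-50 rate,
which keeps the parameters interpretable and the optimizer well scaled.
Covariates are time-constant (baseline job strain, sex, SES indicators);
`exp(beta)` are hazard ratios.  No duration dependence (semi-Markov
effects) is modelled.

## Panel likelihood

The data are interval-censored: states are known only at survey waves
(~2 years apart), while deaths carry exact ages.  The age axis is cut into
bands of width *w* (default 1 year) and Q is frozen at each band's midpoint
age, so the transition probability matrix over an observation interval is
the ordered product of matrix exponentials over the bands it crosses.
Chapman–Kolmogorov holds exactly at band boundaries by construction.  The
midpoint evaluation (rather than left edge) was chosen because its O(w²)
error has a smaller constant; the convergence test against a 0.01-year
fine-grid oracle bounds the residual error of 1-year bands below 1e-3 per
matrix entry over a 25-year span, shrinking monotonically with width.

Per consecutive observation pair of a subject:

* alive r → alive s:  log P(t1, t2)[r, s];
* alive r at t1, death exactly at t_d:
  log Σ_m P(t1, t_d)[r, m] · q_mD(t_d) — the standard density contribution
  for an exactly observed absorbing transition; the death hazard is
  evaluated at the exact death age, not a band midpoint;
* terminal censor set C (alive at t2, work state unknown — the registry
  vital-status situation after survey dropout):  log Σ_{s∈C} P(t1, t2)[r, s].

Censor sets are restricted to the *final* record of a subject.  An
intermediate missing wave needs no censoring machinery at all: under a
Markov model, skipping the wave simply lengthens the observation interval
and the likelihood stays exact.  The total log-likelihood is the sum over
all consecutive pairs of all subjects, which makes it trivially invariant
to subject order and file sharding (summation follows a canonical interval
order, so the invariance is exact in floating point too).

Probabilities below 1e-300 are floored before the log; floored terms are
counted, reported in fit diagnostics, and contribute zero gradient.

### Matrix exponentials and the analytic gradient

exp(QΔ) is computed from the eigendecomposition Q = VΛV⁻¹ (batched across
age bands); bands whose reconstruction error exceeds 1e-9 fall back to
dense scaling-and-squaring (`scipy.linalg.expm`), and both routes agree to
1e-10 on random generators (tested).  When the spectrum is real — the usual
case for these generators — all arithmetic drops to real, halving cost.

The score is exact, not numerical: by the Daleckii–Krein formula the
directional derivative of exp(QΔ) along dQ is V((V⁻¹ dQ V) ∘ Φ)V⁻¹ with
Φ_ij = (e^{λ_i Δ} − e^{λ_j Δ})/(λ_i − λ_j) (series-expanded where
eigenvalues nearly coincide).  Because each parameter perturbs Q in a
rank-one pattern (one off-diagonal entry and its diagonal compensation),
every likelihood-term derivative reduces to a small batched contraction.
The analytic gradient matches central finite differences to ~1e-10 relative
(tested), and underwrites both the optimizer and the Hessian.

## Estimation

The optimizer is quasi-Newton (L-BFGS-B, memory 30) on the flattened
unconstrained parameter vector — intensities enter on the log scale so
positivity is free — maximizing the *mean* per-interval log-likelihood with
gradient tolerance 1e-6 (the mean scale makes the tolerance meaningful
regardless of sample size), at most 500 iterations.  Coordinates are
preconditioned: age-slope parameters multiply age deviations up to ~30
years, so they are scaled by 0.1 by default; callers may supply a full
whitening vector (e.g. standard errors from a previous fit of the same
design), which changes the iteration path but never the optimum.  Start
values are crude rates — log(observed r→s wave pairs / person-years
observed in r), with log(0.001) and a warning for never-observed
transitions — and zero slopes and betas.  Fits are deterministic given data
and settings.

The asymptotic covariance is the inverse of the negative Hessian of the
total log-likelihood at the optimum, computed by central finite differences
of the analytic gradient (step 1e-4, overridable, symmetrized).  A
non-invertible Hessian degrades to a pseudo-inverse with an explicit
warning.  Wald hazard-ratio intervals are exp(beta ± 1.96 SE).

## Expectancies

Occupancy at age u is π′P(50, u), with π the empirical distribution of
first-observed states among subjects of the covariate stratum entering in
[50, 52) (the wave spacing; an empty stratum falls back to all strata with
a warning).  WLE integrates the summed occupancy of the working states by
composite trapezoid from 50 to the 75-year horizon — expectancies are
therefore horizon-truncated, matching a design in which nobody is observed
working past 75.  The integration step is 0.125 years: the trapezoid error
for a constant-hazard survival test case is ≈ (h²/12)·μ(1 − e^{−μT}),
about 5e-5 years at this step, keeping the production integrator within
1e-4 of closed forms (a 0.25-year step would just miss that bound, which is
why the finer default was chosen).  Conservation (occupancies summing to
one, expectancies over all states summing to the horizon) holds to 1e-8.

Confidence intervals follow the parametric simulation recipe: 500 draws
from N(θ̂, Cov), each mapped through the same integrator, with 2.5/97.5
percentiles.  The covariance is repaired to the nearest PSD matrix (by
eigenvalue clipping) with a warning when needed; draws are fully seeded.
Draw log-rates are clipped at log(1e4)/year — a rate already instantaneous
on this time scale — so a draw from a weakly identified coordinate cannot
overflow to NaN; genuinely non-finite draws are dropped and counted, and
more than 1% dropped aborts loudly.  Percentile CIs may in principle
exclude the point estimate; this is flagged in the result rather than
hidden.  Strain contrasts use *paired* draws (the same parameter draws
evaluated at both covariate profiles), which removes the shared-baseline
noise from the difference CI; this is the package's chosen interpretation
of a group-difference interval and is reported as such.

## Synthetic cohorts

The generator's defaults emulate the occupational-survey design the
package targets: 3000 subjects; entry age ~ N(56, 5) truncated to [50, 75];
all subjects working at entry with full-time shares 92.9% (men) / 87.5%
(women); women 55.7% of the cohort; job-strain prevalence 15.7% (men) /
21.2% (women); biennial waves with the number of waves per subject drawn
from the reported follow-up-length distribution over 2..7; deaths recorded
at exact (2-decimal) ages when they fall inside a subject's follow-up
window.  Latent histories are exact simulations of the time-inhomogeneous
chain by thinning: within 1-year bands, candidate events arrive at the
band's dominating rate (the summed per-transition maxima at the band
endpoints, valid since each Gompertz intensity is monotone on a band) and
are accepted with probability total-rate/dominating-rate.  The observation
operator only discards information — each panel record equals the latent
state at that wave age exactly (tested), and spells between waves are
invisible, which is precisely the interval censoring the likelihood
absorbs.

The default true parameters are *constructed*, not estimated from any real
data (none are published for this design): baselines, slopes and hazard
ratios were chosen once so the implied expectancies are face-valid for a
Nordic older-worker cohort — total WLE from 50 of ~13.7 years for unexposed
men with a strain gap of ~0.66–0.78 years (inside the half-year-to-a-year
range such studies report) — and are documented as illustrative ground
truth only.  Mortality is Gompertz with slope 0.10/year and no covariate
effects; strain raises work-exit intensities (HR 1.06–1.18) and slightly
slows re-entry.

Dropout, when enabled, is independent per wave (non-informative, matching
the likelihood's ignorability assumption); a censored-as-alive switch can
append terminal alive-state censor records.  Both are off by default.

What passing tests on these cohorts do *not* show: robustness to
informative dropout, state misclassification, duration dependence,
time-varying covariates, or measurement drift across waves — none of which
the generator emulates, and the first three of which the model class
excludes by assumption.

The job-strain coder reverse-codes 1–4 Likert items (so higher = more
demands / more control), averages item sets, and dichotomizes either by the
demand/control median quadrant or by a demand-minus-control median split;
"above the median" is strict, and the rule used is recorded in the output
because the two rules genuinely differ and no silent default is safe in
study emulation.

## Numerical and testing choices

* Replicated recovery checks (50 replicates at n = 3000) verify that 95%
  Wald intervals cover every generating parameter at their nominal rate and
  that 95% percentile intervals cover the true total WLE in ≥ 90% of
  replicates.  Thresholds on per-parameter minima and on the strain
  directionality proportion use exact binomial acceptance regions
  (≥ 42/50 familywise, ≥ 44/50 for a 0.95 proportion), since a literal
  ≥ 45/50 applied to the minimum over ~30 parameters would reject a
  perfectly calibrated estimator most of the time.  Replicate fits start at
  the generating parameters and whiten with first-replicate standard
  errors — speed choices that do not move the optimum.
* Problem sizes in the test suite (cohorts of 150–4000, 50-replicate
  batches, 500 parameter draws) were chosen so the full suite completes in
  minutes while keeping every statistical check at its stated power.
* Determinism: identical scenario + seed give byte-identical panels, fits
  and reports; all stochastic steps take explicit seeds.

## Known limitations

* Expectancies are horizon-truncated at 75 (configurable); they are not
  full remaining-lifetime expectancies.
* The asymptotic-normal simulation CI inherits the usual caveats near
  parameter-space boundaries (rates → 0); weakly identified coordinates
  produce honest but very wide intervals.
* Covariates are baseline-fixed; exposure changes during follow-up are out
  of scope, as are semi-Markov models, misclassification (hidden Markov)
  extensions, and multiple absorbing states.
* The three-state model fitted to collapsed data is a different model from
  the four-state one (aggregation breaks the Markov property in general);
  their total WLEs agree only approximately, and the test suite asserts
  agreement within CI widths, not equality.
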