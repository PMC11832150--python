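# worklife

Panel-observed multi-state Markov models of late-career work states, and the
working life expectancies (WLE) they imply.

## The problem

Occupational panel surveys of older workers observe each person's work
status — full-time, part-time, not in work — only every couple of years,
while deaths are exactly dated through registry linkage.  A natural summary
of such data is the *working life expectancy*: the average number of years a
person can expect to spend in paid work beyond a given age (here age 50,
truncated at 75).  Because older workers move in and out of work, WLE has to
come from a model of the transition dynamics, not from a single
retirement-age statistic.

`worklife` implements the standard machinery for this design end to end:

* **Model.**  A continuous-time Markov chain over labelled states (default
  four states: 1 = full-time, 2 = part-time, 3 = not in work, 4 = death,
  with death absorbing; or a collapsed three-state version with a single
  "working" state).  Transition intensities are Gompertz, i.e. log-linear in
  age, with multiplicative covariate effects:

  q_rs(a, z) = exp( log q0_rs + b_rs (a − 50) + β_rs′ z ),

  so `exp(log q0)` is the at-age-50 baseline rate and `exp(β)` are hazard
  ratios (e.g. for job strain or sex).

* **Likelihood.**  Ages are cut into bands (default 1 year) within which Q
  is frozen at the band midpoint; interval transition probabilities are
  ordered products of matrix exponentials, P(a0, a1) = Π_b exp(Q_b Δ_b).
  Alive→alive observation pairs contribute P[r, s]; exactly dated deaths
  contribute the event-time density Σ_m P(t1, t_d)[r, m] q_mD(t_d); terminal
  "alive, state unknown" records contribute censor-set sums.

* **Estimation.**  Quasi-Newton maximization with an exact analytic gradient
  (eigendecomposition-based derivative of the matrix exponential), an
  asymptotic covariance from a finite-difference Hessian, and per-transition
  hazard ratios with Wald intervals.

* **Expectancies.**  State occupancy π′P(50, u) integrated by trapezoid to
  the horizon gives total/full-time/part-time WLE, marginalized over the
  empirical entry-state distribution of each covariate stratum; confidence
  intervals come from 500 parameter draws from the estimator's asymptotic
  multivariate normal, with paired-draw CIs for exposure contrasts.

* **Synthetic cohorts.**  A generator emulating the survey design (entry age
  ~ N(56, 5) truncated to [50, 75], biennial waves, 2–7 waves per subject,
  ~90% full-time at entry, strain prevalence 15.7%/21.2% for men/women,
  exact registry-style death dates) with exact CTMC simulation of the latent
  histories, so every pipeline stage can be validated against known truth.
  It also houses the Karasek demand–control job-strain coder.

## Worked example

```python
import worklife as wl

scenario = wl.default_scenario(n_subjects=800)     # known true parameters
study = wl.make_study_cohort(scenario, seed=42)    # simulate a panel
fit = wl.fit_mle(study.panel, covariates=["strain", "female"])

men_ns = wl.CovariateProfile({"strain": 0, "female": 0})
men_s = wl.CovariateProfile({"strain": 1, "female": 0})
est = wl.wle_confidence_interval(fit, study.panel, men_ns, n_draws=500, seed=7)
diff = wl.paired_wle_difference(fit, study.panel, men_s, men_ns,
                                n_draws=500, seed=7)
```

which prints (via the surrounding script):

```
subjects: 800, observations: 3164
log-likelihood: -1713.86, converged: True
men, no strain: total WLE 13.49 (12.30, 14.99) years
  full-time 11.39, part-time 2.10
strain difference (men): 0.57 (-1.09, 2.98) years
true total WLE (men, no strain): 13.74
```

The fitted total WLE for unexposed men, 13.49 years (95% CI 12.30–14.99),
brackets the generating truth of 13.74 years; the paired-draw strain
difference of 0.57 years is the expected direction but, at only 800
subjects, not yet distinguishable from zero.

A command-line interface mirrors the library:

```sh
worklife simulate --out sim --seed 3 --n-subjects 2000
worklife fit --panel sim/panel.csv --out fit4.json
worklife fit --panel sim/panel.csv --three-state --out fit3.json
worklife report --fit4 fit4.json --fit3 fit3.json --panel sim/panel.csv \
    --out table --seed 8
```

`report` writes the standard WLE table — rows no-strain/strain × sex,
columns total (three-state fit), full-time and part-time (four-state fit),
each cell `point (low, high)` — plus paired-draw strain differences.

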