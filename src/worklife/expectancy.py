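"""State-occupancy curves and working life expectancies (WLE).

Starting from the entry-age state distribution, the occupancy vector at age
``u`` is ``pi' P(start_age, u)`` under the fitted piecewise-constant Gompertz
model.  A state expectancy is the trapezoidal integral of the summed
occupancy of a state subset from the start age to the horizon (default 75
years, the oldest working age the design observes, so expectancies are
horizon-truncated).  The marginal WLE averages over the *empirical*
entry-state distribution of the covariate stratum rather than conditioning
on one initial state.

Confidence intervals follow the parametric-simulation recipe: draw parameter
vectors from the asymptotic multivariate normal N(theta_hat, Cov), recompute
the WLE for each draw (default 500), and report 2.5th/97.5th percentiles.
Draws are fully determined by the seed.  Paired draws (the same parameter
draws evaluated at two covariate profiles) give difference CIs between
exposure groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

from .estimation import FitResult
from .likelihood import AgeGrid, _eig_generators
from .panel_io import PanelDataset
from .state_model import AGE_ORIGIN, CovariateProfile, IntensityParameters

logger = logging.getLogger("worklife")

DEFAULT_HORIZON = 75.0
DEFAULT_STEP = 0.125  # years; trapezoid error is O(step^2), ~5e-5 yr here
ENTRY_BAND = 2.0  # wave spacing: entry band for the initial distribution

# Overflow guard for simulated parameter draws: a transition rate of 1e4/yr
# is already instantaneous on this time scale, so clipping log-rates here
# changes nothing identifiable while keeping exp() finite when a draw from a
# weakly identified coordinate runs wild.
LOG_RATE_CEILING = float(np.log(1e4))

__all__ = [
    "OccupancyCurve",
    "WLEEstimate",
    "occupancy",
    "state_expectancy",
    "entry_state_distribution",
    "marginal_wle",
    "wle_confidence_interval",
    "paired_wle_difference",
]


@dataclass(frozen=True)
class OccupancyCurve:
    """State-occupancy probabilities on an age grid.

    ``occupancy[k, i]`` is the probability of being in internal state ``i``
    at ``ages[k]`` given the start-age distribution.
    """

    ages: np.ndarray
    occupancy: np.ndarray  # (n_ages, S)
    codes: tuple[int, ...]

    def state_column(self, code: int) -> np.ndarray:
        return self.occupancy[:, self.codes.index(code)]


@dataclass
class WLEEstimate:
    """Expected years in each working state (and their union) from
    ``start_age`` to the horizon, for one covariate profile."""

    profile: CovariateProfile
    start_age: float
    horizon: float
    per_state: dict[int, float]
    total: float
    ci_low: dict[str, float] = field(default_factory=dict)
    ci_high: dict[str, float] = field(default_factory=dict)
    n_draws: int = 0
    draws: np.ndarray | None = None  # (n_kept, n_working + 1), total last
    n_dropped: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def quantities(self) -> list[str]:
        return [str(c) for c in sorted(self.per_state)] + ["total"]


# ---------------------------------------------------------------------------
# Batched occupancy over parameter draws
# ---------------------------------------------------------------------------


def _age_steps(start_age: float, horizon: float, step: float) -> np.ndarray:
    if step <= 0:
        raise ValueError("integration step must be positive")
    n = int(np.ceil((horizon - start_age) / step - 1e-9))
    ages = start_age + step * np.arange(n + 1)
    ages[-1] = horizon
    return ages


def _batch_log_rates(
    theta: np.ndarray, template: IntensityParameters, z: np.ndarray, ages: np.ndarray
) -> np.ndarray:
    """log q_t(age) for stacked parameter vectors: (D, n_ages, T)."""
    labels = template.flat_labels()
    trans = template.structure.transitions
    t_index = {key: i for i, key in enumerate(trans)}
    covs = template.covariate_names
    D = theta.shape[0]
    out = np.zeros((D, len(ages), len(trans)))
    age_dev = ages - AGE_ORIGIN
    for j, lab in enumerate(labels):
        t = t_index[lab.transition]
        if lab.kind == "log_q0":
            out[:, :, t] += theta[:, j, None]
        elif lab.kind == "b_age":
            out[:, :, t] += theta[:, j, None] * age_dev[None, :]
        else:
            zi = z[list(covs).index(lab.covariate)]
            out[:, :, t] += theta[:, j, None] * zi
    return out


def _batch_occupancy(
    theta: np.ndarray,
    template: IntensityParameters,
    profile: CovariateProfile,
    start_age: float,
    initial_distribution: np.ndarray,
    grid: AgeGrid,
    step: float,
    horizon: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Occupancy curves for stacked parameter vectors.

    Returns ``(ages, occ)`` with ``occ`` of shape (D, n_ages, S); draws whose
    linear algebra fails come back as NaN rows.
    """
    template.validate_profile(profile)
    space = template.space
    S = space.n
    init = np.asarray(initial_distribution, dtype=float)
    if init.shape != (S,):
        raise ValueError(f"initial distribution must have length {S}")
    if abs(init.sum() - 1.0) > 1e-8 or np.any(init < -1e-12):
        raise ValueError("initial distribution must be a probability vector")
    d_idx = space.index(space.death_code)
    if init[d_idx] > 1e-12:
        raise ValueError("initial distribution puts mass on the absorbing state")

    ages = _age_steps(start_age, horizon, step)
    seg_lists = [grid.segments(a, b) for a, b in zip(ages[:-1], ages[1:])]
    uniq: dict[tuple[int, float], int] = {}
    for segs in seg_lists:
        for band, dt in segs:
            uniq.setdefault((band, round(dt, 12)), len(uniq))
    bands = sorted({b for b, _ in uniq})
    b_local = {b: i for i, b in enumerate(bands)}

    D = theta.shape[0]
    z = np.array([profile[c] for c in template.covariate_names], dtype=float)
    mids = np.array([grid.midpoint(b) for b in bands])
    trans = template.structure.transitions
    t_row = np.array([space.index(r) for r, _ in trans])
    t_col = np.array([space.index(s) for _, s in trans])
    rates = np.exp(
        np.minimum(_batch_log_rates(theta, template, z, mids), LOG_RATE_CEILING)
    )  # (D, B, T)
    Q = np.zeros((D, len(bands), S, S))
    Q[:, :, t_row, t_col] = rates
    didx = np.arange(S)
    Q[:, :, didx, didx] = 0.0
    Q[:, :, didx, didx] = -Q.sum(axis=3)

    bad_draws = np.zeros(D, dtype=bool)
    try:
        lam, V, Vinv, ok = _eig_generators(Q)
    except np.linalg.LinAlgError:
        lam = V = Vinv = None
        ok = np.zeros((D, len(bands)), dtype=bool)

    # transition matrix of every unique (band, dt) piece, per draw
    M = np.empty((len(uniq), D, S, S))
    for (band, dt), k in uniq.items():
        bl = b_local[band]
        if lam is not None:
            M[k] = np.einsum(
                "dij,dj,djk->dik", V[:, bl], np.exp(lam[:, bl] * dt), Vinv[:, bl]
            ).real
        for d in np.where(~ok[:, bl])[0]:
            try:
                M[k, d] = expm(Q[d, bl] * dt)
            except Exception:  # pragma: no cover - defensive
                bad_draws[d] = True

    occ = np.empty((D, len(ages), S))
    v = np.broadcast_to(init, (D, S)).copy()
    occ[:, 0] = v
    for k, segs in enumerate(seg_lists):
        for band, dt in segs:
            v = np.einsum("di,dij->dj", v, M[uniq[(band, round(dt, 12))]])
        occ[:, k + 1] = v
    occ[bad_draws] = np.nan
    return ages, occ


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def occupancy(
    params: IntensityParameters,
    start_age: float,
    initial_distribution: Sequence[float],
    profile: CovariateProfile,
    grid: AgeGrid | None = None,
    step: float = DEFAULT_STEP,
    horizon: float = DEFAULT_HORIZON,
) -> OccupancyCurve:
    """State-occupancy curve ``pi' P(start_age, u)`` on an age grid."""
    grid = grid or AgeGrid()
    theta = params.flatten()[None, :]
    ages, occ = _batch_occupancy(
        theta,
        params,
        profile,
        start_age,
        np.asarray(initial_distribution, dtype=float),
        grid,
        step,
        horizon,
    )
    return OccupancyCurve(ages=ages, occupancy=occ[0], codes=params.space.codes)


def state_expectancy(curve: OccupancyCurve, states: Sequence[int]) -> float:
    """Expected years spent in a subset of states: the trapezoidal integral
    of the summed occupancy over the curve's age range."""
    states = list(states)
    if not states:
        raise ValueError("state subset must not be empty")
    cols = [curve.codes.index(c) for c in states]
    mass = curve.occupancy[:, cols].sum(axis=1)
    return float(np.trapezoid(mass, curve.ages))


def entry_state_distribution(
    data: PanelDataset,
    profile: CovariateProfile | None = None,
    start_age: float = AGE_ORIGIN,
    band: float = ENTRY_BAND,
) -> tuple[np.ndarray, bool]:
    """Empirical distribution of first-observed states in the entry age band
    ``[start_age, start_age + band)``.

    Restricted to subjects matching ``profile`` on its named covariates; if
    that stratum is empty in the band, falls back to all strata (the returned
    flag is True when the fallback was used).
    """
    space = data.space

    def counts(match: bool) -> np.ndarray:
        out = np.zeros(space.n)
        for subj in data.subjects:
            if match and profile is not None:
                if any(
                    subj.profile.get(name) != value for name, value in profile.values
                ):
                    continue
            first = subj.observations[0]
            if first.is_censor_set:
                continue
            if start_age <= first.age < start_age + band:
                code = int(first.state)
                if code not in space.absorbing:
                    out[space.index(code)] += 1
        return out

    c = counts(match=True)
    fallback = False
    if c.sum() == 0:
        c = counts(match=False)
        fallback = True
        logger.warning(
            "entry band empty for the requested stratum; using all strata"
        )
    if c.sum() == 0:
        raise ValueError("no entry-band observations to build an initial distribution")
    return c / c.sum(), fallback


def _expectancies_from_occ(
    ages: np.ndarray, occ: np.ndarray, space, working: list[int]
) -> np.ndarray:
    """Per-draw (working states..., total) expectancies: (D, n_working + 1)."""
    cols = [space.index(c) for c in working]
    per = np.trapezoid(occ[:, :, cols], ages, axis=1)  # (D, n_working)
    total = per.sum(axis=1, keepdims=True)
    return np.concatenate([per, total], axis=1)


def marginal_wle(
    fit: FitResult | IntensityParameters,
    data: PanelDataset | None,
    profile: CovariateProfile,
    start_age: float = AGE_ORIGIN,
    initial_distribution: Sequence[float] | None = None,
    step: float = DEFAULT_STEP,
    horizon: float = DEFAULT_HORIZON,
) -> WLEEstimate:
    """Point estimate of total and per-working-state WLE for one profile.

    The initial distribution defaults to the empirical entry-band state
    distribution of the profile's stratum in ``data``.
    """
    params = fit.params if isinstance(fit, FitResult) else fit
    grid = fit.grid if isinstance(fit, FitResult) else AgeGrid()
    warnings: list[str] = []
    if initial_distribution is None:
        if data is None:
            raise ValueError("either data or an initial distribution is required")
        init, fallback = entry_state_distribution(data, profile, start_age)
        if fallback:
            warnings.append("entry band empty for stratum; used all strata")
    else:
        init = np.asarray(initial_distribution, dtype=float)
    working = sorted(params.space.working)
    ages, occ = _batch_occupancy(
        params.flatten()[None, :], params, profile, start_age, init, grid, step, horizon
    )
    vals = _expectancies_from_occ(ages, occ, params.space, working)[0]
    return WLEEstimate(
        profile=profile,
        start_age=start_age,
        horizon=horizon,
        per_state={c: float(v) for c, v in zip(working, vals[:-1])},
        total=float(vals[-1]),
        warnings=warnings,
    )


def _psd_repaired_draws(
    fit: FitResult, n_draws: int, seed, warnings: list[str]
) -> np.ndarray:
    """MVN(theta_hat, Cov) draws; covariance repaired to nearest PSD (by
    eigenvalue clipping) with a warning when needed."""
    cov = 0.5 * (fit.covariance + fit.covariance.T)
    w, U = np.linalg.eigh(cov)
    if np.any(w < -1e-12 * max(w.max(), 1.0)):
        warnings.append("covariance not PSD; clipped negative eigenvalues")
        logger.warning("covariance repaired to nearest PSD before simulation")
    w = np.clip(w, 0.0, None)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_draws, len(w)))
    return fit.theta[None, :] + (Z * np.sqrt(w)) @ U.T


def wle_confidence_interval(
    fit: FitResult,
    data: PanelDataset | None,
    profile: CovariateProfile,
    start_age: float = AGE_ORIGIN,
    n_draws: int = 500,
    seed: int | None = None,
    initial_distribution: Sequence[float] | None = None,
    step: float = DEFAULT_STEP,
    horizon: float = DEFAULT_HORIZON,
    max_dropped_fraction: float = 0.01,
) -> WLEEstimate:
    """Marginal WLE with percentile CIs from parameter-vector simulation."""
    est = marginal_wle(
        fit, data, profile, start_age, initial_distribution, step, horizon
    )
    if initial_distribution is None:
        init, _ = entry_state_distribution(data, profile, start_age)
    else:
        init = np.asarray(initial_distribution, dtype=float)
    theta = _psd_repaired_draws(fit, n_draws, seed, est.warnings)
    ages, occ = _batch_occupancy(
        theta, fit.params, profile, start_age, init, fit.grid, step, horizon
    )
    working = sorted(fit.params.space.working)
    draws = _expectancies_from_occ(ages, occ, fit.params.space, working)
    keep = np.all(np.isfinite(draws), axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped > max_dropped_fraction * n_draws:
        raise RuntimeError(
            f"{n_dropped}/{n_draws} simulation draws yielded non-finite "
            "expectancies"
        )
    if n_dropped:
        est.warnings.append(f"dropped {n_dropped} non-finite simulation draws")
    draws = draws[keep]
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    names = [str(c) for c in working] + ["total"]
    est.ci_low = {k: float(v) for k, v in zip(names, lo)}
    est.ci_high = {k: float(v) for k, v in zip(names, hi)}
    est.n_draws = n_draws
    est.draws = draws
    est.n_dropped = n_dropped
    point = np.array([est.per_state[c] for c in working] + [est.total])
    outside = (point < lo - 1e-12) | (point > hi + 1e-12)
    if outside.any():
        est.warnings.append(
            "percentile CI excludes the point estimate for: "
            + ", ".join(np.array(names)[outside])
        )
    return est


def paired_wle_difference(
    fit: FitResult,
    data: PanelDataset | None,
    profile_exposed: CovariateProfile,
    profile_reference: CovariateProfile,
    start_age: float = AGE_ORIGIN,
    n_draws: int = 500,
    seed: int | None = None,
    step: float = DEFAULT_STEP,
    horizon: float = DEFAULT_HORIZON,
) -> dict[str, dict[str, float]]:
    """Exposed-minus-reference WLE differences with paired-draw CIs.

    The same parameter draws are evaluated at both profiles, so the CI
    reflects parameter uncertainty in the *contrast*.  Returns, per quantity
    (working-state codes and "total"), the point difference and its 2.5/97.5
    percentile bounds.
    """
    working = sorted(fit.params.space.working)
    names = [str(c) for c in working] + ["total"]
    warnings: list[str] = []
    theta = _psd_repaired_draws(fit, n_draws, seed, warnings)
    results = []
    points = []
    for profile in (profile_exposed, profile_reference):
        init, _ = entry_state_distribution(data, profile, start_age)
        ages, occ = _batch_occupancy(
            theta, fit.params, profile, start_age, init, fit.grid, step, horizon
        )
        results.append(_expectancies_from_occ(ages, occ, fit.params.space, working))
        pt = marginal_wle(fit, data, profile, start_age, None, step, horizon)
        points.append(np.array([pt.per_state[c] for c in working] + [pt.total]))
    diff = results[0] - results[1]
    keep = np.all(np.isfinite(diff), axis=1)
    diff = diff[keep]
    lo = np.percentile(diff, 2.5, axis=0)
    hi = np.percentile(diff, 97.5, axis=0)
    point = points[0] - points[1]
    return {
        name: {
            "difference": float(point[i]),
            "ci_low": float(lo[i]),
            "ci_high": float(hi[i]),
        }
        for i, name in enumerate(names)
    }
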