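"""Maximum-likelihood estimation of the panel multi-state model.

The optimizer works on the flattened unconstrained parameter vector (log
intensities, so positivity is free) and maximizes the *mean* per-interval
log-likelihood with its analytic gradient; quasi-Newton (BFGS) by default.
The asymptotic covariance of theta-hat is the inverse of the negative
Hessian of the *total* log-likelihood, obtained by central finite
differences of the analytic gradient.  A non-invertible Hessian degrades to
a pseudo-inverse with a warning, never silently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .likelihood import AgeGrid, LikelihoodEngine
from .panel_io import PanelDataset
from .state_model import (
    CovariateProfile,
    IntensityParameters,
    StateSpace,
    TransitionIntensity,
    TransitionStructure,
)

logger = logging.getLogger("worklife")

FALLBACK_LOG_Q0 = np.log(0.001)  # start value for never-observed transitions

__all__ = [
    "FitSettings",
    "FitResult",
    "initial_values",
    "fit_mle",
    "hazard_ratios",
]


@dataclass(frozen=True)
class FitSettings:
    """Optimizer and Hessian settings (all overridable).

    ``slope_scale`` preconditions the Gompertz age-slope coordinates, whose
    design values (age deviations from 50, up to ~30) make the raw problem
    ill-conditioned for quasi-Newton updates.
    """

    method: str = "L-BFGS-B"
    gtol: float = 1e-6  # on the gradient max-norm of the mean log-likelihood
    maxiter: int = 500
    hessian_step: float = 1e-4
    slope_scale: float = 0.1


@dataclass
class FitResult:
    """MLE output: parameters, covariance and convergence diagnostics."""

    params: IntensityParameters
    loglik: float
    covariance: np.ndarray
    converged: bool
    n_subjects: int
    n_intervals: int
    grad_max_norm: float
    n_iter: int
    grid: AgeGrid
    warnings: list[str] = field(default_factory=list)

    @property
    def theta(self) -> np.ndarray:
        return self.params.flatten()

    @property
    def param_labels(self) -> tuple[str, ...]:
        return tuple(str(l) for l in self.params.flat_labels())

    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        space = self.params.space
        return {
            "states": [
                {"code": c, "label": l} for c, l in zip(space.codes, space.labels)
            ],
            "absorbing": sorted(space.absorbing),
            "working": sorted(space.working),
            "transitions": {
                f"{r}->{s}": {
                    "log_q0": ti.log_q0,
                    "b_age": ti.b_age,
                    "betas": dict(ti.betas),
                }
                for (r, s), ti in self.params.transitions
            },
            "param_labels": list(self.param_labels),
            "covariance": self.covariance.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_subjects": self.n_subjects,
            "n_intervals": self.n_intervals,
            "grad_max_norm": self.grad_max_norm,
            "n_iter": self.n_iter,
            "grid": {
                "start": self.grid.start,
                "width": self.grid.width,
                "age_max": self.grid.age_max,
            },
            "warnings": list(self.warnings),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, doc: Mapping) -> "FitResult":
        states = sorted(doc["states"], key=lambda d: d["code"])
        space = StateSpace(
            labels=tuple(d["label"] for d in states),
            codes=tuple(int(d["code"]) for d in states),
            absorbing=frozenset(int(c) for c in doc["absorbing"]),
            working=frozenset(int(c) for c in doc["working"]),
        )
        trans = {}
        for key, blk in doc["transitions"].items():
            a, b = key.split("->")
            trans[(int(a), int(b))] = TransitionIntensity(
                blk["log_q0"], blk["b_age"], blk["betas"]
            )
        structure = TransitionStructure(allowed=frozenset(trans))
        params = IntensityParameters(space, structure, trans)
        g = doc["grid"]
        return cls(
            params=params,
            loglik=float(doc["loglik"]),
            covariance=np.asarray(doc["covariance"], dtype=float),
            converged=bool(doc["converged"]),
            n_subjects=int(doc["n_subjects"]),
            n_intervals=int(doc["n_intervals"]),
            grad_max_norm=float(doc["grad_max_norm"]),
            n_iter=int(doc["n_iter"]),
            grid=AgeGrid(g["start"], g["width"], g["age_max"]),
            warnings=list(doc.get("warnings", [])),
        )

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Start values
# ---------------------------------------------------------------------------


def _normalize_covariates(
    structure: TransitionStructure,
    covariates: Sequence[str] | Mapping[tuple[int, int], Sequence[str]] | None,
    space: StateSpace,
) -> dict[tuple[int, int], tuple[str, ...]]:
    """Which covariates enter which transition.

    A plain list applies to every transition between alive states (covariate
    effects on mortality are opt-in via the mapping form).
    """
    out: dict[tuple[int, int], tuple[str, ...]] = {}
    if covariates is None:
        covariates = []
    if isinstance(covariates, Mapping):
        for key in structure.transitions:
            out[key] = tuple(covariates.get(key, ()))
    else:
        names = tuple(covariates)
        for r, s in structure.transitions:
            out[(r, s)] = names if s not in space.absorbing else ()
    return out


def initial_values(
    data: PanelDataset,
    structure: TransitionStructure,
    covariates: Sequence[str] | Mapping | None = None,
) -> IntensityParameters:
    """Crude-rate start values: log_q0 = log( observed r->s wave pairs /
    person-years observed in state r ); slopes and betas start at zero.

    Transitions never observed fall back to ``log(0.001)`` with a warning.
    """
    if data.n_subjects == 0:
        raise ValueError("cannot build start values from an empty dataset")
    space = data.space
    structure.validate(space)
    cov_map = _normalize_covariates(structure, covariates, space)
    pair_counts: dict[tuple[int, int], int] = {k: 0 for k in structure.transitions}
    person_years: dict[int, float] = {c: 0.0 for c in space.alive_codes}
    for _, a, b in data.iter_intervals():
        r = int(a.state)
        person_years[r] += b.age - a.age
        if not b.is_censor_set:
            s = int(b.state)
            if s != r and (r, s) in pair_counts:
                pair_counts[(r, s)] += 1
    trans: dict[tuple[int, int], TransitionIntensity] = {}
    for (r, s) in structure.transitions:
        py = person_years[r]
        n = pair_counts[(r, s)]
        if n > 0 and py > 0:
            log_q0 = float(np.log(n / py))
        else:
            log_q0 = FALLBACK_LOG_Q0
            logger.warning(
                "transition %d->%d never observed; start value log(0.001)", r, s
            )
        trans[(r, s)] = TransitionIntensity(
            log_q0, 0.0, {name: 0.0 for name in cov_map[(r, s)]}
        )
    return IntensityParameters(space, structure, trans)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _fd_hessian(engine: LikelihoodEngine, theta: np.ndarray, step: float) -> np.ndarray:
    """Central finite differences of the analytic gradient, symmetrized."""
    p = len(theta)
    H = np.empty((p, p))
    for j in range(p):
        tp = theta.copy()
        tp[j] += step
        _, gp = engine.value_and_grad(tp)
        tm = theta.copy()
        tm[j] -= step
        _, gm = engine.value_and_grad(tm)
        H[:, j] = (gp - gm) / (2.0 * step)
    return 0.5 * (H + H.T)


def fit_mle(
    data: PanelDataset,
    structure: TransitionStructure | None = None,
    covariates: Sequence[str] | Mapping | None = None,
    grid: AgeGrid | None = None,
    settings: FitSettings | None = None,
    start: IntensityParameters | None = None,
    param_scale: np.ndarray | None = None,
) -> FitResult:
    """Maximize the interval-censored panel log-likelihood.

    ``covariates`` may be a list (applied to every transition between alive
    states) or a mapping ``{(r, s): [names]}`` for per-transition placement.
    ``param_scale`` optionally whitens the optimizer coordinates (e.g. with
    standard errors from a previous fit of the same design); it changes the
    iteration path, never the optimum.
    """
    data.validate()
    settings = settings or FitSettings()
    grid = grid or AgeGrid()
    if structure is None:
        structure = (
            start.structure
            if start is not None
            else TransitionStructure.full(data.space)
        )
    if start is None:
        start = initial_values(data, structure, covariates)
    engine = LikelihoodEngine(data, start, grid)
    n_iv = max(engine.n_intervals, 1)
    theta0 = start.flatten()

    warnings: list[str] = []

    # optimize in a preconditioned space: by default slope coordinates are
    # scaled so a unit move perturbs the likelihood comparably across
    # parameter kinds; an explicit param_scale whitens fully
    if param_scale is not None:
        scale = np.asarray(param_scale, dtype=float)
        if scale.shape != theta0.shape or np.any(~np.isfinite(scale)) or np.any(
            scale <= 0
        ):
            raise ValueError("param_scale must be positive, finite, and match theta")
    else:
        scale = np.array(
            [
                settings.slope_scale if lab.kind == "b_age" else 1.0
                for lab in start.flat_labels()
            ]
        )

    def objective(phi: np.ndarray):
        v, g = engine.value_and_grad(phi * scale)
        return -v / n_iv, -(g * scale) / n_iv

    options = {"gtol": settings.gtol, "maxiter": settings.maxiter}
    if settings.method == "L-BFGS-B":
        options.update({"maxcor": 30, "ftol": 1e-13})
    res = minimize(
        objective,
        theta0 / scale,
        jac=True,
        method=settings.method,
        options=options,
    )
    theta_hat = res.x * scale
    loglik, grad = engine.value_and_grad(theta_hat)
    gmax = float(np.abs(grad / n_iv).max()) if len(grad) else 0.0
    # BFGS may stop on precision loss a hair above gtol at a genuine optimum;
    # accept within a documented factor of 100, with a warning
    converged = bool(res.success) or gmax <= 100.0 * settings.gtol
    if not res.success:
        msg = f"optimizer stopped: {res.message} (grad max-norm {gmax:.2e})"
        warnings.append(msg)
        logger.warning(msg)
    if not converged:
        logger.warning("fit did not converge (grad max-norm %.3e)", gmax)
    if engine.n_floored:
        warnings.append(f"{engine.n_floored} interval probabilities floored")

    H = _fd_hessian(engine, theta_hat, settings.hessian_step)
    neg_H = -H
    try:
        cov = np.linalg.inv(neg_H)
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError("non-positive covariance diagonal")
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(neg_H)
        warnings.append("Hessian not invertible; covariance is a pseudo-inverse")
        logger.warning("Hessian not invertible at the optimum; using pseudo-inverse")
    cov = 0.5 * (cov + cov.T)

    return FitResult(
        params=start.with_flat(theta_hat),
        loglik=float(loglik),
        covariance=cov,
        converged=converged,
        n_subjects=engine.n_subjects,
        n_intervals=engine.n_intervals,
        grad_max_norm=gmax,
        n_iter=int(res.nit),
        grid=grid,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Hazard ratios
# ---------------------------------------------------------------------------


def hazard_ratios(fit: FitResult, covariate: str):
    """Per-transition hazard ratio exp(beta) with a 95% Wald CI for one
    covariate.  Returns a DataFrame with one row per transition carrying
    that covariate."""
    import pandas as pd

    labels = fit.params.flat_labels()
    se = fit.standard_errors()
    rows = []
    for j, lab in enumerate(labels):
        if lab.kind == "beta" and lab.covariate == covariate:
            beta = fit.theta[j]
            lo, hi = beta - 1.96 * se[j], beta + 1.96 * se[j]
            r, s = lab.transition
            rows.append(
                {
                    "transition": f"{r}->{s}",
                    "beta": beta,
                    "se": se[j],
                    "hr": float(np.exp(beta)),
                    "hr_low": float(np.exp(lo)),
                    "hr_high": float(np.exp(hi)),
                }
            )
    if not rows:
        raise KeyError(f"covariate {covariate!r} not present in the fit")
    return pd.DataFrame(rows)
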