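"""State spaces, transition structures and Gompertz transition intensities.

The package models late-career work histories as a continuous-time Markov
chain over a small labelled state space — in the four-state configuration
``1 = full-time, 2 = part-time, 3 = not in work, 4 = death`` — with death the
single absorbing state.  Instantaneous transition intensities are log-linear
in age (a Gompertz form) with multiplicative covariate effects:

    q_rs(a, z) = exp( log_q0_rs + b_rs * (a - 50) + beta_rs . z )

The age origin is fixed at 50 years, so ``exp(log_q0_rs)`` is the at-age-50
baseline rate (per year) and ``exp(beta)`` are hazard ratios.  Covariates are
baseline-fixed binary/numeric values (e.g. job strain, sex).

This module owns the model *structure*: which states exist, which are
absorbing, which count as "working", which instantaneous transitions are
allowed, and how a parameter vector maps to a generator matrix Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

AGE_ORIGIN = 50.0

__all__ = [
    "AGE_ORIGIN",
    "StateSpace",
    "TransitionStructure",
    "CovariateProfile",
    "TransitionIntensity",
    "IntensityParameters",
    "ParamLabel",
    "intensity_matrix",
    "collapse_to_three_state",
    "FOUR_TO_THREE_STATE_MAP",
    "load_model_config",
    "save_model_config",
]


# ---------------------------------------------------------------------------
# State spaces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateSpace:
    """Labelled states with their integer file codes.

    ``absorbing`` holds the code of the single absorbing (death) state;
    ``working`` the codes of the non-absorbing states that count towards
    working life expectancy.
    """

    labels: tuple[str, ...]
    codes: tuple[int, ...]
    absorbing: frozenset[int]
    working: frozenset[int]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.codes):
            raise ValueError("labels and codes must have equal length")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("state codes must be unique")
        if tuple(sorted(self.codes)) != tuple(range(1, len(self.codes) + 1)):
            raise ValueError("state codes must be contiguous from 1")
        if not self.absorbing <= set(self.codes):
            raise ValueError("absorbing codes must be valid state codes")
        if len(self.absorbing) != 1:
            raise ValueError("exactly one absorbing (death) state is required")
        if not self.working <= set(self.codes):
            raise ValueError("working codes must be valid state codes")
        if self.working & self.absorbing:
            raise ValueError("working states must be disjoint from absorbing")

    # -- convenience -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.codes)

    @property
    def death_code(self) -> int:
        return next(iter(self.absorbing))

    @property
    def alive_codes(self) -> tuple[int, ...]:
        return tuple(c for c in self.codes if c not in self.absorbing)

    def index(self, code: int) -> int:
        """Zero-based internal index of a state code."""
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(f"unknown state code {code!r}") from None

    def label_of(self, code: int) -> str:
        return self.labels[self.index(code)]

    @classmethod
    def four_state(cls) -> "StateSpace":
        return cls(
            labels=("full-time", "part-time", "not-in-work", "death"),
            codes=(1, 2, 3, 4),
            absorbing=frozenset({4}),
            working=frozenset({1, 2}),
        )

    @classmethod
    def three_state(cls) -> "StateSpace":
        return cls(
            labels=("working", "not-in-work", "death"),
            codes=(1, 2, 3),
            absorbing=frozenset({3}),
            working=frozenset({1}),
        )


@dataclass(frozen=True)
class TransitionStructure:
    """The set of allowed instantaneous transitions as ordered code pairs."""

    allowed: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        for r, s in self.allowed:
            if r == s:
                raise ValueError(f"self-transition ({r},{s}) is not a transition")

    @property
    def transitions(self) -> tuple[tuple[int, int], ...]:
        """Allowed transitions in a deterministic (sorted) order."""
        return tuple(sorted(self.allowed))

    def validate(self, space: StateSpace) -> None:
        """Check the structure against a state space.

        Requires: all codes valid, no transition out of the absorbing state,
        and the directed graph restricted to non-absorbing states strongly
        connected (recovery is possible from every alive state).
        """
        codes = set(space.codes)
        for r, s in self.allowed:
            if r not in codes or s not in codes:
                raise ValueError(f"transition ({r},{s}) uses unknown state codes")
            if r in space.absorbing:
                raise ValueError(f"transition ({r},{s}) leaves the absorbing state")
        alive = list(space.alive_codes)
        if len(alive) > 1:
            edges = {(r, s) for r, s in self.allowed if s not in space.absorbing}
            for direction in (edges, {(s, r) for r, s in edges}):
                reach = {alive[0]}
                frontier = [alive[0]]
                while frontier:
                    r = frontier.pop()
                    for a, b in direction:
                        if a == r and b not in reach:
                            reach.add(b)
                            frontier.append(b)
                if not set(alive) <= reach:
                    raise ValueError(
                        "alive states are not strongly connected under the "
                        "allowed transitions"
                    )

    @classmethod
    def full(cls, space: StateSpace) -> "TransitionStructure":
        """All pairwise transitions among alive states plus alive -> death."""
        alive = space.alive_codes
        death = space.death_code
        pairs = {(r, s) for r in alive for s in alive if r != s}
        pairs |= {(r, death) for r in alive}
        return cls(allowed=frozenset(pairs))


# ---------------------------------------------------------------------------
# Covariates and parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateProfile:
    """A named map of baseline covariate values (e.g. strain=1, female=0)."""

    values: tuple[tuple[str, float], ...]

    def __init__(self, values: Mapping[str, float] | Iterable[tuple[str, float]]):
        items = dict(values)
        object.__setattr__(
            self, "values", tuple(sorted((k, float(v)) for k, v in items.items()))
        )

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)

    def __getitem__(self, name: str) -> float:
        for k, v in self.values:
            if k == name:
                return v
        raise KeyError(f"unknown covariate {name!r}")

    @property
    def names(self) -> frozenset[str]:
        return frozenset(k for k, _ in self.values)


@dataclass(frozen=True)
class TransitionIntensity:
    """Parameters of one transition: log baseline rate at age 50, Gompertz
    age slope (per year), and covariate log hazard ratios."""

    log_q0: float
    b_age: float = 0.0
    betas: tuple[tuple[str, float], ...] = ()

    def __init__(
        self,
        log_q0: float,
        b_age: float = 0.0,
        betas: Mapping[str, float] | Iterable[tuple[str, float]] = (),
    ):
        object.__setattr__(self, "log_q0", float(log_q0))
        object.__setattr__(self, "b_age", float(b_age))
        object.__setattr__(
            self, "betas", tuple(sorted((k, float(v)) for k, v in dict(betas).items()))
        )

    @property
    def beta_dict(self) -> dict[str, float]:
        return dict(self.betas)

    def log_rate(self, age: float, profile: CovariateProfile) -> float:
        out = self.log_q0 + self.b_age * (age - AGE_ORIGIN)
        for name, b in self.betas:
            out += b * profile[name]
        return out


@dataclass(frozen=True)
class ParamLabel:
    """Identity of one coordinate of the flattened parameter vector."""

    transition: tuple[int, int]
    kind: str  # "log_q0" | "b_age" | "beta"
    covariate: str | None = None

    def __str__(self) -> str:
        r, s = self.transition
        tail = f":{self.covariate}" if self.covariate else ""
        return f"{r}->{s}:{self.kind}{tail}"


@dataclass(frozen=True)
class IntensityParameters:
    """The full parameter set theta: one TransitionIntensity per allowed
    transition, against a fixed state space and transition structure.

    The flattened vector orders transitions by sorted ``(from, to)`` code and,
    within a transition, ``log_q0, b_age`` then betas sorted by name.
    """

    space: StateSpace
    structure: TransitionStructure
    transitions: tuple[tuple[tuple[int, int], TransitionIntensity], ...]

    def __init__(
        self,
        space: StateSpace,
        structure: TransitionStructure,
        transitions: Mapping[tuple[int, int], TransitionIntensity],
    ):
        structure.validate(space)
        trans = dict(transitions)
        if set(trans) != set(structure.allowed):
            missing = set(structure.allowed) - set(trans)
            extra = set(trans) - set(structure.allowed)
            raise ValueError(
                f"parameter blocks must match allowed transitions exactly "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )
        for key, ti in trans.items():
            vals = [ti.log_q0, ti.b_age, *(v for _, v in ti.betas)]
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite parameters for transition {key}")
        object.__setattr__(self, "space", space)
        object.__setattr__(self, "structure", structure)
        object.__setattr__(
            self, "transitions", tuple(sorted(trans.items(), key=lambda kv: kv[0]))
        )

    # -- lookups -----------------------------------------------------------

    def __getitem__(self, key: tuple[int, int]) -> TransitionIntensity:
        for k, v in self.transitions:
            if k == key:
                return v
        raise KeyError(f"transition {key} is not allowed")

    @property
    def covariate_names(self) -> tuple[str, ...]:
        names: set[str] = set()
        for _, ti in self.transitions:
            names.update(k for k, _ in ti.betas)
        return tuple(sorted(names))

    def validate_profile(self, profile: CovariateProfile) -> None:
        needed = set(self.covariate_names)
        given = set(profile.names)
        if needed - given:
            raise KeyError(f"profile missing covariates {sorted(needed - given)}")
        if given - needed:
            raise KeyError(f"profile has unknown covariates {sorted(given - needed)}")

    # -- flattening --------------------------------------------------------

    def flat_labels(self) -> tuple[ParamLabel, ...]:
        labels: list[ParamLabel] = []
        for key, ti in self.transitions:
            labels.append(ParamLabel(key, "log_q0"))
            labels.append(ParamLabel(key, "b_age"))
            for name, _ in ti.betas:
                labels.append(ParamLabel(key, "beta", name))
        return tuple(labels)

    def flatten(self) -> np.ndarray:
        out: list[float] = []
        for _, ti in self.transitions:
            out.append(ti.log_q0)
            out.append(ti.b_age)
            out.extend(v for _, v in ti.betas)
        return np.asarray(out, dtype=float)

    def with_flat(self, theta: np.ndarray) -> "IntensityParameters":
        """Rebuild parameters from a flattened vector with this layout."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(self.flat_labels()),):
            raise ValueError(
                f"expected a vector of length {len(self.flat_labels())}, "
                f"got shape {theta.shape}"
            )
        new: dict[tuple[int, int], TransitionIntensity] = {}
        i = 0
        for key, ti in self.transitions:
            log_q0 = theta[i]
            b_age = theta[i + 1]
            i += 2
            betas = {}
            for name, _ in ti.betas:
                betas[name] = theta[i]
                i += 1
            new[key] = TransitionIntensity(log_q0, b_age, betas)
        return IntensityParameters(self.space, self.structure, new)

    # -- the generator matrix ---------------------------------------------

    def intensity_matrix(self, age: float, profile: CovariateProfile) -> np.ndarray:
        """Generator matrix Q (1/year) at a given age for a covariate profile.

        Off-diagonal ``Q[r,s] = q_rs(age, z)`` for allowed transitions, zero
        otherwise; diagonals make rows sum to zero; the absorbing row is zero.
        """
        if age < AGE_ORIGIN:
            raise ValueError(f"age {age} is below the model origin {AGE_ORIGIN}")
        self.validate_profile(profile)
        S = self.space.n
        Q = np.zeros((S, S))
        for (r, s), ti in self.transitions:
            Q[self.space.index(r), self.space.index(s)] = np.exp(
                ti.log_rate(age, profile)
            )
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


def intensity_matrix(
    params: IntensityParameters, age: float, profile: CovariateProfile
) -> np.ndarray:
    """Module-level alias for :meth:`IntensityParameters.intensity_matrix`."""
    return params.intensity_matrix(age, profile)


# ---------------------------------------------------------------------------
# Collapsing four states to three
# ---------------------------------------------------------------------------

#: Study recoding when full- and part-time work are merged into "working".
FOUR_TO_THREE_STATE_MAP = {1: 1, 2: 1, 3: 2, 4: 3}


def collapse_to_three_state(space4, structure4, data4=None):
    """Merge full-time and part-time work into a single "working" state.

    Observation records are relabelled ``1,2 -> 1``, ``3 -> 2``, ``4 -> 3``;
    transitions inside the merged pair are dropped.  ``data4`` may be omitted
    to collapse only the model structure.

    Returns ``(space3, structure3, data3)`` (``data3 is None`` when no data
    were given).
    """
    four = StateSpace.four_state()
    if (space4.codes, space4.absorbing, space4.working) != (
        four.codes,
        four.absorbing,
        four.working,
    ):
        raise ValueError("collapse_to_three_state requires the four-state space")
    space3 = StateSpace.three_state()
    mapping = FOUR_TO_THREE_STATE_MAP
    pairs = {
        (mapping[r], mapping[s])
        for r, s in structure4.allowed
        if mapping[r] != mapping[s]
    }
    structure3 = TransitionStructure(allowed=frozenset(pairs))
    structure3.validate(space3)
    data3 = None
    if data4 is not None:
        data3 = data4.relabel(mapping, space3)
    return space3, structure3, data3


# ---------------------------------------------------------------------------
# Model configuration files
# ---------------------------------------------------------------------------


def _structure_to_strings(structure: TransitionStructure) -> list[str]:
    return [f"{r}->{s}" for r, s in structure.transitions]


def save_model_config(
    path,
    space: StateSpace,
    structure: TransitionStructure,
    covariates: Sequence[str] = (),
    grid: Mapping[str, float] | None = None,
) -> None:
    """Write a model configuration (states, transitions, covariates) as YAML."""
    doc = {
        "states": [
            {"code": c, "label": l} for c, l in zip(space.codes, space.labels)
        ],
        "absorbing": sorted(space.absorbing),
        "working": sorted(space.working),
        "transitions": _structure_to_strings(structure),
        "covariates": list(covariates),
    }
    if grid:
        doc["grid"] = dict(grid)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model_config(path):
    """Read a model configuration written by :func:`save_model_config`.

    Returns ``(space, structure, covariates, grid_kwargs)``.
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    states = sorted(doc["states"], key=lambda d: d["code"])
    space = StateSpace(
        labels=tuple(d["label"] for d in states),
        codes=tuple(int(d["code"]) for d in states),
        absorbing=frozenset(int(c) for c in doc["absorbing"]),
        working=frozenset(int(c) for c in doc["working"]),
    )
    pairs = set()
    for item in doc["transitions"]:
        a, b = str(item).split("->")
        pairs.add((int(a), int(b)))
    structure = TransitionStructure(allowed=frozenset(pairs))
    structure.validate(space)
    covariates = [str(c) for c in doc.get("covariates", [])]
    grid_kwargs = {k: float(v) for k, v in (doc.get("grid") or {}).items()}
    return space, structure, covariates, grid_kwargs
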