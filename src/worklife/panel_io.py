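"""Reading, validating, writing and summarizing long-format panel data.

A panel file is a UTF-8 CSV with header ``subject_id,age,state`` plus one
column per baseline covariate.  Each row is one observation of one subject:
a continuous age in years (stored to 2 decimal places) and either an exact
state code, or — only as the final record of a subject — a censor set of
candidate alive states written ``"1|2|3"`` (work status unknown but the
subject is known to be alive, e.g. from registry vital status after survey
dropout).  Death rows carry the absorbing code and the exact age at death.

Intermediate missing waves need no censor coding: under a Markov model a
skipped wave simply lengthens the observation interval, which is exact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .state_model import StateSpace

AGE_MIN = 50.0
AGE_MAX = 110.0

__all__ = [
    "PanelObservation",
    "Subject",
    "PanelDataset",
    "PanelValidationError",
    "read_panel",
    "write_panel",
    "summarize_transitions",
]


@dataclass(frozen=True)
class PanelObservation:
    """One subject-observation: an age and an observed state or censor set."""

    age: float
    state: int | frozenset[int]
    is_exact_death_time: bool = False

    @property
    def is_censor_set(self) -> bool:
        return isinstance(self.state, frozenset)


@dataclass
class Subject:
    subject_id: str
    profile: dict[str, float]
    observations: list[PanelObservation]


class PanelValidationError(ValueError):
    """Raised when a dataset violates panel invariants; lists every issue."""

    def __init__(self, issues: list[str]):
        self.issues = issues
        preview = "\n".join(issues[:25])
        more = "" if len(issues) <= 25 else f"\n... and {len(issues) - 25} more"
        super().__init__(f"{len(issues)} panel validation issue(s):\n{preview}{more}")


@dataclass
class PanelDataset:
    """Validated long-format observations grouped by subject.

    Each subject carries a baseline covariate profile; all states are coded
    against ``space``.
    """

    subjects: list[Subject]
    space: StateSpace
    covariate_names: tuple[str, ...] = ()

    # -- basic counts ------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    @property
    def n_intervals(self) -> int:
        return sum(max(len(s.observations) - 1, 0) for s in self.subjects)

    def iter_intervals(
        self,
    ) -> Iterator[tuple[Subject, PanelObservation, PanelObservation]]:
        """Yield every consecutive observation pair of every subject."""
        for subj in self.subjects:
            for a, b in zip(subj.observations, subj.observations[1:]):
                yield subj, a, b

    # -- validation --------------------------------------------------------

    def validation_issues(self) -> list[str]:
        issues: list[str] = []
        codes = set(self.space.codes)
        alive = set(self.space.alive_codes)
        death = self.space.death_code
        seen_ids: set[str] = set()
        for subj in self.subjects:
            sid = subj.subject_id
            if sid in seen_ids:
                issues.append(f"subject {sid}: duplicated subject id")
            seen_ids.add(sid)
            if not subj.observations:
                issues.append(f"subject {sid}: no observations")
                continue
            for name in self.covariate_names:
                v = subj.profile.get(name)
                if v is None or not np.isfinite(v):
                    issues.append(f"subject {sid}: covariate {name!r} missing")
            prev_age = None
            for k, obs in enumerate(subj.observations):
                where = f"subject {sid}, row {k + 1}"
                if not (AGE_MIN <= obs.age <= AGE_MAX):
                    issues.append(f"{where}: age {obs.age} outside [{AGE_MIN}, {AGE_MAX}]")
                if prev_age is not None and obs.age <= prev_age:
                    issues.append(f"{where}: ages not strictly increasing")
                prev_age = obs.age
                if obs.is_censor_set:
                    bad = set(obs.state) - codes
                    if bad or not obs.state:
                        issues.append(f"{where}: invalid censor set {sorted(obs.state)}")
                    elif not set(obs.state) <= alive:
                        issues.append(
                            f"{where}: censor set must contain alive states only"
                        )
                    if k != len(subj.observations) - 1:
                        issues.append(
                            f"{where}: censor set allowed only as final record"
                        )
                else:
                    if obs.state not in codes:
                        issues.append(f"{where}: unknown state code {obs.state}")
                    elif obs.state == death:
                        if k != len(subj.observations) - 1:
                            issues.append(f"{where}: observation after death")
                        if not obs.is_exact_death_time:
                            issues.append(f"{where}: death must be exactly dated")
        return issues

    def validate(self) -> "PanelDataset":
        issues = self.validation_issues()
        if issues:
            raise PanelValidationError(issues)
        return self

    # -- transformation ----------------------------------------------------

    def relabel(self, mapping: Mapping[int, int], new_space: StateSpace) -> "PanelDataset":
        """Recode all observation states through ``mapping``."""

        def recode(obs: PanelObservation) -> PanelObservation:
            if obs.is_censor_set:
                state: int | frozenset[int] = frozenset(mapping[c] for c in obs.state)
            else:
                state = mapping[obs.state]
            return replace(obs, state=state)

        subjects = [
            Subject(s.subject_id, dict(s.profile), [recode(o) for o in s.observations])
            for s in self.subjects
        ]
        return PanelDataset(subjects, new_space, self.covariate_names)

    def subset(self, keep: Callable[[Subject], bool]) -> "PanelDataset":
        return PanelDataset(
            [s for s in self.subjects if keep(s)], self.space, self.covariate_names
        )

    # -- tabular form ------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for subj in self.subjects:
            for obs in subj.observations:
                state = (
                    "|".join(str(c) for c in sorted(obs.state))
                    if obs.is_censor_set
                    else str(obs.state)
                )
                row = {"subject_id": subj.subject_id, "age": obs.age, "state": state}
                for name in self.covariate_names:
                    row[name] = subj.profile[name]
                rows.append(row)
        cols = ["subject_id", "age", "state", *self.covariate_names]
        return pd.DataFrame(rows, columns=cols)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        space: StateSpace,
        covariate_names: Iterable[str] = (),
    ) -> "PanelDataset":
        covariate_names = tuple(covariate_names)
        required = {"subject_id", "age", "state", *covariate_names}
        missing = required - set(df.columns)
        if missing:
            raise PanelValidationError(
                [f"missing required columns: {sorted(missing)}"]
            )
        issues: list[str] = []
        death = space.death_code
        subjects: list[Subject] = []
        by_id: dict[str, Subject] = {}
        order = df.reset_index(drop=True)
        for line, row in enumerate(order.itertuples(index=False), start=2):
            sid = str(getattr(row, "subject_id"))
            try:
                age = round(float(getattr(row, "age")), 2)
            except (TypeError, ValueError):
                issues.append(f"line {line} (subject {sid}): unreadable age")
                continue
            raw = str(getattr(row, "state")).strip()
            state: int | frozenset[int]
            try:
                if "|" in raw:
                    state = frozenset(int(p) for p in raw.split("|"))
                else:
                    state = int(float(raw))
            except ValueError:
                issues.append(f"line {line} (subject {sid}): unreadable state {raw!r}")
                continue
            subj = by_id.get(sid)
            if subj is None:
                profile = {}
                for name in covariate_names:
                    try:
                        profile[name] = float(getattr(row, name))
                    except (TypeError, ValueError):
                        profile[name] = float("nan")
                subj = Subject(sid, profile, [])
                by_id[sid] = subj
                subjects.append(subj)
            subj.observations.append(
                PanelObservation(
                    age=age,
                    state=state,
                    is_exact_death_time=(state == death),
                )
            )
        if issues:
            raise PanelValidationError(issues)
        data = cls(subjects, space, covariate_names)
        return data.validate()


def read_panel(
    path, space: StateSpace, covariate_names: Iterable[str] = ()
) -> PanelDataset:
    """Read and validate a panel CSV; raises :class:`PanelValidationError`
    listing every offending row on invalid input."""
    df = pd.read_csv(path, dtype={"subject_id": str, "state": str})
    return PanelDataset.from_dataframe(df, space, covariate_names)


def write_panel(data: PanelDataset, path) -> None:
    """Write a panel CSV (ages to 2 decimal places)."""
    df = data.to_dataframe()
    df["age"] = df["age"].map(lambda a: f"{a:.2f}")
    for name in data.covariate_names:
        df[name] = df[name].map(_fmt_number)
    df.to_csv(path, index=False, lineterminator="\n")


def _fmt_number(v: float) -> str:
    return str(int(v)) if float(v) == int(v) else repr(float(v))


def summarize_transitions(data: PanelDataset) -> pd.DataFrame:
    """Observed wave-to-wave state-pair counts, including self-pairs.

    These are *observed state pairs* at consecutive waves, not inferred jump
    counts: transition timing between waves is interval-censored.  Rows index
    the origin state; columns the destination state, plus a ``censored``
    column counting pairs that end in a censor set.  The grand total equals
    the number of consecutive observation pairs.
    """
    space = data.space
    labels = list(space.labels)
    counts = pd.DataFrame(
        0, index=pd.Index(labels, name="from"), columns=labels + ["censored"]
    )
    for _, a, b in data.iter_intervals():
        if a.is_censor_set:
            continue  # censor sets are terminal; defensive only
        row = space.label_of(int(a.state))
        if b.is_censor_set:
            counts.loc[row, "censored"] += 1
        else:
            counts.loc[row, space.label_of(int(b.state))] += 1
    return counts
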