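"""Synthetic biennial panel cohorts with known ground truth.

The generator emulates the design of a Swedish-style occupational panel
survey of older workers: subjects enter at a continuous age ~ N(56, 5)
truncated to [50, 75], all in work at entry (full-time share 92.9% for men,
87.5% for women), carry baseline covariates (job strain prevalence 15.7% of
men / 21.2% of women; sex share 55.7% women), and are observed every 2 years
for between 2 and 7 waves.  Latent work histories are exact simulations of
the time-inhomogeneous continuous-time Markov chain under the true Gompertz
intensities (thinning against a per-band dominating rate); the panel records
only the state at each wave age — intermediate spells are invisible, which
is precisely the interval censoring the likelihood must absorb — while
deaths are recorded at their exact (registry-linked) age.

The default true parameter scenario is *constructed for face validity*, not
taken from any external fit: baseline intensities give total working life
expectancies near 13 years from age 50 and a strain gap in the half-year to
one-year range.  It is illustrative ground truth for testing the pipeline,
nothing more.

The module also houses the job-strain exposure coder (Karasek demand-control
quadrant or demand-minus-control median split of averaged Likert items).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.stats import truncnorm

from .expectancy import DEFAULT_HORIZON, DEFAULT_STEP, marginal_wle
from .likelihood import AgeGrid
from .panel_io import PanelDataset, PanelObservation, Subject
from .state_model import (
    AGE_ORIGIN,
    CovariateProfile,
    IntensityParameters,
    StateSpace,
    TransitionIntensity,
    TransitionStructure,
    collapse_to_three_state,
)

logger = logging.getLogger("worklife")

__all__ = [
    "CohortDesign",
    "TrueTrajectory",
    "Scenario",
    "StudyCohort",
    "simulate_trajectory",
    "observe_cohort",
    "assign_job_strain",
    "StrainCoding",
    "default_scenario",
    "make_study_cohort",
    "save_scenario",
    "load_scenario",
]


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

#: Share of subjects followed for 2..7 waves, from the survey's reported
#: follow-up-length counts (2666, 2741, 3492, 1252, 1142, 1539).
DEFAULT_WAVES_DIST = {2: 2666, 3: 2741, 4: 3492, 5: 1252, 6: 1142, 7: 1539}


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design of the synthetic cohort (defaults emulate the study)."""

    n_subjects: int = 3000
    entry_age_mean: float = 56.0
    entry_age_sd: float = 5.0
    entry_age_min: float = 50.0
    entry_age_max: float = 75.0
    wave_spacing: float = 2.0
    waves_dist: tuple[tuple[int, float], ...] = ()
    dropout_prob_per_wave: float = 0.0
    censored_as_alive: bool = False
    female_share: float = 0.5568
    entry_state_probs: tuple[tuple[str, tuple[tuple[int, float], ...]], ...] = ()
    strain_prevalence: tuple[tuple[str, float], ...] = (
        ("male", 0.157),
        ("female", 0.212),
    )
    seed: int | None = None

    def __post_init__(self):
        if not self.waves_dist:
            total = sum(DEFAULT_WAVES_DIST.values())
            object.__setattr__(
                self,
                "waves_dist",
                tuple((k, v / total) for k, v in sorted(DEFAULT_WAVES_DIST.items())),
            )
        if not self.entry_state_probs:
            object.__setattr__(
                self,
                "entry_state_probs",
                (
                    ("male", ((1, 0.929), (2, 0.071))),
                    ("female", ((1, 0.875), (2, 0.125))),
                ),
            )
        if self.wave_spacing <= 0:
            raise ValueError("wave spacing must be positive")
        for label, probs in self.entry_state_probs:
            p = [v for _, v in probs]
            if abs(sum(p) - 1.0) > 1e-9 or min(p) < 0:
                raise ValueError(f"entry state probabilities for {label} invalid")
        for _, p in self.strain_prevalence:
            if not 0.0 <= p <= 1.0:
                raise ValueError("strain prevalence must be in [0, 1]")
        if not 0.0 <= self.dropout_prob_per_wave <= 1.0:
            raise ValueError("dropout probability must be in [0, 1]")

    def entry_probs(self, sex: str) -> dict[int, float]:
        return dict(dict(self.entry_state_probs)[sex])

    def strain_prob(self, sex: str) -> float:
        return dict(self.strain_prevalence)[sex]

    @property
    def max_waves(self) -> int:
        return max(k for k, _ in self.waves_dist)


@dataclass
class TrueTrajectory:
    """Latent exact work history of one simulated subject."""

    subject_id: str
    profile: dict[str, float]
    entry_age: float
    entry_state: int
    jump_ages: list[float]
    jump_states: list[int]
    death_age: float | None
    censor_age: float

    def state_at(self, age: float) -> int:
        """State occupied at an age (right-continuous in the jumps)."""
        state = self.entry_state
        for t, s in zip(self.jump_ages, self.jump_states):
            if t <= age:
                state = s
            else:
                break
        return state


# ---------------------------------------------------------------------------
# Exact CTMC simulation by thinning
# ---------------------------------------------------------------------------


def simulate_trajectory(
    params: IntensityParameters,
    entry_age: float,
    entry_state: int,
    profile: CovariateProfile,
    age_max: float,
    rng: np.random.Generator,
    subject_id: str = "",
) -> TrueTrajectory:
    """Exact simulation of the time-inhomogeneous chain.

    Within 1-year age bands, candidate event times are drawn from an
    exponential clock at the band's dominating rate (the summed per-
    transition maximum of the Gompertz intensities over the band) and
    accepted with probability total-rate/dominating-rate; this is thinning,
    so accepted jumps follow the exact inhomogeneous intensities.
    """
    space = params.space
    if entry_state in space.absorbing:
        raise ValueError("entry state must be non-absorbing")
    by_origin: dict[int, list[tuple[int, TransitionIntensity]]] = {}
    for (r, s), ti in params.transitions:
        by_origin.setdefault(r, []).append((s, ti))

    jump_ages: list[float] = []
    jump_states: list[int] = []
    death_age = None
    state = entry_state
    t = entry_age
    while t < age_max - 1e-12:
        band_start = AGE_ORIGIN + np.floor(t - AGE_ORIGIN)
        band_end = min(band_start + 1.0, age_max)
        outgoing = by_origin.get(state, [])
        dominating = sum(
            max(
                np.exp(ti.log_rate(band_start, profile)),
                np.exp(ti.log_rate(band_end, profile)),
            )
            for _, ti in outgoing
        )
        if not np.isfinite(dominating):
            raise ValueError("non-finite dominating rate; parameters rejected")
        if dominating <= 0.0:
            t = band_end
            continue
        t_cand = t + rng.exponential(1.0 / dominating)
        if t_cand >= band_end:
            t = band_end
            continue
        t = t_cand
        rates = np.array(
            [np.exp(ti.log_rate(t, profile)) for _, ti in outgoing]
        )
        total = rates.sum()
        if rng.random() < total / dominating:
            dest = [s for s, _ in outgoing][
                rng.choice(len(outgoing), p=rates / total)
            ]
            jump_ages.append(t)
            jump_states.append(dest)
            state = dest
            if dest in space.absorbing:
                death_age = t
                break
    return TrueTrajectory(
        subject_id=subject_id,
        profile=profile.as_dict(),
        entry_age=entry_age,
        entry_state=entry_state,
        jump_ages=jump_ages,
        jump_states=jump_states,
        death_age=death_age,
        censor_age=age_max,
    )


# ---------------------------------------------------------------------------
# The panel observation operator
# ---------------------------------------------------------------------------


def observe_cohort(
    trajectories: Sequence[TrueTrajectory],
    design: CohortDesign,
    space: StateSpace,
    rng: np.random.Generator,
    covariate_names: Sequence[str] = ("strain", "female"),
) -> PanelDataset:
    """Discretize latent trajectories into biennial panel records.

    Each subject is observed at entry and every ``wave_spacing`` years for a
    drawn number of waves (or until random dropout); the recorded state is
    the trajectory's state at the wave age, so spells between waves are
    invisible.  Death is recorded at its exact age when it falls inside the
    subject's follow-up window and terminates observation.  Ages are stored
    to 2 decimal places.
    """
    wave_ns = np.array([k for k, _ in design.waves_dist])
    wave_ps = np.array([p for _, p in design.waves_dist])
    subjects: list[Subject] = []
    alive_set = frozenset(space.alive_codes)
    for traj in trajectories:
        n_waves = int(wave_ns[rng.choice(len(wave_ns), p=wave_ps)])
        entry = round(traj.entry_age, 2)
        wave_ages = [round(entry + k * design.wave_spacing, 2) for k in range(n_waves)]
        if design.dropout_prob_per_wave > 0 and n_waves > 1:
            kept = [wave_ages[0]]
            for a in wave_ages[1:]:
                if rng.random() < design.dropout_prob_per_wave:
                    break
                kept.append(a)
            wave_ages = kept
        window_end = wave_ages[-1]
        death = None
        if traj.death_age is not None:
            death = max(round(traj.death_age, 2), entry + 0.01)
        obs: list[PanelObservation] = []
        for a in wave_ages:
            if death is not None and a >= death - 1e-9:
                break
            if a > traj.censor_age + 1e-9:
                break
            obs.append(PanelObservation(age=a, state=traj.state_at(a)))
        if not obs:
            continue
        if death is not None and death <= window_end + 1e-9:
            obs.append(
                PanelObservation(
                    age=death, state=space.death_code, is_exact_death_time=True
                )
            )
        elif design.censored_as_alive and len(obs) < n_waves:
            cens_age = round(obs[-1].age + design.wave_spacing, 2)
            if death is None or cens_age < death - 1e-9:
                obs.append(PanelObservation(age=cens_age, state=alive_set))
        profile = {k: traj.profile[k] for k in covariate_names}
        subjects.append(Subject(traj.subject_id, profile, obs))
    return PanelDataset(subjects, space, tuple(covariate_names))


# ---------------------------------------------------------------------------
# Job-strain exposure coder
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrainCoding:
    """Binary strain indicators plus the coding rule that produced them."""

    indicator: np.ndarray
    rule: str
    medians: tuple[float, ...]


def assign_job_strain(
    demand_items: np.ndarray,
    control_items: np.ndarray,
    medians,
    rule: str,
) -> StrainCoding:
    """Code job strain from Likert demand/control items.

    Items are on a 1..4 scale where 1 = "Yes, often" and 4 = "No, hardly
    ever/never"; they are reverse-coded before averaging so that higher
    means more demands / more control.  Under the ``"quadrant"`` rule strain
    is (mean demands strictly above the demand median) AND (mean control
    strictly below the control median), with ``medians = (demand_median,
    control_median)``; under ``"score-median"`` strain is (demands - control
    strictly above its median), with a scalar ``medians``.  "Above the
    median" is strict: scores exactly at the median are not strain.
    """
    d = np.atleast_2d(np.asarray(demand_items, dtype=float))
    c = np.atleast_2d(np.asarray(control_items, dtype=float))
    if d.shape[-1] != 4:
        raise ValueError("expected 4 demand items")
    if c.shape[-1] != 5:
        raise ValueError("expected 5 control items")
    for arr, what in ((d, "demand"), (c, "control")):
        if np.any((arr < 1) | (arr > 4)):
            raise ValueError(f"{what} responses must be in 1..4")
    d_score = (5.0 - d).mean(axis=-1)
    c_score = (5.0 - c).mean(axis=-1)
    if rule == "quadrant":
        d_med, c_med = medians
        ind = (d_score > d_med) & (c_score < c_med)
        meds = (float(d_med), float(c_med))
    elif rule == "score-median":
        med = float(medians)
        ind = (d_score - c_score) > med
        meds = (med,)
    else:
        raise ValueError(f"unknown strain rule {rule!r}")
    return StrainCoding(indicator=ind.astype(int), rule=rule, medians=meds)


# ---------------------------------------------------------------------------
# Scenarios and end-to-end cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """True parameters plus a cohort design: everything needed to simulate."""

    params: IntensityParameters
    design: CohortDesign
    seed: int | None = None
    name: str = "default"


@dataclass
class StudyCohort:
    """An end-to-end synthetic study: panel, hidden truth, and the true WLE
    per covariate profile implied by the generating parameters."""

    panel: PanelDataset
    trajectories: list[TrueTrajectory]
    scenario: Scenario
    true_wle: dict[tuple[int, int], dict[str, float]]


def _default_true_params() -> IntensityParameters:
    """Constructed illustrative truth for the four-state model (see module
    docstring): rates are at-age-50 baselines for men without strain."""
    space = StateSpace.four_state()
    structure = TransitionStructure.full(space)
    ln = np.log
    trans = {
        # work-to-work and work-exit dynamics (strain raises exit, slightly
        # slows re-entry; women shift towards part-time)
        (1, 2): TransitionIntensity(
            ln(0.028), 0.08, {"strain": ln(1.06), "female": ln(1.30)}
        ),
        (1, 3): TransitionIntensity(
            ln(0.013), 0.125, {"strain": ln(1.18), "female": ln(1.05)}
        ),
        (2, 1): TransitionIntensity(
            ln(0.19), -0.05, {"strain": ln(0.96), "female": ln(0.88)}
        ),
        (2, 3): TransitionIntensity(
            ln(0.062), 0.105, {"strain": ln(1.15), "female": ln(0.95)}
        ),
        (3, 1): TransitionIntensity(
            ln(0.085), -0.11, {"strain": ln(0.92), "female": ln(0.90)}
        ),
        (3, 2): TransitionIntensity(
            ln(0.058), -0.07, {"strain": ln(0.96), "female": ln(1.10)}
        ),
        # Gompertz mortality, no covariate effects
        (1, 4): TransitionIntensity(ln(0.0035), 0.10),
        (2, 4): TransitionIntensity(ln(0.0045), 0.10),
        (3, 4): TransitionIntensity(ln(0.0090), 0.10),
    }
    return IntensityParameters(space, structure, trans)


def default_scenario(
    n_subjects: int = 3000, seed: int | None = None, **design_overrides
) -> Scenario:
    """The default four-state study-emulation scenario."""
    design = CohortDesign(n_subjects=n_subjects, seed=seed, **design_overrides)
    return Scenario(params=_default_true_params(), design=design, seed=seed)


def true_wle_by_profile(
    scenario: Scenario,
    step: float = DEFAULT_STEP,
    horizon: float = DEFAULT_HORIZON,
    grid: AgeGrid | None = None,
) -> dict[tuple[int, int], dict[str, float]]:
    """True WLE per (strain, female) profile, computed from the generating
    parameters by the production expectancy integrator, starting from the
    design's entry-state distribution at age 50."""
    params = scenario.params
    space = params.space
    out: dict[tuple[int, int], dict[str, float]] = {}
    for female in (0, 1):
        sex = "female" if female else "male"
        probs = scenario.design.entry_probs(sex)
        init = np.zeros(space.n)
        for code, p in probs.items():
            init[space.index(code)] = p
        for strain in (0, 1):
            profile = CovariateProfile({"strain": strain, "female": female})
            est = marginal_wle(
                params,
                None,
                profile,
                start_age=AGE_ORIGIN,
                initial_distribution=init,
                step=step,
                horizon=horizon,
            )
            vals = {str(c): v for c, v in est.per_state.items()}
            vals["total"] = est.total
            out[(strain, female)] = vals
    return out


def make_study_cohort(
    scenario: Scenario, seed: int | None = None, compute_true_wle: bool = True
) -> StudyCohort:
    """Simulate a full synthetic study from a scenario.

    Returns the observed panel, the latent trajectory archive, and the true
    WLE per profile.  ``seed`` overrides the scenario's own seed; identical
    scenario + seed give a byte-identical panel CSV.
    """
    design = scenario.design
    params = scenario.params
    space = params.space
    rng = np.random.default_rng(seed if seed is not None else scenario.seed)
    n = design.n_subjects

    female = (rng.random(n) < design.female_share).astype(int)
    strain = np.empty(n, dtype=int)
    entry_state = np.empty(n, dtype=int)
    for sex_code, sex in ((0, "male"), (1, "female")):
        mask = female == sex_code
        strain[mask] = (rng.random(mask.sum()) < design.strain_prob(sex)).astype(int)
        probs = design.entry_probs(sex)
        codes = sorted(probs)
        entry_state[mask] = rng.choice(
            codes, size=mask.sum(), p=[probs[c] for c in codes]
        )
    a = (design.entry_age_min - design.entry_age_mean) / design.entry_age_sd
    b = (design.entry_age_max - design.entry_age_mean) / design.entry_age_sd
    entry_age = np.round(
        truncnorm.rvs(
            a,
            b,
            loc=design.entry_age_mean,
            scale=design.entry_age_sd,
            size=n,
            random_state=rng,
        ),
        2,
    )

    horizon = design.entry_age_max + (design.max_waves - 1) * design.wave_spacing
    trajectories = []
    width = len(str(n))
    for i in range(n):
        profile = CovariateProfile(
            {"strain": float(strain[i]), "female": float(female[i])}
        )
        trajectories.append(
            simulate_trajectory(
                params,
                float(entry_age[i]),
                int(entry_state[i]),
                profile,
                age_max=horizon,
                rng=rng,
                subject_id=f"s{i + 1:0{width}d}",
            )
        )
    panel = observe_cohort(trajectories, design, space, rng).validate()
    true_wle = true_wle_by_profile(scenario) if compute_true_wle else {}
    return StudyCohort(
        panel=panel, trajectories=trajectories, scenario=scenario, true_wle=true_wle
    )


# ---------------------------------------------------------------------------
# Scenario files
# ---------------------------------------------------------------------------


def save_scenario(scenario: Scenario, path) -> None:
    space = scenario.params.space
    d = scenario.design
    doc = {
        "name": scenario.name,
        "seed": scenario.seed,
        "states": [
            {"code": c, "label": l} for c, l in zip(space.codes, space.labels)
        ],
        "absorbing": sorted(space.absorbing),
        "working": sorted(space.working),
        "transitions": {
            f"{r}->{s}": {
                "log_q0": float(ti.log_q0),
                "b_age": float(ti.b_age),
                "betas": {k: float(v) for k, v in ti.betas},
            }
            for (r, s), ti in scenario.params.transitions
        },
        "design": {
            "n_subjects": d.n_subjects,
            "entry_age_mean": d.entry_age_mean,
            "entry_age_sd": d.entry_age_sd,
            "entry_age_min": d.entry_age_min,
            "entry_age_max": d.entry_age_max,
            "wave_spacing": d.wave_spacing,
            "waves_dist": {int(k): float(p) for k, p in d.waves_dist},
            "dropout_prob_per_wave": d.dropout_prob_per_wave,
            "censored_as_alive": d.censored_as_alive,
            "female_share": d.female_share,
            "entry_state_probs": {
                sex: {int(c): float(p) for c, p in probs}
                for sex, probs in d.entry_state_probs
            },
            "strain_prevalence": {sex: float(p) for sex, p in d.strain_prevalence},
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_scenario(path) -> Scenario:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    states = sorted(doc["states"], key=lambda s: s["code"])
    space = StateSpace(
        labels=tuple(s["label"] for s in states),
        codes=tuple(int(s["code"]) for s in states),
        absorbing=frozenset(int(c) for c in doc["absorbing"]),
        working=frozenset(int(c) for c in doc["working"]),
    )
    trans = {}
    for key, blk in doc["transitions"].items():
        r, s = key.split("->")
        trans[(int(r), int(s))] = TransitionIntensity(
            blk["log_q0"], blk.get("b_age", 0.0), blk.get("betas", {})
        )
    structure = TransitionStructure(allowed=frozenset(trans))
    params = IntensityParameters(space, structure, trans)
    dd = doc["design"]
    design = CohortDesign(
        n_subjects=int(dd["n_subjects"]),
        entry_age_mean=float(dd["entry_age_mean"]),
        entry_age_sd=float(dd["entry_age_sd"]),
        entry_age_min=float(dd.get("entry_age_min", 50.0)),
        entry_age_max=float(dd.get("entry_age_max", 75.0)),
        wave_spacing=float(dd["wave_spacing"]),
        waves_dist=tuple(
            (int(k), float(p)) for k, p in sorted(dd["waves_dist"].items())
        ),
        dropout_prob_per_wave=float(dd.get("dropout_prob_per_wave", 0.0)),
        censored_as_alive=bool(dd.get("censored_as_alive", False)),
        female_share=float(dd["female_share"]),
        entry_state_probs=tuple(
            (sex, tuple((int(c), float(p)) for c, p in sorted(probs.items())))
            for sex, probs in dd["entry_state_probs"].items()
        ),
        strain_prevalence=tuple(
            (sex, float(p)) for sex, p in dd["strain_prevalence"].items()
        ),
        seed=doc.get("seed"),
    )
    return Scenario(
        params=params, design=design, seed=doc.get("seed"), name=doc.get("name", "")
    )
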