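"""Shared fixtures: tiny model configurations and simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

import worklife as wl
from worklife.panel_io import PanelDataset, PanelObservation, Subject

NEG_INF_RATE = -40.0  # log intensity so small the transition never fires


def two_state_model(mu: float, b_age: float = 0.0, betas=None):
    """2-state alive -> dead model with rate mu at age 50."""
    space = wl.StateSpace(
        labels=("alive", "dead"),
        codes=(1, 2),
        absorbing=frozenset({2}),
        working=frozenset({1}),
    )
    structure = wl.TransitionStructure(frozenset({(1, 2)}))
    params = wl.IntensityParameters(
        space,
        structure,
        {(1, 2): wl.TransitionIntensity(np.log(mu), b_age, betas or {})},
    )
    return space, structure, params


def empty_profile() -> wl.CovariateProfile:
    return wl.CovariateProfile({})


def four_state_random_params(rng: np.random.Generator, covariates=("strain", "female")):
    """Random but well-behaved four-state Gompertz parameters."""
    space = wl.StateSpace.four_state()
    structure = wl.TransitionStructure.full(space)
    trans = {}
    for r, s in structure.transitions:
        betas = (
            {}
            if s == space.death_code
            else {c: rng.normal(0, 0.3) for c in covariates}
        )
        trans[(r, s)] = wl.TransitionIntensity(
            rng.normal(-3.0, 0.6), rng.normal(0.05, 0.05), betas
        )
    return space, structure, wl.IntensityParameters(space, structure, trans)


def build_panel(space, rows, covariate_names=()):
    """rows: list of (subject_id, profile, [(age, state, exact_death)])."""
    subjects = []
    for sid, profile, obs_rows in rows:
        obs = [
            PanelObservation(age=a, state=st, is_exact_death_time=bool(d))
            for a, st, d in obs_rows
        ]
        subjects.append(Subject(sid, dict(profile), obs))
    return PanelDataset(subjects, space, tuple(covariate_names)).validate()


@pytest.fixture(scope="session")
def small_cohort():
    """One modest simulated four-state cohort shared across tests."""
    scenario = wl.default_scenario(n_subjects=1000, seed=202)
    return wl.make_study_cohort(scenario, compute_true_wle=False)


@pytest.fixture(scope="session")
def small_cohort_fit(small_cohort):
    fit = wl.fit_mle(small_cohort.panel, covariates=["strain", "female"])
    return small_cohort, fit
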