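"""Transition probabilities and the interval-censored log-likelihood,
checked against independent scipy-expm oracles and closed forms."""

import numpy as np
import pytest
from scipy.linalg import expm

import worklife as wl
from worklife.likelihood import AgeGrid, LikelihoodEngine
from worklife.panel_io import PanelObservation

from conftest import (
    build_panel,
    empty_profile,
    four_state_random_params,
    two_state_model,
)

GRID = AgeGrid()


class TestTransitionProbability:
    def test_zero_length_interval_is_identity(self):
        _, _, params = two_state_model(0.1)
        P = wl.transition_probability(params, 57.3, 57.3, empty_profile(), GRID)
        assert np.array_equal(P, np.eye(2))

    def test_homogeneous_survival_closed_form(self):
        _, _, params = two_state_model(0.1)
        P = wl.transition_probability(params, 50.0, 55.0, empty_profile(), GRID)
        assert P[0, 1] == pytest.approx(1 - np.exp(-0.5), abs=1e-12)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-10

    def test_gompertz_two_state_vs_fine_grid_oracle(self):
        """1-year bands against an independent 0.01-year expm product."""
        _, _, params = two_state_model(0.02, b_age=0.08)
        P = wl.transition_probability(params, 50.0, 75.0, empty_profile(), GRID)
        oracle = _fine_grid_oracle(params, empty_profile(), 50.0, 75.0, 0.01)
        assert np.abs(P - oracle).max() < 1e-3

    def test_chapman_kolmogorov_on_band_boundary(self):
        rng = np.random.default_rng(3)
        _, _, params = four_state_random_params(rng)
        profile = wl.CovariateProfile({"strain": 0.0, "female": 1.0})
        Pac = wl.transition_probability(params, 51.4, 63.0, profile, GRID)
        Pab = wl.transition_probability(params, 51.4, 57.0, profile, GRID)
        Pbc = wl.transition_probability(params, 57.0, 63.0, profile, GRID)
        assert np.abs(Pac - Pab @ Pbc).max() < 1e-10

    def test_rejects_reversed_interval(self):
        _, _, params = two_state_model(0.1)
        with pytest.raises(ValueError):
            wl.transition_probability(params, 60.0, 55.0, empty_profile(), GRID)

    def test_production_expm_matches_scipy_on_random_generators(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            _, _, params = four_state_random_params(rng)
            profile = wl.CovariateProfile(
                {"strain": float(rng.integers(0, 2)), "female": float(rng.integers(0, 2))}
            )
            age = float(rng.uniform(50, 80))
            dt = float(rng.uniform(0.1, 1.0))
            Q = params.intensity_matrix(age, profile)
            calc = wl.TransitionCalculator(params, profile, GRID)
            band = GRID.band_of(age)
            Qb = params.intensity_matrix(GRID.midpoint(band), profile)
            assert np.abs(calc.band_matrix(band, dt) - expm(Qb * dt)).max() < 1e-10


def _fine_grid_oracle(params, profile, a0, a1, step):
    """Independent piecewise product at a fine step, via scipy expm."""
    P = np.eye(params.space.n)
    t = a0
    while t < a1 - 1e-12:
        dt = min(step, a1 - t)
        P = P @ expm(params.intensity_matrix(t + dt / 2, profile) * dt)
        t += dt
    return P


class TestIntervalLoglik:
    def test_degenerate_interval_same_state(self):
        _, _, params = two_state_model(0.1)
        pair = (PanelObservation(55.0, 1), PanelObservation(55.0, 1))
        assert wl.interval_loglik(pair, params, empty_profile(), GRID) == 0.0

    def test_exact_death_density_closed_form(self):
        # survive 5 years then die instantaneously: exp(-0.5) * 0.1
        _, _, params = two_state_model(0.1)
        pair = (
            PanelObservation(50.0, 1),
            PanelObservation(55.0, 2, is_exact_death_time=True),
        )
        ll = wl.interval_loglik(pair, params, empty_profile(), GRID)
        assert ll == pytest.approx(-0.5 + np.log(0.1), abs=1e-12)

    def test_censor_set_total_probability(self):
        """All alive states in a model with no death hazard: probability 1."""
        space = wl.StateSpace.three_state()
        structure = wl.TransitionStructure.full(space)
        trans = {
            (r, s): wl.TransitionIntensity(-40.0 if s == 3 else np.log(0.2))
            for r, s in structure.transitions
        }
        params = wl.IntensityParameters(space, structure, trans)
        pair = (PanelObservation(50.0, 1), PanelObservation(56.0, frozenset({1, 2})))
        ll = wl.interval_loglik(pair, params, empty_profile(), GRID)
        assert ll == pytest.approx(0.0, abs=1e-9)

    def test_rejects_interval_starting_at_death(self):
        _, _, params = two_state_model(0.1)
        pair = (
            PanelObservation(55.0, 2, is_exact_death_time=True),
            PanelObservation(56.0, 2),
        )
        with pytest.raises(ValueError):
            wl.interval_loglik(pair, params, empty_profile(), GRID)


class TestTotalLoglik:
    def test_subjects_observed_once_contribute_zero(self):
        space, _, params = two_state_model(0.1)
        data = build_panel(space, [("a", {}, [(50.0, 1, 0)]), ("b", {}, [(60.0, 1, 0)])])
        assert wl.total_loglik(data, params, GRID) == 0.0

    def test_three_subject_brute_force_oracle(self):
        """Hand-assembled sum of matrix-exponential entries, independently
        via scipy, for a time-homogeneous three-state toy panel."""
        space = wl.StateSpace.three_state()
        structure = wl.TransitionStructure.full(space)
        rates = {(1, 2): 0.12, (2, 1): 0.3, (1, 3): 0.02, (2, 3): 0.05}
        trans = {k: wl.TransitionIntensity(np.log(v)) for k, v in rates.items()}
        params = wl.IntensityParameters(space, structure, trans)
        data = build_panel(
            space,
            [
                ("a", {}, [(50.0, 1, 0), (52.0, 1, 0), (54.0, 2, 0)]),
                ("b", {}, [(51.0, 2, 0), (55.0, 1, 0)]),
                ("c", {}, [(50.0, 1, 0), (53.5, 3, 1)]),
            ],
        )
        Q = np.zeros((3, 3))
        for (r, s), v in rates.items():
            Q[r - 1, s - 1] = v
        np.fill_diagonal(Q, -Q.sum(axis=1))
        expected = (
            np.log(expm(Q * 2.0)[0, 0])
            + np.log(expm(Q * 2.0)[0, 1])
            + np.log(expm(Q * 4.0)[1, 0])
            + np.log(expm(Q * 3.5)[0, 0] * rates[(1, 3)]
                     + expm(Q * 3.5)[0, 1] * rates[(2, 3)])
        )
        got = wl.total_loglik(data, params, GRID)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_doubling_dataset_doubles_loglik(self, small_cohort):
        data = small_cohort.panel
        params = small_cohort.scenario.params
        base = wl.total_loglik(data, params, GRID)
        doubled = wl.PanelDataset(
            data.subjects
            + [
                wl.Subject(s.subject_id + "_dup", dict(s.profile), list(s.observations))
                for s in data.subjects
            ],
            data.space,
            data.covariate_names,
        )
        assert wl.total_loglik(doubled, params, GRID) == pytest.approx(
            2 * base, rel=1e-12
        )

    def test_invariant_to_sharding_and_order(self, small_cohort):
        data = small_cohort.panel
        params = small_cohort.scenario.params
        base = wl.total_loglik(data, params, GRID)
        half = len(data.subjects) // 2
        shard_sum = sum(
            wl.total_loglik(
                wl.PanelDataset(chunk, data.space, data.covariate_names), params, GRID
            )
            for chunk in (data.subjects[:half], data.subjects[half:])
        )
        assert shard_sum == pytest.approx(base, abs=1e-8)
        reordered = wl.PanelDataset(
            list(reversed(data.subjects)), data.space, data.covariate_names
        )
        assert wl.total_loglik(reordered, params, GRID) == base

    def test_engine_matches_scalar_interval_sum(self, small_cohort):
        data = small_cohort.panel
        params = small_cohort.scenario.params
        scalar = sum(
            wl.interval_loglik((a, b), params, wl.CovariateProfile(s.profile), GRID)
            for s, a, b in data.iter_intervals()
        )
        assert wl.total_loglik(data, params, GRID) == pytest.approx(scalar, abs=1e-9)


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, small_cohort):
        data = small_cohort.panel
        params = small_cohort.scenario.params
        engine = LikelihoodEngine(data, params, GRID)
        theta = params.flatten()
        _, g = engine.value_and_grad(theta)
        h = 1e-6
        for j in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            fd = (engine.value(tp) - engine.value(tm)) / (2 * h)
            assert g[j] == pytest.approx(fd, rel=5e-5, abs=1e-6)


class TestBandConvergence:
    def test_error_shrinks_monotonically_with_band_width(self):
        """Midpoint piecewise-constant error is O(width^2): halving the band
        width must shrink the error against a fine-step oracle."""
        rng = np.random.default_rng(42)
        _, _, params = four_state_random_params(rng)
        profile = wl.CovariateProfile({"strain": 1.0, "female": 1.0})
        oracle = _fine_grid_oracle(params, profile, 50.0, 70.0, 0.01)
        errs = []
        for width in (2.0, 1.0, 0.5, 0.25):
            grid = AgeGrid(width=width)
            P = wl.transition_probability(params, 50.0, 70.0, profile, grid)
            errs.append(np.abs(P - oracle).max())
        assert errs[1] < 1e-3
        assert all(a > b for a, b in zip(errs, errs[1:]))
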