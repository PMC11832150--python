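"""Synthetic cohort generator: exact CTMC simulation, the panel observation
operator, the strain coder, and design-target checks."""

import hashlib

import numpy as np
import pytest

import worklife as wl
from worklife.cohort import TrueTrajectory, observe_cohort
from worklife.panel_io import write_panel

from conftest import NEG_INF_RATE, empty_profile, two_state_model


class TestSimulateTrajectory:
    def test_frozen_chain_never_jumps(self):
        space, _, _ = two_state_model(0.1)
        structure = wl.TransitionStructure(frozenset({(1, 2)}))
        params = wl.IntensityParameters(
            space, structure, {(1, 2): wl.TransitionIntensity(NEG_INF_RATE)}
        )
        traj = wl.simulate_trajectory(
            params, 50.0, 1, empty_profile(), 90.0, np.random.default_rng(0)
        )
        assert traj.jump_ages == [] and traj.death_age is None
        assert traj.censor_age == 90.0

    def test_rejects_absorbing_entry_state(self):
        _, _, params = two_state_model(0.1)
        with pytest.raises(ValueError):
            wl.simulate_trajectory(
                params, 50.0, 2, empty_profile(), 90.0, np.random.default_rng(0)
            )

    def test_exponential_death_wait_oracle(self):
        """Homogeneous mu = 0.1: mean wait over many draws matches 10 yr."""
        _, _, params = two_state_model(0.1)
        rng = np.random.default_rng(123)
        n = 10_000
        waits = np.empty(n)
        for i in range(n):
            traj = wl.simulate_trajectory(
                params, 50.0, 1, empty_profile(), 500.0, rng
            )
            waits[i] = traj.death_age - 50.0
        sem = 10.0 / np.sqrt(n)  # exponential: sd equals the mean
        assert abs(waits.mean() - 10.0) < 3 * sem

    def test_empirical_band_rates_match_intensities(self):
        """Occupancy-time-normalized jump counts per transition reproduce the
        generator entries (homogeneous case, exact check up to MC noise)."""
        space = wl.StateSpace.three_state()
        structure = wl.TransitionStructure.full(space)
        rates = {(1, 2): 0.15, (2, 1): 0.25, (1, 3): 0.05, (2, 3): 0.08}
        params = wl.IntensityParameters(
            space,
            structure,
            {k: wl.TransitionIntensity(np.log(v)) for k, v in rates.items()},
        )
        rng = np.random.default_rng(99)
        counts = {k: 0 for k in rates}
        time_in = {1: 0.0, 2: 0.0}
        for _ in range(10_000):
            traj = wl.simulate_trajectory(params, 50.0, 1, empty_profile(), 55.0, rng)
            ages = [50.0] + traj.jump_ages + [
                traj.death_age if traj.death_age is not None else 55.0
            ]
            states = [1] + traj.jump_states
            for a0, a1, s0, s1 in zip(
                ages, ages[1:], states, states + [None]
            ):
                if s0 in time_in:
                    time_in[s0] += a1 - a0
            for s0, s1 in zip(states, states[1:]):
                counts[(s0, s1)] += 1
        for (r, s), q in rates.items():
            n_jumps = counts[(r, s)]
            est = n_jumps / time_in[r]
            sem = np.sqrt(n_jumps) / time_in[r]
            assert abs(est - q) < 3.5 * max(sem, 1e-4), (r, s, est, q)


class TestObserveCohort:
    def _design(self, **kw):
        return wl.CohortDesign(n_subjects=1, **kw)

    def test_constant_path_gives_constant_records(self):
        space = wl.StateSpace.four_state()
        traj = TrueTrajectory(
            "t1", {"strain": 0.0, "female": 0.0}, 50.0, 1, [], [], None, 90.0
        )
        design = self._design(waves_dist=((4, 1.0),))
        panel = observe_cohort([traj], design, space, np.random.default_rng(0))
        obs = panel.subjects[0].observations
        assert len(obs) == 4
        assert all(o.state == 1 for o in obs)
        assert [o.age for o in obs] == [50.0, 52.0, 54.0, 56.0]

    def test_short_spell_between_waves_is_invisible(self):
        space = wl.StateSpace.four_state()
        traj = TrueTrajectory(
            "t1",
            {"strain": 0.0, "female": 0.0},
            50.0,
            1,
            [50.7, 50.8],  # a one-month not-in-work spell between waves
            [3, 1],
            None,
            90.0,
        )
        design = self._design(waves_dist=((2, 1.0),))
        panel = observe_cohort([traj], design, space, np.random.default_rng(0))
        states = [o.state for o in panel.subjects[0].observations]
        assert states == [1, 1]  # the spell never shows
        assert traj.state_at(50.75) == 3  # but it is in the latent truth

    def test_death_recorded_exactly_and_terminates(self):
        space = wl.StateSpace.four_state()
        traj = TrueTrajectory(
            "t1", {"strain": 0.0, "female": 0.0}, 50.0, 1, [53.137], [4], 53.137, 90.0
        )
        design = self._design(waves_dist=((4, 1.0),))
        panel = observe_cohort([traj], design, space, np.random.default_rng(0))
        obs = panel.subjects[0].observations
        assert [o.age for o in obs] == [50.0, 52.0, 53.14]
        assert obs[-1].state == 4 and obs[-1].is_exact_death_time

    def test_panel_state_equals_trajectory_state_everywhere(self, small_cohort):
        by_id = {t.subject_id: t for t in small_cohort.trajectories}
        for subj in small_cohort.panel.subjects:
            traj = by_id[subj.subject_id]
            for o in subj.observations:
                if o.is_exact_death_time:
                    continue  # death row checked via death_age below
                assert o.state == traj.state_at(o.age)
            if traj.death_age is not None and subj.observations[-1].is_exact_death_time:
                assert subj.observations[-1].age == pytest.approx(
                    traj.death_age, abs=0.011
                )


@pytest.fixture(scope="module")
def big_cohort():
    return wl.make_study_cohort(
        wl.default_scenario(n_subjects=4000, seed=77), compute_true_wle=False
    )


class TestDesignTargets:
    def test_male_entry_fulltime_share(self, big_cohort):
        men = [
            s
            for s in big_cohort.panel.subjects
            if s.profile["female"] == 0.0
        ]
        first = np.array([s.observations[0].state for s in men], dtype=float)
        share = (first == 1).mean()
        sem = np.sqrt(0.929 * 0.071 / len(men))
        assert abs(share - 0.929) < 3 * sem

    def test_strain_prevalence_by_sex(self, big_cohort):
        for female, target in ((0.0, 0.157), (1.0, 0.212)):
            grp = [
                s for s in big_cohort.panel.subjects if s.profile["female"] == female
            ]
            prev = np.mean([s.profile["strain"] for s in grp])
            sem = np.sqrt(target * (1 - target) / len(grp))
            assert abs(prev - target) < 3 * sem

    def test_entry_ages_truncated_normal(self, big_cohort):
        entry = np.array([s.observations[0].age for s in big_cohort.panel.subjects])
        assert entry.min() >= 50.0 and entry.max() <= 75.0
        assert abs(entry.mean() - 56.5) < 1.0  # truncation shifts mean up a bit

    def test_wave_count_distribution_support(self, big_cohort):
        by_id = {t.subject_id: t for t in big_cohort.trajectories}
        n_obs = [len(s.observations) for s in big_cohort.panel.subjects]
        assert min(n_obs) >= 1 and max(n_obs) <= 7


class TestSeededDeterminism:
    def test_identical_seed_byte_identical_panel(self, tmp_path):
        scenario = wl.default_scenario(n_subjects=150, seed=5)
        hashes = []
        for run in (1, 2):
            study = wl.make_study_cohort(scenario, compute_true_wle=False)
            path = tmp_path / f"panel{run}.csv"
            write_panel(study.panel, path)
            hashes.append(hashlib.sha256(path.read_bytes()).hexdigest())
        assert hashes[0] == hashes[1]

    def test_different_seed_differs(self, tmp_path):
        a = wl.make_study_cohort(
            wl.default_scenario(n_subjects=100, seed=1), compute_true_wle=False
        )
        b = wl.make_study_cohort(
            wl.default_scenario(n_subjects=100, seed=2), compute_true_wle=False
        )
        assert a.panel.to_dataframe().to_csv() != b.panel.to_dataframe().to_csv()


class TestScenario:
    def test_null_strain_scenario_has_equal_true_wle(self):
        base = wl.default_scenario()
        trans = {
            key: wl.TransitionIntensity(
                ti.log_q0,
                ti.b_age,
                {k: (0.0 if k == "strain" else v) for k, v in ti.betas},
            )
            for key, ti in base.params.transitions
        }
        null_params = wl.IntensityParameters(
            base.params.space, base.params.structure, trans
        )
        scenario = wl.Scenario(params=null_params, design=base.design)
        true_wle = wl.true_wle_by_profile(scenario)
        for female in (0, 1):
            assert true_wle[(0, female)]["total"] == pytest.approx(
                true_wle[(1, female)]["total"], abs=1e-12
            )

    def test_yaml_roundtrip(self, tmp_path):
        scenario = wl.default_scenario(n_subjects=123, seed=9)
        path = tmp_path / "scenario.yaml"
        wl.save_scenario(scenario, path)
        back = wl.load_scenario(path)
        assert back.design == scenario.design
        assert np.array_equal(back.params.flatten(), scenario.params.flatten())
        assert back.seed == scenario.seed


class TestStrainCoder:
    def test_extreme_quadrant_is_strain_under_both_rules(self):
        demands = np.ones(4)  # "yes often" everywhere -> maximal demands
        control = np.full(5, 4.0)  # no control at all
        for rule, med in (("quadrant", (2.5, 2.5)), ("score-median", 0.0)):
            coding = wl.assign_job_strain(demands, control, med, rule)
            assert coding.indicator[0] == 1
            assert coding.rule == rule

    def test_scores_exactly_at_median_are_not_strain(self):
        demands = np.full(4, 2.5)
        control = np.ones(5)
        coding = wl.assign_job_strain(demands, control, (2.5, 2.5), "quadrant")
        assert coding.indicator[0] == 0  # "above the median" is strict

    def test_rejects_out_of_range_items(self):
        with pytest.raises(ValueError):
            wl.assign_job_strain(np.array([0.5, 2, 2, 2]), np.ones(5), (2.5, 2.5), "quadrant")
        with pytest.raises(ValueError):
            wl.assign_job_strain(np.ones(4), np.ones(5), 0.0, "nonsense")

    def test_quadrant_prevalence_under_independent_uniform_items(self):
        """Independent uniform items: P(above demand median) * P(below
        control median) = 1/4."""
        rng = np.random.default_rng(4)
        n = 40_000
        demands = rng.uniform(1, 4, size=(n, 4))
        control = rng.uniform(1, 4, size=(n, 5))
        d_med = np.median((5 - demands).mean(axis=1))
        c_med = np.median((5 - control).mean(axis=1))
        coding = wl.assign_job_strain(demands, control, (d_med, c_med), "quadrant")
        prev = coding.indicator.mean()
        sem = np.sqrt(0.25 * 0.75 / n)
        assert abs(prev - 0.25) < 3 * sem
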