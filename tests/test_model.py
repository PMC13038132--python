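"""Resource-model dynamics: hand-checked values, invariants, oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import euler_recall_probabilities
from wmtime.design import TrialSpec, schedule_for_trial
from wmtime.model import (
    DEFAULT_PARAMS,
    ModelParams,
    predict_condition_means,
    predict_design,
    predict_trial,
    recall_probability,
    resource_trajectory,
)

SHORT = np.full(6, 0.05)


def _gap_schedule(gap_position, gap_ms, presentation_ms=300):
    isis = [50] * 6
    isis[gap_position - 1] = gap_ms
    return schedule_for_trial(
        TrialSpec(
            experiment_id="exp2b", subject_id=1, block=1, trial=1,
            condition="long_gap" if gap_ms == 2500 else "short_gap",
            gap_position=gap_position, isis_ms=tuple(isis),
            presentation_ms=presentation_ms, retention_ms=1000,
        )
    )


params_strategy = st.builds(
    ModelParams,
    p=st.floats(0.05, 0.8),
    r=st.floats(0.0, 1.5),
    gain=st.floats(2.0, 40.0),
    tau=st.floats(0.0, 0.5),
)
isis_strategy = st.lists(st.floats(0.0, 2.5), min_size=6, max_size=6).map(np.array)


class TestResourceTrajectory:
    def test_hand_iterated_second_position(self):
        traj = resource_trajectory(SHORT, DEFAULT_PARAMS)
        assert traj.available[0] == 1.0
        # (1 - .23) * 1 + .11 * 0.05
        assert traj.available[1] == pytest.approx(0.7755)
        np.testing.assert_allclose(traj.strengths, 0.23 * traj.available)

    def test_no_recovery_reduces_to_geometric_depletion(self):
        params = ModelParams(p=0.3, r=0.0)
        traj = resource_trajectory(np.linspace(0.1, 2.0, 6), params)
        expected = 0.3 * (1 - 0.3) ** np.arange(7)
        np.testing.assert_allclose(traj.strengths, expected, rtol=0, atol=1e-15)

    def test_saturation_with_ample_free_time(self):
        traj = resource_trajectory(np.full(6, 100.0), DEFAULT_PARAMS)
        np.testing.assert_allclose(traj.available, 1.0)
        np.testing.assert_allclose(traj.strengths, 0.23)

    def test_rejects_negative_isi(self):
        with pytest.raises(ValueError, match="nonnegative"):
            resource_trajectory(np.array([0.05] * 5 + [-0.1]), DEFAULT_PARAMS)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(params=params_strategy, isis=isis_strategy)
    def test_resource_stays_in_bounds(self, params, isis):
        traj = resource_trajectory(isis, params)
        assert np.all(traj.available > 0)
        assert np.all(traj.available <= params.r_max + 1e-12)
        assert traj.available[0] == params.r_max


class TestRecallProbability:
    def test_midpoint_at_threshold(self):
        assert recall_probability(DEFAULT_PARAMS.tau, DEFAULT_PARAMS) == 0.5

    def test_hand_evaluated_logistic(self):
        # 1 / (1 + exp(-13 * (0.23 - 0.11)))
        assert recall_probability(0.23, DEFAULT_PARAMS) == pytest.approx(
            0.82635, abs=5e-5
        )

    def test_step_limit_at_high_gain(self):
        steep = ModelParams(p=0.23, r=0.11, gain=1e4, tau=0.11)
        assert recall_probability(0.2, steep) > 0.999999
        assert recall_probability(0.05, steep) < 1e-6

    def test_strictly_increasing_in_strength(self):
        s = np.linspace(0, 1, 50)
        pr = recall_probability(s, DEFAULT_PARAMS)
        assert np.all(np.diff(pr) > 0)
        assert np.all((pr > 0) & (pr < 1))


class TestPredictTrial:
    def test_first_position_independent_of_isis(self):
        for sched in (_gap_schedule(3, 2500), _gap_schedule(1, 500)):
            assert predict_trial(sched, DEFAULT_PARAMS)[0] == pytest.approx(
                0.82635, abs=5e-5
            )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        params=params_strategy,
        isis=isis_strategy,
        k=st.integers(1, 6),
        extra=st.floats(0.01, 2.0),
    )
    def test_perturbing_one_interval_acts_only_forward(self, params, isis, k, extra):
        """Extra free time in interval k: exact equality at positions <= k,
        weak increase at every later position (proactive and global)."""
        base = resource_trajectory(isis, params).strengths
        bumped_isis = isis.copy()
        bumped_isis[k - 1] += extra
        bumped = resource_trajectory(bumped_isis, params).strengths
        np.testing.assert_array_equal(bumped[:k], base[:k])
        assert np.all(bumped[k:] >= base[k:] - 1e-15)

    @pytest.mark.parametrize("gap_position", range(1, 7))
    def test_long_gap_beats_short_gap_after_the_gap(self, gap_position):
        long = predict_trial(_gap_schedule(gap_position, 2500), DEFAULT_PARAMS)
        short = predict_trial(_gap_schedule(gap_position, 500), DEFAULT_PARAMS)
        np.testing.assert_array_equal(long[:gap_position], short[:gap_position])
        assert np.all(long[gap_position:] > short[gap_position:])

    def test_recovery_during_presentation_variant_weakly_helps(self):
        sched = _gap_schedule(3, 500)
        base = predict_trial(sched, DEFAULT_PARAMS)
        more = predict_trial(sched, DEFAULT_PARAMS, "isi_plus_presentation")
        assert np.all(more[1:] >= base[1:])
        with pytest.raises(ValueError, match="time_definition"):
            predict_trial(sched, DEFAULT_PARAMS, "bogus")

    def test_euler_oracle_agreement_on_random_schedules(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            isis_ms = rng.integers(0, 2501, size=6)
            params = ModelParams(
                p=rng.uniform(0.05, 0.8), r=rng.uniform(0.0, 1.5),
                gain=rng.uniform(2, 40), tau=rng.uniform(0, 0.5),
            )
            sched = schedule_for_trial(
                TrialSpec(
                    experiment_id="exp1", subject_id=1, block=1, trial=1,
                    condition="long_variable", isis_ms=tuple(int(x) for x in isis_ms),
                    presentation_ms=250, retention_ms=1250,
                )
            )
            fast = predict_trial(sched, params)
            slow = euler_recall_probabilities(isis_ms, params)
            np.testing.assert_allclose(fast, slow, atol=1e-6)


class TestConditionMeans:
    def test_more_free_time_helps_every_later_position(self, exp1_small):
        means = predict_condition_means(exp1_small, DEFAULT_PARAMS)
        wide = means.pivot(index="serial_position", columns="condition",
                           values="p_recall")
        assert np.all(
            wide.loc[2:, "long_fixed"] > wide.loc[2:, "short_fixed"]
        )
        assert wide.loc[1].nunique() == 1  # first item identical everywhere

    def test_long_fixed_equivalent_to_long_variable(self, exp1_small):
        means = predict_condition_means(exp1_small, DEFAULT_PARAMS)
        overall = means.groupby("condition")["p_recall"].mean()
        assert abs(overall["long_fixed"] - overall["long_variable"]) < 0.03

    def test_empty_design_is_an_error(self, exp1_small):
        from wmtime.design import ExperimentDesign

        empty = ExperimentDesign("exp1", 0, 0, exp1_small.trials.iloc[0:0])
        with pytest.raises(ValueError, match="empty"):
            predict_condition_means(empty, DEFAULT_PARAMS)


class TestModelParams:
    @pytest.mark.parametrize(
        "kwargs", [dict(p=0.0), dict(p=1.0), dict(r=-0.1), dict(gain=0.0),
                   dict(r_max=0.0)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    @pytest.mark.parametrize("name", ["params.json", "params.yaml"])
    def test_file_round_trip(self, tmp_path, name):
        p = ModelParams(p=0.3, r=0.2, gain=8.0, tau=0.15)
        path = tmp_path / name
        p.to_file(path)
        assert ModelParams.from_file(path) == p

    def test_predict_design_matches_per_trial_path(self, exp2b_small):
        probs = predict_design(exp2b_small, DEFAULT_PARAMS)
        for idx in (0, 100, 311):
            row = exp2b_small.trials.iloc[idx]
            sched = schedule_for_trial(TrialSpec.from_row(row))
            np.testing.assert_allclose(
                probs[idx], predict_trial(sched, DEFAULT_PARAMS), atol=1e-12
            )
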