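"""Trial simulator: event schedule, determinism, state invariants."""

import numpy as np
import pytest

from comdyn import ModelParameters, TrialConfig
from comdyn.simulate import run_block, run_coupled_pairs, run_trial


class TestZeroNoise:
    def test_symmetric_trial_stays_symmetric_and_undecided(self, zero_noise_hard):
        rec = zero_noise_hard
        tr = rec.traces
        np.testing.assert_array_equal(tr["S1"], tr["S2"])
        np.testing.assert_array_equal(tr["y_L"], tr["y_R"])
        assert rec.indecision
        assert rec.final_choice == 0

    def test_easy_trial_resolves_correctly_without_reversal(self, zero_noise_easy):
        rec = zero_noise_easy
        assert rec.final_choice == rec.correct_side == 1
        assert not rec.com
        assert rec.rt == rec.rt  # decided

    def test_left_right_relabelling_mirrors_trajectories(self, params):
        a = run_trial(TrialConfig(epsilon=6.4, correct_side=1, noise=False), params)
        b = run_trial(TrialConfig(epsilon=6.4, correct_side=2, noise=False), params)
        np.testing.assert_array_equal(a.traces["H1"], b.traces["H2"])
        np.testing.assert_array_equal(a.traces["y_L"], b.traces["y_R"])
        np.testing.assert_array_equal(a.traces["x"], -b.traces["x"])
        assert a.rt == b.rt
        assert a.final_choice == 1 and b.final_choice == 2

    def test_step_size_convergence_of_deterministic_trajectory(self, params):
        coarse = run_trial(TrialConfig(epsilon=51.2, noise=False, dt=0.5), params)
        fine = run_trial(TrialConfig(epsilon=51.2, noise=False, dt=0.05), params)
        assert abs(coarse.rt - fine.rt) <= 2.0  # within one coarse step pair
        # compare S1 on the common 10 ms grid
        c = coarse.traces["S1"][::20]
        f = fine.traces["S1"][::200][: len(c)]
        np.testing.assert_allclose(c[: len(f)], f, atol=2e-3)


class TestDeterminismAndInvariants:
    def test_same_master_seed_is_bitwise_reproducible(self, params):
        a = run_block(5, [0.0, 25.6], params, master_seed=77)
        b = run_block(5, [0.0, 25.6], params, master_seed=77)
        assert a.to_frame().equals(b.to_frame())

    def test_result_independent_of_batch_size(self, params):
        a = run_block(7, [3.2], params, master_seed=13, max_batch=2)
        b = run_block(7, [3.2], params, master_seed=13, max_batch=64)
        assert a.to_frame().equals(b.to_frame())

    def test_state_bounds_along_stochastic_trajectory(self, traced_trial):
        tr = traced_trial.traces
        assert np.all(tr["S1"] >= 0) and np.all(tr["S1"] <= 1)
        assert np.all(tr["S2"] >= 0) and np.all(tr["S2"] <= 1)
        for key in ("y_inh", "y_U", "y_L", "y_R"):
            assert np.all(tr[key] >= 0), key

    def test_record_invariants(self, small_frame):
        df = small_frame
        undecided = df[df.rt.isna()]
        assert (undecided.final_choice == 0).all()
        assert (df.loc[df.com, "final_choice"] != 0).all()
        assert set(df.loc[df.com, "com_direction"]) <= {"error-to-correct", "correct-to-error"}
        assert (df.loc[~df.com, "com_direction"] == "none").all()
        # motor clamp: nothing moves before the sensorimotor decision
        assert (df.loc[df.rt.isna(), "n_sign_changes"] == 0).all()

    def test_correct_side_counterbalanced(self, small_frame):
        counts = small_frame.groupby(["epsilon", "correct_side"]).size()
        for eps in small_frame.epsilon.unique():
            assert abs(counts[eps][1] - counts[eps][2]) <= 1

    def test_state_snapshot_reflects_gating_schedule(self, traced_trial, params):
        pre = traced_trial.state_at(100.0, params)
        assert pre.g_motor == params.g_baseline
        assert pre.y_U == 0.0 and pre.y_L == 0.0
        if traced_trial.rt == traced_trial.rt:
            post = traced_trial.state_at(900.0 + traced_trial.rt + 50.0, params)
            assert post.g_motor == 0.0
            assert post.g_unc_exc == params.g_reactivated
            assert 0.0 <= post.S1 <= 1.0 and 0.0 <= post.S2 <= 1.0

    def test_uncertainty_clamped_until_release(self, traced_trial):
        tr = traced_trial.traces
        t = tr["time"]
        pre = t < 900.0 + 500.0  # stimulus onset + release delay
        assert np.all(tr["y_U"][pre] == 0.0)


@pytest.fixture(scope="module")
def pairs(params):
    return run_coupled_pairs(30, params, master_seed=5)


class TestCoupledPairs:
    def test_bias_update_is_linear_in_first_trial_area(self, pairs, params):
        df = pairs.to_frame()
        first = df[df.stage == 1].set_index("pair_id")
        second = df[df.stage == 2].set_index("pair_id")
        expected = params.mu_tonic + 0.008 * first.uncertainty_area + 0.5
        np.testing.assert_allclose(second.mu_tonic, expected, rtol=1e-12)

    def test_zero_area_gives_beta_alone(self, pairs, params):
        df = pairs.to_frame()
        first = df[df.stage == 1].set_index("pair_id")
        second = df[df.stage == 2].set_index("pair_id")
        zero = first[first.uncertainty_area == 0.0]
        if len(zero):
            np.testing.assert_allclose(
                second.loc[zero.index, "mu_tonic"], params.mu_tonic + 0.5, rtol=1e-12)

    def test_bias_resets_between_pairs(self, pairs, params):
        df = pairs.to_frame()
        assert (df[df.stage == 1].mu_tonic == params.mu_tonic).all()

    def test_second_trial_epsilon_drawn_from_grid(self, pairs):
        df = pairs.to_frame()
        assert set(df[df.stage == 2].epsilon) <= {0.0, 3.2, 6.4, 12.8, 25.6, 51.2}


def test_nonpositive_trial_counts_rejected(params):
    with pytest.raises(ValueError):
        run_block(0, [0.0], params)
    with pytest.raises(ValueError):
        run_coupled_pairs(0, params)


def test_invalid_trial_config_rejected():
    with pytest.raises(ValueError):
        TrialConfig(dt=0.0)
    with pytest.raises(ValueError):
        TrialConfig(delay_inh=-1.0)
    with pytest.raises(ValueError):
        TrialConfig(correct_side=3)
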