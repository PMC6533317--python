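"""Behavioural read-outs on constructed and simulated data."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from comdyn import analysis
from comdyn.analysis import (
    accuracy_by_uncertainty,
    chronometric_summary,
    classify_change_of_mind,
    com_probability_curve,
    fit_weibull,
    normalize_feature,
    rt_uncertainty_regression,
    uncertainty_measures,
    weibull,
)

from conftest import make_record

GRID = np.array([0.0, 3.2, 6.4, 12.8, 25.6, 51.2])


def synthetic_frame(acc_by_eps, n=400, rng=None):
    """Deterministic per-trial frame with given per-condition accuracies."""
    rows = []
    for eps, acc in acc_by_eps.items():
        k = int(round(acc * n))
        for i in range(n):
            correct = i < k
            rows.append({
                "trial_id": len(rows), "epsilon": eps, "correct_side": 1,
                "rt": 500.0, "initial_choice": 1,
                "final_choice": 1 if correct else 2,
                "indecision": False, "com": False, "com_direction": "none",
                "n_sign_changes": 0, "uncertainty_peak": 0.1,
                "uncertainty_area": 10.0, "t_final": 700.0, "mu_tonic": 2.4,
                "seed": i,
            })
    return pd.DataFrame(rows)


class TestWeibullFit:
    def test_recovers_exact_parameters_from_noiseless_accuracies(self):
        from comdyn.analysis import fit_weibull_points

        acc = weibull(GRID, 7.32, 1.32)
        ls = fit_weibull_points(GRID, acc, np.full(len(GRID), 1000), method="ls")
        assert ls.alpha == pytest.approx(7.32, rel=1e-6)
        assert ls.beta == pytest.approx(1.32, rel=1e-6)
        mle = fit_weibull_points(GRID, acc, np.full(len(GRID), 1000), method="mle")
        assert mle.alpha == pytest.approx(7.32, rel=1e-4)
        assert mle.beta == pytest.approx(1.32, rel=1e-4)

    def test_trial_frame_fit_recovers_parameters_to_count_resolution(self):
        truth = {eps: weibull(eps, 7.32, 1.32) for eps in GRID}
        df = synthetic_frame({e: round(a * 10000) / 10000 for e, a in truth.items()}, n=10000)
        fit = fit_weibull(df, method="ls")
        assert fit.alpha == pytest.approx(7.32, rel=1e-3)
        assert fit.beta == pytest.approx(1.32, rel=1e-3)

    def test_probability_at_threshold(self):
        # by construction p(alpha) = 1 - 0.5/e for any slope
        assert weibull(7.32, 7.32, 1.32) == pytest.approx(1 - 0.5 * np.exp(-1))

    def test_needs_three_conditions(self):
        df = synthetic_frame({0.0: 0.5, 51.2: 1.0})
        with pytest.raises(ValueError):
            fit_weibull(df)


class TestNormalization:
    def test_basic_mapping(self):
        np.testing.assert_allclose(normalize_feature([2, 4, 6]), [0, 0.5, 1])

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            normalize_feature([3.0, 3.0, 3.0])

    @given(st.floats(0.1, 50), st.floats(-100, 100))
    @settings(max_examples=40, deadline=None)
    def test_affine_invariance(self, scale, shift):
        vals = np.array([1.0, 2.5, 4.0, 9.0])
        np.testing.assert_allclose(
            normalize_feature(vals * scale + shift), normalize_feature(vals), atol=1e-9)


class TestUncertaintyMeasures:
    def test_silent_population_gives_zero(self):
        rec = make_record(x=np.zeros(100), y_U=np.zeros(100))
        assert uncertainty_measures(rec) == (0.0, 0.0)

    def test_trapezoid_exact_for_triangle(self):
        h, n, dt = 3.0, 201, 0.5  # symmetric triangle over T = 100 ms
        t = np.arange(n) * dt
        T = t[-1]
        y = h * (1 - np.abs(t - T / 2) / (T / 2))
        rec = make_record(x=np.zeros(n), y_U=y, dt=dt)
        peak, area = uncertainty_measures(rec)
        assert peak == pytest.approx(h)
        # trapezoid rule is exact for piecewise-linear traces: area = h T / 2
        assert area == pytest.approx(h * T / 2, rel=1e-12)

    def test_zero_tail_adds_nothing(self):
        y = np.concatenate([np.linspace(0, 2, 50), np.linspace(2, 0, 50)])
        short = make_record(x=np.zeros(100), y_U=y)
        long = make_record(x=np.zeros(200), y_U=np.concatenate([y, np.zeros(100)]))
        assert uncertainty_measures(short)[0] == uncertainty_measures(long)[0]
        assert uncertainty_measures(short)[1] == pytest.approx(uncertainty_measures(long)[1])


class TestChangeOfMindClassifier:
    def test_monotone_movement_is_not_com(self):
        x = np.concatenate([np.zeros(10), np.linspace(0, 750, 200)])
        assert classify_change_of_mind(make_record(x=x)) == (False, "none")

    def test_reversal_reaching_correct_target(self):
        x = np.concatenate([np.zeros(10), np.linspace(0, -120, 60),
                            np.linspace(-120, 750, 200)])
        rec = make_record(x=x, final_choice=1, correct_side=1)
        assert classify_change_of_mind(rec) == (True, "error-to-correct")

    def test_reversal_reaching_wrong_target(self):
        x = np.concatenate([np.zeros(10), np.linspace(0, 120, 60),
                            np.linspace(120, -750, 200)])
        rec = make_record(x=x, final_choice=2, correct_side=1)
        assert classify_change_of_mind(rec) == (True, "correct-to-error")

    def test_reversal_without_target_is_not_com(self):
        x = np.concatenate([np.zeros(10), np.linspace(0, -120, 60),
                            np.linspace(-120, 200, 100)])
        rec = make_record(x=x, final_choice=0)
        rec.indecision = True
        assert classify_change_of_mind(rec) == (False, "none")

    def test_matches_online_flags_on_simulated_trial(self, traced_trial):
        com, direction = classify_change_of_mind(traced_trial)
        assert com == traced_trial.com
        if com:
            assert direction == traced_trial.com_direction


class TestSummaries:
    def test_single_trial_cell_has_undefined_sem(self):
        df = synthetic_frame({0.0: 1.0}, n=1)
        out = chronometric_summary(df)
        assert out.loc[0, "mean_rt"] == 500.0
        assert np.isnan(out.loc[0, "sem_rt"])

    def test_com_curve_partition_and_zero_case(self, small_block):
        curve = com_probability_curve(small_block)
        np.testing.assert_allclose(curve.p_any, curve.p_to_correct + curve.p_to_error,
                                   atol=1e-12)
        df = synthetic_frame({0.0: 0.5, 3.2: 0.6, 6.4: 0.7})
        zero = com_probability_curve(df)
        assert np.all(zero.p_any == 0)

    def test_perfectly_collinear_regression(self):
        df = synthetic_frame({0.0: 0.5, 3.2: 0.6, 6.4: 0.7})
        df["uncertainty_peak"] = df["rt"] * 0.001  # collinear by construction
        df.loc[df.index[:3], "rt"] = [400.0, 500.0, 600.0]
        df.loc[df.index[:3], "uncertainty_peak"] = [0.4, 0.5, 0.6]
        out = rt_uncertainty_regression(df)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["r_squared"] == pytest.approx(1.0)

    def test_regression_needs_three_points(self):
        df = synthetic_frame({0.0: 0.5}, n=2)
        with pytest.raises(ValueError):
            rt_uncertainty_regression(df)

    def test_quantile_binned_accuracy_table(self, small_block):
        out = accuracy_by_uncertainty(small_block, n_bins=5)
        assert len(out) == 5
        assert out["n"].sum() == (~small_block.to_frame().indecision).sum()
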