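import numpy as np
import pytest

from comdyn import ModelParameters, TrialConfig
from comdyn.simulate import run_block, run_trial


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def small_block(params):
    """Moderate stochastic block shared by the behavioural property tests."""
    return run_block(150, params=params, master_seed=11)


@pytest.fixture(scope="session")
def small_frame(small_block):
    return small_block.to_frame()


@pytest.fixture(scope="session")
def traced_trial(params):
    """One stochastic trial with full traces (hard condition)."""
    return run_trial(TrialConfig(epsilon=3.2, seed=42), params, store_traces=True)


@pytest.fixture(scope="session")
def zero_noise_easy(params):
    return run_trial(TrialConfig(epsilon=51.2, correct_side=1, noise=False), params)


@pytest.fixture(scope="session")
def zero_noise_hard(params):
    return run_trial(TrialConfig(epsilon=0.0, correct_side=1, noise=False), params)


def make_record(x, y_U=None, dt=0.5, final_choice=1, correct_side=1, rt=0.0):
    """Hand-constructed TrialRecord with traces, for read-out unit tests."""
    from comdyn.simulate import TrialRecord

    x = np.asarray(x, float)
    t = np.arange(len(x)) * dt
    if y_U is None:
        y_U = np.zeros_like(x)
    moving = np.abs(x) > 0
    traces = {
        "time": t,
        "x": x,
        "y_U": np.asarray(y_U, float),
        "y_L": np.where(moving, np.maximum(x, 0.0), 0.0),
        "y_R": np.where(moving, np.maximum(-x, 0.0), 0.0),
    }
    return TrialRecord(
        trial_id=0, epsilon=3.2, correct_side=correct_side, seed=0, rt=rt,
        initial_choice=1, final_choice=final_choice,
        indecision=final_choice == 0, com=False, com_direction="none",
        n_sign_changes=0, uncertainty_peak=float(np.max(traces["y_U"])),
        uncertainty_area=float(np.trapezoid(traces["y_U"], t)),
        t_final=float(t[-1]), mu_tonic=2.4, traces=traces,
    )
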