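"""Right-hand sides and static nonlinearities of the circuit model.

Pure functions only: no integration, no event logic.  Every function accepts
scalars or numpy arrays and broadcasts.  Internal time unit is ms, so all
derivatives are per ms; the kinetic product ``gamma * H`` of the gating
equation is divided by 1000 because its fitted constant carries seconds.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParameters

__all__ = [
    "transfer_H",
    "sensorimotor_current",
    "stimulus_current",
    "gating_derivatives",
    "uncertainty_derivatives",
    "motor_derivatives",
    "motor_position",
]


def transfer_H(x, params: ModelParameters):
    """Firing rate (Hz) of a sensorimotor population for total current x (nA).

    H(x) = (a x - b) / (1 - exp(-d (a x - b))), with the removable singularity
    at a x = b filled by its analytic limit 1/d.  Monotone increasing,
    non-negative, continuous.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite synaptic current passed to transfer_H")
    v = params.a * x - params.b
    # exp underflow/overflow is benign: both tails have finite limits
    with np.errstate(over="ignore", under="ignore"):
        denom = 1.0 - np.exp(-params.d * v)
    near = np.abs(v) < 1e-6
    safe = np.where(near, 1.0, denom)
    out = np.where(near, (1.0 + v * params.d / 2.0) / params.d, v / safe)
    out = np.where(v < -500.0 / params.d, 0.0, out)
    return out if out.ndim else float(out)


def stimulus_current(epsilon, preferred: bool, params: ModelParameters):
    """Stimulus input I_i = J_A_ext * mu0 * (1 +/- epsilon/100) in nA.

    ``preferred`` selects the population whose choice matches the true
    stimulus direction (the '+' sign).
    """
    epsilon = np.asarray(epsilon, dtype=float)
    if np.any((epsilon < 0) | (epsilon > 100)):
        raise ValueError("evidence quality epsilon must lie in [0, 100] %")
    sign = 1.0 if preferred else -1.0
    out = params.J_A_ext * params.mu0 * (1.0 + sign * epsilon / 100.0)
    return out if out.ndim else float(out)


def sensorimotor_current(S_self, S_other, I_stim, y_U, I_noise, params: ModelParameters):
    """Total current x_i (nA) into a sensorimotor population.

    x_i = J_N_self S_i - J_N_cross S_j + I0 + I_i + J_mc0 y_U + I_noise.
    The uncertainty feedback term is identical for both populations.
    """
    return (
        params.J_N_self * np.asarray(S_self, dtype=float)
        - params.J_N_cross * np.asarray(S_other, dtype=float)
        + params.I0
        + np.asarray(I_stim, dtype=float)
        + params.J_mc0 * np.asarray(y_U, dtype=float)
        + np.asarray(I_noise, dtype=float)
    )


def gating_derivatives(S1, S2, H1, H2, params: ModelParameters):
    """dS/dt (per ms) of the NMDA gating variables.

    dS_i/dt = -S_i/tau_s + (1 - S_i) * gamma * H_i / 1000.
    Keeps S in [0, 1] for non-negative rates.
    """
    k = params.gamma / 1000.0
    dS1 = -np.asarray(S1, float) / params.tau_s + (1.0 - np.asarray(S1, float)) * k * np.asarray(H1, float)
    dS2 = -np.asarray(S2, float) / params.tau_s + (1.0 - np.asarray(S2, float)) * k * np.asarray(H2, float)
    return dS1, dS2


def _relu(x):
    return np.maximum(x, 0.0)


def uncertainty_derivatives(y_inh, y_U, H1, H2, g_inh, g_exc, mu, params: ModelParameters):
    """(dy_inh/dt, dy_U/dt) per ms for the uncertainty-monitoring module.

    tau_mc dy_inh/dt = [J_V_inh (H1 + H2) - g_inh]_+ - y_inh
    tau_mc dy_U/dt   = [mu - J_N_inh y_inh - g_exc]_+ - y_U

    The threshold-linear rectifier applies to the full bracketed drive before
    the leak is subtracted.
    """
    d_inh = (_relu(params.J_V_inh * (np.asarray(H1, float) + np.asarray(H2, float)) - g_inh)
             - np.asarray(y_inh, float)) / params.tau_mc
    d_U = (_relu(mu - params.J_N_inh * np.asarray(y_inh, float) - g_exc)
           - np.asarray(y_U, float)) / params.tau_mc
    return d_inh, d_U


def motor_derivatives(y_L, y_R, H1, H2, g_motor, params: ModelParameters):
    """(dy_L/dt, dy_R/dt) per ms for the motor integrators.

    tau_h dy_L/dt = [J H1 - J_N_LR y_R - g]_+ - y_L   (and mirror for y_R).
    With the mutual inhibition equal to the leak the rate difference behaves
    as a line attractor integrating H1 - H2.
    """
    d_L = (_relu(params.J_motor * np.asarray(H1, float) - params.J_N_LR * np.asarray(y_R, float) - g_motor)
           - np.asarray(y_L, float)) / params.tau_h
    d_R = (_relu(params.J_motor * np.asarray(H2, float) - params.J_N_RL * np.asarray(y_L, float) - g_motor)
           - np.asarray(y_R, float)) / params.tau_h
    return d_L, d_R


def motor_position(y_L, y_R, params: ModelParameters):
    """Screen position x = q (y_L - y_R), q = |T_pos| / M_th.

    Antisymmetric in (y_L, y_R); |x| = |T_pos| exactly when the leading motor
    rate equals M_th with the other silent.  Positive x is population 1's
    choice target.
    """
    out = params.q * (np.asarray(y_L, float) - np.asarray(y_R, float))
    return out if out.ndim else float(out)
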