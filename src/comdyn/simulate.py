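"""Trial simulation: event schedule, batched Euler-Maruyama integration.

A trial runs on a fixed time grid (default 0.5 ms steps).  The schedule:

1. From trial start the top-down inhibition ``g`` clamps the uncertainty and
   motor modules at its baseline amplitude.
2. Stimulus currents switch on at ``t_stimulus_onset``.
3. ``g`` is removed from the inhibitory population ``delay_inh`` ms after
   stimulus onset and from the uncertainty-encoding population ``delay_unc``
   ms after stimulus onset.
4. When a sensorimotor firing rate first reaches the decision threshold the
   initial response time and choice are recorded, ``g`` is reinstated on the
   uncertainty module at its reactivation amplitude, and removed from the
   motor module.
5. Integration continues (no state is reset) until a motor rate crosses the
   target threshold (final choice) or the timeout elapses (indecision).

Blocks integrate many trials side by side in numpy arrays; each trial owns
an independent RNG stream spawned from the master seed, so results are
bitwise reproducible and independent of batch size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import transfer_H
from .params import ModelParameters

__all__ = [
    "TrialConfig",
    "TrialRecord",
    "TrialSet",
    "run_trial",
    "run_block",
    "run_coupled_pairs",
]

log = logging.getLogger(__name__)

EPSILON_GRID = (0.0, 3.2, 6.4, 12.8, 25.6, 51.2)

#: direction labels for change-of-mind trials
COM_TO_CORRECT = "error-to-correct"
COM_TO_ERROR = "correct-to-error"


@dataclass
class TrialConfig:
    """Protocol constants of a single trial (times in ms)."""

    epsilon: float = 0.0
    correct_side: int = 1
    t_stimulus_onset: float = 900.0
    t_timeout: float = 4000.0
    delay_inh: float = 400.0
    delay_unc: float = 500.0
    dt: float = 0.5
    seed: int = 0
    s_init: float = 0.1
    mu_override: float | None = None
    noise: bool = True
    #: fraction of |T_pos| the position must exceed before a movement
    #: direction is registered; suppresses noise wobble around x = 0 at
    #: movement onset when both motor rates are still near zero
    com_deadband_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_timeout <= 0:
            raise ValueError("t_timeout must be > 0")
        if self.delay_inh < 0 or self.delay_unc < 0:
            raise ValueError("gating-release delays must be >= 0")
        if self.correct_side not in (1, 2):
            raise ValueError("correct_side must be 1 or 2")


@dataclass
class NetworkState:
    """Instantaneous values of all dynamical variables plus gating amplitudes.

    Invariants: S1, S2 in [0, 1]; the threshold-linear variables (y_inh,
    y_U, y_L, y_R) are non-negative for non-negative initial conditions.
    """

    S1: float
    S2: float
    I_noise1: float
    I_noise2: float
    y_inh: float
    y_U: float
    y_L: float
    y_R: float
    g_unc_inh: float
    g_unc_exc: float
    g_motor: float


@dataclass
class TrialRecord:
    """Summary (and optionally full traces) of one simulated trial."""

    trial_id: int
    epsilon: float
    correct_side: int
    seed: int
    rt: float  # ms from stimulus onset; nan if no sensorimotor crossing
    initial_choice: int  # 1, 2 or 0 (none)
    final_choice: int  # 1, 2 or 0 (none)
    indecision: bool
    com: bool
    com_direction: str  # error-to-correct | correct-to-error | none
    n_sign_changes: int
    uncertainty_peak: float
    uncertainty_area: float  # trapezoidal, nA*ms over the recorded window
    t_final: float  # ms from stimulus onset to target/timeout
    mu_tonic: float
    traces: dict[str, np.ndarray] | None = None

    @property
    def correct(self) -> bool | None:
        if self.final_choice == 0:
            return None
        return self.final_choice == self.correct_side

    def state_at(self, t_ms: float, params, config: "TrialConfig | None" = None) -> NetworkState:
        """Snapshot of the recorded dynamical variables at time ``t_ms``
        (from trial start), with the gating amplitudes in force then.
        Requires traces."""
        if self.traces is None:
            raise ValueError("trial was recorded without traces")
        cfg = config or TrialConfig()
        tr = self.traces
        i = int(np.clip(np.searchsorted(tr["time"], t_ms), 0, len(tr["time"]) - 1))
        decided = self.rt == self.rt and t_ms >= cfg.t_stimulus_onset + self.rt
        if decided:
            g_inh = g_exc = params.g_reactivated
            g_mot = 0.0
        else:
            g_inh = params.g_baseline if t_ms < cfg.t_stimulus_onset + cfg.delay_inh else 0.0
            g_exc = params.g_baseline if t_ms < cfg.t_stimulus_onset + cfg.delay_unc else 0.0
            g_mot = params.g_baseline
        noise = tr.get("I_noise1")
        return NetworkState(
            S1=float(tr["S1"][i]), S2=float(tr["S2"][i]),
            I_noise1=float(noise[i]) if noise is not None else float("nan"),
            I_noise2=float(tr["I_noise2"][i]) if "I_noise2" in tr else float("nan"),
            y_inh=float(tr["y_inh"][i]), y_U=float(tr["y_U"][i]),
            y_L=float(tr["y_L"][i]), y_R=float(tr["y_R"][i]),
            g_unc_inh=float(g_inh), g_unc_exc=float(g_exc), g_motor=float(g_mot),
        )


@dataclass
class TrialSet:
    """A collection of trial records sharing one parameter profile."""

    records: list[TrialRecord]
    epsilon_grid: tuple[float, ...]
    n_trials_per_condition: int
    master_seed: int
    profile_hash: str
    extra: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Per-trial summary table (one row per trial, no traces)."""
        cols = [
            "trial_id", "epsilon", "correct_side", "rt", "initial_choice",
            "final_choice", "indecision", "com", "com_direction",
            "n_sign_changes", "uncertainty_peak", "uncertainty_area",
            "t_final", "mu_tonic", "seed",
        ]
        data = {c: [getattr(r, c) for r in self.records] for c in cols}
        df = pd.DataFrame(data)
        for key, values in self.extra.items():
            df[key] = values
        return df


# ----------------------------------------------------------------------
# batched integrator
# ----------------------------------------------------------------------

def _simulate_batch(
    params: ModelParameters,
    cfg: TrialConfig,
    epsilon: np.ndarray,
    correct_side: np.ndarray,
    seeds: Sequence[int],
    mu_tonic: np.ndarray | None = None,
    store_traces: bool = False,
) -> dict[str, np.ndarray]:
    """Integrate a batch of trials in lock-step; returns summary arrays."""
    n = len(epsilon)
    dt = cfg.dt
    n_steps = int(round((cfg.t_stimulus_onset + cfg.t_timeout) / dt))
    t_stim = cfg.t_stimulus_onset
    k_stim = int(round(t_stim / dt))
    k_inh = int(round((t_stim + cfg.delay_inh) / dt))
    k_unc = int(round((t_stim + cfg.delay_unc) / dt))

    p = params
    mu = np.full(n, p.mu_tonic) if mu_tonic is None else np.asarray(mu_tonic, float)
    sgn = np.where(correct_side == 1, 1.0, -1.0)
    I_pref = p.J_A_ext * p.mu0 * (1.0 + epsilon / 100.0)
    I_nonp = p.J_A_ext * p.mu0 * (1.0 - epsilon / 100.0)
    I1_on = np.where(sgn > 0, I_pref, I_nonp)
    I2_on = np.where(sgn > 0, I_nonp, I_pref)

    # state
    S1 = np.full(n, cfg.s_init)
    S2 = np.full(n, cfg.s_init)
    In1 = np.zeros(n)
    In2 = np.zeros(n)
    y_inh = np.zeros(n)
    y_U = np.zeros(n)
    y_L = np.zeros(n)
    y_R = np.zeros(n)

    # bookkeeping
    active = np.ones(n, bool)
    decided = np.zeros(n, bool)
    rt = np.full(n, np.nan)
    initial_choice = np.zeros(n, np.int8)
    final_choice = np.zeros(n, np.int8)
    t_final = np.full(n, np.nan)
    last_sign = np.zeros(n, np.int8)
    n_flips = np.zeros(n, np.int32)
    unc_peak = np.zeros(n)
    unc_area = np.zeros(n)

    k_sigma = p.sigma_noise * np.sqrt(dt / p.tau_noise) if cfg.noise else 0.0
    # deadband on the motor rate difference: |x| >= frac * |T_pos|
    deadband = cfg.com_deadband_frac * abs(p.T_pos) / p.q
    gk = p.gamma / 1000.0
    rngs = [np.random.Generator(np.random.PCG64(s)) for s in seeds]

    traces: dict[str, list] | None = None
    if store_traces:
        traces = {k: [] for k in ("H1", "H2", "y_inh", "y_U", "y_L", "y_R", "x", "S1", "S2")}

    chunk = 2048
    k0 = 0
    while k0 < n_steps and active.any():
        kc = min(chunk, n_steps - k0)
        if cfg.noise:
            xi = np.stack([rng.standard_normal((kc, 2)) for rng in rngs])
        else:
            xi = None
        for j in range(kc):
            k = k0 + j
            stim_on = k >= k_stim
            x1 = p.J_N_self * S1 - p.J_N_cross * S2 + p.I0 + p.J_mc0 * y_U + In1
            x2 = p.J_N_self * S2 - p.J_N_cross * S1 + p.I0 + p.J_mc0 * y_U + In2
            if stim_on:
                x1 = x1 + I1_on
                x2 = x2 + I2_on
            H1 = transfer_H(x1, p)
            H2 = transfer_H(x2, p)

            if store_traces:
                traces["H1"].append(H1.copy()); traces["H2"].append(H2.copy())
                traces["y_inh"].append(y_inh.copy()); traces["y_U"].append(y_U.copy())
                traces["y_L"].append(y_L.copy()); traces["y_R"].append(y_R.copy())
                traces["x"].append(p.q * (y_L - y_R))
                traces["S1"].append(S1.copy()); traces["S2"].append(S2.copy())

            # --- decision detection on the current grid point -------------
            if stim_on:
                Hmax = np.maximum(H1, H2)
                newly = active & ~decided & (Hmax >= p.decision_threshold)
                if newly.any():
                    tie = newly & (H1 == H2)
                    if tie.any():
                        warnings.warn(
                            "exact sensorimotor threshold tie; choosing population 1",
                            RuntimeWarning,
                        )
                    choice = np.where(H1 >= H2, 1, 2).astype(np.int8)
                    initial_choice[newly] = choice[newly]
                    rt[newly] = k * dt - t_stim
                    decided |= newly

            # --- gating amplitudes ----------------------------------------
            g_inh = np.where(decided, p.g_reactivated,
                             p.g_baseline if k < k_inh else 0.0)
            g_unc = np.where(decided, p.g_reactivated,
                             p.g_baseline if k < k_unc else 0.0)
            g_mot = np.where(decided, 0.0, p.g_baseline)

            # --- derivatives ---------------------------------------------
            dS1 = -S1 / p.tau_s + (1.0 - S1) * gk * H1
            dS2 = -S2 / p.tau_s + (1.0 - S2) * gk * H2
            d_inh = (np.maximum(p.J_V_inh * (H1 + H2) - g_inh, 0.0) - y_inh) / p.tau_mc
            d_U = (np.maximum(mu - p.J_N_inh * y_inh - g_unc, 0.0) - y_U) / p.tau_mc
            d_L = (np.maximum(p.J_motor * H1 - p.J_N_LR * y_R - g_mot, 0.0) - y_L) / p.tau_h
            d_R = (np.maximum(p.J_motor * H2 - p.J_N_RL * y_L - g_mot, 0.0) - y_R) / p.tau_h

            S1n = S1 + dt * dS1
            S2n = S2 + dt * dS2
            y_inh_n = y_inh + dt * d_inh
            y_U_n = y_U + dt * d_U
            y_L_n = y_L + dt * d_L
            y_R_n = y_R + dt * d_R
            if xi is not None:
                In1n = In1 - In1 * (dt / p.tau_noise) + k_sigma * xi[:, j, 0]
                In2n = In2 - In2 * (dt / p.tau_noise) + k_sigma * xi[:, j, 1]
            else:
                In1n = In1 - In1 * (dt / p.tau_noise)
                In2n = In2 - In2 * (dt / p.tau_noise)

            if not np.all(np.isfinite(S1n[active])) or not np.all(np.isfinite(y_U_n[active])):
                bad = np.where(active & (~np.isfinite(S1n) | ~np.isfinite(y_U_n)))[0]
                raise FloatingPointError(
                    f"non-finite state at step {k} (t={k*dt:.1f} ms), trial lanes {bad[:5]}"
                )

            # freeze finished lanes
            S1 = np.where(active, S1n, S1)
            S2 = np.where(active, S2n, S2)
            In1 = np.where(active, In1n, In1)
            In2 = np.where(active, In2n, In2)
            # uncertainty accumulators (trapezoid) over the recorded window
            unc_area = np.where(active, unc_area + 0.5 * (y_U + y_U_n) * dt, unc_area)
            y_inh = np.where(active, y_inh_n, y_inh)
            y_U = np.where(active, y_U_n, y_U)
            y_L = np.where(active, y_L_n, y_L)
            y_R = np.where(active, y_R_n, y_R)
            unc_peak = np.where(active, np.maximum(unc_peak, y_U), unc_peak)

            # --- movement sign tracking (after movement initiation) -------
            moving = active & decided
            if moving.any():
                diff = y_L - y_R
                sgn_now = np.where(np.abs(diff) >= deadband, np.sign(diff), 0.0).astype(np.int8)
                upd = moving & (sgn_now != 0)
                flip = upd & (last_sign != 0) & (sgn_now != last_sign)
                n_flips[flip] += 1
                last_sign[upd] = sgn_now[upd]

                # --- motor target detection ------------------------------
                reached = moving & ((y_L >= p.M_th) | (y_R >= p.M_th))
                if reached.any():
                    fc = np.where(y_L >= y_R, 1, 2).astype(np.int8)
                    final_choice[reached] = fc[reached]
                    t_final[reached] = (k + 1) * dt - t_stim
                    active &= ~reached
        k0 += kc

    # timeout for whatever is left
    timeout = active
    t_final[timeout] = n_steps * dt - t_stim

    indecision = final_choice == 0
    com = (n_flips >= 1) & ~indecision
    out = {
        "epsilon": epsilon,
        "correct_side": correct_side.astype(np.int8),
        "rt": rt,
        "initial_choice": initial_choice,
        "final_choice": final_choice,
        "indecision": indecision,
        "com": com,
        "n_sign_changes": n_flips,
        "uncertainty_peak": unc_peak,
        "uncertainty_area": unc_area,
        "t_final": t_final,
        "mu_tonic": mu,
    }
    if store_traces:
        tr = {k: np.stack(v, axis=1) for k, v in traces.items()}
        tr["time"] = np.arange(tr["H1"].shape[1]) * dt
        out["traces"] = tr
    return out


def _records_from_batch(out: dict, seeds: Sequence[int], id_offset: int = 0) -> list[TrialRecord]:
    n = len(out["epsilon"])
    traces = out.get("traces")
    records = []
    for i in range(n):
        final = int(out["final_choice"][i])
        com = bool(out["com"][i])
        if not com:
            direction = "none"
        elif final == int(out["correct_side"][i]):
            direction = COM_TO_CORRECT
        else:
            direction = COM_TO_ERROR
        tr = None
        if traces is not None:
            tr = {k: (v[i] if k != "time" else v) for k, v in traces.items()}
        records.append(
            TrialRecord(
                trial_id=id_offset + i,
                epsilon=float(out["epsilon"][i]),
                correct_side=int(out["correct_side"][i]),
                seed=int(seeds[i]),
                rt=float(out["rt"][i]),
                initial_choice=int(out["initial_choice"][i]),
                final_choice=final,
                indecision=bool(out["indecision"][i]),
                com=com,
                com_direction=direction,
                n_sign_changes=int(out["n_sign_changes"][i]),
                uncertainty_peak=float(out["uncertainty_peak"][i]),
                uncertainty_area=float(out["uncertainty_area"][i]),
                t_final=float(out["t_final"][i]),
                mu_tonic=float(out["mu_tonic"][i]),
                traces=tr,
            )
        )
    return records


# ----------------------------------------------------------------------
# public entry points
# ----------------------------------------------------------------------

def run_trial(config: TrialConfig, params: ModelParameters,
              store_traces: bool = True) -> TrialRecord:
    """Integrate a single trial; traces are recorded by default."""
    out = _simulate_batch(
        params, config,
        epsilon=np.array([config.epsilon], float),
        correct_side=np.array([config.correct_side]),
        seeds=[config.seed],
        mu_tonic=None if config.mu_override is None else np.array([config.mu_override]),
        store_traces=store_traces,
    )
    return _records_from_batch(out, [config.seed])[0]


def _spawned_seeds(master_seed: int, n: int) -> list[int]:
    """Independent 31-bit per-trial seeds derived from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] >> 1) for s in ss.spawn(n)]


def run_block(
    n_trials: int,
    epsilon_grid: Iterable[float] = EPSILON_GRID,
    params: ModelParameters | None = None,
    master_seed: int = 0,
    config: TrialConfig | None = None,
    max_batch: int = 2048,
) -> TrialSet:
    """Simulate ``n_trials`` per evidence-quality condition.

    The correct side is counterbalanced within each condition; indecision
    trials are flagged but retained (the analysis layer excludes them).
    Per-trial RNG streams are spawned from ``master_seed`` so the result is
    bitwise reproducible and independent of ``max_batch``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    params = params or ModelParameters()
    cfg = config or TrialConfig()
    grid = tuple(float(e) for e in epsilon_grid)
    total = n_trials * len(grid)
    seeds = _spawned_seeds(master_seed, total)

    records: list[TrialRecord] = []
    idx = 0
    for eps in grid:
        eps_arr = np.full(n_trials, eps)
        sides = np.where(np.arange(n_trials) % 2 == 0, 1, 2)
        for lo in range(0, n_trials, max_batch):
            hi = min(lo + max_batch, n_trials)
            batch_seeds = seeds[idx + lo: idx + hi]
            out = _simulate_batch(params, cfg, eps_arr[lo:hi], sides[lo:hi], batch_seeds)
            records.extend(_records_from_batch(out, batch_seeds, id_offset=idx + lo))
        idx += n_trials
        log.info("condition eps=%.1f%%: %d trials done", eps, n_trials)
    return TrialSet(
        records=records,
        epsilon_grid=grid,
        n_trials_per_condition=n_trials,
        master_seed=master_seed,
        profile_hash=params.profile_hash(),
    )


def run_coupled_pairs(
    n_pairs: int,
    params: ModelParameters | None = None,
    master_seed: int = 0,
    epsilon_grid: Iterable[float] = EPSILON_GRID,
    config: TrialConfig | None = None,
    alpha: float = 0.008,
    beta: float = 0.5,
    max_batch: int = 2048,
) -> TrialSet:
    """Simulate pairs of coupled trials.

    The first trial of each pair runs with the default tonic bias.  Its
    uncertainty area X_n sets the second trial's bias increment
    C = alpha * X_n + beta, applied as mu -> mu + C; after the pair the
    stored bias resets to zero.  Evidence quality of both trials is drawn
    uniformly from the grid.

    Returned records carry ``pair_id`` and ``stage`` (1 or 2) columns in
    ``TrialSet.extra``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    params = params or ModelParameters()
    cfg = config or TrialConfig()
    grid = np.array(sorted(float(e) for e in epsilon_grid))
    ss = np.random.SeedSequence(master_seed)
    ss_protocol, ss_trials = ss.spawn(2)
    proto_rng = np.random.Generator(np.random.PCG64(ss_protocol))
    eps1 = grid[proto_rng.integers(0, len(grid), n_pairs)]
    eps2 = grid[proto_rng.integers(0, len(grid), n_pairs)]
    sides1 = proto_rng.integers(1, 3, n_pairs)
    sides2 = proto_rng.integers(1, 3, n_pairs)
    seeds = [int(s.generate_state(1)[0] >> 1) for s in ss_trials.spawn(2 * n_pairs)]
    seeds1, seeds2 = seeds[:n_pairs], seeds[n_pairs:]

    records: list[TrialRecord] = []
    extra_pair: list[int] = []
    extra_stage: list[int] = []
    extra_first_correct: list[bool] = []
    extra_first_eps: list[float] = []
    for lo in range(0, n_pairs, max_batch):
        hi = min(lo + max_batch, n_pairs)
        out1 = _simulate_batch(params, cfg, eps1[lo:hi], sides1[lo:hi], seeds1[lo:hi])
        C = alpha * out1["uncertainty_area"] + beta
        mu2 = params.mu_tonic + C
        out2 = _simulate_batch(params, cfg, eps2[lo:hi], sides2[lo:hi], seeds2[lo:hi],
                               mu_tonic=mu2)
        rec1 = _records_from_batch(out1, seeds1[lo:hi], id_offset=2 * lo)
        rec2 = _records_from_batch(out2, seeds2[lo:hi], id_offset=2 * lo + (hi - lo))
        first_correct = out1["final_choice"] == out1["correct_side"]
        for i, (r1, r2) in enumerate(zip(rec1, rec2)):
            records.extend([r1, r2])
            extra_pair.extend([lo + i, lo + i])
            extra_stage.extend([1, 2])
            extra_first_correct.extend([bool(first_correct[i])] * 2)
            extra_first_eps.extend([r1.epsilon] * 2)
    return TrialSet(
        records=records,
        epsilon_grid=tuple(grid),
        n_trials_per_condition=n_pairs,
        master_seed=master_seed,
        profile_hash=params.profile_hash(),
        extra={
            "pair_id": extra_pair,
            "stage": extra_stage,
            "first_correct": extra_first_correct,
            "first_epsilon": extra_first_eps,
        },
    )
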