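"""Phase-plane and bifurcation analysis of the 2-D sensorimotor subsystem.

With the uncertainty feedback replaced by a constant current ``I_fb`` and
noise off, the gating variables (S1, S2) form an autonomous planar system.
This module finds its nullclines, fixed points (with stability from the
Jacobian) and the bifurcation structure as ``I_fb`` varies: at low feedback
the system is in the winner-take-all regime (two choice attractors separated
by a saddle); above a critical current only a single choice-neutral stable
state survives.

All roots are found numerically (dense multi-start root search polished by a
Newton solver and cross-checked against sign-change bracketing on a grid);
no continuation software is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, fsolve

from .core import transfer_H
from .params import ModelParameters

__all__ = [
    "FixedPoint",
    "BifurcationDiagram",
    "reduced_rhs",
    "nullclines",
    "find_fixed_points",
    "bifurcation_scan",
    "critical_current",
]

RESIDUAL_TOL = 1e-10
DEDUP_TOL = 1e-6
#: |S1 - S2| below which a stable state counts as choice-neutral
NEUTRAL_TOL = 0.05


@dataclass
class FixedPoint:
    """A steady state of the reduced (S1, S2) system."""

    S1: float
    S2: float
    eigenvalues: tuple[complex, complex]
    stable: bool
    label: str  # choice-1 attractor | choice-2 attractor | saddle | choice-neutral attractor | other

    @property
    def classification(self) -> str:
        ev = np.asarray(self.eigenvalues)
        re = ev.real
        if np.all(re < 0):
            return "stable focus" if np.any(np.abs(ev.imag) > 1e-12) else "stable node"
        if re[0] * re[1] < 0:
            return "saddle"
        return "unstable"

    def firing_rate(self, epsilon: float, I_fb: float, params: ModelParameters,
                    stimulus_on: bool = True) -> float:
        """H of population 1 at this steady state (for rate-axis diagrams)."""
        I1 = params.J_A_ext * params.mu0 * (1 + epsilon / 100.0) if stimulus_on else 0.0
        x1 = params.J_N_self * self.S1 - params.J_N_cross * self.S2 + params.I0 + I1 + I_fb
        return float(transfer_H(x1, params))


@dataclass
class BifurcationDiagram:
    """Fixed points indexed by constant feedback current."""

    I_fb_grid: np.ndarray
    fixed_points: list[list[FixedPoint]]
    critical_currents: list[float] = field(default_factory=list)

    def n_stable(self) -> np.ndarray:
        return np.array([sum(fp.stable for fp in fps) for fps in self.fixed_points])


def reduced_rhs(S1, S2, epsilon: float, I_fb: float, params: ModelParameters,
                stimulus_on: bool = True):
    """(dS1/dt, dS2/dt) per ms of the noise-free sensorimotor subsystem.

    The uncertainty feedback term is frozen at the constant ``I_fb`` (nA);
    ``stimulus_on`` selects whether the external stimulus currents at the
    given evidence quality are applied.
    """
    S1 = np.asarray(S1, float)
    S2 = np.asarray(S2, float)
    if stimulus_on:
        I1 = params.J_A_ext * params.mu0 * (1 + epsilon / 100.0)
        I2 = params.J_A_ext * params.mu0 * (1 - epsilon / 100.0)
    else:
        I1 = I2 = 0.0
    x1 = params.J_N_self * S1 - params.J_N_cross * S2 + params.I0 + I1 + I_fb
    x2 = params.J_N_self * S2 - params.J_N_cross * S1 + params.I0 + I2 + I_fb
    k = params.gamma / 1000.0
    dS1 = -S1 / params.tau_s + (1.0 - S1) * k * transfer_H(x1, params)
    dS2 = -S2 / params.tau_s + (1.0 - S2) * k * transfer_H(x2, params)
    return dS1, dS2


def _rhs_vec(S, epsilon, I_fb, params, stimulus_on):
    d1, d2 = reduced_rhs(S[0], S[1], epsilon, I_fb, params, stimulus_on)
    return np.array([d1, d2])


def nullclines(epsilon: float, I_fb: float, params: ModelParameters,
               resolution: int = 200, stimulus_on: bool = True
               ) -> tuple[np.ndarray, np.ndarray]:
    """Points on the dS1/dt = 0 and dS2/dt = 0 curves in the unit square.

    For each grid value of one variable, all roots of the other variable's
    rate-of-change are located by sign-change bracketing and polished with a
    bounded root solver.  Returns two (n, 2) arrays of (S1, S2) points.
    """
    if resolution < 50:
        raise ValueError("resolution must be >= 50")
    grid = np.linspace(0.0, 1.0, resolution)
    fine = np.linspace(0.0, 1.0, 4 * resolution)

    def branch(which: int) -> np.ndarray:
        pts = []
        for fixed in grid:
            if which == 0:  # roots in S1 for fixed S2
                vals = reduced_rhs(fine, fixed, epsilon, I_fb, params, stimulus_on)[0]
                f = lambda s: reduced_rhs(s, fixed, epsilon, I_fb, params, stimulus_on)[0]
            else:  # roots in S2 for fixed S1
                vals = reduced_rhs(fixed, fine, epsilon, I_fb, params, stimulus_on)[1]
                f = lambda s: reduced_rhs(fixed, s, epsilon, I_fb, params, stimulus_on)[1]
            sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
            for i in sign_change:
                root = brentq(f, fine[i], fine[i + 1], xtol=1e-12)
                pts.append((root, fixed) if which == 0 else (fixed, root))
        return np.array(pts) if pts else np.empty((0, 2))

    return branch(0), branch(1)


def _jacobian(S, epsilon, I_fb, params, stimulus_on, h=1e-7):
    J = np.zeros((2, 2))
    for j in range(2):
        dp = np.array(S, float)
        dm = np.array(S, float)
        dp[j] += h
        dm[j] -= h
        J[:, j] = (_rhs_vec(dp, epsilon, I_fb, params, stimulus_on)
                   - _rhs_vec(dm, epsilon, I_fb, params, stimulus_on)) / (2 * h)
    return J


def find_fixed_points(epsilon: float, I_fb: float, params: ModelParameters,
                      n_starts: int = 15, stimulus_on: bool = True) -> list[FixedPoint]:
    """All steady states in [0, 1]^2, classified and labelled.

    Multi-start Newton search from an ``n_starts`` x ``n_starts`` lattice,
    deduplicated at distance 1e-6; residuals are verified below 1e-10.
    Stable states are labelled choice-1/choice-2 attractors or, when
    |S1 - S2| < 0.05, the choice-neutral attractor.
    """
    found: list[np.ndarray] = []
    for s1 in np.linspace(0.0, 1.0, n_starts):
        for s2 in np.linspace(0.0, 1.0, n_starts):
            sol, _info, ier, _msg = fsolve(
                _rhs_vec, [s1, s2], args=(epsilon, I_fb, params, stimulus_on),
                full_output=True, xtol=1e-13,
            )
            if ier != 1:
                continue
            if not (-1e-9 <= sol[0] <= 1 + 1e-9 and -1e-9 <= sol[1] <= 1 + 1e-9):
                continue
            if np.max(np.abs(_rhs_vec(sol, epsilon, I_fb, params, stimulus_on))) > RESIDUAL_TOL:
                continue
            if any(np.hypot(sol[0] - p[0], sol[1] - p[1]) < DEDUP_TOL for p in found):
                continue
            found.append(np.clip(sol, 0.0, 1.0))

    out: list[FixedPoint] = []
    for p in sorted(found, key=lambda q: (q[0], q[1])):
        ev = np.linalg.eigvals(_jacobian(p, epsilon, I_fb, params, stimulus_on))
        stable = bool(np.all(ev.real < 0))
        if stable:
            if abs(p[0] - p[1]) < NEUTRAL_TOL:
                label = "choice-neutral attractor"
            elif p[0] > p[1]:
                label = "choice-1 attractor"
            else:
                label = "choice-2 attractor"
        elif ev.real[0] * ev.real[1] < 0:
            label = "saddle"
        else:
            label = "other"
        out.append(FixedPoint(float(p[0]), float(p[1]),
                              (complex(ev[0]), complex(ev[1])), stable, label))
    return out


def _n_choice_attractors(epsilon, I_fb, params, stimulus_on):
    fps = find_fixed_points(epsilon, I_fb, params, stimulus_on=stimulus_on)
    return sum(fp.stable and abs(fp.S1 - fp.S2) >= NEUTRAL_TOL for fp in fps)


def critical_current(epsilon: float, params: ModelParameters,
                     I_max: float = 0.08, tol: float = 1e-4,
                     stimulus_on: bool = True) -> float:
    """Smallest constant feedback current at which the choice attractors
    have vanished, leaving a single stable steady state (bisection to
    ``tol`` nA)."""
    lo, hi = 0.0, I_max
    if _n_choice_attractors(epsilon, lo, params, stimulus_on) == 0:
        return 0.0
    if _n_choice_attractors(epsilon, hi, params, stimulus_on) > 0:
        raise ValueError(f"choice attractors persist up to I_fb = {I_max} nA")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _n_choice_attractors(epsilon, mid, params, stimulus_on) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def bifurcation_scan(epsilon: float, I_fb_range: tuple[float, float],
                     params: ModelParameters, n_steps: int = 40,
                     stimulus_on: bool = True) -> BifurcationDiagram:
    """Fixed points on a grid of feedback currents, with critical currents.

    Critical currents (changes in the number of choice attractors) are
    located by bisection to 1e-4 nA.  The scan is stateless: reversing the
    range yields identical branches.
    """
    lo, hi = I_fb_range
    if lo == hi:
        raise ValueError("I_fb_range must be non-degenerate")
    grid = np.linspace(min(lo, hi), max(lo, hi), n_steps)
    fps = [find_fixed_points(epsilon, ifb, params, stimulus_on=stimulus_on) for ifb in grid]

    criticals = []
    counts = [sum(fp.stable and abs(fp.S1 - fp.S2) >= NEUTRAL_TOL for fp in f) for f in fps]
    for i in range(len(grid) - 1):
        if counts[i] != counts[i + 1]:
            a, b = grid[i], grid[i + 1]
            ca = counts[i]
            while b - a > 1e-4:
                m = 0.5 * (a + b)
                if _n_choice_attractors(epsilon, m, params, stimulus_on) == ca:
                    a = m
                else:
                    b = m
            criticals.append(0.5 * (a + b))
    return BifurcationDiagram(grid, fps, criticals)
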