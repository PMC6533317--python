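"""Model parameters and configuration handling.

All couplings are in nA (or nA per Hz where they scale a firing rate), rates
in Hz, and times in ms internally.  Configuration files may give any time
constant in seconds by writing the value as a string with a unit suffix,
e.g. ``tau_s: "0.1 s"``; bare numbers are taken to be in the internal unit.

The default profile couples the published reduced two-variable sensorimotor
model (input-output function and synaptic constants fitted to a spiking
network) to an uncertainty-monitoring microcircuit and a motor integrator.
Couplings of the uncertainty and motor modules were calibrated once against
the behavioural test suite and are frozen in ``profiles/default.yaml``; every
value can be overridden from a user profile.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import yaml

__all__ = ["ModelParameters", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """A configuration file violated the parameter schema."""


#: fields whose internal unit is milliseconds (unit suffixes allowed in config)
_TIME_FIELDS = frozenset({"tau_s", "tau_mc", "tau_h", "tau_noise"})

_UNIT_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*(ms|s)\s*$")


def _parse_time(value: Any, key: str) -> float:
    """Convert a config time value to ms; strings may carry an ``ms``/``s`` suffix."""
    if isinstance(value, str):
        m = _UNIT_RE.match(value)
        if m is None:
            raise ConfigError(f"cannot parse time value {value!r} for key {key!r}")
        num, unit = float(m.group(1)), m.group(2)
        return num * 1000.0 if unit == "s" else num
    return float(value)


@dataclass
class ModelParameters:
    """All circuit constants, in physical units (nA, Hz, ms).

    Sensorimotor populations (two-variable reduced model)
    -----------------------------------------------------
    a, b, d : gain (Hz/nA), threshold (Hz) and curvature (s) of the
        single-cell input-output function fitted to a leaky integrate-and-fire
        neuron.
    gamma : kinetic constant of the NMDA synaptic gating (dimensionless;
        multiplies a rate in Hz, time kept in seconds for this product).
    tau_s : NMDA gating time constant, ms.
    J_N_self, J_N_cross : recurrent self/cross couplings, nA.
    I0 : background current, nA.
    J_A_ext : external synaptic coupling, nA/Hz.
    mu0 : stimulus strength constant, Hz.
    J_mc0 : excitatory feedback coupling from the uncertainty-encoding
        population into both sensorimotor populations, nA per unit activity.

    Uncertainty-monitoring module
    -----------------------------
    tau_mc : time constant of both populations, ms.
    J_V_inh : sensorimotor -> inhibitory coupling, nA/Hz.
    J_N_inh : inhibitory -> uncertainty-encoding coupling (effective, converts
        the inhibitory activity into nA).
    mu_tonic : tonic excitatory bias onto the uncertainty-encoding
        population, nA; modulated across coupled trials.
    g_baseline, g_reactivated : top-down inhibition amplitudes, nA.  The
        baseline value clamps the module from trial start; the larger value is
        reinstated at decision time.

    Motor module
    ------------
    tau_h : motor integrator time constant, ms.
    J_motor : sensorimotor -> motor coupling, nA/Hz.
    J_N_LR, J_N_RL : mutual-inhibition couplings (effective).  Equal to the
        leak (1.0) they make the rate difference a line attractor that
        integrates the sensorimotor rate difference.
    T_pos : choice-target position, screen units.
    M_th : motor target threshold, Hz.

    Read-out and noise
    ------------------
    decision_threshold : sensorimotor firing-rate threshold defining the
        initial response time, Hz.
    sigma_noise, tau_noise : amplitude (nA) and correlation time (ms) of the
        Ornstein-Uhlenbeck noise currents entering the sensorimotor input.
    """

    # sensorimotor (published reduced-model constants)
    a: float = 270.0
    b: float = 108.0
    d: float = 0.154
    gamma: float = 0.641
    tau_s: float = 100.0
    J_N_self: float = 0.266
    J_N_cross: float = 0.065
    I0: float = 0.325
    J_A_ext: float = 5.2e-4
    mu0: float = 30.0
    J_mc0: float = 0.042
    # uncertainty-monitoring module (calibrated profile)
    tau_mc: float = 160.0
    J_V_inh: float = 0.021
    J_N_inh: float = 2.0
    mu_tonic: float = 2.4
    g_baseline: float = 1000.0
    g_reactivated: float = 3000.0
    # motor module
    tau_h: float = 300.0
    J_motor: float = 1.0
    J_N_LR: float = 1.0
    J_N_RL: float = 1.0
    T_pos: float = 750.0
    M_th: float = 17.4
    # read-out and noise
    decision_threshold: float = 35.5
    sigma_noise: float = 0.011
    tau_noise: float = 14.0

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    @property
    def q(self) -> float:
        """Motor-to-position scaling |T_pos| / M_th (recomputed, never stored)."""
        return abs(self.T_pos) / self.M_th

    def validate(self) -> None:
        for name in ("tau_s", "tau_mc", "tau_h", "tau_noise"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"time constant {name} must be > 0")
        for name in ("decision_threshold", "M_th"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"threshold {name} must be > 0")
        if self.d <= 0:
            raise ConfigError("transfer-function curvature d must be > 0")
        if self.g_baseline < 0 or self.g_reactivated < self.g_baseline:
            raise ConfigError(
                "require g_reactivated >= g_baseline >= 0 "
                f"(got {self.g_reactivated}, {self.g_baseline})"
            )
        if self.sigma_noise < 0:
            raise ConfigError("sigma_noise must be >= 0")

    # ------------------------------------------------------------------
    def replace(self, **overrides: Any) -> "ModelParameters":
        """A copy with the given fields replaced (validated)."""
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown parameter key(s): {sorted(unknown)}")
        kwargs = {}
        for key, value in data.items():
            kwargs[key] = _parse_time(value, key) if key in _TIME_FIELDS else float(value)
        return cls(**kwargs)

    def profile_hash(self) -> str:
        """Stable short hash of the fully resolved parameter profile."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class Protocol:
    """Simulation protocol: the evidence-quality grid and trial counts."""

    epsilon_grid: tuple[float, ...] = (0.0, 3.2, 6.4, 12.8, 25.6, 51.2)
    n_trials: int = 100
    master_seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return {
            "epsilon_grid": list(self.epsilon_grid),
            "n_trials": int(self.n_trials),
            "master_seed": int(self.master_seed),
        }


def default_parameters() -> ModelParameters:
    """The shipped default profile (``profiles/default.yaml``)."""
    text = resources.files("comdyn").joinpath("profiles/default.yaml").read_text()
    data = yaml.safe_load(text) or {}
    return ModelParameters.from_dict(data.get("parameters", {}))


def load_config(path: str | None) -> tuple[ModelParameters, Protocol]:
    """Load a YAML/JSON config file into (parameters, protocol).

    An empty or missing-section file yields the full default profile.  Unknown
    keys raise :class:`ConfigError` naming the offending key.
    """
    if path is None:
        return default_parameters(), Protocol()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - {"parameters", "protocol"}
    if unknown:
        raise ConfigError(f"unknown top-level config key(s): {sorted(unknown)}")
    base = default_parameters().to_dict()
    overrides = data.get("parameters", {}) or {}
    known = set(base)
    bad = set(overrides) - known
    if bad:
        raise ConfigError(f"unknown parameter key(s): {sorted(bad)}")
    for key in _TIME_FIELDS & set(overrides):
        overrides[key] = _parse_time(overrides[key], key)
    base.update({k: float(v) for k, v in overrides.items()})
    params = ModelParameters.from_dict(base)

    proto_data = data.get("protocol", {}) or {}
    bad = set(proto_data) - {"epsilon_grid", "n_trials", "master_seed"}
    if bad:
        raise ConfigError(f"unknown protocol key(s): {sorted(bad)}")
    protocol = Protocol(
        epsilon_grid=tuple(proto_data.get("epsilon_grid", Protocol.epsilon_grid)),
        n_trials=int(proto_data.get("n_trials", Protocol.n_trials)),
        master_seed=int(proto_data.get("master_seed", Protocol.master_seed)),
    )
    return params, protocol
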