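"""Two-state oxygenation environments: periodic schedules and telegraph-style noise.

Oxygen is binary — fully oxygenated (``Y = 1``, normoxia) or depleted
(``Y = 0``, hypoxia) — and switches instantaneously.  A profile is a sequence
of constant-state segments.  Periodic profiles alternate fixed interval
lengths ``T_N``/``T_H``; stochastic profiles flip state with a per-step
Bernoulli probability (``P_N→H = 1/T_N`` converts a cycle time into a
switching rate), giving geometric dwell times with mean ``1/p`` steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PeriodicSchedule",
    "SwitchingRates",
    "OxygenProfile",
    "periodic_profile",
    "stochastic_profile",
    "profile_q",
    "constant_profile",
    "write_profile",
    "read_profile",
]

NORMOXIA = 1
HYPOXIA = 0


@dataclass(frozen=True)
class PeriodicSchedule:
    """Fixed alternation of ``t_n`` minutes normoxia and ``t_h`` minutes hypoxia."""

    t_n: float
    t_h: float

    def __post_init__(self) -> None:
        if not (self.t_n > 0 and self.t_h > 0):
            raise ValueError(
                f"interval lengths must be > 0, got T_N={self.t_n}, T_H={self.t_h}"
            )

    @property
    def cycle_length(self) -> float:
        return self.t_n + self.t_h

    @property
    def q(self) -> float:
        """Fraction of the cycle spent normoxic."""
        return self.t_n / (self.t_n + self.t_h)


@dataclass(frozen=True)
class SwitchingRates:
    """Per-step switching probabilities of the two-state environment.

    ``p_nh`` is the probability per time step of leaving normoxia, ``p_hn`` of
    leaving hypoxia.  The stationary normoxic fraction is
    ``p_hn / (p_nh + p_hn)``.
    """

    p_nh: float
    p_hn: float

    def __post_init__(self) -> None:
        for name, p in (("p_nh", self.p_nh), ("p_hn", self.p_hn)):
            if not 0.0 < p <= 1.0:
                raise ValueError(f"switching probability {name} must be in (0, 1], got {p}")

    @property
    def stationary_q(self) -> float:
        return self.p_hn / (self.p_nh + self.p_hn)


@dataclass(frozen=True)
class OxygenProfile:
    """Piecewise-constant oxygenation trace.

    ``durations[i]`` minutes are spent in state ``states[i]`` (0 hypoxic,
    1 normoxic); consecutive segments have distinct states.  ``dt`` is the
    sampling step used when the profile is expanded to a time grid.
    """

    durations: np.ndarray
    states: np.ndarray
    dt: float = 1.0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        durations = np.asarray(self.durations, dtype=float)
        states = np.asarray(self.states, dtype=np.int8)
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "states", states)
        if durations.size == 0:
            raise ValueError("oxygen profile must contain at least one segment")
        if durations.shape != states.shape:
            raise ValueError("durations and states must have equal length")
        if np.any(durations <= 0):
            raise ValueError("all segment durations must be > 0")
        if not np.isin(states, (HYPOXIA, NORMOXIA)).all():
            raise ValueError("oxygen states must be 0 (hypoxic) or 1 (normoxic)")
        if not self.dt > 0:
            raise ValueError(f"sampling step dt must be > 0, got {self.dt}")

    @property
    def total_time(self) -> float:
        return float(self.durations.sum())

    @property
    def n_segments(self) -> int:
        return int(self.durations.size)

    @property
    def q(self) -> float:
        return profile_q(self)

    def step_states(self) -> np.ndarray:
        """State per ``dt`` step over the full trace (segment durations must be dt multiples)."""
        counts = np.rint(self.durations / self.dt).astype(np.int64)
        if not np.allclose(counts * self.dt, self.durations, atol=1e-9 * self.dt):
            raise ValueError("segment durations are not integer multiples of dt")
        return np.repeat(self.states, counts)


def profile_q(profile: OxygenProfile) -> float:
    """Duration-weighted fraction of the trace spent normoxic."""
    return float(profile.durations[profile.states == NORMOXIA].sum() / profile.total_time)


def constant_profile(state: int, total_time: float, dt: float = 1.0) -> OxygenProfile:
    """A single-segment profile that never switches."""
    return OxygenProfile(np.array([total_time]), np.array([state]), dt=dt)


def periodic_profile(
    schedule: PeriodicSchedule, n_cycles: int, dt: float = 1.0
) -> OxygenProfile:
    """Alternating normoxia/hypoxia for ``n_cycles`` cycles, starting normoxic."""
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    durations = np.tile([schedule.t_n, schedule.t_h], n_cycles)
    states = np.tile([NORMOXIA, HYPOXIA], n_cycles)
    return OxygenProfile(
        durations,
        states,
        dt=dt,
        meta={"kind": "periodic", "t_n": schedule.t_n, "t_h": schedule.t_h,
              "n_cycles": n_cycles, "dt": dt},
    )


def _segments_from_steps(step_states: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    change = np.flatnonzero(np.diff(step_states)) + 1
    bounds = np.concatenate(([0], change, [step_states.size]))
    durations = np.diff(bounds) * dt
    states = step_states[bounds[:-1]]
    return durations, states


def stochastic_profile(
    rates: SwitchingRates,
    total_time: float,
    dt: float = 1.0,
    seed: int | np.random.Generator | None = None,
    initial_state: int = NORMOXIA,
) -> OxygenProfile:
    """Simulate a two-state telegraph-style trace with per-step Bernoulli switching.

    At each step of length ``dt`` the state flips with probability ``p_nh``
    (if currently normoxic) or ``p_hn`` (if hypoxic).  The trace starts in
    ``initial_state`` (normoxia by default, mirroring the periodic
    initialization) and is reproducible given ``seed``.
    """
    if not (total_time >= dt > 0):
        raise ValueError(f"need total_time >= dt > 0, got total_time={total_time}, dt={dt}")
    if initial_state not in (HYPOXIA, NORMOXIA):
        raise ValueError(f"initial_state must be 0 or 1, got {initial_state}")
    rng = np.random.default_rng(seed)
    n_steps = int(round(total_time / dt))
    if rates.p_nh == rates.p_hn:
        # flip probability is state-independent: draw all flips at once
        flips = rng.random(n_steps - 1) < rates.p_nh
        parity = np.concatenate(([0], np.cumsum(flips) & 1)).astype(np.int8)
        steps = np.int8(initial_state) ^ parity
    else:
        draws = rng.random(n_steps - 1)
        steps = np.empty(n_steps, dtype=np.int8)
        state = initial_state
        steps[0] = state
        for i in range(n_steps - 1):
            p = rates.p_nh if state == NORMOXIA else rates.p_hn
            if draws[i] < p:
                state = NORMOXIA + HYPOXIA - state
            steps[i + 1] = state
    durations, states = _segments_from_steps(steps, dt)
    meta = {"kind": "stochastic", "p_nh": rates.p_nh, "p_hn": rates.p_hn,
            "total_time": total_time, "dt": dt, "initial_state": initial_state}
    if isinstance(seed, (int, np.integer)):
        meta["seed"] = int(seed)
    return OxygenProfile(durations, states, dt=dt, meta=meta)


def write_profile(profile: OxygenProfile, path: str | Path) -> None:
    """Write a profile as two-column CSV with a JSON metadata sidecar."""
    path = Path(path)
    frame = pd.DataFrame({"duration_min": profile.durations, "state": profile.states})
    frame.to_csv(path, index=False)
    sidecar = {"dt": profile.dt, **profile.meta}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_profile(path: str | Path) -> OxygenProfile:
    path = Path(path)
    frame = pd.read_csv(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    dt = meta.pop("dt", 1.0)
    return OxygenProfile(
        frame["duration_min"].to_numpy(),
        frame["state"].to_numpy(),
        dt=dt,
        meta=meta,
    )
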