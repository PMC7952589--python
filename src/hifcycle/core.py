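"""Fitness payoffs for HIF-α regulation strategies in a two-state oxygen environment.

The model treats a cancer cell's net proliferation rate (its *payoff* ``G``,
per minute) as a function of its HIF-α expression level ``u ∈ [0, 1]`` and of
the fraction of time ``q`` the microenvironment spends fully oxygenated.
Expressing HIF-α carries a proliferation cost ``c·u`` at all times; during
hypoxia it buys protection against an oxygen-starvation death rate, reducing
mortality from ``m/k`` to ``m/(k + b·u)``.

This module provides the payoff functions themselves, the closed-form optimum
for a *constitutive* strategy (``u`` held fixed), the payoff of a *perfect*
strategy (instantaneous, cost-free switching between ``u=0`` and ``u=1``), and
the cost calibration that pins ``c`` so that a permanently hypoxic environment
selects for full expression (``u* = 1`` at ``q = 0``).
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass, replace
from pathlib import Path

__all__ = [
    "ModelParameters",
    "calibrate_cost",
    "normoxic_payoff",
    "hypoxic_payoff",
    "expected_payoff",
    "perfect_strategy_payoff",
    "optimal_constitutive_u",
    "optimal_constitutive_payoff",
    "load_parameters",
]


@dataclass(frozen=True)
class ModelParameters:
    """Constants of the proliferation payoff.

    Parameters
    ----------
    r : float
        Baseline proliferation rate, per minute.
    c : float
        Proliferation cost per unit of HIF-α expression, per minute.  The
        default is the calibrated value ``m·b/(k+b)²`` (see
        :func:`calibrate_cost`).
    m : float
        Hypoxia-induced death rate at zero tolerance, per minute.
    k : float
        Intrinsic hypoxia tolerance without HIF-α stabilization
        (dimensionless; normalized to 1).
    b : float
        Mortality-reduction benefit per unit of HIF-α expression
        (dimensionless).
    """

    r: float = 0.00048
    c: float = 0.0001328
    m: float = 0.00083
    k: float = 1.0
    b: float = 4.0

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"baseline proliferation rate r must be > 0, got {self.r}")
        if self.c < 0:
            raise ValueError(f"cost coefficient c must be >= 0, got {self.c}")
        if self.m < 0:
            raise ValueError(f"death rate m must be >= 0, got {self.m}")
        if not self.k > 0:
            raise ValueError(f"hypoxia tolerance k must be > 0, got {self.k}")
        if self.b < 0:
            raise ValueError(f"benefit b must be >= 0, got {self.b}")

    def with_calibrated_cost(self) -> "ModelParameters":
        """Return a copy whose cost ``c`` satisfies ``u*(q=0) = 1``."""
        return replace(self, c=calibrate_cost(self.m, self.b, self.k))


def calibrate_cost(m: float, b: float, k: float) -> float:
    """Cost coefficient that makes full expression optimal under pure hypoxia.

    Solves ``u*(q=0) = 1`` for ``c`` in the constitutive optimum, giving
    ``c = m / [b(1 + k/b)]² = m·b/(k + b)²``.
    """
    if b <= 0:
        raise ValueError(f"benefit b must be > 0 to calibrate the cost, got {b}")
    if k < 0:
        raise ValueError(f"tolerance k must be >= 0, got {k}")
    if m < 0:
        raise ValueError(f"death rate m must be >= 0, got {m}")
    return m * b / (k + b) ** 2


def _check_unit_interval(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


def normoxic_payoff(u: float, params: ModelParameters = ModelParameters()) -> float:
    """Net proliferation rate under full oxygenation: ``r − c·u``."""
    _check_unit_interval(u, "expression level u")
    return params.r - params.c * u


def hypoxic_payoff(u: float, params: ModelParameters = ModelParameters()) -> float:
    """Net proliferation rate under oxygen depletion: ``r − c·u − m/(k + b·u)``."""
    _check_unit_interval(u, "expression level u")
    return params.r - params.c * u - params.m / (params.k + params.b * u)


def expected_payoff(
    u: float, q: float, params: ModelParameters = ModelParameters()
) -> float:
    """Time-averaged payoff of holding expression ``u`` with normoxic fraction ``q``.

    ``G(u; q) = q·G_N(u) + (1−q)·G_H(u) = r − c·u − (1−q)·m/(k + b·u)``.
    Linear in ``q``; reduces to :func:`normoxic_payoff` at ``q=1`` and
    :func:`hypoxic_payoff` at ``q=0``.
    """
    _check_unit_interval(u, "expression level u")
    _check_unit_interval(q, "normoxic fraction q")
    return params.r - params.c * u - (1.0 - q) * params.m / (params.k + params.b * u)


def perfect_strategy_payoff(
    q: float, params: ModelParameters = ModelParameters()
) -> float:
    """Payoff of instantaneously tracking the environment (``u=0`` in normoxia, ``u=1`` in hypoxia).

    ``G_perfect = r − (1−q)·(c + m/(k + b))``; affine and decreasing in the
    hypoxic fraction ``1−q``.
    """
    _check_unit_interval(q, "normoxic fraction q")
    return params.r - (1.0 - q) * (params.c + params.m / (params.k + params.b))


def optimal_constitutive_u(
    q: float, params: ModelParameters = ModelParameters()
) -> float:
    """Expression level maximizing :func:`expected_payoff`, clamped to ``[0, 1]``.

    The unconstrained maximizer is ``u* = sqrt(m(1−q)/(b·c)) − k/b``; it is
    decreasing in ``q`` and may leave the unit interval, in which case the
    constrained optimum sits on the nearer boundary (the payoff is concave in
    ``u``).
    """
    _check_unit_interval(q, "normoxic fraction q")
    if params.c <= 0 or params.b <= 0:
        raise ValueError(
            "the constitutive optimum requires c > 0 and b > 0 "
            f"(got c={params.c}, b={params.b})"
        )
    u_star = math.sqrt(params.m * (1.0 - q) / (params.b * params.c)) - params.k / params.b
    return min(1.0, max(0.0, u_star))


def optimal_constitutive_payoff(
    q: float, params: ModelParameters = ModelParameters()
) -> float:
    """Maximal payoff available to a fixed-expression strategy at normoxic fraction ``q``.

    Evaluates :func:`expected_payoff` at the clamped optimum.  When the clamp
    is inactive this equals ``r − 2·sqrt(c·m·(1−q)/b) + c·k/b``; it never
    exceeds :func:`perfect_strategy_payoff`, with equality at ``q ∈ {0, 1}``
    under the calibrated cost.
    """
    return expected_payoff(optimal_constitutive_u(q, params), q, params)


def load_parameters(path: str | Path) -> ModelParameters:
    """Read :class:`ModelParameters` from a JSON or TOML file.

    Recognized keys: ``r``, ``c``, ``m``, ``k``, ``b``.  The value of ``c``
    may be the string ``"calibrated"`` to request the calibration
    ``c = m·b/(k+b)²``.  Missing keys fall back to the defaults; unknown keys
    are rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = json.load(fh)
    known = {"r", "c", "m", "k", "b"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown parameter keys in {path.name}: {sorted(unknown)}")
    calibrate = raw.get("c") == "calibrated"
    if calibrate:
        raw = {key: val for key, val in raw.items() if key != "c"}
    params = ModelParameters(**raw)
    return params.with_calibrated_cost() if calibrate else params
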