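"""Optimal facultative strategy bounds and selection coefficients.

For periodic environments the cycle-averaged payoff is available in closed
form, so the optimal ``(u_min, u_max)`` pair is found with a derivative-free
constrained local optimizer (COBYLA) launched from a lattice of starting
points.  For stochastic environments no steady state exists; the payoff is
instead evaluated numerically along a simulated trace for every pair on a
grid of candidate values (``0 ≤ u_min < u_max ≤ 1``), the per-trace argmax is
recorded, and replicate traces give a mean and standard error.

The fitness advantage of the facultative over the constitutive strategy is
summarized by the selection coefficient ``SC = (G_F − G_C)/G_C``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .core import (
    ModelParameters,
    optimal_constitutive_payoff,
    optimal_constitutive_u,
)
from .dynamics import (
    DEFAULT_ALPHA0,
    DEFAULT_ALPHA1,
    _cycle_payoff_arrays,
    closed_form_cycle_payoff,
    FacultativeStrategy,
)
from .environment import (
    NORMOXIA,
    OxygenProfile,
    PeriodicSchedule,
    SwitchingRates,
    stochastic_profile,
)

__all__ = [
    "OptimizationResult",
    "optimize_fixed",
    "optimize_stochastic",
    "grid_optimum_for_profile",
    "selection_coefficient",
    "selection_surface",
    "SelectionSurface",
]

#: Payoffs closer than this are treated as tied in grid searches.
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class OptimizationResult:
    """Optimal strategy bounds and the payoff they achieve.

    For stochastic environments ``u_min_star``/``u_max_star`` are the means
    across replicate traces, with per-replicate optima and standard errors
    attached; for fixed schedules the replicate fields are ``None``.
    """

    u_min_star: float
    u_max_star: float
    payoff: float
    n_replicates: int = 1
    replicate_u_min: np.ndarray | None = None
    replicate_u_max: np.ndarray | None = None
    u_min_se: float | None = None
    u_max_se: float | None = None
    seeds: list[int] = field(default_factory=list)


def _cobyla_from(x0, objective):
    constraints = [
        {"type": "ineq", "fun": lambda x: x[0]},
        {"type": "ineq", "fun": lambda x: 1.0 - x[1]},
        {"type": "ineq", "fun": lambda x: x[1] - x[0]},
    ]
    return minimize(
        objective,
        x0,
        method="COBYLA",
        constraints=constraints,
        options={"rhobeg": 0.2, "tol": 1e-12, "maxiter": 10_000},
    )


def optimize_fixed(
    schedule: PeriodicSchedule,
    params: ModelParameters = ModelParameters(),
    alpha0: float = DEFAULT_ALPHA0,
    alpha1: float = DEFAULT_ALPHA1,
) -> OptimizationResult:
    """Maximize the closed-form cycle payoff over ``0 ≤ u_min ≤ u_max ≤ 1``.

    COBYLA is run from a deterministic coarse lattice of starting points
    (local optima can appear near the ``u_max = 1`` boundary) and the best
    converged solution is returned.
    """

    def objective(x):
        u_lo = min(max(x[0], 0.0), 1.0)
        u_hi = min(max(x[1], u_lo), 1.0)
        return -_cycle_payoff_arrays(u_lo, u_hi, schedule, alpha0, alpha1, params)

    lattice = (0.1, 0.3, 0.5, 0.7, 0.9)
    best = None
    n_converged = 0
    for lo in lattice:
        for hi in lattice:
            if lo >= hi:
                continue
            res = _cobyla_from([lo, hi], objective)
            if res.success or res.fun is not None:
                n_converged += res.success
            if best is None or res.fun < best.fun:
                best = res
    if best is None or n_converged == 0:
        raise RuntimeError(
            f"COBYLA failed to converge from every start for schedule {schedule}: {best}"
        )
    u_lo = float(min(max(best.x[0], 0.0), 1.0))
    u_hi = float(min(max(best.x[1], u_lo), 1.0))
    return OptimizationResult(u_min_star=u_lo, u_max_star=u_hi, payoff=float(-best.fun))


def _strategy_grid(grid_n: int) -> tuple[np.ndarray, np.ndarray]:
    """All pairs with u_min < u_max from ``grid_n`` equally spaced values in [0, 1]."""
    if grid_n < 2:
        raise ValueError(f"grid_n must be >= 2, got {grid_n}")
    values = np.linspace(0.0, 1.0, grid_n)
    i_lo, i_hi = np.triu_indices(grid_n, k=1)
    return values[i_lo], values[i_hi]


def _tied_argmax(payoffs: np.ndarray) -> int:
    """Index of the maximal payoff; ties within tolerance resolve to the first
    (smallest u_min, then smallest u_max, given the grid's ordering)."""
    return int(np.flatnonzero(payoffs >= payoffs.max() - _TIE_TOL)[0])


def grid_optimum_for_profile(
    profile: OxygenProfile,
    params: ModelParameters = ModelParameters(),
    alpha0: float = DEFAULT_ALPHA0,
    alpha1: float = DEFAULT_ALPHA1,
    grid_n: int = 250,
    u0_rule_q: float | None = None,
) -> tuple[float, float, float]:
    """Best ``(u_min, u_max, payoff)`` on the candidate grid for one oxygen trace.

    The relaxation recursion is stepped once per ``dt`` for all grid pairs
    simultaneously; the payoff of a pair is the plain average of its
    instantaneous payoff over all time points.  Each pair starts halfway
    between the constitutive optimum (at ``u0_rule_q``, default the profile's
    nominal normoxic fraction) and its own ``u_max``.
    """
    steps = profile.step_states()
    u_min, u_max = _strategy_grid(grid_n)
    q0 = profile.q if u0_rule_q is None else u0_rule_q
    u = 0.5 * (optimal_constitutive_u(q0, params) + u_max)
    decay_h = np.exp(-alpha0 * profile.dt)
    decay_n = np.exp(-alpha1 * profile.dt)
    total = np.zeros_like(u_min)
    for state in steps:
        if state == NORMOXIA:
            total += params.r - params.c * u
            u = u_min + (u - u_min) * decay_n
        else:
            total += params.r - params.c * u - params.m / (params.k + params.b * u)
            u = u_max + (u - u_max) * decay_h
    payoffs = total / steps.size
    best = _tied_argmax(payoffs)
    return float(u_min[best]), float(u_max[best]), float(payoffs[best])


def optimize_stochastic(
    rates: SwitchingRates,
    params: ModelParameters = ModelParameters(),
    alpha0: float = DEFAULT_ALPHA0,
    alpha1: float = DEFAULT_ALPHA1,
    grid_n: int = 250,
    total_time: float = 2000.0,
    n_replicates: int = 10,
    seed: int | None = None,
    dt: float = 1.0,
) -> OptimizationResult:
    """Grid-search the optimal bounds across replicate stochastic traces.

    One trace is generated per replicate and reused for every candidate pair
    (common random numbers keep the argmax comparison low-variance); the
    result reports the mean and standard error of the per-replicate optima.
    The initial expression follows the halfway rule evaluated at the
    stationary normoxic fraction ``p_hn/(p_nh + p_hn)``.
    """
    if total_time <= 0:
        raise ValueError(f"total_time must be > 0, got {total_time}")
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    root = np.random.default_rng(seed)
    rep_seeds = [int(s) for s in root.integers(0, 2**31 - 1, size=n_replicates)]
    best_lo = np.empty(n_replicates)
    best_hi = np.empty(n_replicates)
    best_payoff = np.empty(n_replicates)
    for i, rep_seed in enumerate(rep_seeds):
        profile = stochastic_profile(rates, total_time, dt=dt, seed=rep_seed)
        best_lo[i], best_hi[i], best_payoff[i] = grid_optimum_for_profile(
            profile, params, alpha0, alpha1, grid_n, u0_rule_q=rates.stationary_q
        )
    def se(x):
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    return OptimizationResult(
        u_min_star=float(best_lo.mean()),
        u_max_star=float(best_hi.mean()),
        payoff=float(best_payoff.mean()),
        n_replicates=n_replicates,
        replicate_u_min=best_lo,
        replicate_u_max=best_hi,
        u_min_se=se(best_lo),
        u_max_se=se(best_hi),
        seeds=rep_seeds,
    )


def selection_coefficient(payoff_facultative: float, payoff_constitutive: float) -> float:
    """Relative fitness advantage ``(G_F − G_C)/G_C`` of facultative regulation.

    Undefined for ``G_C = 0``; a negative comparator inverts the sign's
    meaning, so it triggers a warning rather than an error.
    """
    if payoff_constitutive == 0:
        raise ZeroDivisionError(
            "selection coefficient undefined for zero constitutive payoff"
        )
    if payoff_constitutive < 0:
        warnings.warn(
            "constitutive payoff is negative; the selection coefficient's sign "
            "no longer orders fitness",
            RuntimeWarning,
            stacklevel=2,
        )
    return (payoff_facultative - payoff_constitutive) / payoff_constitutive


@dataclass(frozen=True)
class SelectionSurface:
    """Selection coefficient over the ``(u_min, u_max)`` plane for one schedule.

    ``sc[i, j]`` compares the facultative strategy ``(values[i], values[j])``
    with the optimal constitutive strategy at the schedule's ``q``; cells
    with ``u_min >= u_max`` are NaN (infeasible).
    """

    values: np.ndarray
    payoff: np.ndarray
    sc: np.ndarray
    constitutive_payoff: float

    def argmax(self) -> tuple[float, float]:
        flat = np.where(np.isnan(self.sc), -np.inf, self.sc)
        i, j = np.unravel_index(int(np.argmax(flat)), flat.shape)
        return float(self.values[i]), float(self.values[j])


def selection_surface(
    schedule: PeriodicSchedule,
    params: ModelParameters = ModelParameters(),
    alpha0: float = DEFAULT_ALPHA0,
    alpha1: float = DEFAULT_ALPHA1,
    grid_n: int = 101,
) -> SelectionSurface:
    """Closed-form payoff and SC at every feasible grid pair of bounds."""
    if grid_n < 2:
        raise ValueError(f"grid_n must be >= 2, got {grid_n}")
    values = np.linspace(0.0, 1.0, grid_n)
    lo = values[:, None]
    hi = values[None, :]
    feasible = lo < hi
    payoff = np.full((grid_n, grid_n), np.nan)
    u_lo, u_hi = np.broadcast_arrays(lo, hi)
    payoff[feasible] = _cycle_payoff_arrays(
        u_lo[feasible], u_hi[feasible], schedule, alpha0, alpha1, params
    )
    g_c = optimal_constitutive_payoff(schedule.q, params)
    sc = (payoff - g_c) / g_c
    return SelectionSurface(values=values, payoff=payoff, sc=sc, constitutive_payoff=g_c)
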