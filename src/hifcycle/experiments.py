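"""Config-driven numerical experiments with tabular outputs.

Each runner reproduces one of the model's headline computations — the
constitutive-vs-perfect payoff scan over ``q``, optimal facultative bounds
for fixed 10/120-minute cycles together with their selection surfaces, the
stochastic-switching replicate study, and the kinetic-rate estimates — and
writes CSV tables plus a JSON summary.  Every output directory receives a
sidecar with the fully resolved configuration and seeds, so any run can be
replayed exactly.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ModelParameters,
    optimal_constitutive_payoff,
    optimal_constitutive_u,
    perfect_strategy_payoff,
)
from .dynamics import (
    DEFAULT_ALPHA0,
    DEFAULT_ALPHA1,
    FacultativeStrategy,
    simulate_trajectory,
)
from .environment import (
    PeriodicSchedule,
    SwitchingRates,
    periodic_profile,
    stochastic_profile,
)
from .kinetics import estimate_rates
from .optimize import (
    optimize_fixed,
    optimize_stochastic,
    selection_surface,
)

__all__ = [
    "ExperimentConfig",
    "run_constitutive_scan",
    "run_fixed_interval",
    "run_stochastic",
    "run_kinetics",
    "run_surface",
]

_PARAM_KEYS = {"r", "c", "m", "k", "b"}


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated settings for the experiment runners.

    Unknown keys in a config mapping are rejected outright; every value is
    checked against the owning module's preconditions before any computation
    starts (constructing the parameter, schedule, and rate objects performs
    the checks).
    """

    params: ModelParameters = ModelParameters()
    alpha0: float = DEFAULT_ALPHA0
    alpha1: float = DEFAULT_ALPHA1
    schedules: tuple[tuple[float, float], ...] = ((10.0, 10.0), (120.0, 120.0))
    switch_probs: tuple[float, ...] = (0.1, 0.0083)
    q_grid_n: int = 101
    surface_grid_n: int = 101
    grid_n: int = 250
    total_time: float = 2000.0
    n_replicates: int = 10
    dt: float = 1.0
    seed: int = 0
    rise_times: tuple[float, ...] = (60.0, 240.0)
    decay_times: tuple[float, ...] = (1.0, 5.0)
    kinetics_labels: tuple[str, ...] = ("TOV112D", "A2780s")

    def __post_init__(self) -> None:
        if not (self.alpha0 > 0 and self.alpha1 > 0):
            raise ValueError("relaxation rates must be > 0")
        if self.q_grid_n < 2 or self.surface_grid_n < 2 or self.grid_n < 2:
            raise ValueError("grid sizes must be >= 2")
        if self.total_time <= 0 or self.dt <= 0 or self.n_replicates < 1:
            raise ValueError("total_time, dt must be > 0 and n_replicates >= 1")
        for t_n, t_h in self.schedules:
            PeriodicSchedule(t_n, t_h)
        for p in self.switch_probs:
            SwitchingRates(p, p)
        if len(self.rise_times) != len(self.decay_times) or (
            len(self.kinetics_labels) != len(self.rise_times)
        ):
            raise ValueError("kinetics labels, rise and decay times must align")

    @classmethod
    def from_mapping(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "params" in raw and isinstance(raw["params"], dict):
            params_raw = dict(raw["params"])
            bad = set(params_raw) - _PARAM_KEYS
            if bad:
                raise ValueError(f"unknown parameter keys: {sorted(bad)}")
            calibrate = params_raw.get("c") == "calibrated"
            if calibrate:
                params_raw.pop("c")
            params = ModelParameters(**params_raw)
            raw["params"] = params.with_calibrated_cost() if calibrate else params
        for key in ("schedules",):
            if key in raw:
                raw[key] = tuple(tuple(pair) for pair in raw[key])
        for key in ("switch_probs", "rise_times", "decay_times", "kinetics_labels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        path = Path(path)
        if path.suffix.lower() == ".toml":
            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        else:
            with open(path) as fh:
                raw = json.load(fh)
        return cls.from_mapping(raw)

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        out["params"] = dataclasses.asdict(self.params)
        return out


def _write_sidecar(outdir: Path, config: ExperimentConfig, extra: dict | None = None) -> None:
    payload = {"config": config.resolved()}
    if extra:
        payload.update(extra)
    (outdir / "run.json").write_text(json.dumps(payload, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_constitutive_scan(config: ExperimentConfig, outdir: str | Path) -> Path:
    """Perfect vs optimal-constitutive payoffs over a grid of normoxic fractions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    q_grid = np.linspace(0.0, 1.0, config.q_grid_n)
    rows = [
        {
            "q": q,
            "perfect_payoff": perfect_strategy_payoff(q, config.params),
            "u_star": optimal_constitutive_u(q, config.params),
            "constitutive_payoff": optimal_constitutive_payoff(q, config.params),
        }
        for q in q_grid
    ]
    frame = pd.DataFrame(rows)
    csv_path = outdir / "constitutive_scan.csv"
    frame.to_csv(csv_path, index=False)
    midpoint = {
        "q": 0.5,
        "u_star": optimal_constitutive_u(0.5, config.params),
        "perfect_payoff": perfect_strategy_payoff(0.5, config.params),
        "constitutive_payoff": optimal_constitutive_payoff(0.5, config.params),
    }
    _write_sidecar(outdir, config, {"midpoint": midpoint})
    return csv_path


def run_fixed_interval(config: ExperimentConfig, outdir: str | Path) -> Path:
    """Optimal bounds, steady-state trajectories and selection surfaces per schedule.

    Payoffs are also reported normalized to the perfect strategy, whose
    normalized column is identically 1.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summaries = []
    for t_n, t_h in config.schedules:
        schedule = PeriodicSchedule(t_n, t_h)
        tag = f"tn{t_n:g}_th{t_h:g}"
        result = optimize_fixed(schedule, config.params, config.alpha0, config.alpha1)
        g_perfect = perfect_strategy_payoff(schedule.q, config.params)
        g_const = optimal_constitutive_payoff(schedule.q, config.params)

        strategy = FacultativeStrategy(
            round(result.u_min_star, 12), round(result.u_max_star, 12),
            config.alpha0, config.alpha1,
        )
        profile = periodic_profile(schedule, n_cycles=max(3, int(600 / schedule.cycle_length)))
        trajectory = simulate_trajectory(profile, strategy, params=config.params)
        pd.DataFrame(
            {"time_min": trajectory.times, "u": trajectory.u_values, "Y": trajectory.y_values}
        ).to_csv(outdir / f"trajectory_{tag}.csv", index=False)

        surface = selection_surface(
            schedule, config.params, config.alpha0, config.alpha1, config.surface_grid_n
        )
        i_lo, i_hi = np.triu_indices(config.surface_grid_n, k=1)
        pd.DataFrame(
            {
                "u_min": surface.values[i_lo],
                "u_max": surface.values[i_hi],
                "payoff": surface.payoff[i_lo, i_hi],
                "SC": surface.sc[i_lo, i_hi],
            }
        ).to_csv(outdir / f"surface_{tag}.csv", index=False)

        summaries.append(
            {
                "t_n": t_n,
                "t_h": t_h,
                "u_min_star": result.u_min_star,
                "u_max_star": result.u_max_star,
                "facultative_payoff": result.payoff,
                "perfect_payoff": g_perfect,
                "constitutive_payoff": g_const,
                "normalized_perfect": 1.0,
                "normalized_facultative": result.payoff / g_perfect,
                "normalized_constitutive": g_const / g_perfect,
                "selection_coefficient": (result.payoff - g_const) / g_const,
            }
        )
    summary_path = outdir / "fixed_interval_summary.csv"
    pd.DataFrame(summaries).to_csv(summary_path, index=False)
    _write_sidecar(outdir, config, {"schedules": summaries})
    return summary_path


def run_stochastic(config: ExperimentConfig, outdir: str | Path) -> Path:
    """Replicate grid optimization under stochastic switching, with example traces."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(config.seed)
    summaries = []
    for p in config.switch_probs:
        rates = SwitchingRates(p, p)
        sub_seed = int(root.integers(0, 2**31 - 1))
        result = optimize_stochastic(
            rates,
            config.params,
            config.alpha0,
            config.alpha1,
            grid_n=config.grid_n,
            total_time=config.total_time,
            n_replicates=config.n_replicates,
            seed=sub_seed,
            dt=config.dt,
        )
        tag = f"p{p:g}"
        pd.DataFrame(
            {
                "replicate": np.arange(result.n_replicates),
                "seed": result.seeds,
                "u_min_star": result.replicate_u_min,
                "u_max_star": result.replicate_u_max,
            }
        ).to_csv(outdir / f"replicates_{tag}.csv", index=False)

        example_profile = stochastic_profile(
            rates, config.total_time, dt=config.dt, seed=result.seeds[0]
        )
        strategy = FacultativeStrategy(
            round(result.u_min_star, 12),
            round(result.u_max_star, 12),
            config.alpha0,
            config.alpha1,
        )
        trajectory = simulate_trajectory(example_profile, strategy, params=config.params)
        pd.DataFrame(
            {"time_min": trajectory.times, "u": trajectory.u_values, "Y": trajectory.y_values}
        ).to_csv(outdir / f"trajectory_{tag}.csv", index=False)

        summaries.append(
            {
                "p": p,
                "mean_u_min_star": result.u_min_star,
                "mean_u_max_star": result.u_max_star,
                "se_u_min_star": result.u_min_se,
                "se_u_max_star": result.u_max_se,
                "mean_payoff": result.payoff,
                "n_replicates": result.n_replicates,
                "sub_seed": sub_seed,
                "replicate_seeds": result.seeds,
            }
        )
    summary_path = outdir / "stochastic_summary.csv"
    pd.DataFrame(
        [{k: v for k, v in s.items() if k != "replicate_seeds"} for s in summaries]
    ).to_csv(summary_path, index=False)
    _write_sidecar(outdir, config, {"stochastic": summaries})
    return summary_path


def run_kinetics(config: ExperimentConfig, outdir: str | Path) -> Path:
    """Threshold-rule rate estimates for the configured stabilization/decay times."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for label, t_rise, t_decay in zip(
        config.kinetics_labels, config.rise_times, config.decay_times
    ):
        est = estimate_rates(t_rise, t_decay)
        rows.append(
            {
                "cell_line": label,
                "rise_time_min": t_rise,
                "decay_time_min": t_decay,
                "alpha0_per_min": est.alpha0,
                "alpha1_per_min": est.alpha1,
            }
        )
    csv_path = outdir / "kinetic_rates.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    _write_sidecar(outdir, config, {"kinetics": rows})
    return csv_path


def run_surface(
    config: ExperimentConfig, outdir: str | Path, schedule_index: int = 0
) -> Path:
    """Selection surface CSV for one configured schedule."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_n, t_h = config.schedules[schedule_index]
    schedule = PeriodicSchedule(t_n, t_h)
    surface = selection_surface(
        schedule, config.params, config.alpha0, config.alpha1, config.surface_grid_n
    )
    i_lo, i_hi = np.triu_indices(config.surface_grid_n, k=1)
    csv_path = outdir / f"surface_tn{t_n:g}_th{t_h:g}.csv"
    pd.DataFrame(
        {
            "u_min": surface.values[i_lo],
            "u_max": surface.values[i_hi],
            "payoff": surface.payoff[i_lo, i_hi],
            "SC": surface.sc[i_lo, i_hi],
        }
    ).to_csv(csv_path, index=False)
    star = surface.argmax()
    _write_sidecar(
        outdir, config,
        {"schedule": {"t_n": t_n, "t_h": t_h}, "surface_argmax": {"u_min": star[0], "u_max": star[1]}},
    )
    return csv_path
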