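"""HIF-α kinetic-rate estimation from stabilization and destabilization times.

Assuming the full-range response (``u_min = 0``, ``u_max = 1``), the
relaxation model gives ``u(t) = 1 − e^(−α0·t)`` during stabilization and
``u(t) = e^(−α1·t)`` during destabilization.  A rate can therefore be read
off a single threshold-crossing time — the convention used for the TOV112D
and A2780s measurements: rise to 90% of maximum and decay to 10% of maximum.
A least-squares generalization fits the same exponential forms to full
(possibly noisy) time courses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "KineticEstimate",
    "rate_from_rise_time",
    "rate_from_decay_time",
    "estimate_rates",
    "fit_relaxation",
]


@dataclass(frozen=True)
class KineticEstimate:
    """Estimated relaxation rates with the times and thresholds they came from."""

    alpha0: float | None = None
    alpha1: float | None = None
    rise_time: float | None = None
    decay_time: float | None = None
    rise_fraction: float = 0.9
    decay_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name, rate in (("alpha0", self.alpha0), ("alpha1", self.alpha1)):
            if rate is not None and not rate > 0:
                raise ValueError(f"{name} must be > 0, got {rate}")
        for name, frac in (
            ("rise_fraction", self.rise_fraction),
            ("decay_fraction", self.decay_fraction),
        ):
            if not 0.0 < frac < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {frac}")


def rate_from_rise_time(t_rise: float, fraction: float = 0.9) -> float:
    """Up-regulation rate from the time to reach ``fraction`` of maximum.

    Solves ``1 − e^(−α0·t_rise) = fraction``, i.e. ``α0 = −ln(1−fraction)/t_rise``.
    """
    if not t_rise > 0:
        raise ValueError(f"rise time must be > 0, got {t_rise}")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"threshold fraction must be in (0, 1), got {fraction}")
    return -math.log(1.0 - fraction) / t_rise


def rate_from_decay_time(t_decay: float, fraction: float = 0.1) -> float:
    """Down-regulation rate from the time to decay to ``fraction`` of maximum.

    Solves ``e^(−α1·t_decay) = fraction``, i.e. ``α1 = −ln(fraction)/t_decay``.
    """
    if not t_decay > 0:
        raise ValueError(f"decay time must be > 0, got {t_decay}")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"threshold fraction must be in (0, 1), got {fraction}")
    return -math.log(fraction) / t_decay


def estimate_rates(
    t_rise: float,
    t_decay: float,
    rise_fraction: float = 0.9,
    decay_fraction: float = 0.1,
) -> KineticEstimate:
    """Threshold-based point estimates of both rates for one cell line."""
    return KineticEstimate(
        alpha0=rate_from_rise_time(t_rise, rise_fraction),
        alpha1=rate_from_decay_time(t_decay, decay_fraction),
        rise_time=t_rise,
        decay_time=t_decay,
        rise_fraction=rise_fraction,
        decay_fraction=decay_fraction,
    )


def _threshold_crossing(times: np.ndarray, signal: np.ndarray, level: float) -> float | None:
    """First linear-interpolated crossing of ``level``, or None if never crossed."""
    above = signal >= level
    if above[0]:
        idx = np.flatnonzero(~above)
    else:
        idx = np.flatnonzero(above)
    if idx.size == 0:
        return None
    j = idx[0]
    if j == 0:
        return float(times[0])
    t0, t1 = times[j - 1], times[j]
    s0, s1 = signal[j - 1], signal[j]
    if s1 == s0:
        return float(t1)
    return float(t0 + (level - s0) * (t1 - t0) / (s1 - s0))


def fit_relaxation(
    table: pd.DataFrame | np.ndarray,
    direction: str,
    threshold: float | None = None,
) -> KineticEstimate:
    """Least-squares exponential fit of a normalized HIF-α time course.

    ``table`` holds times in minutes and signal normalized to the maximal
    stabilization level (two columns: time then signal, or a DataFrame whose
    first two columns are read the same way).  ``direction`` selects the
    model: ``"rise"`` fits ``A·(1 − e^(−α·t))``, ``"decay"`` fits
    ``A·e^(−α·t)``.  If the fit is degenerate the estimate falls back to
    interpolating the threshold crossing and applying the single-time rule.
    """
    if direction not in ("rise", "decay"):
        raise ValueError(f"direction must be 'rise' or 'decay', got {direction!r}")
    arr = np.asarray(table if not isinstance(table, pd.DataFrame) else table.iloc[:, :2])
    if arr.ndim != 2 or arr.shape[1] < 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (time, signal) pairs")
    times = arr[:, 0].astype(float)
    signal = arr[:, 1].astype(float)
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    if np.any((signal < 0) | (signal > 1.5)):
        raise ValueError("signal must be normalized (expected range [0, 1.5])")
    if np.ptp(signal) == 0:
        raise ValueError("constant signal carries no kinetic information")

    fraction = threshold if threshold is not None else (0.9 if direction == "rise" else 0.1)
    if direction == "rise":
        model = lambda t, amp, rate: amp * -np.expm1(-rate * t)
    else:
        model = lambda t, amp, rate: amp * np.exp(-rate * t)

    # crude rate guess from the characteristic time of the observed span
    span = times.max() - times.min()
    p0 = (max(signal.max(), 1e-6), 2.0 / max(span, 1e-12))
    rate = None
    try:
        popt, _ = curve_fit(model, times, signal, p0=p0, maxfev=10_000)
        if popt[1] > 0 and np.isfinite(popt[1]):
            rate = float(popt[1])
    except RuntimeError:
        pass
    if rate is None:
        peak = signal.max()
        t_cross = _threshold_crossing(times, signal, fraction * peak)
        if t_cross is None or t_cross <= 0:
            raise ValueError("degenerate time course: no usable threshold crossing")
        rate = (
            rate_from_rise_time(t_cross, fraction)
            if direction == "rise"
            else rate_from_decay_time(t_cross, fraction)
        )
    if direction == "rise":
        t_thr = -math.log(1.0 - fraction) / rate
        return KineticEstimate(alpha0=rate, rise_time=t_thr, rise_fraction=fraction)
    t_thr = -math.log(fraction) / rate
    return KineticEstimate(alpha1=rate, decay_time=t_thr, decay_fraction=fraction)
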