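"""Critical-slowing-down indicators for tipping-point anticipation.

Near a tipping point a bistable system recovers ever more slowly from
perturbations, which shows up as rising autocorrelation of its state.
This module estimates the lag-1 (or lag-k) autocorrelation of the
symptom count D in a sliding window, locates abrupt transitions between
the low-D and high-D regimes, and tests whether the indicator in the
window just before each transition exceeds a distant plateau baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_VAR_EPS = 1e-12


class EarlyWarningError(ValueError):
    """Invalid windowing for an early-warning computation."""


@dataclass(frozen=True)
class EWSeries:
    """Sliding-window autocorrelation estimates aligned to a trace.

    ``values[t]`` is the Pearson correlation between the window
    ``D[t-w+1 .. t-lag]`` and its lag-shifted copy ``D[t-w+1+lag .. t]``;
    NaN before the first full window and wherever a window has zero
    variance (undefined, not zero).
    """

    values: np.ndarray
    window_size: int
    lag: int

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def to_frame(self, trace=None) -> pd.DataFrame:
        frame = pd.DataFrame({"t": np.arange(len(self.values)), "autocorrelation": self.values})
        if trace is not None:
            frame.insert(1, "stress", trace.stress)
            frame.insert(2, "D", trace.D)
        return frame


def _rolling_sum(x: np.ndarray, w: int) -> np.ndarray:
    """Sum of x over each length-w window, aligned to the window end."""
    c = np.concatenate(([0.0], np.cumsum(x)))
    return c[w:] - c[:-w]


def sliding_autocorrelation(D, window_size: int = 100, lag: int = 1) -> EWSeries:
    """Lag-k autocorrelation of a series in a sliding window.

    Vectorised via rolling sums: for each window the correlation of the
    leading and trailing lag-shifted segments is computed from their
    rolling first and second moments and cross-products.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 1:
        raise EarlyWarningError(f"series must be 1-D, got shape {D.shape}")
    n = len(D)
    if lag < 1:
        raise EarlyWarningError(f"lag must be >= 1, got {lag}")
    if window_size < lag + 2:
        raise EarlyWarningError(f"window_size must be >= lag + 2, got {window_size}")
    if window_size > n:
        raise EarlyWarningError(f"window_size {window_size} exceeds series length {n}")

    m = window_size - lag  # pairs per window
    u = D[: n - lag]  # leading values
    v = D[lag:]  # lagged partners
    Su = _rolling_sum(u, m)
    Sv = _rolling_sum(v, m)
    Suu = _rolling_sum(u * u, m)
    Svv = _rolling_sum(v * v, m)
    Suv = _rolling_sum(u * v, m)

    cov = Suv / m - (Su / m) * (Sv / m)
    var_u = Suu / m - (Su / m) ** 2
    var_v = Svv / m - (Sv / m) ** 2
    denom = var_u * var_v
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > _VAR_EPS, cov / np.sqrt(np.maximum(denom, _VAR_EPS)), np.nan)
    r = np.clip(r, -1.0, 1.0)

    values = np.full(n, np.nan)
    # window ending at t covers D[t-window_size+1 .. t]; first full window
    # ends at t = window_size - 1
    values[window_size - 1 :] = r[: n - window_size + 1]
    return EWSeries(values=values, window_size=window_size, lag=lag)


def find_transitions(D, J: int, persist: int = 10) -> list[tuple[int, int]]:
    """Locate abrupt regime switches in the symptom count.

    A transition is a crossing of the midpoint D = J/2 that persists for
    at least ``persist`` steps on the new side. Returns (time, sign)
    pairs with sign +1 for a low-to-high switch and -1 for the reverse.
    """
    D = np.asarray(D)
    high = D >= J / 2.0
    transitions: list[tuple[int, int]] = []
    t = 1
    n = len(D)
    while t < n:
        if high[t] != high[t - 1]:
            stop = min(t + persist, n)
            if stop - t >= persist and np.all(high[t:stop] == high[t]):
                transitions.append((t, 1 if high[t] else -1))
                t = stop
                continue
        t += 1
    return transitions


@dataclass(frozen=True)
class IndicatorTest:
    """Pre-transition vs baseline comparison for one transition."""

    transition_time: int
    rising: bool
    effect: float  # pre-transition mean minus baseline mean


def detect_rising_indicator(
    ew: EWSeries,
    transition_times: list[int],
    baseline_window: tuple[int, int],
    pre_window_size: int = 100,
    gap: int = 5,
) -> list[IndicatorTest]:
    """Test whether the indicator rises ahead of each transition.

    For every transition time ``t*`` the mean indicator over
    ``[t* - gap - pre_window_size, t* - gap)`` is compared one-sided
    against the mean over ``baseline_window`` (a half-open index range
    well away from any transition, e.g. the middle of a plateau).
    Windows that contain a transition are rejected.
    """
    times = [int(t) for t in transition_times]
    if not times:
        return []
    b_lo, b_hi = baseline_window
    if not 0 <= b_lo < b_hi <= len(ew.values):
        raise EarlyWarningError(f"baseline window {baseline_window} out of range")
    for t in times:
        if b_lo <= t < b_hi:
            raise EarlyWarningError(
                f"baseline window {baseline_window} overlaps transition at t={t}"
            )
    baseline_vals = ew.values[b_lo:b_hi]
    baseline_vals = baseline_vals[~np.isnan(baseline_vals)]
    if baseline_vals.size == 0:
        raise EarlyWarningError("baseline window contains no defined indicator values")
    baseline = float(baseline_vals.mean())

    results = []
    for t in times:
        p_lo = t - gap - pre_window_size
        p_hi = t - gap
        if p_lo < 0:
            raise EarlyWarningError(f"pre-transition window for t={t} starts before the series")
        for other in times:
            if other != t and p_lo <= other < p_hi:
                raise EarlyWarningError(
                    f"pre-transition window for t={t} overlaps transition at t={other}"
                )
        vals = ew.values[p_lo:p_hi]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise EarlyWarningError(f"no defined indicator values before transition at t={t}")
        effect = float(vals.mean()) - baseline
        results.append(IndicatorTest(transition_time=t, rising=effect > 0, effect=effect))
    return results
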