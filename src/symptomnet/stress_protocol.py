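"""Stress-ramp experiments: hysteresis and forbidden-zone analysis.

The diathesis-stress experiment drives every symptom with the same
slowly varying external input S(t): a triangular ramp that climbs from
``s_min`` to ``s_max`` in small increments and back down, repeatedly,
while the network state evolves continuously (no reset at reversals).
Averaging the symptom count D within narrow stress bins, separately for
the ascending and descending legs, yields a dose-response curve per
direction. In a bistable (strongly connected) network the two curves
separate — the stress at which the system tips into the high-D state on
the way up exceeds the stress at which it escapes on the way down — and
the area between them quantifies hysteresis. The occupancy histogram of
D additionally reveals a "forbidden zone": intermediate symptom counts
the system passes through but never dwells in.

Defaults follow the reference protocol: ramp from -15 to 15 in steps of
0.01 (6000 steps per full cycle) and 0.20-wide stress bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from symptomnet.core_model import (
    DimensionMismatchError,
    ModelConfig,
    SimulationTrace,
    SymptomNetwork,
    simulate,
)


class ProtocolError(ValueError):
    """The stress protocol inputs are inconsistent."""


@dataclass(frozen=True)
class StressSchedule:
    """Deterministic per-step stress values of a triangular ramp."""

    values: np.ndarray  # (n_steps,)
    direction: np.ndarray  # (n_steps,) +1 ascending, -1 descending
    spec: tuple[float, float, float, float]  # (s_min, s_max, step_size, n_cycles)

    @property
    def n_steps(self) -> int:
        return len(self.values)


def make_ramp_schedule(
    s_min: float = -15.0,
    s_max: float = 15.0,
    step_size: float = 0.01,
    n_steps: int = 10_000,
) -> StressSchedule:
    """Triangular stress wave: s_min -> s_max -> s_min, repeated.

    One full cycle spans ``2 * (s_max - s_min) / step_size`` steps
    (6000 with the defaults); the wave is truncated at ``n_steps``, so
    the last cycle may be partial. ``step_size`` must divide the range.
    """
    if step_size <= 0:
        raise ProtocolError(f"step_size must be positive, got {step_size}")
    if not s_min < s_max:
        raise ProtocolError(f"need s_min < s_max, got [{s_min}, {s_max}]")
    span = s_max - s_min
    n_up = span / step_size
    if abs(n_up - round(n_up)) > 1e-9 * max(1.0, n_up):
        raise ProtocolError(
            f"step_size {step_size} does not divide the range {span} evenly"
        )
    n_up = int(round(n_up))
    if n_steps < 1:
        raise ProtocolError(f"n_steps must be >= 1, got {n_steps}")
    period = 2 * n_up
    phase = np.arange(n_steps) % period
    # ascend for phase 0..n_up-1 (values s_min .. s_max - step), then
    # descend for phase n_up..2*n_up-1 (values s_max .. s_min + step)
    values = np.where(
        phase < n_up,
        s_min + step_size * phase,
        s_min + step_size * (period - phase),
    )
    direction = np.where(phase < n_up, 1, -1).astype(np.int8)
    return StressSchedule(
        values=values,
        direction=direction,
        spec=(s_min, s_max, step_size, n_steps / period),
    )


def run_stress_experiment(
    net: SymptomNetwork, cfg: ModelConfig, schedule: StressSchedule
) -> SimulationTrace:
    """Simulate the network under a stress ramp.

    The scheduled scalar stress is applied identically to every symptom
    at each step; state is carried continuously across ramp reversals.
    """
    if schedule.n_steps != cfg.n_steps:
        raise DimensionMismatchError(
            f"schedule has {schedule.n_steps} steps but cfg.n_steps={cfg.n_steps}"
        )
    return simulate(net, cfg, schedule)


@dataclass(frozen=True)
class HysteresisCurve:
    """Binned dose-response curve, one branch per ramp direction.

    Means are NaN in bins a direction never visited.
    """

    bin_centers: np.ndarray
    mean_D_up: np.ndarray
    mean_D_down: np.ndarray
    count_up: np.ndarray
    count_down: np.ndarray
    bin_width: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "mean_D_up": self.mean_D_up,
                "mean_D_down": self.mean_D_down,
                "count_up": self.count_up,
                "count_down": self.count_down,
            }
        )


def bin_hysteresis_curve(trace: SimulationTrace, bin_width: float = 0.20) -> HysteresisCurve:
    """Average D within fixed-width stress bins, per ramp direction.

    Bins are half-open ``[edge, edge + bin_width)`` anchored at the
    smallest stress value in the trace; each step contributes to exactly
    one bin, so counts sum to the trace length. The per-bin mean is the
    sum of D over qualifying steps divided by their count.
    """
    if bin_width <= 0:
        raise ProtocolError(f"bin_width must be positive, got {bin_width}")
    if trace.n_steps == 0:
        raise ProtocolError("empty trace")
    if trace.stress_direction is None or not np.any(trace.stress != 0):
        raise ProtocolError("trace carries no stress ramp; run run_stress_experiment first")

    s = trace.stress
    lo = float(s.min())
    hi = float(s.max())
    n_bins = int(np.floor((hi - lo) / bin_width + 1e-9)) + 1
    idx = np.floor((s - lo) / bin_width + 1e-9).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    centers = lo + (np.arange(n_bins) + 0.5) * bin_width

    out = {}
    for name, mask in (("up", trace.stress_direction == 1), ("down", trace.stress_direction == -1)):
        counts = np.bincount(idx[mask], minlength=n_bins)
        sums = np.bincount(idx[mask], weights=trace.D[mask].astype(float), minlength=n_bins)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        out[name] = (means, counts)

    return HysteresisCurve(
        bin_centers=centers,
        mean_D_up=out["up"][0],
        mean_D_down=out["down"][0],
        count_up=out["up"][1],
        count_down=out["down"][1],
        bin_width=bin_width,
    )


def hysteresis_area(curve: HysteresisCurve) -> float:
    """Area between the ascending and descending branches.

    Sum over bins visited in both directions of
    ``|mean_D_up - mean_D_down| * bin_width``; zero iff the branches
    coincide. Requires at least two shared bins.
    """
    shared = (curve.count_up > 0) & (curve.count_down > 0)
    if shared.sum() < 2:
        raise ProtocolError(
            f"only {int(shared.sum())} bin(s) visited in both directions; need >= 2"
        )
    gap = np.abs(curve.mean_D_up[shared] - curve.mean_D_down[shared])
    return float(np.sum(gap) * curve.bin_width)


def forbidden_zone(
    trace: SimulationTrace, dwell_threshold: float = 0.005
) -> tuple[int, int] | None:
    """Interior band of symptom counts the system never dwells in.

    Computes the fraction of steps spent at each D level 0..J and finds
    the widest contiguous run of levels each occupied less than
    ``dwell_threshold`` of the time, lying strictly between two levels
    that exceed the threshold. Returns the inclusive (lo, hi) band, or
    None when no interior gap exists.
    """
    J = trace.J
    occupancy = np.bincount(trace.D, minlength=J + 1) / trace.n_steps
    occupied = occupancy >= dwell_threshold
    anchors = np.flatnonzero(occupied)
    if anchors.size < 2:
        return None
    best: tuple[int, int] | None = None
    run_start = None
    for d in range(anchors[0] + 1, anchors[-1] + 1):
        if not occupied[d]:
            if run_start is None:
                run_start = d
        else:
            if run_start is not None:
                band = (run_start, d - 1)
                if best is None or (band[1] - band[0]) > (best[1] - best[0]):
                    best = band
                run_start = None
    return best
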