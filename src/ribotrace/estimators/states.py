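"""Segmentation of intensity traces into translating (on) and silent (off) states.

A single mRNA can shut down initiation entirely and later reinitiate; on the
trace this appears as a progressive loss of signal (the polysome drains at
the elongation rate) followed by a recovery.  The segmenter thresholds the
median-filtered trace with hysteresis and a minimum dwell, and reports cycle
statistics.

Because the polysome needs roughly L / k_elong seconds to drain, an off
interval is only *detected* when it outlasts that dead time.  For memoryless
(exponential) off dwells the observed complete-shutdown rate is the true
switching rate times exp(-T0 / mean_off), while the observed off durations
remain exponential with the same mean — ``corrected_switching_rates`` uses
this to recover the underlying telegraph parameters from the censored
observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import medfilt

from ..simulate import IntensityTrace

__all__ = [
    "StateSegmentSummary",
    "segment_states",
    "corrected_switching_rates",
]


@dataclass
class StateSegmentSummary:
    """On/off segments of one trace plus switching statistics."""

    segments: tuple[tuple[float, float, str], ...]
    cycles_per_hour: float
    off_fraction: float
    reinitiation_times_s: tuple[float, ...]
    fraction_reinitiated_within_600s: float
    tracked_hours: float
    n_complete_cycles: int


def segment_states(
    trace: IntensityTrace,
    threshold: float,
    min_dwell_frames: int = 2,
    median_filter_frames: int = 3,
) -> StateSegmentSummary:
    """Threshold a trace into on/off segments with hysteresis.

    The trace is median filtered, then scanned with hysteresis: the state
    flips to off below ``0.8 * threshold`` and back to on above
    ``1.2 * threshold``.  Segments shorter than ``min_dwell_frames`` are
    absorbed into their neighbours.  A complete cycle is one off segment
    with translation on both sides; its duration is the reinitiation time.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if trace.n_frames < 2:
        raise ValueError("trace must have at least 2 frames")
    x = trace.green.astype(float)
    if median_filter_frames and median_filter_frames > 1:
        k = median_filter_frames + (1 - median_filter_frames % 2)  # force odd
        if k < len(x):
            x = medfilt(x, k)

    lo, hi = 0.8 * threshold, 1.2 * threshold
    states = np.empty(len(x), dtype=np.int8)
    on = bool(x[0] >= threshold)
    for i, v in enumerate(x):
        if on and v < lo:
            on = False
        elif not on and v > hi:
            on = True
        states[i] = 1 if on else 0

    # enforce the minimum dwell by absorbing short runs into the previous state
    changed = True
    while changed:
        changed = False
        runs = _runs(states)
        for j, (i0, i1, s) in enumerate(runs):
            if i1 - i0 < min_dwell_frames and len(runs) > 1:
                states[i0:i1] = runs[j - 1][2] if j > 0 else runs[j + 1][2]
                changed = True
                break

    t = trace.times
    dt = trace.frame_interval_s
    segments = []
    for i0, i1, s in _runs(states):
        start = t[i0]
        end = t[i1 - 1] + dt if i1 - 1 == len(t) - 1 else t[i1]
        segments.append((float(start), float(end), "on" if s else "off"))

    total = segments[-1][1] - segments[0][0]
    tracked_hours = total / 3600.0
    off_time = sum(e - s for s, e, st in segments if st == "off")
    reinit = tuple(
        float(e - s)
        for j, (s, e, st) in enumerate(segments)
        if st == "off" and 0 < j < len(segments) - 1
    )
    n_cycles = len(reinit)
    frac_600 = (
        float(np.mean([r <= 600.0 for r in reinit])) if reinit else float("nan")
    )
    return StateSegmentSummary(
        segments=tuple(segments),
        cycles_per_hour=n_cycles / tracked_hours if tracked_hours > 0 else 0.0,
        off_fraction=off_time / total if total > 0 else 0.0,
        reinitiation_times_s=reinit,
        fraction_reinitiated_within_600s=frac_600,
        tracked_hours=tracked_hours,
        n_complete_cycles=n_cycles,
    )


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    out = []
    i = 0
    n = len(states)
    while i < n:
        j = i
        while j < n and states[j] == states[i]:
            j += 1
        out.append((i, j, int(states[i])))
        i = j
    return out


def corrected_switching_rates(
    summaries: Sequence[StateSegmentSummary],
    detection_deadtime_s: float,
) -> dict:
    """Recover underlying telegraph rates from censored segment summaries.

    ``detection_deadtime_s`` is the polysome drain time L / k_elong: an off
    interval shorter than this never produces a complete signal loss.  With
    exponential off dwells of mean m, the observed complete-cycle rate is
    r_true exp(-T0 / m) and the observed off durations are again Exp(m), so

        r_true = r_obs * exp(T0 / m_hat),
        off_fraction_true = r_true * m_hat / 3600.

    Returns a dict with measured and corrected rates.
    """
    hours = sum(s.tracked_hours for s in summaries)
    cycles = sum(s.n_complete_cycles for s in summaries)
    offs = np.concatenate([np.asarray(s.reinitiation_times_s) for s in summaries]) if summaries else np.array([])
    measured_rate = cycles / hours if hours > 0 else float("nan")
    mean_off = float(offs.mean()) if offs.size else float("nan")
    if offs.size and mean_off > 0:
        corrected_rate = measured_rate * float(np.exp(detection_deadtime_s / mean_off))
        corrected_off_fraction = corrected_rate * mean_off / 3600.0
    else:
        corrected_rate = float("nan")
        corrected_off_fraction = float("nan")
    return {
        "tracked_hours": hours,
        "n_complete_cycles": int(cycles),
        "measured_cycles_per_hour": measured_rate,
        "mean_off_s": mean_off,
        "cycles_per_hour": corrected_rate,
        "off_fraction": corrected_off_fraction,
    }
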