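"""Detection of single-ribosome translation events in low-initiation traces.

When initiation is rare, one ribosome at a time decodes the mRNA and the
trace shows a characteristic rise (epitope array being synthesized), a
plateau near one mature-protein unit (full nascent chain, gene body being
decoded) and an abrupt loss (termination and chain release).  The event
duration converts to a per-ribosome elongation rate: the signal appears when
the ribosome passes the first visible codon a = e_1 + delta and is lost at
termination, so

    k = (L - a) / (t_loss - t_appear).

``t_appear`` is estimated by extrapolating a straight-line fit of the rising
flank to zero intensity (the intensity ramp starts exactly at codon a),
which avoids the upward bias a fixed detection threshold would introduce.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import medfilt

from ..constructs import ReporterConstruct
from ..simulate import IntensityTrace

__all__ = ["SingleRibosomeEvent", "detect_single_ribosome_events"]


@dataclass
class SingleRibosomeEvent:
    """One rise-plateau-drop episode attributed to a single ribosome."""

    t_appear_s: float
    t_plateau_start_s: float
    t_loss_s: float
    plateau_intensity: float
    inferred_rate_codons_per_s: float
    overlapping: bool = False


def _estimate_noise_sd(x: np.ndarray) -> float:
    # robust: successive differences are insensitive to the slow event shape
    d = np.diff(x)
    if d.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def detect_single_ribosome_events(
    trace: IntensityTrace,
    construct: ReporterConstruct,
    *,
    detection_threshold: Optional[float] = None,
    noise_sd: Optional[float] = None,
    min_frames: int = 4,
    max_plateau: float = 1.25,
    max_gap_frames: int = 2,
) -> list[SingleRibosomeEvent]:
    """Find rise-plateau-drop episodes and convert durations to rates.

    Runs above the detection threshold separated by short noise dips
    (``max_gap_frames``) are merged; episodes touching either end of the
    trace are discarded (their duration is censored).  Episodes whose plateau
    exceeds ``max_plateau`` single-protein units, or whose peak exceeds
    roughly two plateaus' worth of signal, are flagged as overlapping (more
    than one ribosome at a time) rather than split.  Returns an empty list on
    flat traces.
    """
    x_raw = trace.green.astype(float)
    t = trace.times
    dt = trace.frame_interval_s
    x = medfilt(x_raw, 3) if len(x_raw) >= 3 else x_raw

    sd = noise_sd if noise_sd is not None else _estimate_noise_sd(x_raw)
    thr = detection_threshold if detection_threshold is not None else max(0.25, 3.0 * sd)

    above = x > thr
    # close short sub-threshold gaps so one event is one run
    if max_gap_frames > 0:
        gap = 0
        for idx in range(len(above)):
            if above[idx]:
                if 0 < gap <= max_gap_frames and idx - gap > 0:
                    above[idx - gap : idx] = True
                gap = 0
            else:
                gap += 1

    events: list[SingleRibosomeEvent] = []
    i = 0
    n = len(x)
    a = construct.first_visible_codon
    L = construct.orf_length_codons
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        run = slice(i, j)
        i_next = j
        # censored episodes (in progress at either end of the trace) are skipped
        if i > 0 and j < n and j - i >= min_frames:
            seg = x[run]
            top = np.sort(seg)[len(seg) // 2 :]
            plateau = float(np.median(top))
            overlapping = plateau > max_plateau or float(seg.max()) > 1.6
            ev = _characterize(t, x, run, plateau, dt, a, L, construct, sd)
            if ev is not None:
                ev.overlapping = overlapping
                events.append(ev)
        i = i_next
    return events


def _characterize(t, x, run, plateau, dt, a, L, construct, noise_sd) -> Optional[SingleRibosomeEvent]:
    i0, i1 = run.start, run.stop  # [i0, i1) above threshold

    above_plateau = np.nonzero(x[i0:i1] >= 0.9 * plateau)[0]
    if above_plateau.size == 0:
        return None
    t_plateau_start = float(t[i0 + above_plateau[0]])

    half = 0.5 * plateau
    last = i1 - 1
    while last > i0 and x[last] < half:
        last -= 1
    t_loss = float(t[last] + 0.5 * dt)

    # appearance time by template fit: the rise is a linear ramp whose
    # duration is tied to the event duration through the construct geometry
    # ((b - a) codons of ramp out of (L - a) total), so t_appear is the only
    # free parameter; minimize SSE over a fine grid on the pre-plateau frames
    b = construct.last_visible_codon
    ramp_share = (b - a) / (L - a)
    # earliest conceivable appearance: a full ramp ending at the run start,
    # with slack; baseline frames inside the window penalize too-early fits
    t_lower = t[i0] - 1.3 * ramp_share * (t_loss - t[i0])
    w0 = int(np.searchsorted(t, t_lower))
    w1 = min(i0 + int(above_plateau[0]) + 2, len(x))
    tt = t[w0:w1]
    yy = x[w0:w1]
    candidates = np.arange(t_lower, t_plateau_start, max(dt / 30.0, 0.5))
    best_sse, t_appear = np.inf, t[i0] - 0.5 * dt
    for ta in candidates:
        dur = t_loss - ta
        if dur <= 0:
            continue
        rise = ramp_share * dur
        model = plateau * np.clip((tt - ta) / rise, 0.0, 1.0)
        sse = float(np.sum((yy - model) ** 2))
        if sse < best_sse:
            best_sse, t_appear = sse, float(ta)

    if not (t_appear < t_plateau_start < t_loss):
        return None
    duration = t_loss - t_appear
    rate = (L - a) / duration if duration > 0 else float("nan")
    return SingleRibosomeEvent(
        t_appear_s=float(t_appear),
        t_plateau_start_s=t_plateau_start,
        t_loss_s=t_loss,
        plateau_intensity=plateau,
        inferred_rate_codons_per_s=float(rate),
    )
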