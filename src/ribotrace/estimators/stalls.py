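"""Classification of post-drug decay traces: normal runoff, damage, roadblock.

After initiation is blocked, a healthy polysome drains completely within
roughly L / k_elong seconds.  mRNAs that retain a bright signal long after
that are classified as stalled, and the *shape* of their decay distinguishes
two mechanisms:

- a single defective ribosome acts as a roadblock: downstream ribosomes run
  off, the signal then plateaus until the stalled ribosome is removed, and
  the remainder runs off in a burst — decay concentrated in short segments;
- chemical damage to the mRNA delays every ribosome crossing the lesion,
  producing a slow, near-linear decay.

The decay derivative is segmented by binary changepoint splitting with a
BIC-style penalty; a trace is called "burst" when most of the decline is
concentrated in segments covering a small fraction of the decay interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import medfilt

from ..simulate import IntensityTrace

__all__ = ["StallCall", "classify_stall", "binary_segmentation"]


@dataclass
class StallCall:
    """Stall decision for one post-drug trace."""

    is_stalled: bool
    retained_fraction_at_check: float
    decay_class: str  # "normal" | "slow_linear" | "burst"
    changepoints_s: tuple[float, ...] = ()


def binary_segmentation(d: np.ndarray, min_size: int = 3, penalty: Optional[float] = None) -> list[int]:
    """Changepoints of a piecewise-constant mean signal by binary splitting.

    Splits greedily where the squared-error reduction is largest, accepting a
    split while the reduction exceeds a BIC-style penalty ``sigma^2 log n``
    (noise scale estimated robustly from first differences of ``d``).
    Returns sorted interior changepoint indices.
    """
    n = len(d)
    if n < 2 * min_size:
        return []
    if penalty is None:
        dd = np.diff(d)
        sigma = 1.4826 * np.median(np.abs(dd - np.median(dd))) / np.sqrt(2.0) if dd.size else 0.0
        sigma = max(sigma, 1e-6)
        penalty = 2.0 * sigma**2 * np.log(n)

    def sse(seg):
        return float(np.sum((seg - seg.mean()) ** 2)) if len(seg) else 0.0

    def best_split(lo, hi):
        seg = d[lo:hi]
        base = sse(seg)
        best_gain, best_i = 0.0, None
        csum = np.cumsum(seg)
        csq = np.cumsum(seg**2)
        m = hi - lo
        for i in range(min_size, m - min_size + 1):
            s1, q1 = csum[i - 1], csq[i - 1]
            s2, q2 = csum[-1] - s1, csq[-1] - q1
            cost = (q1 - s1**2 / i) + (q2 - s2**2 / (m - i))
            gain = base - cost
            if gain > best_gain:
                best_gain, best_i = gain, i
        return best_gain, best_i

    cps: list[int] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        gain, i = best_split(lo, hi)
        if i is not None and gain > penalty:
            cp = lo + i
            cps.append(cp)
            stack.append((lo, cp))
            stack.append((cp, hi))
    return sorted(cps)


def classify_stall(
    trace: IntensityTrace,
    *,
    check_time_s: float = 900.0,
    retain_threshold: float = 0.5,
    normal_runoff_horizon_s: float = 450.0,
    burst_window_s: float = 120.0,
    burst_share: float = 0.5,
    quiet_share: float = 0.2,
) -> StallCall:
    """Classify one post-drug trace.

    The trace must be aligned at the drug-add time (t = 0); it is normalized
    to its pre-drug level (frames with t <= 0) if such frames are present.
    ``is_stalled`` is true when the normalized intensity at ``check_time_s``
    is at least ``retain_threshold``.

    The decay class looks only at what happens *after* the normal-runoff
    horizon (~L / k_elong; everything before is the shared downstream runoff).
    A roadblock leaves the trace flat until the stalled ribosome is removed
    and then releases the queued ribosomes almost at once, so the remaining
    decline is concentrated: "burst" is called when one ``burst_window_s``
    window carries at least ``burst_share`` of the post-horizon decline and
    the decline preceding that window is below ``quiet_share`` of it.  A
    damaged mRNA drains steadily through the lesion: stalled but diffuse
    decay is "slow_linear"; anything else is "normal".
    """
    t = trace.times
    if t[-1] < check_time_s:
        raise ValueError("trace shorter than the stall check time")
    y = trace.green.astype(float)
    pre = y[t <= 0.0]
    level = pre.mean() if pre.size else y[0]
    if level <= 0:
        raise ValueError("non-positive pre-drug level")
    norm = y / level
    x = medfilt(norm, 5) if len(norm) >= 5 else norm

    retained = float(np.interp(check_time_s, t, x))
    is_stalled = retained >= retain_threshold

    post = t >= normal_runoff_horizon_s
    tp = t[post]
    xp = x[post]
    below = np.nonzero(xp <= 0.05)[0]
    end = int(below[0]) + 1 if below.size else len(xp)
    tp, xp = tp[:end], xp[:end]

    decay_class = "normal"
    changepoints: tuple[float, ...] = ()
    if len(xp) >= 4:
        d = np.diff(xp)
        decline = np.clip(-d, 0.0, None)
        total = float(decline.sum())
        cps = binary_segmentation(d)
        changepoints = tuple(float(tp[c]) for c in cps)
        if total >= 0.15:
            dt = float(tp[1] - tp[0])
            w = max(int(round(burst_window_s / dt)), 1)
            windows = np.convolve(decline, np.ones(w), mode="valid")
            i_best = int(np.argmax(windows))
            best = float(windows[i_best])
            before = float(decline[:i_best].sum())
            if best >= burst_share * total and before <= quiet_share * total:
                decay_class = "burst"
            else:
                # a healthy polysome is gone by the horizon, so substantial
                # diffuse decline after it means delayed passage (damage)
                decay_class = "slow_linear"
        elif is_stalled:
            decay_class = "slow_linear"

    return StallCall(
        is_stalled=is_stalled,
        retained_fraction_at_check=retained,
        decay_class=decay_class,
        changepoints_s=changepoints,
    )
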