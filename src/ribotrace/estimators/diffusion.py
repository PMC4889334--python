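"""Diffusion-coefficient estimation from 2D spot trajectories.

The time-averaged mean squared displacement of a 2D Brownian walk is linear
in the lag time, MSD(tau) = 4 D tau + b, with the intercept absorbing static
and dynamic localization error.  D is obtained by a weighted linear fit over
the first few lags (long lags are noisy and anticorrelated), weighting each
lag by its number of displacement pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..simulate import Trajectory2D

__all__ = ["DiffusionFit", "msd_time_averaged", "estimate_diffusion", "estimate_diffusion_ensemble"]


@dataclass
class DiffusionFit:
    """MSD-fit diffusion estimate for one track."""

    D_um2_per_s: float
    intercept: float
    lags_used: int
    truncated: bool
    lag_times_s: np.ndarray
    msd_um2: np.ndarray


def msd_time_averaged(track: Trajectory2D, max_lag_frames: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-averaged MSD at lags 1..max_lag (lag times, MSD, pair counts)."""
    n = len(track.times)
    if n <= max_lag_frames + 1:
        raise ValueError("track too short for the requested number of lags")
    dt = track.frame_interval_s
    lags = np.arange(1, max_lag_frames + 1)
    msd = np.empty(max_lag_frames)
    counts = np.empty(max_lag_frames)
    x, y = track.x_um, track.y_um
    for i, m in enumerate(lags):
        dx = x[m:] - x[:-m]
        dy = y[m:] - y[:-m]
        msd[i] = np.mean(dx**2 + dy**2)
        counts[i] = n - m
    return lags * dt, msd, counts


def estimate_diffusion(track: Trajectory2D, max_lag_frames: int = 5) -> DiffusionFit:
    """Weighted linear fit MSD(tau) = 4 D tau + b over lags 1..max_lag.

    A negative fitted slope is truncated to D = 0 with ``truncated=True``.
    """
    if max_lag_frames < 2:
        raise ValueError("need at least 2 lags for a linear fit")
    taus, msd, counts = msd_time_averaged(track, max_lag_frames)
    w = np.sqrt(counts)
    A = np.vstack([taus, np.ones_like(taus)]).T * w[:, None]
    slope, intercept = np.linalg.lstsq(A, msd * w, rcond=None)[0]
    D = slope / 4.0
    truncated = D < 0
    return DiffusionFit(
        D_um2_per_s=max(float(D), 0.0),
        intercept=float(intercept),
        lags_used=max_lag_frames,
        truncated=bool(truncated),
        lag_times_s=taus,
        msd_um2=msd,
    )


def estimate_diffusion_ensemble(
    tracks: Sequence[Trajectory2D], max_lag_frames: int = 5
) -> dict:
    """Per-track MSD fits plus the ensemble mean and SEM of D."""
    fits = [estimate_diffusion(tr, max_lag_frames) for tr in tracks]
    Ds = np.array([f.D_um2_per_s for f in fits])
    return {
        "D_mean": float(Ds.mean()),
        "D_sd": float(Ds.std(ddof=1)) if len(Ds) > 1 else 0.0,
        "D_sem": float(Ds.std(ddof=1) / np.sqrt(len(Ds))) if len(Ds) > 1 else 0.0,
        "n_tracks": len(Ds),
        "fits": fits,
    }
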