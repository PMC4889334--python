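"""Event-driven stochastic simulation of ribosome traffic on a reporter mRNA.

The simulator is an exclusion-process (TASEP-like) model: ribosomes initiate
at rate ``k_init`` when the translating state is on, no initiation-blocking
drug is active and the entry region is free; each ribosome advances one codon
with an exponential waiting time of mean ``1/k_elong``, blocked whenever the
next codon would violate the footprint exclusion; crossing a pause or damage
site inserts an extra dwell; reaching the stop codon removes the ribosome and
releases its nascent chain.  The event loop is an exact Gillespie simulation
compiled with numba; drug actions, telegraph state switches and frame
sampling are handled as scheduled boundaries at which the memoryless clock is
legitimately redrawn.

Trajectories are sampled on a uniform frame grid and rendered into intensity
traces through the construct's intensity function, with optional Gaussian
measurement noise whose variance is affine in the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numba as nb
import numpy as np

from .constructs import (
    LabelStoichiometry,
    ReporterConstruct,
    _fraction_table,
    expected_label_ratio,
)
from .kinetics import DamageSite, DrugEvent, KineticParameters, PauseSite

__all__ = [
    "RibosomeTrajectory",
    "IntensityTrace",
    "Trajectory2D",
    "simulate_translation",
    "render_intensity_trace",
    "simulate_runoff_ensemble",
    "simulate_diffusion_track",
    "simulate_diffusion_ensemble",
    "EVENT_NAMES",
]

# event codes in the event log
EV_INITIATE, EV_STEP, EV_PAUSE_ENTER, EV_PAUSE_EXIT, EV_TERMINATE, EV_PURO_RELEASE = range(6)
EVENT_NAMES = ("initiate", "step", "pause_enter", "pause_exit", "terminate", "puromycin_release")

# scheduled boundary codes
_SC_INIT_OFF, _SC_INIT_ON, _SC_PURO, _SC_FREEZE = range(4)

_INF = 1.0e300


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RibosomeTrajectory:
    """Time-resolved ribosome positions and lifecycle events on one mRNA.

    ``positions`` is an (n_frames, m) int array padded with -1; row i holds
    the codon positions of all ribosomes present at ``sample_times[i]``,
    ordered 3' to 5' (leading ribosome first).
    """

    mrna_id: str
    sample_times: np.ndarray
    positions: np.ndarray
    orf_length_codons: int
    footprint_codons: int
    state_log: tuple[tuple[float, float, str], ...] = ()
    events: Optional[dict] = None
    n_initiated: int = 0
    n_terminated: int = 0
    seed: Optional[int] = None

    def ribosomes_at(self, frame: int) -> np.ndarray:
        row = self.positions[frame]
        return row[row >= 0]

    @property
    def n_frames(self) -> int:
        return len(self.sample_times)

    def validate(self) -> None:
        """Check the trajectory invariants (exclusion, position range)."""
        L = self.orf_length_codons
        for i in range(self.n_frames):
            pos = self.ribosomes_at(i)
            if pos.size == 0:
                continue
            if pos.min() < 1 or pos.max() > L:
                raise AssertionError("ribosome position outside [1, L]")
            gaps = pos[:-1] - pos[1:]
            if np.any(gaps < self.footprint_codons):
                raise AssertionError("footprint exclusion violated at a sampled frame")


@dataclass
class IntensityTrace:
    """Per-mRNA two-channel intensity time series in single-mature-protein units."""

    mrna_id: str
    times: np.ndarray
    green: np.ndarray
    red: np.ndarray
    frame_interval_s: float
    noise_sigma0: float = 0.0
    noise_sigma1: float = 0.0
    truth: Optional[RibosomeTrajectory] = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.green) or len(self.times) != len(self.red):
            raise ValueError("times/green/red must have equal length")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0]):
                raise ValueError("intensity traces require a uniform time grid")
        if not (np.all(np.isfinite(self.green)) and np.all(np.isfinite(self.red))):
            raise ValueError("trace values must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class Trajectory2D:
    """A 2D spot trajectory in micrometers on a uniform time grid."""

    mrna_id: str
    times: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.x_um)) and np.all(np.isfinite(self.y_um))):
            raise ValueError("coordinates must be finite")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0]):
                raise ValueError("trajectories require a uniform time grid")

    @property
    def frame_interval_s(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@nb.njit(cache=True)
def _run_kernel(
    L,
    footprint,
    k_init,
    k_elong,
    deterministic,
    sample_times,
    site_pos,
    site_short,
    site_long,
    site_pfrac,
    site_single,
    site_fixed,
    sched_times,
    sched_codes,
    init_on_start,
    init_positions,
    seed,
    record_events,
    max_events,
):  # pragma: no cover - exercised through simulate_translation
    np.random.seed(seed)
    max_ribs = L // footprint + 2
    pos = np.full(max_ribs, -1, np.int64)
    paused = np.zeros(max_ribs, np.bool_)
    exit_rate = np.zeros(max_ribs, np.float64)
    wake = np.full(max_ribs, _INF, np.float64)
    rid = np.full(max_ribs, -1, np.int64)
    n_sites = len(site_pos)
    long_used = np.zeros(n_sites, np.bool_)

    n = 0
    for i in range(len(init_positions)):
        pos[i] = init_positions[i]
        rid[i] = i
        n += 1
    next_rid = n

    n_frames = len(sample_times)
    frames = np.full((n_frames, max_ribs), -1, np.int64)
    cap = max_events if record_events else 1
    ev_t = np.empty(cap, np.float64)
    ev_r = np.empty(cap, np.int64)
    ev_c = np.empty(cap, np.int8)
    n_ev = 0
    overflow = False

    t = 0.0
    si = 0
    bi = 0
    n_sched = len(sched_times)
    init_on = init_on_start
    frozen = False
    init_blocked = False
    n_term = 0

    while si < n_frames or bi < n_sched:
        # next scheduled boundary (drug/state changes take priority on ties so
        # that a frame coinciding with e.g. puromycin shows its effect)
        next_sched = sched_times[bi] if bi < n_sched else _INF
        next_sample = sample_times[si] if si < n_frames else _INF
        # earliest fixed-dwell wake-up
        min_wake = _INF
        for i in range(n):
            if wake[i] < min_wake:
                min_wake = wake[i]
        boundary = min(min(next_sched, next_sample), min_wake)

        # total propensity
        R = 0.0
        if not frozen:
            for i in range(n):
                if paused[i]:
                    R += exit_rate[i]  # zero for fixed-dwell pauses
                elif i == 0 or pos[i - 1] - pos[i] > footprint:
                    R += k_elong
        can_init = (
            init_on
            and not init_blocked
            and not frozen
            and k_init > 0.0
            and (n == 0 or pos[n - 1] > footprint)
            and n < max_ribs - 1
        )
        if can_init:
            R += k_init

        if R <= 0.0:
            t_next = _INF
        else:
            if deterministic:
                dt = 1.0 / R
            else:
                dt = np.random.exponential(1.0 / R)
            t_next = t + dt

        if t_next >= boundary:
            if boundary >= _INF:
                break
            t = boundary
            if boundary == min_wake and boundary < min(next_sched, next_sample):
                for i in range(n):
                    if wake[i] <= t:
                        wake[i] = _INF
                        paused[i] = False
                        if record_events and n_ev < cap:
                            ev_t[n_ev] = t
                            ev_r[n_ev] = rid[i]
                            ev_c[n_ev] = EV_PAUSE_EXIT
                            n_ev += 1
            elif next_sched <= next_sample and bi < n_sched:
                code = sched_codes[bi]
                bi += 1
                if code == _SC_INIT_OFF:
                    init_on = False
                elif code == _SC_INIT_ON:
                    init_on = True
                elif code == _SC_PURO:
                    if record_events:
                        for i in range(n):
                            if n_ev < cap:
                                ev_t[n_ev] = t
                                ev_r[n_ev] = rid[i]
                                ev_c[n_ev] = EV_PURO_RELEASE
                                n_ev += 1
                    n = 0
                    init_blocked = True
                elif code == _SC_FREEZE:
                    frozen = True
                    init_blocked = True
            else:
                for i in range(n):
                    frames[si, i] = pos[i]
                si += 1
            continue

        # a stochastic event fires strictly before the boundary
        t = t_next
        u = np.random.random() * R
        acc = 0.0
        fired = False
        if not frozen:
            for i in range(n):
                if paused[i]:
                    r = exit_rate[i]
                elif i == 0 or pos[i - 1] - pos[i] > footprint:
                    r = k_elong
                else:
                    r = 0.0
                if r <= 0.0:
                    continue
                acc += r
                if u < acc:
                    fired = True
                    if paused[i]:
                        paused[i] = False
                        if record_events and n_ev < cap:
                            ev_t[n_ev] = t
                            ev_r[n_ev] = rid[i]
                            ev_c[n_ev] = EV_PAUSE_EXIT
                            n_ev += 1
                    elif pos[i] == L:
                        # termination: leader steps off the stop codon
                        if record_events and n_ev < cap:
                            ev_t[n_ev] = t
                            ev_r[n_ev] = rid[i]
                            ev_c[n_ev] = EV_TERMINATE
                            n_ev += 1
                        for j in range(i + 1, n):
                            pos[j - 1] = pos[j]
                            paused[j - 1] = paused[j]
                            exit_rate[j - 1] = exit_rate[j]
                            wake[j - 1] = wake[j]
                            rid[j - 1] = rid[j]
                        n -= 1
                        n_term += 1
                    else:
                        pos[i] += 1
                        if record_events and n_ev < cap:
                            ev_t[n_ev] = t
                            ev_r[n_ev] = rid[i]
                            ev_c[n_ev] = EV_STEP
                            n_ev += 1
                        # landed on a special site?
                        for s in range(n_sites):
                            if site_pos[s] == pos[i]:
                                m = site_short[s]
                                if site_pfrac[s] > 0.0 and not (site_single[s] and long_used[s]):
                                    if np.random.random() < site_pfrac[s]:
                                        m = site_long[s]
                                        if site_single[s]:
                                            long_used[s] = True
                                if m > 0.0:
                                    paused[i] = True
                                    if site_fixed[s]:
                                        exit_rate[i] = 0.0
                                        wake[i] = t + m
                                    else:
                                        exit_rate[i] = 1.0 / m
                                        wake[i] = _INF
                                    if record_events and n_ev < cap:
                                        ev_t[n_ev] = t
                                        ev_r[n_ev] = rid[i]
                                        ev_c[n_ev] = EV_PAUSE_ENTER
                                        n_ev += 1
                                break
                    break
        if not fired and can_init:
            # initiation: place a new ribosome on the first codon
            pos[n] = 1
            paused[n] = False
            exit_rate[n] = 0.0
            wake[n] = _INF
            rid[n] = next_rid
            if record_events and n_ev < cap:
                ev_t[n_ev] = t
                ev_r[n_ev] = next_rid
                ev_c[n_ev] = EV_INITIATE
                n_ev += 1
            next_rid += 1
            n += 1
            # entry codon is never a pause site by construction (validated upstream)
        if record_events and n_ev >= cap:
            overflow = True

    return frames, ev_t[:n_ev], ev_r[:n_ev], ev_c[:n_ev], next_rid, n_term, overflow


# ---------------------------------------------------------------------------
# schedule construction
# ---------------------------------------------------------------------------

def _telegraph_intervals(
    kinetics: KineticParameters,
    duration_s: float,
    rng: np.random.Generator,
    initial_state_on: Optional[bool],
) -> list[tuple[float, float, str]]:
    """On/off state intervals over [0, duration]; stationary initial state by default."""
    if kinetics.k_shutdown_per_hr <= 0:
        return [(0.0, duration_s, "on")]
    mean_on = 3600.0 / kinetics.k_shutdown_per_hr
    mean_off = 1.0 / kinetics.k_reinit_per_s
    if initial_state_on is None:
        p_off = mean_off / (mean_on + mean_off)
        on = bool(rng.random() >= p_off)
    else:
        on = bool(initial_state_on)
    intervals: list[tuple[float, float, str]] = []
    t = 0.0
    while t < duration_s:
        dwell = rng.exponential(mean_on if on else mean_off)
        end = min(t + dwell, duration_s)
        intervals.append((t, end, "on" if on else "off"))
        t = end
        on = not on
    return intervals


def _build_schedule(
    kinetics: KineticParameters,
    drugs: Sequence[DrugEvent],
    state_intervals: list[tuple[float, float, str]],
    duration_s: float,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Merge telegraph switching and drug contracts into kernel boundaries."""
    events: list[tuple[float, int]] = []
    for start, _end, state in state_intervals[1:]:
        events.append((start, _SC_INIT_ON if state == "on" else _SC_INIT_OFF))
    init_on_start = state_intervals[0][2] == "on"

    block_time = _INF
    for d in drugs:
        t_eff = d.effective_time_s
        if d.drug in ("harringtonine", "hippuristanol"):
            block_time = min(block_time, t_eff)
        elif d.drug == "puromycin":
            events.append((t_eff, _SC_PURO))
            block_time = min(block_time, t_eff)
        elif d.drug == "cycloheximide":
            events.append((t_eff, _SC_FREEZE))
    if block_time < _INF:
        if block_time <= 0:
            init_on_start = False
        else:
            events.append((block_time, _SC_INIT_OFF))
        # telegraph re-activation after the block must not re-enable initiation
        events = [
            (t, c)
            for (t, c) in events
            if not (c == _SC_INIT_ON and t >= block_time)
        ]
    events = [(t, c) for (t, c) in events if 0.0 <= t <= duration_s]
    events.sort(key=lambda tc: tc[0])
    times = np.array([t for t, _ in events], dtype=np.float64)
    codes = np.array([c for _, c in events], dtype=np.int64)
    return times, codes, init_on_start


def _site_arrays(kinetics: KineticParameters, L: int):
    sites = []
    for p in kinetics.pause_sites:
        if p.position > L:
            raise ValueError(f"pause site at codon {p.position} beyond ORF length {L}")
        sites.append((p.position, p.short_dwell_mean_s, p.long_dwell_mean_s, p.long_fraction,
                      p.single_long, p.fixed_dwell))
    for d in kinetics.damage_sites:
        if d.position > L:
            raise ValueError(f"damage site at codon {d.position} beyond ORF length {L}")
        sites.append((d.position, d.dwell_mean_s, 0.0, 0.0, False, d.fixed_dwell))
    if any(s[0] == 1 for s in sites):
        raise ValueError("pause/damage sites on the entry codon are not supported")
    if not sites:
        return (np.empty(0, np.int64),) + tuple(np.empty(0, np.float64) for _ in range(3)) + (
            np.empty(0, np.bool_), np.empty(0, np.bool_))
    pos = np.array([s[0] for s in sites], np.int64)
    short = np.array([s[1] for s in sites], np.float64)
    long_ = np.array([s[2] for s in sites], np.float64)
    pfrac = np.array([s[3] for s in sites], np.float64)
    single = np.array([s[4] for s in sites], np.bool_)
    fixed = np.array([s[5] for s in sites], np.bool_)
    return pos, short, long_, pfrac, single, fixed


# ---------------------------------------------------------------------------
# deterministic stepping (analytic reference mode)
# ---------------------------------------------------------------------------

def _deterministic_trajectory(
    construct: ReporterConstruct,
    kinetics: KineticParameters,
    duration_s: float,
    drugs: Sequence[DrugEvent],
    sample_times: np.ndarray,
    initial_positions: np.ndarray,
    mrna_id: str,
) -> RibosomeTrajectory:
    """Fixed-interval stepping: each ribosome advances one codon every 1/k_elong s.

    Exact reference mode for analytic tests: a ribosome initiating at t0 on
    codon 1 terminates at t0 + L/k_elong.  Pause/damage sites add their mean
    dwell.  Exclusion is not enforced (equal speeds never collide for spaced
    starts); initiation is supported only as a single ribosome at t = 0 when
    no initial positions are given.
    """
    L = construct.orf_length_codons
    k = kinetics.k_elong
    if k <= 0:
        raise ValueError("deterministic mode requires k_elong > 0")
    starts = [(0.0, int(p)) for p in initial_positions]
    if not starts:
        starts = [(0.0, 1)]

    dwell_at = np.zeros(L + 2)
    for p in kinetics.pause_sites:
        exp_dwell = (1 - p.long_fraction) * p.short_dwell_mean_s + p.long_fraction * p.long_dwell_mean_s
        dwell_at[p.position] += exp_dwell
    for d in kinetics.damage_sites:
        dwell_at[d.position] += d.dwell_mean_s

    puro_t = min(
        (d.effective_time_s for d in drugs if d.drug == "puromycin"), default=_INF
    )
    freeze_t = min(
        (d.effective_time_s for d in drugs if d.drug == "cycloheximide"), default=_INF
    )

    n_frames = len(sample_times)
    frames = np.full((n_frames, len(starts)), -1, np.int64)
    n_term = 0
    for j, (t0, p0) in enumerate(sorted(starts, key=lambda s: -s[1])):
        # arrival time at each codon q >= p0, then termination one step later
        codons = np.arange(p0, L + 1)
        arr = t0 + (codons - p0) / k + np.cumsum(np.concatenate([[0.0], dwell_at[p0 + 1 : L + 1]]))
        t_term = arr[-1] + 1.0 / k
        if freeze_t < _INF:
            keep = arr <= freeze_t
            codons, arr = codons[keep], arr[keep]
            t_term = _INF
        gone_t = min(t_term, puro_t)
        for fi, tt in enumerate(sample_times):
            if tt < t0 or tt >= gone_t:
                continue
            idx = int(np.searchsorted(arr, tt, side="right") - 1)
            if idx >= 0:
                frames[fi, j] = codons[idx]
        if gone_t <= duration_s:
            n_term += int(gone_t == t_term)
    return RibosomeTrajectory(
        mrna_id=mrna_id,
        sample_times=sample_times,
        positions=frames,
        orf_length_codons=L,
        footprint_codons=kinetics.footprint_codons,
        state_log=((0.0, duration_s, "on"),),
        events=None,
        n_initiated=len(starts),
        n_terminated=n_term,
        seed=None,
    )


# ---------------------------------------------------------------------------
# public wrappers
# ---------------------------------------------------------------------------

def simulate_translation(
    construct: ReporterConstruct,
    kinetics: KineticParameters,
    duration_s: float,
    drugs: Sequence[DrugEvent] = (),
    *,
    seed: int = 0,
    frame_interval_s: float = 30.0,
    sample_times: Optional[np.ndarray] = None,
    initial_positions: Sequence[int] = (),
    initial_state_on: Optional[bool] = None,
    record_events: bool = False,
    deterministic: bool = False,
    mrna_id: str = "mrna_0",
) -> RibosomeTrajectory:
    """Simulate ribosome traffic on one mRNA and sample positions on a frame grid.

    ``initial_positions`` (codon indices, any order) seeds the mRNA with
    ribosomes already elongating at t = 0, e.g. a steady-state polysome.
    ``deterministic=True`` replaces exponential waits with their means, which
    is exact for a single active process and used for analytic checks.
    Reproducible: identical seeds and configurations give identical output.
    """
    if not duration_s > 0:
        raise ValueError("duration_s must be > 0")
    L = construct.orf_length_codons
    if sample_times is None:
        n_frames = int(np.floor(duration_s / frame_interval_s + 1e-9)) + 1
        sample_times = np.arange(n_frames, dtype=np.float64) * frame_interval_s
    else:
        sample_times = np.asarray(sample_times, dtype=np.float64)
        if np.any(np.diff(sample_times) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        frame_interval_s = float(sample_times[1] - sample_times[0]) if len(sample_times) > 1 else frame_interval_s

    init_pos = np.sort(np.asarray(list(initial_positions), dtype=np.int64))[::-1].copy()
    if init_pos.size:
        if init_pos.min() < 1 or init_pos.max() > L:
            raise ValueError("initial positions must lie in [1, L]")
        if not deterministic and np.any(init_pos[:-1] - init_pos[1:] < kinetics.footprint_codons):
            raise ValueError("initial positions violate the footprint exclusion")

    if deterministic:
        return _deterministic_trajectory(
            construct, kinetics, duration_s, drugs, sample_times, init_pos, mrna_id
        )

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    kernel_seed = int(rng.integers(1, 2**31 - 1))

    state_intervals = _telegraph_intervals(kinetics, duration_s, rng, initial_state_on)
    sched_times, sched_codes, init_on_start = _build_schedule(
        kinetics, drugs, state_intervals, duration_s
    )
    site_arrays = _site_arrays(kinetics, L)

    max_events = 0
    if record_events:
        expected = (kinetics.k_init * duration_s + len(init_pos) + 2) * (L + 6)
        max_events = int(min(expected * 1.5 + 1000, 20_000_000))

    frames, ev_t, ev_r, ev_c, n_init, n_term, overflow = _run_kernel(
        L,
        kinetics.footprint_codons,
        kinetics.k_init,
        kinetics.k_elong,
        deterministic,
        sample_times,
        *site_arrays,
        sched_times,
        sched_codes,
        init_on_start,
        init_pos,
        kernel_seed,
        record_events,
        max_events,
    )
    if overflow:
        raise RuntimeError("event log capacity exceeded; rerun with record_events=False")

    # trim padding columns
    occupied = frames.max(axis=0) >= 0
    m = int(np.max(np.nonzero(occupied)[0]) + 1) if occupied.any() else 0
    frames = frames[:, :m].copy()

    events = None
    if record_events:
        events = {"time_s": ev_t, "ribosome": ev_r, "event": ev_c}

    return RibosomeTrajectory(
        mrna_id=mrna_id,
        sample_times=sample_times,
        positions=frames,
        orf_length_codons=L,
        footprint_codons=kinetics.footprint_codons,
        state_log=tuple(state_intervals),
        events=events,
        n_initiated=int(n_init),
        n_terminated=int(n_term),
        seed=seed,
    )


def render_intensity_trace(
    trajectory: RibosomeTrajectory,
    construct: ReporterConstruct,
    *,
    frame_interval_s: Optional[float] = None,
    noise_sigma0: float = 0.0,
    noise_sigma1: float = 0.0,
    seed: int = 0,
    stoichiometry: Optional[LabelStoichiometry] = None,
    red_noise_cv: float = 0.05,
    keep_truth: bool = True,
) -> IntensityTrace:
    """Render a trajectory into a two-channel intensity trace.

    Green channel: site intensity plus Gaussian noise with variance
    ``sigma0^2 + sigma1^2 * intensity`` (zero noise gives the exact noiseless
    forward model).  Red channel: the expected mRNA-label brightness with a
    small multiplicative noise.  The frame grid is the trajectory's sampling
    grid, optionally decimated to a coarser ``frame_interval_s``.
    """
    if noise_sigma0 < 0 or noise_sigma1 < 0:
        raise ValueError("noise parameters must be >= 0")
    times = trajectory.sample_times
    positions = trajectory.positions
    native_dt = float(times[1] - times[0]) if len(times) > 1 else 0.0
    if frame_interval_s is not None and native_dt > 0 and frame_interval_s != native_dt:
        step = frame_interval_s / native_dt
        if abs(step - round(step)) > 1e-9 or step < 1:
            raise ValueError("frame_interval_s must be an integer multiple of the trajectory grid")
        sel = slice(None, None, int(round(step)))
        times = times[sel]
        positions = positions[sel]
    else:
        frame_interval_s = native_dt

    ftab = _fraction_table(construct)
    if positions.shape[1]:
        vals = ftab[np.clip(positions, 0, None)]
        green0 = np.where(positions >= 0, vals, 0.0).sum(axis=1)
    else:
        green0 = np.zeros(len(times))

    rng = np.random.default_rng(seed)
    if noise_sigma0 > 0 or noise_sigma1 > 0:
        sd = np.sqrt(noise_sigma0**2 + noise_sigma1**2 * green0)
        green = green0 + rng.normal(0.0, 1.0, size=green0.shape) * sd
    else:
        green = green0.copy()

    stoich = stoichiometry or LabelStoichiometry()
    red_level = expected_label_ratio(stoich)
    if red_noise_cv > 0 and (noise_sigma0 > 0 or noise_sigma1 > 0):
        red = red_level * (1.0 + rng.normal(0.0, red_noise_cv, size=green0.shape))
    else:
        red = np.full_like(green0, red_level)

    return IntensityTrace(
        mrna_id=trajectory.mrna_id,
        times=times.copy(),
        green=green,
        red=red,
        frame_interval_s=frame_interval_s or 0.0,
        noise_sigma0=noise_sigma0,
        noise_sigma1=noise_sigma1,
        truth=trajectory if keep_truth else None,
    )


def simulate_runoff_ensemble(
    construct: ReporterConstruct,
    kinetics: KineticParameters,
    n_mrna: int,
    drug: DrugEvent,
    *,
    pre_equilibration_s: float = 900.0,
    duration_after_s: float = 2400.0,
    frame_interval_s: float = 30.0,
    noise_sigma0: float = 0.0,
    noise_sigma1: float = 0.0,
    pre_drug_frames: int = 5,
    seed: int = 0,
    record_events: bool = False,
) -> list[IntensityTrace]:
    """Simulate a drug-perturbation ensemble, aligned at the drug-add time.

    Each mRNA is equilibrated from an empty state for ``pre_equilibration_s``
    before the drug is added; returned traces carry times relative to drug
    addition (t = 0), including ``pre_drug_frames`` frames of the pre-drug
    steady state used for normalization.
    """
    if n_mrna < 1:
        raise ValueError("n_mrna must be >= 1")
    if drug is None:
        raise ValueError("a DrugEvent is required for a runoff ensemble")
    t_add = pre_equilibration_s + drug.add_time_s
    shifted = DrugEvent(drug.drug, add_time_s=t_add, entry_delay_s=drug.entry_delay_s)
    t0 = t_add - pre_drug_frames * frame_interval_s
    duration = t_add + duration_after_s
    sample_times = np.arange(t0, duration + frame_interval_s / 2, frame_interval_s)

    traces = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_mrna)):
        child_rng = np.random.default_rng(child)
        sim_seed = int(child_rng.integers(1, 2**31 - 1))
        noise_seed = int(child_rng.integers(1, 2**31 - 1))
        traj = simulate_translation(
            construct,
            kinetics,
            duration,
            drugs=(shifted,),
            seed=sim_seed,
            sample_times=sample_times,
            record_events=record_events,
            mrna_id=f"mrna_{i}",
        )
        trace = render_intensity_trace(
            traj,
            construct,
            noise_sigma0=noise_sigma0,
            noise_sigma1=noise_sigma1,
            seed=noise_seed,
        )
        trace.times = trace.times - t_add  # align: t = 0 at drug addition
        traces.append(trace)
    return traces


def draw_polysome_positions(
    L: int,
    n_ribosomes: int,
    footprint_codons: int,
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> list[int]:
    """Draw ribosome positions uniformly on [1, L] under footprint exclusion.

    Rejection sampling: candidates are accepted when at least one footprint
    away from every accepted position.  Useful to seed a steady-state
    polysome without simulating the equilibration transient.
    """
    accepted: list[int] = []
    tries = 0
    while len(accepted) < n_ribosomes and tries < max_tries:
        tries += 1
        p = int(rng.integers(1, L + 1))
        if all(abs(p - q) >= footprint_codons for q in accepted):
            accepted.append(p)
    if len(accepted) < n_ribosomes:
        raise ValueError("could not place the requested number of ribosomes")
    return sorted(accepted)


def simulate_diffusion_track(
    D_um2_per_s: float,
    duration_s: float,
    frame_interval_s: float,
    seed: int = 0,
    *,
    mrna_id: str = "track_0",
    start_um: tuple[float, float] = (0.0, 0.0),
) -> Trajectory2D:
    """A 2D Brownian trajectory: per-frame increments Normal(0, 2 D dt) per axis."""
    if D_um2_per_s < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    n_steps = int(np.floor(duration_s / frame_interval_s + 1e-9))
    times = np.arange(n_steps + 1, dtype=float) * frame_interval_s
    rng = np.random.default_rng(seed)
    sd = np.sqrt(2.0 * D_um2_per_s * frame_interval_s)
    dxy = rng.normal(0.0, sd, size=(n_steps, 2)) if sd > 0 else np.zeros((n_steps, 2))
    xy = np.vstack([np.array(start_um, dtype=float), dxy]).cumsum(axis=0)
    return Trajectory2D(mrna_id=mrna_id, times=times, x_um=xy[:, 0], y_um=xy[:, 1])


def simulate_diffusion_ensemble(
    D_um2_per_s: float,
    n_tracks: int,
    duration_s: float,
    frame_interval_s: float,
    seed: int = 0,
) -> list[Trajectory2D]:
    tracks = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_tracks)):
        s = int(np.random.default_rng(child).integers(1, 2**31 - 1))
        tracks.append(
            simulate_diffusion_track(
                D_um2_per_s, duration_s, frame_interval_s, seed=s, mrna_id=f"track_{i}"
            )
        )
    return tracks
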