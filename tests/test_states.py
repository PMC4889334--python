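"""On/off state segmentation and switching-rate recovery."""

import numpy as np
import pytest

import ribotrace as rt
from ribotrace.estimators import corrected_switching_rates, segment_states


def telegraph_trace(switches, level=10.0, duration=3600.0, dt=30.0):
    """Idealized trace: intensity follows the on/off state instantly."""
    times = np.arange(0.0, duration, dt)
    state = np.ones_like(times)
    for t0, t1 in switches:
        state[(times >= t0) & (times < t1)] = 0.0
    return rt.IntensityTrace("tg", times, level * state, np.zeros_like(times), dt)


class TestSegmentation:
    def test_constant_trace_single_on_segment(self):
        tr = telegraph_trace([])
        s = segment_states(tr, threshold=1.0)
        assert len(s.segments) == 1 and s.segments[0][2] == "on"
        assert s.cycles_per_hour == 0.0 and s.off_fraction == 0.0

    def test_noiseless_telegraph_recovered_exactly(self):
        switches = [(600.0, 900.0), (2400.0, 2700.0)]
        s = segment_states(telegraph_trace(switches), threshold=5.0)
        offs = [(a, b) for a, b, st in s.segments if st == "off"]
        assert offs == switches
        assert s.n_complete_cycles == 2
        assert s.cycles_per_hour == pytest.approx(2.0)
        assert s.off_fraction == pytest.approx(600.0 / 3600.0)
        assert s.reinitiation_times_s == (300.0, 300.0)
        assert s.fraction_reinitiated_within_600s == 1.0

    def test_min_dwell_suppresses_chatter(self):
        tr = telegraph_trace([(600.0, 630.0)])  # a single-frame dip
        s = segment_states(tr, threshold=5.0, min_dwell_frames=2)
        assert all(st == "on" for _, _, st in s.segments)

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            segment_states(telegraph_trace([]), threshold=0.0)

    def test_segments_tile_the_trace(self):
        rng = np.random.default_rng(5)
        times = np.arange(0.0, 7200.0, 30.0)
        green = np.abs(rng.normal(3, 3, size=times.size))
        tr = rt.IntensityTrace("noisy", times, green, np.zeros_like(times), 30.0)
        s = segment_states(tr, threshold=3.0)
        assert s.segments[0][0] == times[0]
        assert s.segments[-1][1] == pytest.approx(times[-1] + 30.0)
        for (a0, b0, _), (a1, b1, _) in zip(s.segments, s.segments[1:]):
            assert b0 == a1


class TestSwitchingRateRecovery:
    def test_generator_defaults_recovered_within_2se(self, kif):
        """200 mRNA-hours at the calibrated switching defaults.

        Off intervals only register once the polysome has drained, so raw
        counts are corrected for the L/k detection dead time; the corrected
        cycle rate and off fraction must bracket the generating truth within
        twice their bootstrap standard error.
        """
        cfg = rt.ScenarioConfig("state_switching", n_mrna=200, duration_s=3600.0, seed=21)
        ds = rt.generate_dataset(cfg)
        summaries = [segment_states(tr, threshold=3.0) for tr in ds.traces]
        deadtime = kif.orf_length_codons / 3.5
        corr = corrected_switching_rates(summaries, deadtime)

        rng = np.random.default_rng(0)
        boots = np.empty((200, 2))
        for b in range(200):
            sel = rng.integers(0, len(summaries), size=len(summaries))
            cb = corrected_switching_rates([summaries[i] for i in sel], deadtime)
            boots[b] = (cb["cycles_per_hour"], cb["off_fraction"])
        se_rate, se_off = np.nanstd(boots, axis=0, ddof=1)

        assert abs(corr["cycles_per_hour"] - 0.29) <= 2 * se_rate
        assert abs(corr["off_fraction"] - 0.025) <= 2 * se_off
        # observed off durations stay exponential-like: mean in a sane window
        assert 150.0 <= corr["mean_off_s"] <= 600.0
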