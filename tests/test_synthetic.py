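"""Scenario generator: determinism, trace validity, calibrated defaults."""

import numpy as np
import pytest

import ribotrace as rt
from ribotrace import io as rio


class TestDefaults:
    def test_calibrated_parameter_table(self):
        p = rt.default_parameters()
        assert p["k_shutdown_per_hr"]["value"] == 0.29
        assert p["off_dwell_mean_s"]["value"] == pytest.approx(0.025 / 0.29 * 3600, rel=0.01)
        assert p["stall_fraction"]["value"] == 0.075
        assert p["D_free"]["value"] == 0.047
        assert p["D_tethered"]["value"] == 1.06e-3
        for entry in p.values():
            assert "note" in entry and "units" in entry

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            rt.ScenarioConfig("nonsense")


class TestGeneratedDatasets:
    def test_determinism_byte_identical(self, tmp_path):
        cfg = rt.ScenarioConfig("steady_state", n_mrna=5, duration_s=600.0, seed=7)
        d1 = rt.generate_dataset(cfg)
        d2 = rt.generate_dataset(cfg)
        p1 = d1.save(tmp_path / "a")
        p2 = d2.save(tmp_path / "b")
        assert p1["traces"].read_bytes() == p2["traces"].read_bytes()
        assert p1["truth"].read_bytes() == p2["truth"].read_bytes()
        d3 = rt.generate_dataset(rt.ScenarioConfig("steady_state", n_mrna=5,
                                                   duration_s=600.0, seed=8))
        assert not np.allclose(d1.traces[0].green, d3.traces[0].green)

    def test_steady_state_ribosome_counts(self, kif):
        """Most translating mRNAs carry 10-25 estimated ribosomes at defaults."""
        cfg = rt.ScenarioConfig("steady_state", n_mrna=60, duration_s=600.0, seed=9)
        ds = rt.generate_dataset(cfg)
        counts = [
            rt.estimate_ribosome_count(max(tr.green[-5:].mean(), 0.0), kif)
            for tr in ds.traces
        ]
        share = np.mean([(10 <= c <= 25) for c in counts])
        assert share >= 0.6

    @pytest.mark.parametrize("scenario", [
        "steady_state", "harringtonine_runoff", "puromycin", "cycloheximide",
        "hippuristanol_runoff", "state_switching", "new_transcript_buildup",
        "single_ribosome", "xbp1_pause_runoff", "damage_stall_runoff",
        "emi1_mixture", "diffusion_free", "diffusion_tethered",
    ])
    def test_every_scenario_produces_valid_output(self, scenario):
        cfg = rt.ScenarioConfig(scenario, n_mrna=4, seed=11)
        if scenario in ("state_switching", "single_ribosome"):
            cfg = rt.ScenarioConfig(scenario, n_mrna=4, seed=11, duration_s=1800.0)
        ds = rt.generate_dataset(cfg)
        assert len(ds.truth) == cfg.n_mrna
        assert ds.metadata["seed"] == 11
        for tr in ds.traces:
            assert np.all(np.isfinite(tr.green))
            assert len(tr.times) >= 2
        for tk in ds.tracks:
            assert np.all(np.isfinite(tk.x_um))
        assert (len(ds.traces) == cfg.n_mrna) or (len(ds.tracks) == cfg.n_mrna)

    def test_puromycin_traces_zero_after_drug(self):
        cfg = rt.ScenarioConfig("puromycin", n_mrna=3, seed=13,
                                noise_sigma0=0.0, noise_sigma1=0.0)
        ds = rt.generate_dataset(cfg)
        for tr in ds.traces:
            after = tr.times >= rt.DrugEvent("puromycin").entry_delay_s
            assert np.all(tr.green[after] == 0.0)

    def test_xbp1_runoff_slower_than_control(self, kif):
        """The pause-site reporter retains more signal late in the runoff."""
        n, t_check = 40, 600.0
        ctrl = rt.generate_dataset(
            rt.ScenarioConfig("harringtonine_runoff", n_mrna=n, seed=15,
                              noise_sigma0=0.0, noise_sigma1=0.0))
        xbp1 = rt.generate_dataset(
            rt.ScenarioConfig("xbp1_pause_runoff", n_mrna=n, seed=15,
                              construct="xbp1_pause", noise_sigma0=0.0, noise_sigma1=0.0))

        def retained(ds):
            times = ds.traces[0].times
            mean = np.stack([t.green for t in ds.traces]).mean(axis=0)
            return np.interp(t_check, times, mean / mean[times <= 0].mean())

        assert retained(xbp1) > retained(ctrl) + 0.05

    def test_csv_roundtrip(self, tmp_path):
        cfg = rt.ScenarioConfig("steady_state", n_mrna=3, duration_s=300.0, seed=17)
        ds = rt.generate_dataset(cfg)
        path = tmp_path / "traces.csv"
        rio.write_traces(ds.traces, path, dataset_id="rt")
        back = rio.read_traces(path)
        assert len(back) == 3
        for a, b in zip(ds.traces, back):
            assert a.mrna_id == b.mrna_id
            np.testing.assert_allclose(a.green, b.green, rtol=1e-6)
            np.testing.assert_allclose(a.times, b.times, rtol=1e-9)

    def test_track_csv_roundtrip(self, tmp_path):
        cfg = rt.ScenarioConfig("diffusion_tethered", n_mrna=3, seed=19)
        ds = rt.generate_dataset(cfg)
        path = tmp_path / "tracks.csv"
        rio.write_tracks(ds.tracks, path)
        back = rio.read_tracks(path)
        assert len(back) == 3
        np.testing.assert_allclose(back[0].x_um, ds.tracks[0].x_um, rtol=1e-6)
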