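"""Stochastic simulator: exclusion, drug contracts, steady state, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ribotrace as rt
from ribotrace.estimators.elongation import runoff_model_curve


class TestBasicContracts:
    def test_zero_initiation_gives_empty_trajectory(self, kif):
        kin = rt.KineticParameters(k_init=0.0, k_elong=3.5)
        traj = rt.simulate_translation(kif, kin, 600, seed=1)
        assert traj.n_initiated == 0
        tr = rt.render_intensity_trace(traj, kif)
        assert np.all(tr.green == 0.0)

    def test_deterministic_single_ribosome_terminates_at_L_over_k(self, kif):
        kin = rt.KineticParameters(k_init=0.0, k_elong=3.0)
        traj = rt.simulate_translation(
            kif, kin, 600, seed=1, frame_interval_s=1.0,
            initial_positions=[1], deterministic=True,
        )
        present = (traj.positions >= 0).any(axis=1)
        t_last = traj.sample_times[present][-1]
        # termination at L / k = 489 s: last present frame at 488, absent at 489
        assert t_last == pytest.approx(1467 / 3.0 - 1.0, abs=1e-9)
        assert not present[traj.sample_times >= 489.0].any()

    def test_puromycin_clears_everything(self, kif):
        kin = rt.KineticParameters(k_init=0.04, k_elong=3.5)
        drug = rt.DrugEvent("puromycin", add_time_s=600, entry_delay_s=0)
        traj = rt.simulate_translation(kif, kin, 1200, drugs=(drug,), seed=3)
        tr = rt.render_intensity_trace(traj, kif)
        after = tr.times >= 600
        assert np.all(tr.green[after] == 0.0)
        assert all(traj.ribosomes_at(i).size == 0 for i in np.nonzero(after)[0])

    def test_cycloheximide_freezes_intensity(self, kif):
        kin = rt.KineticParameters(k_init=0.04, k_elong=3.5)
        drug = rt.DrugEvent("cycloheximide", add_time_s=900, entry_delay_s=0)
        traj = rt.simulate_translation(kif, kin, 2400, drugs=(drug,), seed=4)
        tr = rt.render_intensity_trace(traj, kif)
        frozen = tr.green[tr.times >= 900]
        assert frozen.size > 10
        assert np.all(frozen == frozen[0])

    def test_harringtonine_runoff_reaches_zero_by_transit_time(self, kif):
        kin = rt.KineticParameters(k_init=0.04, k_elong=3.5)
        traces = rt.simulate_runoff_ensemble(
            kif, kin, 40, rt.DrugEvent("harringtonine"), seed=6
        )
        # last pre-block ribosome finishes within L/k plus its stochastic
        # stepping spread (sd = sqrt(L)/k); allow five sds on top of the delay
        deadline = 60 + (1467 + 5 * np.sqrt(1467)) / 3.5
        for tr in traces:
            assert np.all(tr.green[tr.times > deadline] == 0.0)
        # the ensemble mean decays monotonically once the block is active
        mean = np.stack([tr.green for tr in traces]).mean(axis=0)
        post = traces[0].times >= 60
        assert np.all(np.diff(mean[post]) <= 0.05)  # Monte-Carlo wiggle only

    def test_runoff_requires_drug_and_positive_n(self, kif):
        kin = rt.KineticParameters(k_init=0.04, k_elong=3.5)
        with pytest.raises(ValueError):
            rt.simulate_runoff_ensemble(kif, kin, 0, rt.DrugEvent("harringtonine"), seed=1)
        with pytest.raises(ValueError):
            rt.simulate_runoff_ensemble(kif, kin, 5, None, seed=1)

    def test_pause_site_beyond_orf_rejected(self, kif):
        kin = rt.KineticParameters(
            k_init=0.04, k_elong=3.5,
            pause_sites=(rt.PauseSite(3000, 5.0),),
        )
        with pytest.raises(ValueError):
            rt.simulate_translation(kif, kin, 100, seed=1)


class TestExclusionInvariant:
    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(
        k_init=st.floats(0.01, 0.5),
        k_elong=st.floats(0.5, 8.0),
        footprint=st.integers(3, 20),
        seed=st.integers(0, 10_000),
    )
    def test_exclusion_never_violated(self, k_init, k_elong, footprint, seed):
        c = rt.ReporterConstruct("short", 200, (10, 30, 50), 10, 24)
        kin = rt.KineticParameters(k_init=k_init, k_elong=k_elong, footprint_codons=footprint)
        traj = rt.simulate_translation(c, kin, 300, seed=seed, frame_interval_s=5.0)
        traj.validate()  # raises on any violation

    def test_validate_on_polysome_runoff(self, runoff_ensemble_35):
        for tr in runoff_ensemble_35[:20]:
            tr.truth.validate()


class TestSteadyState:
    def test_littles_law_with_realized_flux(self, kif):
        """N_bar equals the realized initiation flux times the transit time L/k.

        The nominal rate k_init overstates the realized flux by the
        entry-exclusion factor 1/(1 + k_init * footprint / k_elong) (~6% at
        these rates), so the sharp statement of the law uses the measured
        initiation rate; the nominal-rate instance is exercised in the
        acceptance suite.
        """
        kin = rt.KineticParameters(k_init=0.0239, k_elong=3.5)
        counts, n_init, total_time = [], 0, 0.0
        for i, child in enumerate(np.random.SeedSequence(900).spawn(100)):
            s = int(np.random.default_rng(child).integers(1, 2**31 - 1))
            traj = rt.simulate_translation(kif, kin, 2 * 3600, seed=s, frame_interval_s=60.0)
            burn = traj.sample_times > 2 * 1467 / 3.5
            counts.append((traj.positions[burn] >= 0).sum(axis=1).mean())
            n_init += traj.n_initiated
            total_time += 2 * 3600
        lam = n_init / total_time
        assert np.mean(counts) == pytest.approx(lam * 1467 / 3.5, rel=0.02)
        # the realized flux itself matches the entry-gated renewal prediction
        lam_pred = 1.0 / (kin.footprint_codons / kin.k_elong + 1.0 / kin.k_init)
        assert lam == pytest.approx(lam_pred, rel=0.02)

    def test_ensemble_mean_matches_continuum_oracle(self, kif):
        """The mean noiseless runoff curve converges to the receding-density curve."""
        kin = rt.KineticParameters(k_init=0.04, k_elong=3.5)
        traces = rt.simulate_runoff_ensemble(
            kif, kin, 2000, rt.DrugEvent("harringtonine", entry_delay_s=0),
            duration_after_s=600, seed=77,
        )
        times = traces[0].times
        Y = np.stack([tr.green for tr in traces])
        mean = Y.mean(axis=0)
        pre = mean[times <= 0].mean()
        norm = mean / pre
        se = Y.std(axis=0, ddof=1) / np.sqrt(len(traces)) / pre
        model = runoff_model_curve(times, 3.5, kif, t0=0.0)
        post = times >= 0
        # Monte-Carlo error plus a margin for step-dispersion smoothing and the
        # censored entry gap, both concentrated near the end of the decay and
        # bounded well below one ribosome's normalized weight (~0.08 here)
        tol = np.maximum(4 * se[post], 0.03)
        assert np.all(np.abs(norm[post] - model[post]) <= tol)


class TestNoiseModel:
    def test_additive_noise_sd(self, kif):
        kin = rt.KineticParameters(k_init=0.0, k_elong=3.5)
        traj = rt.simulate_translation(kif, kin, 10_000 * 1.0, seed=1, frame_interval_s=1.0)
        tr = rt.render_intensity_trace(traj, kif, noise_sigma0=0.3, seed=12)
        assert tr.green.std(ddof=1) == pytest.approx(0.3, rel=0.03)

    def test_noiseless_trace_is_exact_forward_model(self, runoff_ensemble_35, kif):
        tr = runoff_ensemble_35[0]
        traj = tr.truth
        for i in (0, len(tr.times) // 2, len(tr.times) - 1):
            pos = traj.ribosomes_at(i)
            assert tr.green[i] == pytest.approx(
                rt.site_intensity(pos, kif) if pos.size else 0.0
            )

    def test_negative_noise_params_rejected(self, kif):
        kin = rt.KineticParameters(k_init=0.0, k_elong=3.5)
        traj = rt.simulate_translation(kif, kin, 60, seed=1)
        with pytest.raises(ValueError):
            rt.render_intensity_trace(traj, kif, noise_sigma0=-0.1)


class TestDeterminism:
    def test_identical_seeds_identical_output(self, kif):
        kin = rt.KineticParameters(
            k_init=0.05, k_elong=3.5, k_shutdown_per_hr=2.0, k_reinit_per_s=0.01,
            pause_sites=(rt.PauseSite(700, 5.0, 300.0, 0.2),),
        )
        a = rt.simulate_translation(kif, kin, 1800, seed=123, record_events=True)
        b = rt.simulate_translation(kif, kin, 1800, seed=123, record_events=True)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.events["time_s"], b.events["time_s"])
        assert np.array_equal(a.events["event"], b.events["event"])
        assert a.state_log == b.state_log
        c = rt.simulate_translation(kif, kin, 1800, seed=124)
        assert not np.array_equal(a.positions, c.positions)


class TestDiffusionSimulator:
    def test_zero_D_is_stationary(self):
        t = rt.simulate_diffusion_track(0.0, 100, 1.0, seed=1)
        assert np.all(t.x_um == 0) and np.all(t.y_um == 0)

    def test_increment_variance(self):
        D, dt = 0.047, 30.0
        t = rt.simulate_diffusion_track(D, 10_000 * dt, dt, seed=2)
        vx = np.var(np.diff(t.x_um), ddof=1)
        assert vx == pytest.approx(2 * D * dt, rel=0.05)

    def test_ensemble_msd_at_one_lag(self):
        D, dt = 0.047, 30.0
        disp = []
        for i, tr in enumerate(rt.simulate_diffusion_ensemble(D, 2000, 2 * dt, dt, seed=3)):
            disp.append((tr.x_um[1] - tr.x_um[0]) ** 2 + (tr.y_um[1] - tr.y_um[0]) ** 2)
        assert np.mean(disp) == pytest.approx(4 * D * dt, rel=0.1)

    def test_negative_D_rejected(self):
        with pytest.raises(ValueError):
            rt.simulate_diffusion_track(-1.0, 10, 1.0, seed=0)
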