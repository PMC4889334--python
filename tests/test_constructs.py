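"""Reporter geometry, the intensity function and the counting formulas."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ribotrace as rt
from ribotrace.constructs import uniform_epitope_positions


def brute_force_fraction(position, construct):
    """Independent oracle: explicit loop over epitopes."""
    n = 0
    for e in construct.epitope_positions:
        if e + construct.exit_tunnel_codons <= position:
            n += 1
    return n / construct.n_epitopes


class TestExposedEpitopeFraction:
    @pytest.mark.parametrize(
        "position, expected",
        [(0, 0.0), (1467, 1.0), (374, 0.5)],  # 374: 12 of 24 epitopes visible
    )
    def test_reference_positions(self, kif, position, expected):
        assert rt.exposed_epitope_fraction(position, kif) == pytest.approx(expected)

    def test_matches_brute_force(self, kif):
        for x in range(0, kif.orf_length_codons + 1, 7):
            assert rt.exposed_epitope_fraction(x, kif) == brute_force_fraction(x, kif)

    def test_out_of_range_raises(self, kif):
        with pytest.raises(ValueError):
            rt.exposed_epitope_fraction(-1, kif)
        with pytest.raises(ValueError):
            rt.exposed_epitope_fraction(kif.orf_length_codons + 1, kif)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_monotone_and_bounded_on_random_constructs(self, data):
        L = data.draw(st.integers(10, 3000))
        K = data.draw(st.integers(1, 40))
        positions = data.draw(
            st.lists(st.integers(1, L), min_size=K, max_size=K, unique=True)
        )
        delta = data.draw(st.integers(0, 50))
        c = rt.ReporterConstruct("rand", L, tuple(sorted(positions)), delta, 24)
        f = rt.exposed_epitope_fraction(np.arange(0, L + 1, dtype=float), c)
        assert np.all(f >= 0) and np.all(f <= 1)
        assert np.all(np.diff(f) >= 0)
        # ramp mode shares bounds and monotonicity
        fr = rt.exposed_epitope_fraction(np.arange(0, L + 1, dtype=float), c, mode="ramp")
        assert np.all(fr >= 0) and np.all(fr <= 1)
        assert np.all(np.diff(fr) >= -1e-12)


class TestSiteIntensity:
    def test_empty_and_single(self, kif):
        assert rt.site_intensity([], kif) == 0.0
        assert rt.site_intensity([1467], kif) == 1.0

    def test_reference_pair(self, kif):
        assert rt.site_intensity([374, 1467], kif) == pytest.approx(1.5)

    def test_additive_in_ribosomes(self, kif):
        rng = np.random.default_rng(0)
        a = list(rng.integers(1, 1468, size=7))
        b = list(rng.integers(1, 1468, size=5))
        assert rt.site_intensity(a + b, kif) == pytest.approx(
            rt.site_intensity(a, kif) + rt.site_intensity(b, kif)
        )

    def test_out_of_range_raises(self, kif):
        with pytest.raises(ValueError):
            rt.site_intensity([0], kif)


class TestMeanPositionalCorrection:
    def test_matches_enumeration(self, kif):
        L = kif.orf_length_codons
        exact = sum(brute_force_fraction(x, kif) for x in range(1, L + 1)) / L
        assert rt.mean_positional_correction(kif) == pytest.approx(exact, abs=1e-12)
        assert rt.mean_positional_correction(kif) == pytest.approx(0.752, abs=0.001)

    def test_immediately_visible_epitopes(self):
        c = rt.ReporterConstruct("instant", 100, (1,), exit_tunnel_codons=0)
        # single epitope visible from codon 1 onward: every position contributes 1
        assert rt.mean_positional_correction(c) == pytest.approx(1.0)

    def test_terminal_epitope_only(self):
        L = 200
        c = rt.ReporterConstruct("terminal", L, (L,), exit_tunnel_codons=0)
        assert rt.mean_positional_correction(c) == pytest.approx(1.0 / L)

    def test_ramp_agrees_with_discrete_within_half_step(self, kif):
        d = rt.mean_positional_correction(kif)
        r = rt.mean_positional_correction(kif, mode="ramp")
        assert abs(d - r) < 1.0 / (2 * kif.n_epitopes)


class TestRibosomeCount:
    def test_zero_and_reference(self, kif):
        assert rt.estimate_ribosome_count(0.0, kif) == 0.0
        assert rt.estimate_ribosome_count(7.52, kif) == pytest.approx(10.0, abs=0.01)

    def test_negative_clamped_nonfinite_raises(self, kif):
        assert rt.estimate_ribosome_count(-0.2, kif) == 0.0
        with pytest.raises(ValueError):
            rt.estimate_ribosome_count(float("nan"), kif)

    def test_unbiased_under_uniform_placement(self, kif):
        """Forward model + inversion recovers the true count for uniform ribosomes."""
        rng = np.random.default_rng(42)
        n_true, n_mrna = 15, 1000
        estimates = []
        for _ in range(n_mrna):
            pos = rng.integers(1, kif.orf_length_codons + 1, size=n_true)
            I = rt.site_intensity(pos, kif)
            estimates.append(rt.estimate_ribosome_count(I, kif))
        assert np.mean(estimates) == pytest.approx(n_true, rel=0.02)


class TestLabelStoichiometry:
    @pytest.mark.parametrize("occupancy, expected", [(1.0, 4.0), (0.5, 2.0), (0.0, 0.0)])
    def test_expected_ratio(self, occupancy, expected):
        s = rt.LabelStoichiometry(24, 2, 2, occupancy, 24)
        assert rt.expected_label_ratio(s) == expected

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            rt.expected_label_ratio(rt.LabelStoichiometry(reference_fluorophores=0))


class TestConstructValidationAndIO:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            rt.ReporterConstruct("bad", 100, (5, 5))  # not strictly increasing
        with pytest.raises(ValueError):
            rt.ReporterConstruct("bad", 100, (0,))
        with pytest.raises(ValueError):
            rt.ReporterConstruct("bad", 100, (150,))
        with pytest.raises(ValueError):
            rt.ReporterConstruct("bad", 100, (10,), exit_tunnel_codons=-1)

    def test_presets_consistent(self):
        for name in rt.list_presets():
            c = rt.get_preset(name)
            assert c.last_visible_codon <= c.orf_length_codons
        assert rt.get_preset("kif18b_suntag24").orf_length_codons == 1467
        assert rt.get_preset("kif18b_suntag24").epitope_positions == uniform_epitope_positions(24)
        with pytest.raises(KeyError):
            rt.get_preset("nope")

    @pytest.mark.parametrize("suffix", [".yaml", ".json"])
    def test_roundtrip(self, tmp_path, kif, suffix):
        p = tmp_path / f"c{suffix}"
        rt.save_construct(kif, p)
        assert rt.load_construct(p) == kif
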