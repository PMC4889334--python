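import numpy as np
import pytest

import ribotrace as rt


@pytest.fixture(scope="session")
def kif() -> rt.ReporterConstruct:
    return rt.get_preset("kif18b_suntag24")


@pytest.fixture(scope="session")
def runoff_ensemble_35(kif):
    """Harringtonine runoff ensemble at 3.5 codons/s (noiseless), shared by tests."""
    kin = rt.KineticParameters(k_init=0.04, k_elong=3.5)
    return rt.simulate_runoff_ensemble(
        kif, kin, 150, rt.DrugEvent("harringtonine"), seed=105
    )


def make_steady_traces(construct, k_init, k_elong, n, duration_s, seed,
                       frame_interval_s=30.0, noise=(0.0, 0.0), **kin_kwargs):
    """Simulate n independent steady-state-style traces starting from empty."""
    kin = rt.KineticParameters(k_init=k_init, k_elong=k_elong, **kin_kwargs)
    out = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n)):
        rng = np.random.default_rng(child)
        s1, s2 = (int(rng.integers(1, 2**31 - 1)) for _ in range(2))
        traj = rt.simulate_translation(
            construct, kin, duration_s, seed=s1,
            frame_interval_s=frame_interval_s, mrna_id=f"mrna_{i}",
        )
        out.append(
            rt.render_intensity_trace(
                traj, construct, noise_sigma0=noise[0], noise_sigma1=noise[1], seed=s2
            )
        )
    return out
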