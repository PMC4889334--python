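"""End-to-end regression targets: simulate at calibrated truth, re-estimate.

Each target regenerates its inputs from scratch with the synthetic-data
machinery at the calibrated default parameters, runs the matching estimator,
and reports the recovered value together with the generating truth and the
package's pre-registered recovery tolerance.  These are the quantities a
full reanalysis of the imaging study would produce.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from . import estimators as est
from .constructs import LabelStoichiometry, expected_label_ratio, get_preset
from .kinetics import DrugEvent, KineticParameters
from .simulate import simulate_diffusion_ensemble, simulate_runoff_ensemble
from .synthetic import ScenarioConfig, default_parameters, generate_dataset

__all__ = ["TargetResult", "TARGETS", "run_target", "run_all"]

_P = {k: v["value"] for k, v in default_parameters().items()}


@dataclass
class TargetResult:
    name: str
    value: float
    n: int
    truth: Optional[float]
    rel_tol: Optional[float]
    passed: Optional[bool]
    units: str
    detail: str = ""


def _derive_seed(seed: int, salt: int) -> int:
    return int(np.random.default_rng(np.random.SeedSequence((seed, salt))).integers(1, 2**31 - 1))


def label_ratio_half_occupancy(seed: int = 0) -> TargetResult:
    """Expected mRNA-label brightness at 50% hairpin occupancy (fold)."""
    value = expected_label_ratio(LabelStoichiometry(occupancy=0.5))
    return TargetResult("label_ratio_half_occupancy", float(value), 1, 2.0, 0.0,
                        value == 2.0, "fold")


def label_ratio_full_occupancy(seed: int = 0) -> TargetResult:
    value = expected_label_ratio(LabelStoichiometry(occupancy=1.0))
    return TargetResult("label_ratio_full_occupancy", float(value), 1, 4.0, 0.0,
                        value == 4.0, "fold")


def initiation_rate_range(seed: int = 0) -> tuple[TargetResult, TargetResult]:
    """Steady-state initiation rates for 10- and 25-ribosome polysomes (per min)."""
    c = get_preset("kif18b_suntag24")
    lo = est.estimate_initiation_rate(10, 3.5, c)
    hi = est.estimate_initiation_rate(25, 3.5, c)
    return (
        TargetResult("initiation_rate_low", lo, 1, 1.43, 0.01, abs(lo - 1.43) < 0.01, "1/min"),
        TargetResult("initiation_rate_high", hi, 1, 3.58, 0.01, abs(hi - 3.58) < 0.01, "1/min"),
    )


def elongation_model_fit(seed: int = 0, n_mrna: int = 300) -> TargetResult:
    """Runoff-model elongation rate recovered from a simulated drug ensemble."""
    c = get_preset("kif18b_suntag24")
    truth = _P["k_elong"]
    kin = KineticParameters(k_init=_P["k_init"], k_elong=truth,
                            footprint_codons=_P["footprint_codons"])
    traces = simulate_runoff_ensemble(
        c, kin, n_mrna, DrugEvent("harringtonine"),
        pre_equilibration_s=_P["pre_equilibration_s"],
        duration_after_s=_P["runoff_duration_s"],
        noise_sigma0=_P["noise_sigma0"], noise_sigma1=_P["noise_sigma1"],
        seed=_derive_seed(seed, 5),
    )
    fit = est.fit_runoff_elongation(traces, c, entry_delay_s=_P["entry_delay_harringtonine_s"],
                                    n_bootstrap=200, seed=_derive_seed(seed, 55))
    value = fit.rate_codons_per_s
    return TargetResult("elongation_model_fit", float(value), n_mrna, truth, 0.10,
                        abs(value - truth) <= 0.10 * truth, "codons/s",
                        detail=f"bootstrap sd {fit.sd:.3f}")


def elongation_runoff_time(seed: int = 0, n_mrna: int = 300) -> TargetResult:
    """Total-runoff-time elongation rate on a noiseless simulated ensemble."""
    c = get_preset("kif18b_suntag24")
    truth = _P["k_elong_runoff_time"]
    kin = KineticParameters(k_init=_P["k_init"], k_elong=truth,
                            footprint_codons=_P["footprint_codons"])
    traces = simulate_runoff_ensemble(
        c, kin, n_mrna, DrugEvent("harringtonine"),
        pre_equilibration_s=_P["pre_equilibration_s"],
        duration_after_s=_P["runoff_duration_s"],
        seed=_derive_seed(seed, 6),
    )
    T = est.disappearance_times(traces)
    fit = est.elongation_from_runoff_time(T, c, entry_delay_s=_P["entry_delay_harringtonine_s"])
    value = fit.rate_codons_per_s
    return TargetResult("elongation_runoff_time", float(value), int(fit.n_traces), truth, 0.10,
                        abs(value - truth) <= 0.10 * truth, "codons/s",
                        detail=f"delta-method sd {fit.sd:.3f}")


def single_ribosome_rate(seed: int = 0, min_events: int = 100) -> TargetResult:
    """Mean single-ribosome elongation rate from detected translation events."""
    c = get_preset("kif18b_suntag24")
    truth = _P["k_elong_single_ribosome"]
    rates: list[float] = []
    batch = 0
    while len(rates) < min_events and batch < 6:
        cfg = ScenarioConfig(
            "single_ribosome", n_mrna=60, seed=_derive_seed(seed, 7 + batch)
        )
        ds = generate_dataset(cfg)
        for tr in ds.traces:
            for ev in est.detect_single_ribosome_events(tr, c):
                if not ev.overlapping:
                    rates.append(ev.inferred_rate_codons_per_s)
        batch += 1
    value = float(np.mean(rates))
    return TargetResult("single_ribosome_rate", value, len(rates), truth, 0.10,
                        abs(value - truth) <= 0.10 * truth, "codons/s",
                        detail=f"event sd {np.std(rates):.3f}")


def diffusion_free(seed: int = 0, n_tracks: int = 300) -> TargetResult:
    """MSD-fit diffusion coefficient of freely diffusing mRNA spots."""
    truth = _P["D_free"]
    tracks = simulate_diffusion_ensemble(truth, n_tracks, 100.0, 1.0, seed=_derive_seed(seed, 8))
    r = est.estimate_diffusion_ensemble(tracks)
    value = r["D_mean"]
    return TargetResult("diffusion_free", float(value), n_tracks, truth, 0.10,
                        abs(value - truth) <= 0.10 * truth, "um^2/s",
                        detail=f"sem {r['D_sem']:.2e}")


def diffusion_tethered(seed: int = 0, n_tracks: int = 300) -> TargetResult:
    """MSD-fit diffusion coefficient of membrane-tethered mRNA spots."""
    truth = _P["D_tethered"]
    tracks = simulate_diffusion_ensemble(truth, n_tracks, 3600.0, 30.0, seed=_derive_seed(seed, 9))
    r = est.estimate_diffusion_ensemble(tracks)
    value = r["D_mean"]
    return TargetResult("diffusion_tethered", float(value), n_tracks, truth, 0.10,
                        abs(value - truth) <= 0.10 * truth, "um^2/s",
                        detail=f"sem {r['D_sem']:.2e}")


TARGETS: dict[str, Callable[..., TargetResult]] = {
    "label_ratio_full_occupancy": label_ratio_full_occupancy,
    "label_ratio_half_occupancy": label_ratio_half_occupancy,
    "elongation_model_fit": elongation_model_fit,
    "elongation_runoff_time": elongation_runoff_time,
    "single_ribosome_rate": single_ribosome_rate,
    "diffusion_free": diffusion_free,
    "diffusion_tethered": diffusion_tethered,
}


def run_target(name: str, seed: int = 0) -> TargetResult:
    if name not in TARGETS:
        raise KeyError(f"unknown target {name!r}; available: {sorted(TARGETS)}")
    return TARGETS[name](seed=seed)


def run_all(seed: int = 0, names: Optional[list[str]] = None) -> list[TargetResult]:
    names = list(TARGETS) if names is None else names
    out = []
    for name in names:
        out.append(run_target(name, seed=seed))
    return out
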