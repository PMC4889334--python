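# ribotrace

Simulation and inference for live-cell single-mRNA translation imaging.

In SunTag/PP7 imaging experiments, single mRNAs are visualized for an hour
or more while ribosomes translate them: nascent chains carry an N-terminal
epitope array bound co-translationally by a fluorescent antibody
(scFv-GFP), and the mRNA itself is labeled through 3'-UTR hairpins bound by
PP7–mCherry. The green intensity of a translation site is then a direct,
quantitative readout of how many ribosomes are on the transcript and where
they are. `ribotrace` provides the machinery to analyze — and to simulate —
such experiments:

- **Intensity model.** A ribosome at codon `x` exposes
  `f(x) = #{i : e_i + Δ ≤ x}/K` of the full label (epitopes `e_i`,
  exit-tunnel offset `Δ`); site intensity is `Σ_j f(x_j)` in units of one
  mature protein, and ribosome number is recovered as `N = I/c̄` with
  `c̄ = (1/L)Σ_x f(x)` the mean positional correction.
- **Traffic simulator.** An exact event-driven exclusion-process
  (TASEP-like) simulation of initiation, per-codon elongation, pause and
  damage sites, translational on/off switching, and the standard drug
  perturbations (harringtonine, puromycin, cycloheximide, hippuristanol),
  rendered into noisy two-channel intensity traces and 2D spot tracks.
- **Estimators.** Elongation rate from runoff decays (three-stage model fit,
  normalized stage-2 slope `−k/(L c̄)`) and from total runoff times
  (`k = L/mean(T − delay)`); initiation rate by flux balance
  (`α = N·k·60/L` per minute); on/off state segmentation with a dead-time
  correction for switching rates; single-ribosome event detection with
  duration-to-rate conversion `(L − e_1 − Δ)/duration`; stall detection and
  roadblock-vs-damage decay classification; polysome-buildup slopes;
  intensity distributions with ribosome-weighted shares; MSD diffusion fits
  (`MSD = 4Dτ + b`).
- **Synthetic data.** Thirteen calibrated scenarios with per-mRNA ground
  truth, so every estimator is testable end to end without any external
  data.

The library is the primary interface; `examples/` holds one short script
per capability, and a thin CLI (`ribotrace simulate | analyze | reproduce`)
wraps the same functions for shell use.

## Worked example

Recover the elongation rate from a simulated harringtonine runoff
(`examples/02_runoff_elongation.py`):

```python
import ribotrace as rt
from ribotrace.estimators import (
    disappearance_times, elongation_from_runoff_time, fit_runoff_elongation,
)

c = rt.get_preset("kif18b_suntag24")            # L = 1467 codons, 24 epitopes
kin = rt.KineticParameters(k_init=0.04, k_elong=3.5)

traces = rt.simulate_runoff_ensemble(
    c, kin, n_mrna=150, drug=rt.DrugEvent("harringtonine"), seed=20,
)
fit = fit_runoff_elongation(traces, c, entry_delay_s=60, n_bootstrap=100, seed=1)
fit2 = elongation_from_runoff_time(disappearance_times(traces), c, entry_delay_s=60)
```

prints

```
model fit: k = 3.25 +/- 0.13 codons/s (n = 150 mRNAs; truth 3.5)
  fitted stage boundaries: linear stage ends at 482 s after drug
total runoff time: k = 3.71 +/- 0.02 codons/s (mean disappearance 456 s)
```

Both estimators land within ~10% of the generating truth; the first fits
the three-stage decay of the ensemble-mean intensity after initiation is
blocked, the second divides the ORF length by the mean time until each
mRNA's signal disappears (minus the 60 s the drug needs to enter the
cell). The diffusion example (`examples/07_diffusion.py`) prints

```
free mRNA:     D = 0.0465 +/- 0.0006 um^2/s (truth 0.047)
tethered mRNA: D = 1.07e-03 +/- 1.2e-05 um^2/s (truth 1.06e-3)
tethering slows diffusion 43-fold
```

— membrane tethering is what makes hour-long tracking of single
transcripts possible.

See `docs/methods.md` for the models, calibrated defaults and their
rationale, and known limitations.

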