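# Methods

`ribotrace` models the quantitative machinery of live-cell single-mRNA
translation imaging: a reporter mRNA whose nascent chains are labeled
co-translationally through an N-terminal epitope array (SunTag bound by
scFv-GFP) and whose 3' UTR carries hairpins bound by fluorescent PP7 coat
protein. This note records the models, the calibrated defaults, the
numerical choices, and what the synthetic-data tests do and do not
establish about real data.

## Intensity model

A ribosome at codon `x` has completed every epitope whose last codon lies at
least the exit-tunnel offset Δ behind it, so its nascent chain carries

    f(x) = #{i : e_i + Δ ≤ x} / K,

with `e_1 < … < e_K` the epitope completion positions. The package's
canonical intensity unit is one fully synthesized, fully labeled mature
protein (`f = 1`); calibration from camera units is an explicit division at
the I/O boundary (`CalibrationUnit`). Translation-site intensity is the sum
of `f` over ribosome positions — additive, with no proximity effects.

Two forms of `f` are provided: the discrete staircase (default everywhere)
and a continuum linear ramp between the first and last visible codons, used
by the runoff fitter where a smooth model is wanted. For the default 24×
reporter the two agree to well under half an epitope weight.

Ribosome counting inverts the forward model in expectation: a ribosome
uniformly positioned on the ORF contributes on average
`c̄ = (1/L) Σ f(x) ≈ 0.752` (default construct), so `N = I / c̄`.

**Reporter geometry.** The default construct is a 24× epitope array followed
by a kinesin gene body: tag array 634 codons (epitopes at `round(26.4·i)`),
gene body 833 codons, `L = 1467` (a 4.4 kb ORF). The exact epitope spacing
of the real array is not known to this package; uniform spacing is an
assumption, configurable per construct (`ReporterConstruct`, YAML/JSON
presets). Δ defaults to 35 codons, a typical exit-tunnel occlusion
(~30–40 aa); it is likewise configurable.

## Traffic simulator

Ribosome traffic is an exclusion process with per-codon exponential steps:

- initiation attempts at rate `k_init` while (a) the mRNA is in the
  translating state, (b) no initiation-blocking drug is active, and (c) the
  first `footprint` codons are free; a new ribosome enters at codon 1;
- each ribosome advances one codon with mean waiting time `1/k_elong`,
  blocked while the ribosome ahead is within the footprint (default 10
  codons; observed inter-ribosome spacings are 200–400 nt, so results are
  footprint-insensitive except for the entry gating discussed below);
- crossing a pause or damage site adds an extra dwell — exponential by
  default, fixed at the mean when `fixed_dwell=True`; pause dwells are a
  short/long mixture, and `single_long=True` lets at most one ribosome per
  mRNA draw the long component (a roadblock);
- stepping off codon `L` terminates the ribosome and releases its chain.

The event loop is an exact Gillespie simulation (numba-compiled). Drug
actions, telegraph state switches, frame sampling and fixed-dwell wake-ups
are scheduled boundaries at which the exponential clock is redrawn — valid
by memorylessness. Deterministic stepping (fixed `1/k_elong` intervals) is a
separate exact code path used for analytic reference tests; it supports a
single ribosome or pre-placed, non-interacting ribosomes only.

Drug contracts: harringtonine and hippuristanol block initiation only;
puromycin releases every nascent chain instantly and blocks initiation;
cycloheximide freezes all movement and initiation. Default cell-entry
delays: 60 s (harringtonine, hippuristanol, cycloheximide), 30 s
(puromycin); all configurable. Nucleotide damage (the 4NQO condition) is
not a drug but a `DamageSite` placed on a configurable fraction of mRNAs.

Translational state switching is a two-state telegraph process gating
initiation only: shutdown at `k_shutdown` per hour, reinitiation at
`k_reinit` per second, initial state drawn from the stationary distribution.
Elongating ribosomes finish normally after a shutdown, which is what makes
the observed signal decay gradual.

**Entry-region gating.** Because initiation attempts are only accepted while
the entry region is free, the realized initiation flux is
`1/(footprint/k_elong + 1/k_init)` — about 6% below nominal at the default
rates. This is a property of the model contract, not an artifact: the
long-run mean ribosome number obeys Little's law exactly against the
realized flux (verified to <1% in the test suite) but sits ~6% below the
idealized `k_init·L/k_elong`. Estimates of "initiation rate" from data
(flux balance, buildup slopes) recover the realized flux.

**Measurement model.** Rendered traces add Gaussian noise with variance
`σ0² + σ1²·I` (affine in signal). The study's own noise level is not
published; the defaults σ0 = 0.2, σ1 = 0.05 give a single-ribosome plateau
an SNR of about 5, which reproduces the visual quality of published
single-event traces. The red (mRNA) channel is the expected label ratio
with 5% multiplicative noise.

## Estimators

**Runoff elongation (model fit).** After the block takes effect at `t0`, a
steady-state ribosome density recedes at speed `k`; with the ramp intensity
function the normalized ensemble mean is `I(t) = G(k(t−t0))/G(0)`,
`G(y) = ∫_y^L f`. Stage 1 is curved (trailing edge inside the epitope
array), stage 2 linear with normalized slope `−k/(L c̄)`, stage 3 zero. The
fitter normalizes the cumulative mean to its pre-drug level and
least-squares fits `(k, t0)` (`t0` free within a few entry delays, which
also absorbs the `k/k_init` entry gap at the block). Uncertainty is a
bootstrap over mRNAs (200 resamples, seeded). Fitting individual traces is
supported but the cumulative mean is the default. If the trace does not
decay (final level > 0.9 of pre-drug) the result is flagged, not raised.

**Runoff elongation (total time).** `k = L / mean(T − delay)` with `T` the
final signal-disappearance time (midpoint of the last positive frame and
the next). The sd comes from the delta method. This estimator runs a few
percent high because the last pre-block ribosome has already advanced
~`k/k_init` codons when the block lands; the bias is inherent to the
measurement definition and stays well inside the 10% recovery tolerance.

**Initiation rate.** Steady-state flux balance `α = N·k_elong·60/L` per
minute. Ten and twenty-five ribosomes at 3.5 codons/s give 1.43 and
3.58 min⁻¹.

**State segmentation.** Median filter (3 frames), hysteresis thresholding
(off below 0.8×, on above 1.2× the threshold), minimum dwell 2 frames to
suppress chatter. A complete cycle is an off segment flanked by on
segments; its duration is the reinitiation time. Because the polysome needs
`T0 ≈ L/k_elong` to drain, an off interval registers only if it outlasts
`T0`. For exponential off dwells of mean `m` this censoring has a clean
structure: the observed cycle rate is `r·exp(−T0/m)` while the observed off
durations remain `Exp(m)`. `corrected_switching_rates` inverts this to
recover the underlying telegraph parameters; the identity
`r·m = off fraction` (0.29 hr⁻¹ × 5.2 min ≈ 2.5%) is preserved by the
correction. The observed off durations carry a small positive bias (the
signal-rise delay after reinitiation, ~30–60 s), which propagates into a
mild overestimate of the corrected off fraction; both stay within two
standard errors at the calibrated defaults.

**Single-ribosome events.** Runs above a detection threshold (3× a robust
noise estimate, floor 0.25 units), with sub-threshold gaps of up to 2
frames closed and episodes touching either trace end discarded as
censored. The appearance time is found by fitting the known rise template —
a linear ramp whose duration is tied to the event duration through the
construct geometry, leaving `t_appear` as the only free parameter — which
avoids the late-detection bias of simple thresholding. Loss is the midpoint
of the abrupt drop below half-plateau. The rate conversion is
`(L − e_1 − Δ)/(t_loss − t_appear)`. Events whose plateau exceeds 1.25
units (or peak 1.6) are flagged as overlapping, not split. At the default
noise and 30 s frames the recovered mean runs ~3–4% high (residual partial
overlaps and drop quantization), inside the 10% tolerance.

**Stall classification.** A trace is stalled if it retains ≥ 50% of its
pre-drug intensity 15 min after the block. The decay class inspects only
the interval after a normal-runoff horizon (450 s ≈ `L/k` at the default
rate, configurable): a roadblock leaves the trace flat until the stalled
ribosome clears and the queued ribosomes then stream through the site
almost at once, so "burst" is called when one 120 s window carries ≥ 50% of
the post-horizon decline with ≤ 20% of it occurring earlier; substantial
diffuse post-horizon decline is "slow_linear" (damage); anything else is
"normal". Changepoints from binary segmentation with a BIC-style penalty
are reported for inspection but the window test makes the call — it proved
far more robust than segment-counting at single-ribosome granularity, where
even damage decays are step-like. On 200-trace ensembles the classifier
separates roadblock from damage at ≥ 95%.

**Buildup analysis.** Traces are aligned at the first frame above a
detection threshold (0.5 units), averaged, and the initial rise fitted over
a 480 s window. The slope is converted to an implied initiation rate with
the model curve `M(t) = F(min(kt, L))/k` (`F` the running integral of `f`):
the alignment time depends on the rate itself, so a short fixed-point
iteration finds the rate whose model slope over the detection-shifted
window matches the fit. The two-ensemble comparison bootstraps the slope
difference (500 resamples) and reports a single two-sided p-value — one
planned comparison, no multiplicity correction.

**Intensity distributions.** Negative intensities are clamped, mRNAs at or
below the translating threshold (conventionally 2× the background SD) are
excluded, and each bin reports both the mRNA fraction and the
intensity-weighted (ribosome) share; values above the top edge accumulate
in the top bin.

**Diffusion.** Time-averaged MSD at lags 1–5, weighted linear fit
`MSD = 4Dτ + b` with weights √(pair count); the intercept absorbs
localization error, negative slopes truncate to `D = 0` with a flag.

## Synthetic-data generator

Thirteen scenarios cover the standard experiment designs: polysomal steady
state, the four drug perturbations, reversible state switching, new
transcript buildup, single-ribosome traces, pause-site and damage runoffs,
an initiation-rate mixture, and free/tethered 2D diffusion. Every dataset
carries one ground-truth record per mRNA and a metadata block echoing the
resolved configuration; identical configurations and seeds give
byte-identical files.

Calibrated defaults (see `default_parameters()` for the full table with
provenance notes): elongation 3.5 codons/s (3.1 for the runoff-time
condition, 3.0 for single ribosomes, 4.9 available for the codon-optimized
preset), initiation 0.04 s⁻¹ (≈ 17 ribosomes on the long reporter, inside
the reported 10–25 band), shutdown 0.29 hr⁻¹ with mean off dwell 312 s
(chosen so rate × dwell = 2.5% silent time), stall fraction 7.5% (midpoint
of the observed 5–10%), damage dwell 300 s, pause mixture 10 s/900 s with
10% long fraction at codon 1300, diffusion 0.047 and 1.06×10⁻³ μm²/s,
frames every 30 s, runoffs observed for 40 min after 15 min equilibration,
long-term imaging 2 hr. The initiation mixture for the repressive-5'UTR
scenario is 80% silent, 18% at 0.004 s⁻¹, 2% at 0.04 s⁻¹ — weights chosen
once so the bright minority carries ≈ half of all ribosomes, matching the
reported heterogeneity. A Poisson tracking-loss truncation is available
(`track_loss_rate_per_hr`) but off by default.

**What the generator does not emulate:** pixel-level detection and
tracking (inputs are already traces), photobleaching (disappearance in the
study was shown not to be photobleaching), mRNA decay, codon-specific
elongation rates, cell-to-cell expression differences beyond per-mRNA
parameter mixtures, and clearance of stalled ribosomes (stalls persist for
the simulation unless released by their dwell). Passing tests therefore
demonstrate estimator correctness under the stated noise and kinetic
model, not robustness to segmentation errors or optical artifacts in real
movies.

## Numerical choices and degenerate inputs

Positions are 1-based; 0 means "initiating, nothing synthesized".
Intensity traces require a uniform time grid and finite values; noiseless
rendering is exactly the forward model. The runoff fitter bounds
`k ∈ [0.05, 50]` codons/s and seeds it from the 5%-crossing time; the
bootstrap reuses the point estimate as its start. Empty position sets give
zero intensity; empty trace collections and too-short tracks raise.
Negative measured intensities clamp to zero before counting. All
randomness flows from `numpy.random.SeedSequence`, with one spawned child
per mRNA; kernel seeds stay below 2³¹.

## Problem sizes

The regression targets use 300 mRNAs per runoff ensemble, ≥ 100
single-ribosome events, 300 diffusion tracks each, 200 mRNA-hours for
switching statistics and 200 traces per stall ensemble — sizes comparable
to the study's own n (536 runoff sites, 211 tethered tracks, 106 switching
mRNAs) and sufficient to hold Monte-Carlo error well inside each
tolerance.

## Known limitations

- The entry-exclusion gating means nominal `k_init` overstates realized
  flux by ~6% at default rates; all flux-based estimators recover the
  realized value (see above).
- The runoff-time estimator and the event detector carry small (≤ 5%)
  documented biases inherent to their measurement definitions.
- The dead-time correction for switching rates assumes exponential off
  dwells; strongly non-exponential silent periods would bias it.
- The deterministic stepping mode ignores exclusion and is intended only
  for single-ribosome analytic checks.
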