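# Methods

This note describes the models and numerical choices behind `thetaburst`:
what each analysis computes, what the synthetic-data generator emulates (and
does not), and where the design was genuinely open.

## Burst segmentation

A complex spike burst is a maximal run of ≥ 2 spikes whose inter-spike
intervals (ISIs) are all ≤ 15 ms; the comparison is inclusive ("no more
than"), so an ISI of exactly 15 ms still joins a burst. Every other spike is
a single spike, which by construction has both neighbouring ISIs > 15 ms.
The burst's timestamp is its first spike. Segmentation is a linear scan and
is tested against an independent brute-force run-scanner; the partition
conserves spike counts on every input and commutes with a joint rescaling of
times and threshold.

Burst-structure statistics follow the field's conventions:

* **Rates** — bursts/s, single spikes/s, all spikes/s, and the fraction of
  spikes inside bursts, per cell; population values are means ± SEM across
  cells (not across bursts), because cells are the statistical unit.
* **Length histogram** — per-cell relative probability over burst lengths
  2, 3, 4, 5, ≥ 6, normalised per cell before summarising across cells.
* **Accommodation** — mean ISI per (burst length, interval order); the
  accommodation rate is the slope of ISI against order over the first two
  intervals of 3-spike bursts, in ms per interval. A positive slope is
  spike-frequency accommodation; a slope near zero with shorter ISIs in
  longer bursts is the "inverse length–frequency coupling" pattern.
* **Post-event conditional** — for each trigger event (burst or single),
  the latency from its last spike to the next event and that event's class.
  The default estimator is hazard-style: per 5 ms bin, P(next event falls in
  this bin and is of the response class | the silence reached the bin).
  A plain normalised latency histogram is available via
  `estimator="histogram"`; the hazard form is the default because it has a
  flat closed-form expectation (1 − e^(−λΔ)) for Poisson firing, which makes
  suppression visible as a dip rather than as a shape change.

## Theta phase

Theta epochs are detected from the ratio of theta (5–10 Hz) to delta
(1–4 Hz) band power in 1 s windows; windows with ratio > 2 are merged and
intervals shorter than 1 s dropped. The band edges and the threshold are
config-exposed defaults — reasonable for mouse CA1, but not universal.

Instantaneous phase is the angle of the analytic signal of the zero-phase
band-passed (Butterworth order 3, 5–10 Hz, `sosfiltfilt`) LFP, in degrees,
**with the filtered trough at 0°/360° and the peak at 180°**. Every phase
number in the package depends on this convention; it was chosen so that
phase-locking "close to the oscillation trough" reads as a mean phase near
0°/360°.

Phase histograms are occupancy corrected: each of the 20 bins' event counts
is divided by the fraction of in-epoch LFP samples whose phase falls in that
bin (times the bin count), then normalised to a probability. This removes
the bias a nonuniform phase-dwell distribution would otherwise imprint on
any event train. Zero-occupancy bins are excluded and the rest renormalised.
The displayed curve may be smoothed with a circular Gaussian (SD 2 bins);
the circular statistics — mean direction, resultant length R, Rayleigh p —
are always computed from the raw event phases, because tests on events
should not inherit smoothing. An `correct_stats=True` switch computes
occupancy-weighted statistics instead; raw is the default.

The Rayleigh p uses the standard large-sample approximation
p = exp(√(1 + 4n + 4(n² − (nR)²)) − (1 + 2n)). Its type-I error at n = 50
is 0.047–0.051 in our Monte Carlo calibration.

Silverman's modality bootstrap is implemented circularly with a von Mises
kernel: the critical concentration κ* is the largest kernel concentration
still giving ≤ k modes of the KDE (the circular analogue of the smallest
critical bandwidth), found by geometric bisection on a 256-point grid;
bootstrap samples are smoothed resamples at κ*, and p is the add-one
fraction of bootstrap critical bandwidths exceeding the observed one. A
degenerate point mass returns p = 1.

The multitaper PSD averages DPSS-tapered periodograms (NW = 3, 2NW − 1
tapers, 1024-sample windows, 50% overlap). Band power integrates the PSD
over a band by trapezoid with edge interpolation, so it scales with true
bandwidth rather than with bin placement.

## Pair synchrony

The burst cross-correlogram (CCG) histograms target-minus-reference burst
onset lags in 10 ms bins centred on zero over ±200 ms, normalised per
reference event. Bins are centred on multiples of the bin width so lag 0 is
a bin centre. Pair averages carry SEM across pairs.

The CCG spectrum is a continuous complex Morlet transform (ω₀ = 6, unit-
energy wavelets) of the mean-subtracted CCG, with power averaged over lags,
on a 1–40 Hz grid. Theta-band power is the 5–10 Hz mean. Significance comes
from a permutation null: each pair's target train is independently
circularly shifted by a uniform offset (which preserves each train's own
autostructure and event count exactly), the pair-average CCG and its
theta-band power are recomputed N times (default 1000), and p is the
add-one fraction of null powers ≥ observed. Null p-values are uniform by
construction (verified by KS test in the suite).

The burst autocorrelogram excludes the zero-lag self-count bin; its theta
rhythmicity index is theta-band Morlet power divided by mean 1–40 Hz power.
For strongly periodic trains part of the power sits in harmonics above
10 Hz, so the index is a monotone readout of locking strength only over the
physiological range of concentrations (κ ≲ 4); the suite tests it there.

## Place fields

The arena (50 × 30 cm) is binned into 2 × 2 cm pixels; the circular track
(Ø 60 cm) is linearised by angle onto a circularly wrapped 1-D axis with
2 cm bins. Occupancy accumulates frame durations per pixel; immobility
frames (< 2 cm/s) are excluded from both occupancy and spikes, with the
2–3 cm/s band included (the behavioural-state thresholds are > 3 cm/s
running, < 2 cm/s immobility). Rate is spike count over dwell time, with
spikes assigned to the nearest tracked frame; pixels never visited are
undefined (NaN), not zero.

Maps are not smoothed by default; place fields are 4-connected components
(wrap-adjacent in 1-D) of pixels with rate > 1 Hz and at least 2 pixels,
largest field first. Field sizes are pixels × 4 cm² (2-D) or pixels × 2 cm
(1-D); per-class field sizes are reported as a fraction of the all-spike
field size, using the largest field by default (summing is available).

Field statistics over the defined pixels, with pᵢ the occupancy fraction,
λᵢ the pixel rate and λ̄ = Σpᵢλᵢ:

* sparsity = (Σpᵢλᵢ)² / Σpᵢλᵢ² (1 = uniform, → 0 = compact);
* spatial information = Σpᵢ(λᵢ/λ̄)log₂(λᵢ/λ̄) in bits/spike;
* in-field rate = occupancy-weighted mean rate over field pixels.

Both statistics are invariant to uniform occupancy rescaling. Map
similarity between spike classes is Pearson r over jointly defined pixels,
Fisher z-transformed with r clipped at ±0.999999 (flagged "perfect" at the
clip).

## Optogenetics

**Entrainment fidelity** per 10 s window is the cumulative PSD within
±0.5 Hz of the stimulation frequency divided by the cumulative theta-band
(5–10 Hz) PSD; windows above 0.3 count as highly entrained. The PSD of each
window is a multitaper estimate over the whole 10 s segment (NW = 3, i.e.
half-bandwidth 0.3 Hz). The full-window taper is essential: a shorter
window would smear a pure tone beyond the ±0.5 Hz numerator band and cap
fidelity well below 1 even for perfect entrainment. For 12 Hz stimulation
the denominator band is extended with [11.5, 12.5] Hz so fidelity stays ≤ 1.

**Light-triggered CCG**: spike counts in 1 ms bins over ±10 ms around pulse
onsets; the peak response is also expressed in SDs above the mean of the
pre-pulse bins.

**ChAT⁺ identification**: A_obs/B_obs are the maximum 1 ms bin counts in
[−10, 0) and (0, +10] ms around the true pulses. Surrogates shift the whole
pulse train by a uniform random offset constrained so every surrogate pulse
lands in the pre-stimulation baseline, preserving the train's structure;
p₁ = P(Aᵢ > A_obs) and p₂ = P(Bᵢ > B_obs) with an add-one correction.
Because the bin maxima are small integers, ties between observed and
surrogate maxima are pervasive; ranks are therefore computed after adding
independent Uniform(0,1) jitter to each maximum (seeded), which makes the
permutation p-values exactly uniform under the null — with strict integer
ranks the null ChAT⁺ rate inflates to ~0.14 at a nominal 0.05. A cell is
ChAT⁺ if, for at least one stimulation epoch (2 Hz and 5 Hz, 4 min each,
5 ms pulses), p₂ < 0.05 and p₁ ≥ 0.05; the pre-pulse screen removes cells
locked to the stimulation rhythm rather than driven by it.

**Pulse-window burst-spike test**: burst-class spike counts inside the 30 ms
pulse windows (or the 30 ms after pulse offset, via `offset_s`) against the
same count over equally many randomly placed baseline windows; two-sided
rank p with add-one correction.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, with
full ground truth. Defaults are the study conditions:

| parameter | control | mutant |
|---|---|---|
| burst event rate | 0.23 Hz | 0.24 Hz |
| single-spike rate | 0.80 Hz | 0.49 Hz |
| burst phase locking (run) | von Mises μ = 344°, κ = 1 | κ = 0 (unlocked) |
| burst phase locking (immobility) | μ = 344°, κ = 1 | μ = 315°, κ = 1 |
| ISI rule | 6 ms + 1.5 ms/interval | 7.2 ms flat, −0.35 ms per extra spike |
| burst-length pmf | geometric ratio 0.55 over 2–7 | ratio 0.70 over 2–7 |
| post-burst suppression | 55 ms | 55 ms |

The control pmf/ISI combination implies a pooled mean ISI of 7.396 ms
(`expected_mean_isi_ms`), the generator's own closure target. The burst-
length pmf values themselves are illustrative free parameters, not measured
quantities.

Mechanics: burst events are an inhomogeneous Poisson process — rate = base
rate × place gain × von Mises phase gain — sampled exactly by thinning. The
place gain is a Gaussian bump (σ = 6 cm, peak/baseline 8) normalised to
trajectory-average 1; the phase gain e^{κcos(θ−μ)}/I₀(κ) has unit mean over
uniform phase. Each event draws a length and emits spikes with the preset
ISI rule jittered ±0.5 ms. Because definitionally two bursts ≤ 15 ms apart
would be one burst, and a single spike has all neighbour ISIs > 15 ms, the
generator enforces matching dead times (15.5 ms) between bursts and around
singles, and compensates the base rates for the blocked time and dead time
— weighted by the local gain squared, since events concentrate where the
rate is high — so the *realised* rates match the preset targets. Single
spikes are silenced for 55 ms after each burst's last spike. The merged
train enforces a 2 ms refractory period by deletion; ground truth records
the intended labels, so segmentation-vs-truth agreement (≥ 99%) is itself a
tested quantity.

The LFP is a theta sinusoid (7 Hz) with slow frequency wander (SD 0.3 Hz,
1 s smoothing) plus 1/√f background, as −A·cos(φ) so the ground-truth phase
follows the trough = 0° convention; the oscillator runs through both run
and (alert) immobility blocks. Trajectories are an Ornstein–Uhlenbeck
velocity walk with reflecting walls in the arena (run blocks held above
3 cm/s, immobility blocks at 0) or unidirectional motion with pauses on the
track. The state schedule alternates 40 s run / 20 s immobility blocks.

What the generator does **not** emulate: spike waveforms and sorting noise,
theta harmonics and asymmetry, phase precession, inter-cell correlations
beyond shared phase locking, behaviour-dependent remapping, and LFP
artifacts around light pulses. Tests passing on this generator therefore
certify the analysis code under its stated assumptions, not robustness of
the science to real-data pathologies.

Light sessions: a 300 s baseline, then 4 min epochs of 2 Hz and 5 Hz 5 ms
pulses; responsive cells add one spike per pulse at 3 ± 1 ms latency with
probability 0.8 on top of 2 Hz Poisson background.

All simulation is seeded; identical config + seed gives bit-identical
output.

## Problem sizes in the test suite

The suite runs the closure and calibration checks at sizes chosen to keep
statistical power while remaining desk-scale: rate/ISI closure at 50 cells ×
600 s, phase recovery pooled over 10 cells × 600 s, Rayleigh calibration at
10⁴ draws, optotag calibration at 1000 null cells × 199 shifts, CCG null
uniformity at 200 datasets × 49 permutations and the genotype contrast at
2 × 20 seeded 400 s populations. `scripts/acceptance.py` recomputes the same
quantities at comparable sizes from a single master seed.

## Known limitations

* Theta-epoch detection assumes the 1/f background of the generator; real
  LIA/REM structure may need different ratio thresholds.
* The hazard estimator of the post-burst curve conditions on "next event",
  so very low firing rates give wide bins with few at-risk triggers.
* The rhythmicity index mixes fundamental and harmonic power for extremely
  regular trains (see above).
* The Silverman bootstrap evaluates the KDE on a 256-point grid; modes
  narrower than ~1.4° are not resolved.
* On the 1-D track, field "areas" are lengths (cm); only the dimensionless
  size fractions are comparable across enclosures.
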