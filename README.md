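# thetaburst

Analysis toolbox for complex spike bursts, theta-phase coordination and
place fields in hippocampal unit recordings, with a ground-truth synthetic
session generator.

Hippocampal CA1 pyramidal cells emit two elementary signals: single action
potentials and complex spike bursts — runs of ≥ 2 spikes with inter-spike
intervals (ISIs) ≤ 15 ms and accommodating intervals. Their timing relative
to the theta rhythm (5–10 Hz) and their spatial firing maps carry distinct
information, and manipulations that de-coordinate bursts from theta (K⁺
channel knockouts, optogenetic control of medial-septal inputs) reshape the
place code of single spikes. `thetaburst` implements the complete analysis
chain needed to quantify these effects:

* **Burst analysis** — segmentation (inclusive 15 ms ISI rule), rates per
  spike class, burst-length distributions, spike-frequency accommodation
  (ISI vs. order in burst), and the post-burst conditional probability of
  single-spike firing (the ~50–60 ms suppression window).
* **Theta phase** — theta-epoch detection by theta/delta power ratio,
  Hilbert phase with the trough at 0°, occupancy-corrected phase
  histograms, Rayleigh and Silverman-bootstrap circular statistics,
  multitaper PSD (NW = 3).
* **Pair synchrony** — burst-time cross-correlograms (±200 ms), Morlet
  wavelet spectra (< 40 Hz) of the pair-averaged CCG, and a circular-shift
  permutation test of theta-band co-firing.
* **Place fields** — occupancy-normalised 2 × 2 cm rate maps per spike
  class (all / burst / single), 1 Hz-contour field detection, Skaggs
  sparsity and spatial information (bits/spike), Fisher-z map correlations.
* **Optogenetics** — entrainment fidelity (power within ±0.5 Hz of the
  stimulation frequency over theta-band power, per 10 s window),
  light-triggered CCGs, ChAT⁺ identification by a stimulus-shift
  permutation test (p₂ < 0.05 after, p₁ ≥ 0.05 before the pulse), and
  pulse-window burst-spike tests.
* **Synthetic data** — seeded generator of theta LFP, arena/track
  trajectories, bursty theta-locked place cells with genotype presets
  (control / mutant), and light protocols with responsive cells; every
  session carries full ground truth.

I/O covers the Neurosuite-style dialects: `.res`/`.clu` spike files (or
plain-text seconds, auto-detected), flat int16 `.eeg` LFP at 1250 Hz,
position CSV at 25 frames/s, and light-pulse CSV.

## Worked example

Simulate a control-preset session and measure burst statistics and theta
phase locking:

```python
import numpy as np
from thetaburst import (SynthConfig, simulate_session, segment_bursts,
                        burst_rate_stats, accommodation, detect_theta_epochs,
                        instantaneous_phase, phase_histogram)

cfg = SynthConfig(duration=600.0, n_cells=10, seed=101)
session, truths = simulate_session(cfg)

segs = [segment_bursts(u) for u in session.units]
rates = [burst_rate_stats(s, cfg.duration) for s in segs]
prof = accommodation(segs)
print(f"burst rate {np.mean([r['burst_rate'] for r in rates]):.3f} Hz, "
      f"single rate {np.mean([r['single_rate'] for r in rates]):.3f} Hz")
print(f"mean ISI {np.mean(prof.per_cell_mean_isi):.2f} ms, "
      f"accommodation {prof.accommodation_rate:+.2f} ms/interval")

epochs = detect_theta_epochs(session.lfp)
phase = instantaneous_phase(session.lfp)
onsets = np.sort(np.concatenate([s.burst_onsets() for s in segs]))
h = phase_histogram(onsets, phase, epochs)
print(f"burst phase: mean {h.mean_phase:.0f} deg, R = {h.resultant_length:.2f}, "
      f"Rayleigh p = {h.rayleigh_p:.2g} (n = {h.n_events})")
```

Output:

```
burst rate 0.231 Hz, single rate 0.802 Hz
mean ISI 7.41 ms, accommodation +1.48 ms/interval
burst phase: mean 342 deg, R = 0.47, Rayleigh p = 6.7e-141 (n = 1389)
```

The recovered numbers match the generator presets: bursts at ~0.23 Hz,
single spikes at ~0.80 Hz, pooled mean ISI ~7.4 ms with ~1.5 ms/interval
accommodation, and burst emission locked near the theta trough (μ = 344°,
κ = 1 → R ≈ 0.45). With `preset="mutant"` the same pipeline shows flat
accommodation, shorter ISIs in longer bursts, and no phase locking during
running.

A CLI wraps the same pipelines (`thetaburst simulate | bursts | phase |
pairs | placefields | optotag`), each taking a YAML config and an output
directory and writing a provenance JSON.

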