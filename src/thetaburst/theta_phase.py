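"""Theta-epoch detection, instantaneous phase, phase histograms and circular
statistics.

Theta oscillations (5-10 Hz) are detected from the ratio of theta- to
delta-band (1-4 Hz) power in sliding windows.  Instantaneous phase comes from
the Hilbert transform of the 5-10 Hz zero-phase filtered LFP, expressed in
degrees with the **trough at 0 deg / 360 deg and the peak at 180 deg**.  All
phase numbers in this package follow that convention.

Event-phase histograms are occupancy corrected: each bin's event count is
divided by the fraction of (in-epoch) LFP samples whose phase falls in that
bin, so a nonuniform dwell time across phases does not masquerade as phase
locking.  The probability curve may be smoothed with a circular Gaussian
kernel for display; the circular statistics (mean phase, resultant length R,
Rayleigh p) are always computed from the events themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core_io import LFPSignal, PositionTrack

THETA_BAND = (5.0, 10.0)
DELTA_BAND = (1.0, 4.0)


@dataclass
class ThetaEpochs:
    intervals: np.ndarray  # shape (n, 2), [start, end] in s, disjoint, sorted
    ratio_threshold: float
    band: tuple[float, float] = THETA_BAND

    @property
    def total_duration(self) -> float:
        if self.intervals.size == 0:
            return 0.0
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def contains(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask: which times fall inside any epoch."""
        t = np.asarray(t, dtype=float)
        mask = np.zeros(t.shape, dtype=bool)
        for start, end in self.intervals:
            mask |= (t >= start) & (t <= end)
        return mask


@dataclass
class PhaseSeries:
    t: np.ndarray      # s, LFP sample times
    phase: np.ndarray  # degrees in [0, 360), trough = 0

    def at(self, times: np.ndarray) -> np.ndarray:
        """Phase at arbitrary event times (nearest-sample lookup)."""
        times = np.asarray(times, dtype=float)
        idx = np.clip(np.searchsorted(self.t, times), 0, self.t.size - 1)
        left = np.clip(idx - 1, 0, self.t.size - 1)
        use_left = np.abs(self.t[left] - times) < np.abs(self.t[idx] - times)
        idx = np.where(use_left, left, idx)
        return self.phase[idx]


@dataclass
class PhaseHistogram:
    bin_edges: np.ndarray    # degrees, length n_bins + 1
    probability: np.ndarray  # sums to 1 over included bins
    mean_phase: float        # degrees
    resultant_length: float  # R in [0, 1]
    rayleigh_p: float
    n_events: int

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


@dataclass
class BehavioralState:
    """Running (> 3 cm/s) and immobility (< 2 cm/s) intervals; speeds in
    between stay unclassified."""

    running: np.ndarray    # (n, 2) intervals, s
    immobility: np.ndarray

    RUN_THRESHOLD = 3.0   # cm/s
    IMMOBILE_THRESHOLD = 2.0


def _mask_to_intervals(mask: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Convert a boolean per-sample mask to [start, end] intervals."""
    if not mask.any():
        return np.empty((0, 2))
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2] - 1
    return np.column_stack([t[starts], t[ends]])


def classify_behavioral_state(track: PositionTrack) -> BehavioralState:
    if track.speed is None:
        raise ValueError("track has no speed; run compute_speed first")
    return BehavioralState(
        running=_mask_to_intervals(track.speed > BehavioralState.RUN_THRESHOLD, track.t),
        immobility=_mask_to_intervals(
            track.speed < BehavioralState.IMMOBILE_THRESHOLD, track.t
        ),
    )


def _bandpass_sos(lo: float, hi: float, rate: float, order: int = 3):
    return signal.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")


def band_power_timecourse(
    lfp: LFPSignal, band: tuple[float, float], window: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mean squared band-limited amplitude in non-overlapping windows.

    Returns (window start times, power per window).
    """
    sos = _bandpass_sos(band[0], band[1], lfp.rate)
    filtered = signal.sosfiltfilt(sos, lfp.samples)
    n_win = int(round(window * lfp.rate))
    n_full = filtered.size // n_win
    if n_full == 0:
        raise ValueError("signal shorter than one window")
    chunks = filtered[: n_full * n_win].reshape(n_full, n_win)
    power = np.mean(chunks**2, axis=1)
    starts = np.arange(n_full) * n_win / lfp.rate
    return starts, power


def detect_theta_epochs(
    lfp: LFPSignal,
    ratio_threshold: float = 2.0,
    window: float = 1.0,
    min_duration: float = 1.0,
) -> ThetaEpochs:
    """Detect theta epochs from the theta/delta power ratio in sliding
    windows; contiguous supra-threshold windows merge into intervals and
    intervals shorter than ``min_duration`` are dropped."""
    if lfp.rate < 20.0:
        raise ValueError("LFP rate below Nyquist requirement for the theta band")
    starts, theta_p = band_power_timecourse(lfp, THETA_BAND, window)
    _, delta_p = band_power_timecourse(lfp, DELTA_BAND, window)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(delta_p > 0, theta_p / delta_p, np.inf)
    above = ratio > ratio_threshold

    intervals = []
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j < above.size and above[j]:
                j += 1
            start = starts[i]
            end = starts[j - 1] + window
            if end - start >= min_duration:
                intervals.append([start, min(end, lfp.duration)])
            i = j
        else:
            i += 1
    return ThetaEpochs(
        intervals=np.asarray(intervals).reshape(-1, 2),
        ratio_threshold=ratio_threshold,
    )


def instantaneous_phase(lfp: LFPSignal, band: tuple[float, float] = THETA_BAND) -> PhaseSeries:
    """Instantaneous theta phase: zero-phase 5-10 Hz band-pass, analytic
    signal angle, shifted so the filtered trough maps to 0/360 deg."""
    if lfp.rate < 20.0:
        raise ValueError("LFP rate below Nyquist requirement for the theta band")
    if not np.any(lfp.samples):
        raise ValueError("all-zero signal has no defined phase")
    sos = _bandpass_sos(band[0], band[1], lfp.rate)
    filtered = signal.sosfiltfilt(sos, lfp.samples)
    analytic = signal.hilbert(filtered)
    # angle(analytic) = 0 at the filtered peak; trough convention adds 180
    phase = (np.degrees(np.angle(analytic)) + 180.0) % 360.0
    return PhaseSeries(t=lfp.t, phase=phase)


# ---------------------------------------------------------------------------
# Circular statistics
# ---------------------------------------------------------------------------

def circular_mean_deg(phases_deg: np.ndarray, weights: np.ndarray | None = None) -> tuple[float, float]:
    """Weighted circular mean direction (deg) and resultant length R."""
    rad = np.radians(np.asarray(phases_deg, dtype=float))
    if weights is None:
        weights = np.ones_like(rad)
    w = np.asarray(weights, dtype=float)
    c = np.sum(w * np.cos(rad)) / np.sum(w)
    s = np.sum(w * np.sin(rad)) / np.sum(w)
    mean = np.degrees(np.arctan2(s, c)) % 360.0
    return float(mean), float(np.hypot(c, s))


def rayleigh_test(phases_deg: np.ndarray) -> dict[str, float]:
    """Rayleigh test of circular uniformity.

    R = |sum e^{i theta}| / n; the p-value uses the standard large-sample
    approximation p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n)).
    """
    phases = np.asarray(phases_deg, dtype=float)
    n = phases.size
    if n < 5:
        raise ValueError("Rayleigh test requires at least 5 events")
    _, r = circular_mean_deg(phases)
    rn = n * r
    z = n * r * r
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - rn * rn)) - (1.0 + 2.0 * n))
    return {"R": float(r), "p": float(min(p, 1.0)), "z": float(z), "n": n}


def _circular_gaussian_smooth(values: np.ndarray, sd_bins: float) -> np.ndarray:
    """Smooth a circular curve with a wrapped Gaussian kernel (SD in bins)."""
    n = values.size
    if sd_bins <= 0:
        return values
    offsets = np.arange(n) - n // 2
    kernel = np.exp(-0.5 * (offsets / sd_bins) ** 2)
    kernel /= kernel.sum()
    return np.real(np.fft.ifft(np.fft.fft(values) * np.fft.fft(np.fft.ifftshift(kernel))))


def phase_histogram(
    events: np.ndarray,
    phase: PhaseSeries,
    epochs: ThetaEpochs | None = None,
    n_bins: int = 20,
    smooth_sd_bins: float = 2.0,
    correct_stats: bool = False,
) -> PhaseHistogram:
    """Occupancy-corrected phase histogram of event times.

    Events outside the theta epochs are discarded.  Each bin's event count is
    divided by the phase-occupancy fraction of that bin times ``n_bins`` (so a
    uniform occupancy leaves counts untouched), then normalised to a
    probability.  Bins with zero occupancy are excluded (NaN) with a warning
    and the rest renormalised.  The probability curve is smoothed with a
    circular Gaussian (SD ``smooth_sd_bins`` bins); mean phase, R and the
    Rayleigh p come from the unsmoothed events (occupancy-weighted when
    ``correct_stats``).
    """
    events = np.asarray(events, dtype=float)
    if epochs is not None:
        in_epoch_events = epochs.contains(events)
        events = events[in_epoch_events]
        sample_mask = epochs.contains(phase.t)
    else:
        sample_mask = np.ones(phase.t.size, dtype=bool)
    if events.size == 0:
        raise ValueError("no events inside the theta epochs")

    event_phases = phase.at(events)
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(event_phases, bins=edges)

    occ_counts, _ = np.histogram(phase.phase[sample_mask], bins=edges)
    occ_frac = occ_counts / occ_counts.sum()

    zero_occ = occ_frac == 0
    if zero_occ.any():
        warnings.warn(f"{zero_occ.sum()} phase bins with zero occupancy excluded")
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = np.where(zero_occ, np.nan, counts / (occ_frac * n_bins))
    total = np.nansum(corrected)
    prob = corrected / total if total > 0 else corrected

    smoothed = prob.copy()
    valid = ~np.isnan(prob)
    if smooth_sd_bins > 0 and valid.all():
        smoothed = _circular_gaussian_smooth(prob, smooth_sd_bins)
        smoothed /= smoothed.sum()

    if correct_stats:
        # weight each event by the inverse occupancy of its phase bin
        which = np.clip(np.digitize(event_phases, edges) - 1, 0, n_bins - 1)
        w = np.where(occ_frac[which] > 0, 1.0 / (occ_frac[which] * n_bins), 0.0)
        mean_phase, r = circular_mean_deg(event_phases, weights=w)
    else:
        mean_phase, r = circular_mean_deg(event_phases)
    try:
        p = rayleigh_test(event_phases)["p"]
    except ValueError:
        p = float("nan")

    return PhaseHistogram(
        bin_edges=edges,
        probability=smoothed,
        mean_phase=mean_phase,
        resultant_length=r,
        rayleigh_p=p,
        n_events=int(events.size),
    )


def phase_histogram_squared_difference(
    h1: PhaseHistogram, h2: PhaseHistogram
) -> np.ndarray:
    """Per-bin squared probability differences for two-sample comparison of
    phase modulation across behaviours/genotypes."""
    if h1.bin_edges.size != h2.bin_edges.size or not np.allclose(
        h1.bin_edges, h2.bin_edges
    ):
        raise ValueError("histograms must share identical binning")
    return (h1.probability - h2.probability) ** 2


# ---------------------------------------------------------------------------
# Silverman modality bootstrap
# ---------------------------------------------------------------------------

def _von_mises_kde(phases_rad: np.ndarray, kappa: float, grid: np.ndarray) -> np.ndarray:
    # log-sum-exp style stabilisation is unnecessary for kappa <= ~700
    dens = np.exp(kappa * np.cos(grid[:, None] - phases_rad[None, :])).sum(axis=1)
    return dens / dens.sum()


def _count_modes(density: np.ndarray) -> int:
    d = density
    left = np.roll(d, 1)
    right = np.roll(d, -1)
    return int(np.sum((d > left) & (d >= right)))


def _critical_kappa(
    phases_rad: np.ndarray, k_null: int, grid_size: int = 256,
    kappa_hi: float = 500.0, tol: float = 1e-2,
) -> float:
    """Largest von Mises kernel concentration giving <= k_null modes.

    Larger kappa = narrower kernel = more modes; the critical concentration
    is the analogue of Silverman's critical bandwidth (bandwidth ~ 1/sqrt(kappa)).
    """
    grid = np.linspace(0.0, 2.0 * np.pi, grid_size, endpoint=False)
    lo, hi = 1e-3, kappa_hi
    if _count_modes(_von_mises_kde(phases_rad, hi, grid)) <= k_null:
        return hi
    while hi / lo > 1.0 + tol:
        mid = np.sqrt(lo * hi)
        if _count_modes(_von_mises_kde(phases_rad, mid, grid)) <= k_null:
            lo = mid
        else:
            hi = mid
    return lo


def silverman_modality_test(
    phases_deg: np.ndarray,
    k_null: int = 1,
    n_boot: int = 1000,
    seed: int | None = None,
) -> float:
    """Silverman's bootstrap test of the null "at most k_null modes" for
    circular data, using a von Mises kernel density.

    The critical concentration is the narrowest kernel still giving <= k_null
    modes; bootstrap samples are drawn from the critical-concentration
    density, and p is the fraction of bootstrap samples whose own critical
    bandwidth exceeds the observed one (i.e. whose critical concentration is
    smaller).  Small p rejects k_null modes in favour of more.
    """
    phases = np.radians(np.asarray(phases_deg, dtype=float) % 360.0)
    if phases.size < 20:
        raise ValueError("need at least 20 phases")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives a coarse p-value")
    if np.allclose(phases, phases[0]):
        return 1.0  # degenerate point mass: trivially unimodal

    rng = np.random.default_rng(seed)
    kappa_crit = _critical_kappa(phases, k_null)
    n = phases.size
    exceed = 0
    for _ in range(n_boot):
        resample = rng.choice(phases, size=n, replace=True)
        boot = resample + rng.vonmises(0.0, kappa_crit, size=n)
        if _critical_kappa(boot, k_null) < kappa_crit:
            exceed += 1
    return (exceed + 1) / (n_boot + 1)


# ---------------------------------------------------------------------------
# Multitaper PSD
# ---------------------------------------------------------------------------

def multitaper_psd(
    lfp: LFPSignal,
    nw: float = 3.0,
    window: int = 1024,
    overlap: float = 0.5,
) -> dict[str, np.ndarray]:
    """Multitaper power spectral density: DPSS-tapered periodograms averaged
    over 2*NW-1 tapers and sliding windows.

    Frequency resolution is rate / window.  Returns frequencies (Hz), the PSD
    and the number of windows averaged.
    """
    x = lfp.samples
    if x.size < window:
        raise ValueError("signal shorter than the PSD window")
    k = int(2 * nw - 1)
    tapers = signal.windows.dpss(window, nw, Kmax=k)
    step = max(1, int(window * (1.0 - overlap)))
    starts = np.arange(0, x.size - window + 1, step)
    freqs = np.fft.rfftfreq(window, d=1.0 / lfp.rate)
    psd = np.zeros(freqs.size)
    for s in starts:
        seg = x[s : s + window]
        seg = seg - seg.mean()
        spec = np.abs(np.fft.rfft(tapers * seg[None, :], axis=1)) ** 2
        psd += spec.mean(axis=0)
    psd /= starts.size * lfp.rate
    return {"frequencies": freqs, "psd": psd, "n_windows": np.array(starts.size)}


def band_power(freqs: np.ndarray, psd: np.ndarray, f_lo: float, f_hi: float) -> float:
    """Cumulative PSD over [f_lo, f_hi] by trapezoidal integration with edge
    interpolation, so the result scales with true bandwidth rather than with
    the accidental placement of frequency bins."""
    f_grid = np.unique(np.concatenate([freqs, [f_lo, f_hi]]))
    f_grid = f_grid[(f_grid >= f_lo) & (f_grid <= f_hi)]
    if f_grid.size < 2:
        return 0.0
    p_grid = np.interp(f_grid, freqs, psd)
    return float(np.trapezoid(p_grid, f_grid))
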