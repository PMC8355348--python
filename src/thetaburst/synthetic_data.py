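"""Synthetic session generator with full ground truth.

Emulates the statistical structure the analysis pipeline assumes: theta-band
LFP (5-10 Hz) with 1/f background during running and alert immobility,
smoothed random-walk trajectories in a rectangular arena or
unidirectional-with-pauses motion on a circular track, bursty theta-modulated
place cells, and light-pulse protocols with responsive and non-responsive
units.

Genotype presets encode the two study conditions:

* ``control`` — burst events at 0.23 Hz, single spikes at 0.80 Hz, bursts
  phase-locked to the theta trough region (von Mises, mu = 344 deg,
  kappa = 1) in both behavioural states, spike-frequency accommodation
  (ISIs start at 6 ms and lengthen by 1.5 ms per interval), pooled mean ISI
  ~= 7.4 ms, and a ~55 ms post-burst suppression of single spikes.
* ``mutant`` — burst events at 0.24 Hz, single spikes at 0.49 Hz, bursts
  unlocked during running (kappa = 0) but locked (mu = 315 deg, kappa = 1)
  during immobility, flat accommodation with an inverse length-frequency
  coupling (longer bursts have shorter, constant ISIs), same suppression.

Every generated session carries its ground truth (per-spike labels, intended
burst ISIs, true phase series, state schedule, light-responsiveness flags) so
downstream tests are parameter-recovery tests, not smoke tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import (
    DEFAULT_LFP_RATE,
    DEFAULT_VIDEO_RATE,
    LFPSignal,
    LightProtocol,
    PositionTrack,
    Session,
    SpikeTrain,
    StimSite,
)
from .place_fields import ARENA_CM, TRACK_DIAMETER_CM

MAX_BURST_ISI_MS = 15.0


@dataclass
class CellParams:
    burst_event_rate: float          # Hz, burst occurrences
    single_rate: float               # Hz, single spikes
    phase_mu_run: float              # deg, preferred burst phase while running
    phase_kappa_run: float
    phase_mu_immobile: float
    phase_kappa_immobile: float
    burst_length_support: tuple[int, ...] = (2, 3, 4, 5, 6, 7)
    burst_length_ratio: float = 0.55  # geometric decay of the length pmf
    isi_start_ms: float = 6.0
    isi_slope_ms: float = 1.5         # ms per interval (accommodation)
    inverse_length_frequency_coupling: bool = False
    inverse_coupling_step_ms: float = 0.35  # ISI shortening per extra spike
    isi_jitter_ms: float = 0.5
    post_burst_suppression_ms: float = 55.0
    field_sigma_cm: float = 6.0
    field_gain: float = 8.0           # peak/baseline ratio of the place field
    refractory_ms: float = 2.0

    def validate(self) -> None:
        n_max = max(self.burst_length_support)
        if self.inverse_length_frequency_coupling:
            worst = self.isi_start_ms
        else:
            worst = self.isi_start_ms + self.isi_slope_ms * (n_max - 2)
        if worst + self.isi_jitter_ms > MAX_BURST_ISI_MS:
            raise ValueError(
                "ISI parameters can exceed the 15 ms burst criterion: "
                f"max intended ISI {worst + self.isi_jitter_ms:.2f} ms"
            )
        if self.isi_start_ms <= 0 or self.isi_start_ms > MAX_BURST_ISI_MS:
            raise ValueError("isi_start must lie in (0, 15] ms")
        for r in (self.burst_event_rate, self.single_rate):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if min(self.phase_kappa_run, self.phase_kappa_immobile) < 0:
            raise ValueError("kappa must be non-negative")


CONTROL_CELL = CellParams(
    burst_event_rate=0.23,
    single_rate=0.80,
    phase_mu_run=344.0,
    phase_kappa_run=1.0,
    phase_mu_immobile=344.0,
    phase_kappa_immobile=1.0,
)

MUTANT_CELL = CellParams(
    burst_event_rate=0.24,
    single_rate=0.49,
    phase_mu_run=315.0,
    phase_kappa_run=0.0,
    phase_mu_immobile=315.0,
    phase_kappa_immobile=1.0,
    burst_length_ratio=0.70,
    isi_start_ms=7.2,
    isi_slope_ms=0.0,
    inverse_length_frequency_coupling=True,
)

PRESETS = {"control": CONTROL_CELL, "mutant": MUTANT_CELL}


@dataclass
class SynthConfig:
    duration: float = 600.0
    seed: int = 0
    enclosure: str = "arena"          # "arena" | "track"
    theta_frequency: float = 7.0
    lfp_rate: float = DEFAULT_LFP_RATE
    video_rate: float = DEFAULT_VIDEO_RATE
    n_cells: int = 50
    preset: str = "control"
    cell: CellParams | None = None
    run_block_s: float = 40.0
    immobility_block_s: float = 20.0
    theta_amplitude: float = 1000.0   # int16-scale units
    noise_amplitude: float = 150.0
    freq_jitter_hz: float = 0.3       # SD of the slow theta-frequency wander
    run_speed_cm_s: float = 12.0

    def cell_params(self) -> CellParams:
        if self.cell is not None:
            return self.cell
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        return PRESETS[self.preset]


@dataclass
class GroundTruth:
    cell_params: CellParams
    spike_labels: np.ndarray          # per spike: -1 single, else burst index
    burst_onsets: np.ndarray
    burst_lengths: np.ndarray
    intended_isis_ms: list[np.ndarray]
    state_intervals: dict[str, np.ndarray] = field(default_factory=dict)
    true_phase: "TruePhase | None" = None
    responsive: bool = False


@dataclass
class TruePhase:
    """Ground-truth oscillator phase, degrees with trough = 0."""

    t: np.ndarray
    phase_deg: np.ndarray

    def at(self, times: np.ndarray) -> np.ndarray:
        # phase is stored unwrapped-free; interpolate on the complex circle
        times = np.asarray(times, dtype=float)
        rad = np.radians(self.phase_deg)
        c = np.interp(times, self.t, np.cos(rad))
        s = np.interp(times, self.t, np.sin(rad))
        return np.degrees(np.arctan2(s, c)) % 360.0


def state_schedule(config: SynthConfig) -> dict[str, np.ndarray]:
    """Alternating run / immobility blocks covering the session."""
    run, imm = [], []
    t = 0.0
    while t < config.duration:
        r_end = min(t + config.run_block_s, config.duration)
        if r_end > t:
            run.append([t, r_end])
        i_end = min(r_end + config.immobility_block_s, config.duration)
        if i_end > r_end:
            imm.append([r_end, i_end])
        t = i_end
        if config.run_block_s + config.immobility_block_s <= 0:
            break
    return {
        "run": np.asarray(run).reshape(-1, 2),
        "immobility": np.asarray(imm).reshape(-1, 2),
    }


def _in_intervals(t: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    mask = np.zeros(t.shape, dtype=bool)
    for start, end in intervals:
        mask |= (t >= start) & (t < end)
    return mask


def simulate_trajectory(config: SynthConfig, rng: np.random.Generator) -> PositionTrack:
    """Arena: Ornstein-Uhlenbeck velocity with reflecting walls.  Track:
    unidirectional motion with pauses.  Immobility blocks keep speed below
    2 cm/s; run blocks above 3 cm/s."""
    schedule = state_schedule(config)
    dt = 1.0 / config.video_rate
    t = np.arange(0.0, config.duration, dt)
    running = _in_intervals(t, schedule["run"])

    if config.enclosure == "arena":
        w, h = ARENA_CM
        x = np.empty(t.size)
        y = np.empty(t.size)
        x[0], y[0] = w / 2.0, h / 2.0
        # OU velocity: relaxation ~1 s, stationary speed ~ run_speed
        tau = 1.0
        sigma = config.run_speed_cm_s
        vx = vy = 0.0
        for i in range(1, t.size):
            if running[i]:
                vx += (-vx / tau) * dt + sigma * np.sqrt(2.0 * dt / tau) * rng.standard_normal()
                vy += (-vy / tau) * dt + sigma * np.sqrt(2.0 * dt / tau) * rng.standard_normal()
                speed = np.hypot(vx, vy)
                if speed < 3.5:  # keep run blocks above the 3 cm/s criterion
                    scale = 3.5 / max(speed, 1e-9)
                    vx *= scale
                    vy *= scale
            else:
                vx = vy = 0.0
            nx, ny_ = x[i - 1] + vx * dt, y[i - 1] + vy * dt
            if nx < 0 or nx > w:
                vx = -vx
                nx = np.clip(nx, 0, w)
            if ny_ < 0 or ny_ > h:
                vy = -vy
                ny_ = np.clip(ny_, 0, h)
            x[i], y[i] = nx, ny_
        return PositionTrack(t=t, x=x, y=y)

    # circular track: angle advances at run speed during run blocks
    radius = TRACK_DIAMETER_CM / 2.0
    omega = config.run_speed_cm_s / radius  # rad/s tangential
    dtheta = np.where(running, omega * dt, 0.0)
    theta = np.cumsum(dtheta)
    cx = cy = radius
    return PositionTrack(t=t, x=cx + radius * np.cos(theta), y=cy + radius * np.sin(theta))


def simulate_lfp(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[LFPSignal, TruePhase]:
    """Theta sinusoid with slow frequency wander plus 1/f background.

    The oscillator runs through both run and (alert) immobility blocks; the
    signal is -A cos(phase) so the ground-truth phase follows the trough = 0
    convention.  Returns the LFP and the true phase series.
    """
    n = int(round(config.duration * config.lfp_rate))
    t = np.arange(n) / config.lfp_rate
    # slow frequency wander: smoothed white noise, SD freq_jitter_hz
    slow = rng.standard_normal(n)
    n_smooth = int(config.lfp_rate)  # 1 s smoothing
    kernel = np.ones(n_smooth) / n_smooth
    slow = np.convolve(slow, kernel, mode="same")
    sd = slow.std()
    freq = config.theta_frequency + (config.freq_jitter_hz / sd if sd > 0 else 0.0) * slow
    phase_rad = 2.0 * np.pi * np.cumsum(freq) / config.lfp_rate
    theta_wave = -config.theta_amplitude * np.cos(phase_rad)

    # 1/f background via spectral shaping
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / config.lfp_rate)
    with np.errstate(divide="ignore"):
        shaping = np.where(freqs > 0, 1.0 / np.sqrt(freqs), 0.0)
    pink = np.fft.irfft(spec * shaping, n=n)
    pink *= config.noise_amplitude / max(pink.std(), 1e-12)

    samples = theta_wave + pink
    phase_deg = np.degrees(phase_rad) % 360.0
    return LFPSignal(samples=samples, rate=config.lfp_rate), TruePhase(t=t, phase_deg=phase_deg)


def _place_field_gain(
    track: PositionTrack, center: tuple[float, float], sigma: float, gain: float
) -> np.ndarray:
    d2 = (track.x - center[0]) ** 2 + (track.y - center[1]) ** 2
    g = 1.0 + (gain - 1.0) * np.exp(-d2 / (2.0 * sigma**2))
    return g / g.mean()  # normalise so the trajectory-average gain is 1


def _intended_isi_sum_ms(params: CellParams, support: np.ndarray) -> np.ndarray:
    """Sum of intended ISIs (ms) for a burst of each length in ``support``."""
    sums = []
    for n in support:
        k = np.arange(n - 1)
        if params.inverse_length_frequency_coupling:
            isis = np.full(n - 1, params.isi_start_ms
                           - params.inverse_coupling_step_ms * (n - 2))
        else:
            isis = params.isi_start_ms + params.isi_slope_ms * k
        sums.append(isis.sum())
    return np.asarray(sums)


def expected_mean_isi_ms(params: CellParams) -> float:
    """Pooled mean intra-burst ISI implied by the length pmf and ISI rule
    (the generator's own closure target)."""
    support = np.asarray(params.burst_length_support)
    pmf = params.burst_length_ratio ** (support - support[0])
    pmf = pmf / pmf.sum()
    isi_sums = _intended_isi_sum_ms(params, support)
    n_intervals = support - 1
    return float(np.sum(pmf * isi_sums) / np.sum(pmf * n_intervals))


def _thinned_poisson(
    rng: np.random.Generator, duration: float, rate_at: callable, rate_max: float
) -> np.ndarray:
    """Exact inhomogeneous-Poisson sampling by thinning."""
    n_cand = rng.poisson(rate_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
    if cand.size == 0:
        return cand
    accept = rng.uniform(0.0, rate_max, size=cand.size) < rate_at(cand)
    return cand[accept]


def simulate_cell(
    config: SynthConfig,
    trajectory: PositionTrack,
    true_phase: TruePhase,
    rng: np.random.Generator,
    field_center: tuple[float, float] | None = None,
    unit_id: str = "cell",
) -> tuple[SpikeTrain, GroundTruth]:
    """One bursty theta-modulated place cell.

    Burst events follow a thinned inhomogeneous Poisson process with rate
    burst_event_rate x place gain x von Mises phase gain (state-dependent mu
    and kappa); each event draws a length from the geometric pmf and emits
    spikes with accommodating (control) or length-coupled constant (mutant)
    ISIs, jittered +/- 0.5 ms.  Single spikes are an independent place-
    modulated Poisson process silenced for the post-burst suppression window
    after each burst.  The merged train enforces a 2 ms refractory period by
    deletion; ground truth records the intended structure.
    """
    params = config.cell_params()
    params.validate()
    schedule = state_schedule(config)

    if field_center is None:
        if config.enclosure == "arena":
            field_center = (
                rng.uniform(0.15, 0.85) * ARENA_CM[0],
                rng.uniform(0.15, 0.85) * ARENA_CM[1],
            )
        else:
            radius = TRACK_DIAMETER_CM / 2.0
            ang = rng.uniform(0.0, 2.0 * np.pi)
            field_center = (radius + radius * np.cos(ang), radius + radius * np.sin(ang))

    place_gain_frames = _place_field_gain(
        trajectory, field_center, params.field_sigma_cm, params.field_gain
    )

    def place_gain(times: np.ndarray) -> np.ndarray:
        return np.interp(times, trajectory.t, place_gain_frames)

    run_iv = schedule["run"]

    def phase_gain(times: np.ndarray) -> np.ndarray:
        phases = np.radians(true_phase.at(times))
        running = _in_intervals(times, run_iv)
        mu = np.where(running, np.radians(params.phase_mu_run),
                      np.radians(params.phase_mu_immobile))
        kappa = np.where(running, params.phase_kappa_run, params.phase_kappa_immobile)
        from scipy.special import i0
        return np.exp(kappa * np.cos(phases - mu)) / i0(kappa)

    kmax = max(params.phase_kappa_run, params.phase_kappa_immobile)
    from scipy.special import i0 as _i0
    phase_gain_max = float(np.exp(kmax) / _i0(kmax))
    place_gain_max = float(place_gain_frames.max())

    # --- burst events ---
    # Two bursts separated by <= 15 ms would, by definition, be one burst;
    # the generator therefore enforces a dead time of (span + 15.5 ms)
    # between successive bursts and compensates the event rate for the lost
    # time, weighted by E[gain^2] since events cluster where the rate is high.
    gap_s = (MAX_BURST_ISI_MS + 0.5) / 1000.0
    support = np.asarray(params.burst_length_support)
    pmf = params.burst_length_ratio ** (support - support[0])
    pmf = pmf / pmf.sum()
    mean_span_s = float(np.sum(pmf * _intended_isi_sum_ms(params, support))) / 1000.0

    probe_t = np.linspace(0.0, config.duration, 4096, endpoint=False)
    g_joint = place_gain(probe_t) * phase_gain(probe_t)
    e_joint2 = float(np.mean(g_joint**2) / np.mean(g_joint) ** 2)
    dead_loss = params.burst_event_rate * (mean_span_s + gap_s) * e_joint2
    effective_burst_rate = params.burst_event_rate / max(1.0 - dead_loss, 1e-6)

    burst_rate_max = effective_burst_rate * place_gain_max * phase_gain_max

    def burst_rate_at(times: np.ndarray) -> np.ndarray:
        return effective_burst_rate * place_gain(times) * phase_gain(times)

    candidates = _thinned_poisson(rng, config.duration, burst_rate_at, burst_rate_max)
    cand_lengths = rng.choice(support, size=candidates.size, p=pmf)

    onset_list: list[float] = []
    length_list: list[int] = []
    burst_spikes: list[np.ndarray] = []
    intended_isis: list[np.ndarray] = []
    last_end = -np.inf
    for onset, n_sp in zip(candidates, cand_lengths):
        if onset <= last_end + gap_s:
            continue
        k = np.arange(n_sp - 1)
        if params.inverse_length_frequency_coupling:
            base = params.isi_start_ms - params.inverse_coupling_step_ms * (n_sp - 2)
            isis = np.full(n_sp - 1, base)
        else:
            isis = params.isi_start_ms + params.isi_slope_ms * k
        isis = isis + rng.uniform(-params.isi_jitter_ms, params.isi_jitter_ms,
                                  size=n_sp - 1)
        spikes = onset + np.concatenate(([0.0], np.cumsum(isis) / 1000.0))
        onset_list.append(onset)
        length_list.append(int(n_sp))
        intended_isis.append(isis)
        burst_spikes.append(spikes)
        last_end = spikes[-1]
    onsets = np.asarray(onset_list)
    lengths = np.asarray(length_list, dtype=int)

    # --- single spikes: place-modulated Poisson with exclusion zones ---
    # A single spike by definition has all neighbouring ISIs > 15 ms, so the
    # generator blocks, around every burst, the interval from 15.5 ms before
    # its onset to max(suppression, 15.5 ms) after its last spike, and
    # enforces a 15.5 ms dead time between successive singles.  The rate is
    # compensated for the blocked time and the dead time so the *realised*
    # single-spike rate matches params.single_rate (the preset targets are
    # measured rates, not conditional intensities).
    gap_s = (MAX_BURST_ISI_MS + 0.5) / 1000.0
    burst_ends = np.array(
        [sp[-1] for sp in burst_spikes]) if burst_spikes else np.empty(0)
    post_block = max(params.post_burst_suppression_ms / 1000.0, gap_s)
    if burst_spikes:
        blocked = np.column_stack([onsets - gap_s, burst_ends + post_block])
        lengths_s = (np.minimum(blocked[:, 1], config.duration)
                     - np.maximum(blocked[:, 0], 0.0))
        # singles share the burst place field, so weight the blocked time by
        # the local place gain (losses concentrate where the rate is high)
        mid_gain = place_gain((blocked[:, 0] + blocked[:, 1]) / 2.0)
        blocked_time = float(np.sum(lengths_s * mid_gain))
    else:
        blocked = np.empty((0, 2))
        blocked_time = 0.0
    free_frac = max(1.0 - blocked_time / config.duration, 1e-6)
    # dead-time loss is second-order in the local rate: weight by E[g^2]
    e_g2 = float(np.mean(place_gain_frames**2))
    effective = params.single_rate
    for _ in range(3):  # fixed point for the self-referential loss terms
        dead_frac = 1.0 - np.exp(-effective * e_g2 * gap_s)
        effective = params.single_rate / (free_frac * (1.0 - dead_frac))
    effective_single_rate = effective

    def single_rate_at(times: np.ndarray) -> np.ndarray:
        r = effective_single_rate * place_gain(times)
        if blocked.size:
            idx = np.searchsorted(blocked[:, 0], times) - 1
            in_block = (idx >= 0) & (times < blocked[np.clip(idx, 0, None), 1])
            r = np.where(in_block, 0.0, r)
        return r

    single_rate_max = effective_single_rate * place_gain_max
    if params.single_rate > 0:
        singles = _thinned_poisson(
            rng, config.duration, single_rate_at, single_rate_max
        )
        # sequential dead time: drop any single within gap of the last kept
        if singles.size:
            kept = [singles[0]]
            for s in singles[1:]:
                if s - kept[-1] > gap_s:
                    kept.append(s)
            singles = np.asarray(kept)
    else:
        singles = np.empty(0)

    # --- merge, label, enforce refractory by deletion ---
    all_times = np.concatenate([np.concatenate(burst_spikes), singles]) if burst_spikes else singles
    labels = np.concatenate(
        [
            np.concatenate(
                [np.full(sp.size, i) for i, sp in enumerate(burst_spikes)]
            ) if burst_spikes else np.empty(0, dtype=int),
            np.full(singles.size, -1, dtype=int),
        ]
    ).astype(int)
    order = np.argsort(all_times, kind="stable")
    all_times, labels = all_times[order], labels[order]

    keep = np.ones(all_times.size, dtype=bool)
    last_t = -np.inf
    for i, ti in enumerate(all_times):
        if (ti - last_t) * 1000.0 < params.refractory_ms:
            keep[i] = False
        else:
            last_t = ti
    all_times, labels = all_times[keep], labels[keep]

    train = SpikeTrain(unit_id=unit_id, times=all_times)
    truth = GroundTruth(
        cell_params=params,
        spike_labels=labels,
        burst_onsets=onsets,
        burst_lengths=lengths.astype(int),
        intended_isis_ms=intended_isis,
        state_intervals=schedule,
        true_phase=true_phase,
    )
    return train, truth


def simulate_session(config: SynthConfig) -> tuple[Session, list[GroundTruth]]:
    """Full session: trajectory, LFP and ``n_cells`` place cells.

    Deterministic: the same (config, seed) always yields bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    trajectory = simulate_trajectory(config, rng)
    lfp, true_phase = simulate_lfp(config, rng)
    units, truths = [], []
    for i in range(config.n_cells):
        train, truth = simulate_cell(
            config, trajectory, true_phase, rng, unit_id=f"u{i}"
        )
        units.append(train)
        truths.append(truth)
    session = Session(
        id=f"synth-{config.preset}-{config.seed}",
        units=units,
        lfp=lfp,
        position=trajectory,
        light=None,
        genotype_label=config.preset,
        duration=config.duration,
    )
    return session, truths


# ---------------------------------------------------------------------------
# Light-stimulation sessions
# ---------------------------------------------------------------------------

@dataclass
class LightConfig:
    baseline_s: float = 300.0
    epoch_s: float = 240.0            # 4 min per stimulation epoch
    frequencies_hz: tuple[float, ...] = (2.0, 5.0)
    pulse_duration_s: float = 0.005
    latency_ms: float = 3.0
    latency_jitter_ms: float = 1.0
    p_respond: float = 0.8
    background_rate_hz: float = 2.0


def make_pulse_protocol(
    start: float, frequency_hz: float, epoch_s: float, pulse_duration_s: float
) -> LightProtocol:
    n = int(round(epoch_s * frequency_hz))
    onsets = start + np.arange(n) / frequency_hz
    return LightProtocol(
        pulse_onsets=onsets,
        pulse_duration=pulse_duration_s,
        frequency_hz=frequency_hz,
        site=StimSite.MS,
    )


def simulate_light_cell(
    lc: LightConfig,
    protocols: list[LightProtocol],
    duration: float,
    responsive: bool,
    rng: np.random.Generator,
    unit_id: str = "cell",
) -> tuple[SpikeTrain, GroundTruth]:
    """Background Poisson firing plus, for responsive cells, one spike per
    pulse at latency +/- jitter with probability p_respond."""
    n_bg = rng.poisson(lc.background_rate_hz * duration)
    times = rng.uniform(0.0, duration, size=n_bg)
    if responsive:
        for prot in protocols:
            respond = rng.uniform(size=prot.n_pulses) < lc.p_respond
            lat = (
                lc.latency_ms
                + rng.uniform(-lc.latency_jitter_ms, lc.latency_jitter_ms,
                              size=prot.n_pulses)
            ) / 1000.0
            times = np.concatenate([times, prot.pulse_onsets[respond] + lat[respond]])
    times = np.unique(times)
    train = SpikeTrain(unit_id=unit_id, times=times)
    truth = GroundTruth(
        cell_params=CONTROL_CELL,
        spike_labels=np.full(times.size, -1),
        burst_onsets=np.empty(0),
        burst_lengths=np.empty(0, dtype=int),
        intended_isis_ms=[],
        responsive=responsive,
    )
    return train, truth


def simulate_light_session(
    lc: LightConfig | None = None,
    n_cells: int = 10,
    responsive_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[Session, list[LightProtocol], tuple[float, float], list[bool]]:
    """Baseline period followed by one 4-min epoch per stimulation frequency
    (2 and 5 Hz, 5 ms pulses).  Returns the session, the per-epoch
    protocols, the baseline interval and the responsiveness flags."""
    lc = lc or LightConfig()
    rng = np.random.default_rng(seed)
    protocols = []
    t = lc.baseline_s
    for f in lc.frequencies_hz:
        protocols.append(make_pulse_protocol(t, f, lc.epoch_s, lc.pulse_duration_s))
        t += lc.epoch_s
    duration = t
    baseline = (0.0, lc.baseline_s)

    flags = [i < round(n_cells * responsive_fraction) for i in range(n_cells)]
    units = []
    for i, resp in enumerate(flags):
        train, _ = simulate_light_cell(
            lc, protocols, duration, resp, rng, unit_id=f"u{i}"
        )
        units.append(train)

    # combined protocol for session bookkeeping
    all_onsets = np.sort(np.concatenate([p.pulse_onsets for p in protocols]))
    session = Session(
        id=f"synth-light-{seed}",
        units=units,
        light=LightProtocol(
            pulse_onsets=all_onsets,
            pulse_duration=lc.pulse_duration_s,
            frequency_hz=0.0,
            site=StimSite.MS,
        ),
        duration=duration,
    )
    return session, protocols, baseline, flags
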