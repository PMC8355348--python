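"""Session data model and readers/writers for the recording file formats.

A recording *session* bundles everything one analysis run needs: the sorted
unit spike trains, the down-sampled local field potential (LFP), the animal's
tracked position, and (for optogenetic sessions) the light-pulse protocol.
All time series share one origin (t = 0 at session start) and all internal
times are seconds in double precision; phases elsewhere in the package are
degrees.

Supported on-disk dialects:

* ``.res`` / ``.clu`` — Neurosuite spike-sorting output: the ``.res`` file is
  one integer sample index per line (wide-band clock, typically 32 kHz); the
  ``.clu`` file starts with the number of clusters and then carries one
  integer label per spike.  Clusters 0 and 1 hold artifacts and unsorted
  noise by convention and are dropped.
* plain-text spike times — one float (seconds) per line, auto-detected.
* ``.eeg`` — flat little-endian int16, single- or multi-channel interleaved,
  nominally 1250 samples/s.
* position CSV with a ``t,x,y`` header at a nominal 25 frames/s.
* light CSV with an ``onset,duration`` header.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("thetaburst")

# Acquisition defaults (config-exposed through function arguments).
DEFAULT_WIDEBAND_RATE = 32000.0  # Hz, wide-band acquisition clock
DEFAULT_LFP_RATE = 1250.0        # Hz, down-sampled field potential
DEFAULT_VIDEO_RATE = 25.0        # frames/s position tracking
NOISE_CLUSTERS = (0, 1)          # Neurosuite artifact/noise labels


class FormatError(ValueError):
    """Raised when an on-disk file violates its dialect."""


class CellClass(str, Enum):
    PYRAMIDAL = "pyramidal"
    INTERNEURON = "interneuron"
    UNCLASSIFIED = "unclassified"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SpikeTrain:
    """Sorted spike times (s) of one unit.

    ``times`` must be strictly increasing; duplicate timestamps are rejected
    because downstream interval logic assumes a proper point process.
    """

    unit_id: str
    times: np.ndarray
    cell_class: CellClass = CellClass.UNCLASSIFIED

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be a 1-D sequence")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError(
                f"unit {self.unit_id}: spike times must be strictly increasing"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def isis_ms(self) -> np.ndarray:
        """Inter-spike intervals in milliseconds."""
        return np.diff(self.times) * 1000.0

    def shifted(self, dt: float) -> "SpikeTrain":
        return replace(self, times=self.times + dt)


@dataclass
class LFPSignal:
    """Continuous field potential, arbitrary units (int16 on disk)."""

    samples: np.ndarray
    rate: float = DEFAULT_LFP_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("LFP rate must be positive")
        if self.samples.size < 1:
            raise ValueError("LFP must contain at least one sample")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate


@dataclass
class PositionTrack:
    """Tracked head position (cm) at the video frame rate, with derived speed."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    speed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.size == self.x.size == self.y.size):
            raise ValueError("t, x, y must have equal length")
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("position timestamps must be strictly increasing")
        if self.speed is not None:
            self.speed = np.asarray(self.speed, dtype=float)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0


class StimSite(str, Enum):
    HIPPOCAMPUS = "hippocampus"
    MS = "MS"


@dataclass
class LightProtocol:
    """Optogenetic pulse train: onsets (s), fixed pulse duration, frequency."""

    pulse_onsets: np.ndarray
    pulse_duration: float
    frequency_hz: float
    site: StimSite = StimSite.MS

    def __post_init__(self) -> None:
        self.pulse_onsets = np.asarray(self.pulse_onsets, dtype=float)
        if self.pulse_duration <= 0:
            raise ValueError("pulse duration must be positive")
        gaps = np.diff(self.pulse_onsets)
        if gaps.size and np.any(gaps <= 0):
            raise ValueError("pulse onsets must be strictly increasing")
        if gaps.size and np.any(gaps < self.pulse_duration):
            raise ValueError("pulses overlap: onset gap shorter than duration")

    @property
    def n_pulses(self) -> int:
        return int(self.pulse_onsets.size)

    @property
    def span(self) -> float:
        """Time from first onset to end of last pulse."""
        if self.n_pulses == 0:
            return 0.0
        return float(self.pulse_onsets[-1] + self.pulse_duration - self.pulse_onsets[0])


@dataclass
class Session:
    """One recording session; the unit all pipelines operate on."""

    id: str
    units: list[SpikeTrain] = field(default_factory=list)
    lfp: LFPSignal | None = None
    position: PositionTrack | None = None
    light: LightProtocol | None = None
    genotype_label: str = ""
    duration: float | None = None

    def get_duration(self) -> float:
        if self.duration is not None:
            return self.duration
        candidates = [u.times[-1] for u in self.units if u.n_spikes]
        if self.lfp is not None:
            candidates.append(self.lfp.duration)
        if self.position is not None and self.position.t.size:
            candidates.append(self.position.t[-1])
        if not candidates:
            raise ValueError("session duration unknown and not derivable")
        return float(max(candidates))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_int_lines(path: Path | str) -> np.ndarray:
    try:
        values = np.loadtxt(path, dtype=np.int64, ndmin=1)
    except ValueError as exc:
        raise FormatError(f"{path}: expected one integer per line") from exc
    return values


def read_spike_trains(
    res_path: Path | str,
    clu_path: Path | str,
    wideband_rate: float = DEFAULT_WIDEBAND_RATE,
    noise_clusters: tuple[int, ...] = NOISE_CLUSTERS,
) -> list[SpikeTrain]:
    """Read Neurosuite .res/.clu pairs into one SpikeTrain per cluster.

    Sample indices are converted to seconds with ``wideband_rate``; clusters
    listed in ``noise_clusters`` (artifact/noise by convention) are dropped.
    """
    indices = _read_int_lines(res_path)
    clu = _read_int_lines(clu_path)
    if clu.size < 1:
        raise FormatError(f"{clu_path}: missing cluster-count header")
    labels = clu[1:]
    if labels.size != indices.size:
        raise FormatError(
            f"res/clu length mismatch: {indices.size} spikes vs {labels.size} labels"
        )
    if indices.size and np.any(np.diff(indices) < 0):
        raise FormatError(f"{res_path}: sample indices must be non-decreasing")

    trains: list[SpikeTrain] = []
    for label in np.unique(labels):
        if int(label) in noise_clusters:
            continue
        times = indices[labels == label] / float(wideband_rate)
        # Guard against duplicate indices within one cluster (ties at the
        # wide-band clock resolution are physically impossible spikes).
        times = np.unique(times)
        trains.append(SpikeTrain(unit_id=str(int(label)), times=times))
    return trains


def write_spike_trains(
    trains: list[SpikeTrain],
    res_path: Path | str,
    clu_path: Path | str,
    wideband_rate: float = DEFAULT_WIDEBAND_RATE,
) -> None:
    """Write trains back to the .res/.clu dialect (lossless round trip at the
    wide-band clock resolution)."""
    events: list[tuple[int, int]] = []
    label_of = {}
    for i, train in enumerate(trains):
        label = int(train.unit_id) if train.unit_id.isdigit() else i + 2
        label_of[train.unit_id] = label
        for t in train.times:
            events.append((int(round(t * wideband_rate)), label))
    events.sort()
    n_clusters = len({lab for _, lab in events}) if events else 0
    with open(res_path, "w") as fh:
        fh.writelines(f"{idx}\n" for idx, _ in events)
    with open(clu_path, "w") as fh:
        fh.write(f"{n_clusters}\n")
        fh.writelines(f"{lab}\n" for _, lab in events)


def read_spike_times_text(path: Path | str, unit_id: str = "0") -> SpikeTrain:
    """Read one plain-text spike train (one float of seconds per line)."""
    times = np.loadtxt(path, dtype=float, ndmin=1)
    return SpikeTrain(unit_id=unit_id, times=np.sort(times))


def detect_spike_dialect(path: Path | str) -> str:
    """Auto-detect 'res' (integer sample indices) vs 'seconds' (floats).

    The deposited-data layouts vary; a file whose first non-empty lines all
    parse as integers is treated as sample indices, anything else as seconds.
    """
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            try:
                int(line)
            except ValueError:
                return "seconds"
            return "res"
    return "seconds"


def read_lfp(
    path: Path | str,
    rate: float = DEFAULT_LFP_RATE,
    n_channels: int = 1,
    channel: int = 0,
) -> LFPSignal:
    """Read a flat little-endian int16 .eeg file (interleaved channels)."""
    raw = np.fromfile(path, dtype="<i2")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if raw.size % n_channels:
        raise FormatError(
            f"{path}: {raw.size} samples not divisible by {n_channels} channels"
        )
    data = raw.reshape(-1, n_channels)[:, channel]
    return LFPSignal(samples=data.astype(float), rate=rate)


def write_lfp(lfp: LFPSignal, path: Path | str) -> None:
    clipped = np.clip(np.round(lfp.samples), -32768, 32767).astype("<i2")
    clipped.tofile(path)


def read_position(path: Path | str) -> PositionTrack:
    df = pd.read_csv(path)
    missing = {"t", "x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: position CSV missing columns {sorted(missing)}")
    return PositionTrack(t=df["t"].to_numpy(), x=df["x"].to_numpy(), y=df["y"].to_numpy())


def write_position(track: PositionTrack, path: Path | str) -> None:
    pd.DataFrame({"t": track.t, "x": track.x, "y": track.y}).to_csv(path, index=False)


def read_light(path: Path | str, frequency_hz: float | None = None,
               site: StimSite = StimSite.MS) -> LightProtocol:
    df = pd.read_csv(path)
    missing = {"onset", "duration"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: light CSV missing columns {sorted(missing)}")
    onsets = df["onset"].to_numpy(dtype=float)
    durations = df["duration"].to_numpy(dtype=float)
    if durations.size and not np.allclose(durations, durations[0]):
        raise FormatError(f"{path}: mixed pulse durations in one protocol")
    if frequency_hz is None:
        gaps = np.diff(onsets)
        frequency_hz = 1.0 / float(np.median(gaps)) if gaps.size else 0.0
    return LightProtocol(
        pulse_onsets=onsets,
        pulse_duration=float(durations[0]) if durations.size else 0.005,
        frequency_hz=frequency_hz,
        site=site,
    )


def write_light(protocol: LightProtocol, path: Path | str) -> None:
    pd.DataFrame(
        {
            "onset": protocol.pulse_onsets,
            "duration": np.full(protocol.n_pulses, protocol.pulse_duration),
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Unit classification and speed
# ---------------------------------------------------------------------------

def classify_units(
    unit: SpikeTrain,
    duration: float,
    pyramidal_max_rate: float = 3.0,
    interneuron_min_rate: float = 7.0,
    refractory_ms: float = 3.0,
    refractory_ceiling: float = 0.01,
) -> CellClass:
    """Classify a unit by mean rate: < 3 Hz pyramidal, > 7 Hz interneuron.

    Putative pyramidal cells must additionally show a clear refractory
    period: the fraction of ISIs below ``refractory_ms`` must stay under
    ``refractory_ceiling`` (default 1%), otherwise the unit stays
    unclassified.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if unit.n_spikes == 0:
        warnings.warn(f"unit {unit.unit_id}: empty spike train, unclassified")
        return CellClass.UNCLASSIFIED
    rate = unit.n_spikes / duration
    if rate > interneuron_min_rate:
        return CellClass.INTERNEURON
    if rate < pyramidal_max_rate:
        isis = unit.isis_ms()
        if isis.size == 0:
            return CellClass.PYRAMIDAL
        if np.mean(isis < refractory_ms) <= refractory_ceiling:
            return CellClass.PYRAMIDAL
        return CellClass.UNCLASSIFIED
    return CellClass.UNCLASSIFIED


def compute_speed(track: PositionTrack, smoothing_window: float = 0.4) -> PositionTrack:
    """Attach speed (cm/s) = centred finite difference of boxcar-smoothed
    position; endpoints use one-sided differences."""
    if track.t.size < 2:
        raise ValueError("need at least two position samples")
    dt = np.median(np.diff(track.t))
    n_win = max(1, int(round(smoothing_window / dt)))
    kernel = np.ones(n_win) / n_win

    def smooth(v: np.ndarray) -> np.ndarray:
        if n_win <= 1:
            return v
        padded = np.pad(v, n_win, mode="edge")
        return np.convolve(padded, kernel, mode="same")[n_win:-n_win]

    xs, ys = smooth(track.x), smooth(track.y)
    vx = np.gradient(xs, track.t)
    vy = np.gradient(ys, track.t)
    speed = np.hypot(vx, vy)
    return PositionTrack(t=track.t, x=track.x, y=track.y, speed=speed)
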