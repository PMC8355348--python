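"""Complex-spike-burst segmentation and burst-structure statistics.

A complex spike burst is a maximal run of >= 2 spikes from one pyramidal cell
in which every inter-spike interval (ISI) is no more than 15 ms (inclusive
threshold).  All other spikes are *single spikes*.  The burst timestamp is
the time of its first spike.  On top of the segmentation this module computes
the population statistics used to characterise burst discharge: occurrence
rates per class, the distribution of burst lengths, spike-frequency
accommodation (ISI vs. its order within the burst), and the conditional
probability of the next event as a function of post-event silence (the
post-burst single-spike suppression curve).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import SpikeTrain

MAX_ISI_MS = 15.0  # inclusive burst ISI criterion


@dataclass
class Burst:
    spike_times: np.ndarray  # seconds, sorted
    onset: float             # first spike time
    n_spikes: int
    isis: np.ndarray         # ms, ordered within the burst

    @property
    def offset(self) -> float:
        """Time of the last spike in the burst."""
        return float(self.spike_times[-1])


@dataclass
class BurstSegmentation:
    """Partition of one spike train into bursts and single spikes."""

    unit_id: str
    bursts: list[Burst]
    single_spikes: np.ndarray  # seconds

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    @property
    def n_single(self) -> int:
        return int(self.single_spikes.size)

    @property
    def n_spikes_total(self) -> int:
        return self.n_single + sum(b.n_spikes for b in self.bursts)

    def burst_onsets(self) -> np.ndarray:
        return np.array([b.onset for b in self.bursts])

    def burst_spike_times(self) -> np.ndarray:
        """All spikes emitted within bursts, sorted."""
        if not self.bursts:
            return np.empty(0)
        return np.sort(np.concatenate([b.spike_times for b in self.bursts]))


@dataclass
class AccommodationProfile:
    """Mean ISI by order-in-burst and by burst length.

    ``mean_isi_by_order`` maps (burst_length n, isi order k in 1..n-1) to a
    (mean, sem, count) triple in ms; ``accommodation_rate`` is the
    least-squares slope of ISI vs. order over orders 1-2 of 3-spike bursts
    (ms per interval), positive when successive intervals lengthen.
    """

    mean_isi_by_order: dict[tuple[int, int], tuple[float, float, int]]
    mean_isi_by_length: dict[int, float]
    accommodation_rate: float
    overall_mean_isi: float
    per_cell_mean_isi: np.ndarray = field(default_factory=lambda: np.empty(0))


def segment_bursts(train: SpikeTrain, max_isi_ms: float = MAX_ISI_MS) -> BurstSegmentation:
    """Partition a spike train into bursts (runs of ISIs <= max_isi_ms, length
    >= 2) and single spikes.  Empty trains give an empty segmentation."""
    times = train.times
    if times.size == 0:
        return BurstSegmentation(train.unit_id, [], np.empty(0))
    if times.size == 1:
        return BurstSegmentation(train.unit_id, [], times.copy())

    in_run = np.diff(times) * 1000.0 <= max_isi_ms  # ISI i joins spikes i, i+1
    bursts: list[Burst] = []
    singles: list[float] = []
    i = 0
    n = times.size
    while i < n:
        j = i
        while j < n - 1 and in_run[j]:
            j += 1
        if j > i:  # run of j - i + 1 >= 2 spikes
            run = times[i : j + 1]
            bursts.append(
                Burst(
                    spike_times=run.copy(),
                    onset=float(run[0]),
                    n_spikes=run.size,
                    isis=np.diff(run) * 1000.0,
                )
            )
        else:
            singles.append(times[i])
        i = j + 1
    return BurstSegmentation(train.unit_id, bursts, np.asarray(singles))


def burst_rate_stats(seg: BurstSegmentation, duration: float) -> dict[str, float]:
    """Occurrence rates: bursts/s, single spikes/s, all spikes/s, and the
    fraction of spikes emitted within bursts."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_burst_spikes = sum(b.n_spikes for b in seg.bursts)
    n_total = seg.n_single + n_burst_spikes
    return {
        "burst_rate": seg.n_bursts / duration,
        "single_rate": seg.n_single / duration,
        "all_rate": n_total / duration,
        "burst_spike_fraction": n_burst_spikes / n_total if n_total else 0.0,
    }


LENGTH_BINS = (2, 3, 4, 5, 6)  # last bin is ">= 6"


def burst_length_histogram(
    segs: list[BurstSegmentation], bins: tuple[int, ...] = LENGTH_BINS
) -> dict[str, np.ndarray]:
    """Per-cell relative probability of burst lengths, summarised across cells.

    Each cell's burst-length distribution is normalised to sum 1 over the
    length bins (the last bin pools all longer bursts); cells without bursts
    are excluded with a warning.  Returns the per-cell matrix plus the
    across-cell median and quartiles per bin.
    """
    per_cell = []
    for seg in segs:
        if seg.n_bursts == 0:
            warnings.warn(f"unit {seg.unit_id}: no bursts, excluded from histogram")
            continue
        lengths = np.array([b.n_spikes for b in seg.bursts])
        counts = np.array(
            [
                np.sum(lengths == b) if b < bins[-1] else np.sum(lengths >= b)
                for b in bins
            ],
            dtype=float,
        )
        per_cell.append(counts / counts.sum())
    if not per_cell:
        raise ValueError("no bursts in any segmentation")
    mat = np.vstack(per_cell)
    return {
        "bins": np.asarray(bins),
        "per_cell": mat,
        "median": np.median(mat, axis=0),
        "q25": np.percentile(mat, 25, axis=0),
        "q75": np.percentile(mat, 75, axis=0),
        "mean": mat.mean(axis=0),
    }


def accommodation(segs: list[BurstSegmentation]) -> AccommodationProfile:
    """Spike-frequency accommodation: ISIs averaged by their order in bursts
    of each length, the mean ISI per burst length, and the accommodation
    slope (orders 1-2 of 3-spike bursts)."""
    by_order: dict[tuple[int, int], list[float]] = {}
    by_length: dict[int, list[float]] = {}
    all_isis: list[float] = []
    per_cell_means: list[float] = []
    triplet_pairs: list[np.ndarray] = []

    any_burst = False
    for seg in segs:
        cell_isis: list[float] = []
        for b in seg.bursts:
            any_burst = True
            n = b.n_spikes
            for k, isi in enumerate(b.isis, start=1):
                by_order.setdefault((n, k), []).append(isi)
            by_length.setdefault(n, []).extend(b.isis)
            cell_isis.extend(b.isis)
            if n == 3:
                triplet_pairs.append(b.isis)
        all_isis.extend(cell_isis)
        if cell_isis:
            per_cell_means.append(float(np.mean(cell_isis)))
    if not any_burst:
        raise ValueError("no bursts in any segmentation")

    order_stats = {
        key: (
            float(np.mean(v)),
            float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
            len(v),
        )
        for key, v in by_order.items()
    }
    length_means = {n: float(np.mean(v)) for n, v in by_length.items()}

    if triplet_pairs:
        pairs = np.vstack(triplet_pairs)  # columns: order 1, order 2
        # least-squares slope of ISI vs order over orders {1, 2} reduces to
        # the mean order-2 minus mean order-1 interval
        slope = float(pairs[:, 1].mean() - pairs[:, 0].mean())
    else:
        slope = float("nan")

    return AccommodationProfile(
        mean_isi_by_order=order_stats,
        mean_isi_by_length=length_means,
        accommodation_rate=slope,
        overall_mean_isi=float(np.mean(all_isis)),
        per_cell_mean_isi=np.asarray(per_cell_means),
    )


def _event_sequence(seg: BurstSegmentation) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merged event sequence: per event its onset, end (last spike) and class
    (0 = single, 1 = burst), time-sorted."""
    onsets = np.concatenate([seg.burst_onsets(), seg.single_spikes])
    ends = np.concatenate(
        [np.array([b.offset for b in seg.bursts]), seg.single_spikes]
    )
    kinds = np.concatenate(
        [np.ones(seg.n_bursts, dtype=int), np.zeros(seg.n_single, dtype=int)]
    )
    order = np.argsort(onsets)
    return onsets[order], ends[order], kinds[order]


def post_event_conditional(
    seg: BurstSegmentation,
    trigger: str = "burst",
    response: str = "single",
    window_ms: float = 300.0,
    bin_ms: float = 5.0,
    estimator: str = "hazard",
) -> dict[str, np.ndarray]:
    """Probability of the next event being of the response class as a function
    of silence duration after a trigger event.

    For each trigger event the elapsed time (from its last spike) to the next
    emitted event is recorded with that event's class.  The default hazard
    estimator returns, per bin, P(next event in this bin and of the response
    class | silence reached the bin); ``estimator='histogram'`` returns the
    plain normalised latency histogram of response-class next events.
    """
    if window_ms <= bin_ms:
        raise ValueError("window must exceed bin width")
    kind_code = {"single": 0, "burst": 1}
    trig_code, resp_code = kind_code[trigger], kind_code[response]

    onsets, ends, kinds = _event_sequence(seg)
    trig_idx = np.where(kinds == trig_code)[0]
    trig_idx = trig_idx[trig_idx < onsets.size - 1]
    if trig_idx.size < 10:
        raise ValueError("need at least 10 trigger events with a successor")

    latency_ms = (onsets[trig_idx + 1] - ends[trig_idx]) * 1000.0
    next_kind = kinds[trig_idx + 1]

    edges = np.arange(0.0, window_ms + bin_ms, bin_ms)
    centers = edges[:-1] + bin_ms / 2.0
    which_bin = np.digitize(latency_ms, edges) - 1
    in_window = (which_bin >= 0) & (which_bin < centers.size)

    resp_counts = np.bincount(
        which_bin[in_window & (next_kind == resp_code)], minlength=centers.size
    ).astype(float)

    if estimator == "hazard":
        any_counts = np.bincount(which_bin[in_window], minlength=centers.size).astype(float)
        # number of triggers whose silence reached each bin's start
        n_at_risk = trig_idx.size - np.concatenate(([0.0], np.cumsum(any_counts)[:-1]))
        # also censor latencies beyond the window: they stay at risk throughout
        with np.errstate(divide="ignore", invalid="ignore"):
            prob = np.where(n_at_risk > 0, resp_counts / n_at_risk, 0.0)
    elif estimator == "histogram":
        total = resp_counts.sum()
        prob = resp_counts / total if total else resp_counts
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    return {"bin_centers_ms": centers, "probability": prob, "n_triggers": trig_idx.size}
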