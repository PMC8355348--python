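"""Occupancy-normalised firing maps, place-field detection and field
statistics, computed separately for all spikes, burst spikes and single
spikes.

The arena (50 x 30 cm) is binned into 2 x 2 cm pixels on a 2-D grid; the
circular track (diameter 60 cm) is linearised onto a circularly wrapped 1-D
axis with 2 cm bins.  Periods of immobility (< 2 cm/s) are excluded from
both occupancy and spikes.  A place field is a spatially continuous region
(4-connected in 2-D, wrap-adjacent in 1-D) where the occupancy-normalised
rate exceeds 1 Hz.  Field compactness is summarised by Skaggs sparsity
(sum p_i l_i)^2 / sum p_i l_i^2 and spatial information
sum p_i (l_i / L) log2(l_i / L) in bits per spike, with p_i the occupancy
fraction, l_i the pixel rate and L the occupancy-weighted mean rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import PositionTrack
from .theta_phase import BehavioralState

PIXEL_CM = 2.0
FIELD_THRESHOLD_HZ = 1.0
ARENA_CM = (50.0, 30.0)
TRACK_DIAMETER_CM = 60.0


@dataclass
class Enclosure:
    kind: str                      # "arena" | "track"
    size_cm: tuple[float, float]   # arena (w, h); track (circumference, 0)
    center_cm: tuple[float, float] = (0.0, 0.0)

    @classmethod
    def arena(cls, width: float = ARENA_CM[0], height: float = ARENA_CM[1]) -> "Enclosure":
        return cls(kind="arena", size_cm=(width, height))

    @classmethod
    def track(cls, diameter: float = TRACK_DIAMETER_CM) -> "Enclosure":
        circumference = np.pi * diameter
        return cls(kind="track", size_cm=(circumference, 0.0),
                   center_cm=(diameter / 2.0, diameter / 2.0))


@dataclass
class OccupancyMap:
    occupancy: np.ndarray  # seconds per pixel; 2-D (arena) or 1-D (track)
    enclosure: Enclosure
    pixel_cm: float = PIXEL_CM

    @property
    def total_time(self) -> float:
        return float(self.occupancy.sum())


@dataclass
class RateMap:
    rates: np.ndarray       # Hz per pixel, NaN where occupancy = 0
    spike_class: str        # "all" | "burst" | "single"
    occupancy: OccupancyMap
    n_spikes: int

    @property
    def peak_rate(self) -> float:
        if np.all(np.isnan(self.rates)):
            return 0.0
        return float(np.nanmax(self.rates))


@dataclass
class PlaceField:
    pixel_index: np.ndarray  # flat indices into the map
    size_cm2: float
    peak_rate: float
    in_field_rate: float


def _positions_to_coords(
    track: PositionTrack, enclosure: Enclosure, pixel_cm: float
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Map positions to pixel indices; returns per-frame flat index and the
    grid shape.  Positions slightly outside the enclosure are clipped."""
    if enclosure.kind == "arena":
        nx = int(np.ceil(enclosure.size_cm[0] / pixel_cm))
        ny = int(np.ceil(enclosure.size_cm[1] / pixel_cm))
        ix = np.floor(track.x / pixel_cm).astype(int)
        iy = np.floor(track.y / pixel_cm).astype(int)
        out = (ix < -2) | (ix >= nx + 2) | (iy < -2) | (iy >= ny + 2)
        if out.any():
            warnings.warn(f"{out.sum()} frames outside the enclosure, clipped")
        ix = np.clip(ix, 0, nx - 1)
        iy = np.clip(iy, 0, ny - 1)
        return iy * nx + ix, (ny, nx)
    # circular track: linearise the angle to arclength, wrap into bins
    cx, cy = enclosure.center_cm
    theta = np.arctan2(track.y - cy, track.x - cx) % (2.0 * np.pi)
    circumference = enclosure.size_cm[0]
    n_bins = max(1, int(round(circumference / pixel_cm)))
    ib = np.floor(theta / (2.0 * np.pi) * n_bins).astype(int) % n_bins
    return ib, (n_bins,)


def _state_mask(track: PositionTrack, state: BehavioralState | None) -> np.ndarray:
    """Frames to include: everything except immobility (< 2 cm/s)."""
    if state is None:
        return np.ones(track.t.size, dtype=bool)
    mask = np.ones(track.t.size, dtype=bool)
    for start, end in state.immobility:
        mask &= ~((track.t >= start) & (track.t <= end))
    return mask


def occupancy_map(
    track: PositionTrack,
    state: BehavioralState | None = None,
    enclosure: Enclosure | None = None,
    pixel_cm: float = PIXEL_CM,
) -> OccupancyMap:
    """Accumulate frame durations per pixel, excluding immobility frames."""
    if enclosure is None:
        enclosure = Enclosure.arena()
    flat_idx, shape = _positions_to_coords(track, enclosure, pixel_cm)
    include = _state_mask(track, state)

    frame_dur = np.empty(track.t.size)
    if track.t.size > 1:
        dt = np.diff(track.t)
        frame_dur[:-1] = dt
        frame_dur[-1] = dt[-1]
    else:
        frame_dur[:] = 1.0 / 25.0

    occ = np.zeros(int(np.prod(shape)))
    np.add.at(occ, flat_idx[include], frame_dur[include])
    if occ.sum() < 30.0:
        warnings.warn("insufficient sampling: less than 30 s of included time")
    return OccupancyMap(occupancy=occ.reshape(shape), enclosure=enclosure,
                        pixel_cm=pixel_cm)


def rate_map(
    spikes: np.ndarray,
    occ: OccupancyMap,
    track: PositionTrack,
    spike_class: str = "all",
    state: BehavioralState | None = None,
) -> RateMap:
    """Spike count per pixel divided by the time spent there.

    Each spike is assigned to the pixel of the (nearest-frame) position at
    the spike time; spikes during excluded immobility are dropped, matching
    the occupancy exclusion.
    """
    spikes = np.asarray(spikes, dtype=float)
    flat_idx, shape = _positions_to_coords(track, occ.enclosure, occ.pixel_cm)
    include = _state_mask(track, state)

    frame_of = np.clip(np.searchsorted(track.t, spikes), 0, track.t.size - 1)
    left = np.clip(frame_of - 1, 0, track.t.size - 1)
    use_left = np.abs(track.t[left] - spikes) < np.abs(track.t[frame_of] - spikes)
    frame_of = np.where(use_left, left, frame_of)

    kept = include[frame_of]
    counts = np.zeros(int(np.prod(shape)))
    np.add.at(counts, flat_idx[frame_of[kept]], 1.0)
    counts = counts.reshape(shape)

    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(occ.occupancy > 0, counts / occ.occupancy, np.nan)
    return RateMap(rates=rates, spike_class=spike_class, occupancy=occ,
                   n_spikes=int(kept.sum()))


def detect_fields(
    rmap: RateMap,
    threshold_hz: float = FIELD_THRESHOLD_HZ,
    min_pixels: int = 2,
) -> list[PlaceField]:
    """Spatially continuous regions with rate > threshold (4-connected in
    2-D; wrap-adjacent on the 1-D track), at least ``min_pixels`` pixels,
    sorted largest first."""
    rates = rmap.rates
    above = np.nan_to_num(rates, nan=0.0) > threshold_hz
    if not above.any():
        return []

    if rates.ndim == 2:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        labels, n_comp = ndimage.label(above, structure=structure)
        labels = labels.ravel()
    else:
        labels, n_comp = ndimage.label(above)
        # merge components touching across the circular wrap point
        if n_comp > 1 and above[0] and above[-1]:
            labels[labels == labels[-1]] = labels[0]

    flat_rates = np.nan_to_num(rates, nan=0.0).ravel()
    occ = rmap.occupancy.occupancy.ravel()
    pixel_area = rmap.occupancy.pixel_cm**2 if rates.ndim == 2 else rmap.occupancy.pixel_cm

    fields = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        idx = np.flatnonzero(labels == lab)
        if idx.size < min_pixels:
            continue
        w = occ[idx]
        in_rate = float(np.average(flat_rates[idx], weights=w)) if w.sum() > 0 else float(
            flat_rates[idx].mean()
        )
        fields.append(
            PlaceField(
                pixel_index=idx,
                size_cm2=float(idx.size * pixel_area),
                peak_rate=float(flat_rates[idx].max()),
                in_field_rate=in_rate,
            )
        )
    fields.sort(key=lambda f: f.size_cm2, reverse=True)
    return fields


def field_statistics(
    rmap: RateMap, occ: OccupancyMap, field: PlaceField | None = None
) -> dict[str, float]:
    """Peak rate, in-field rate, Skaggs sparsity and spatial information
    (bits/spike) over the defined pixels of a rate map."""
    rates = rmap.rates.ravel()
    weights = occ.occupancy.ravel()
    defined = (~np.isnan(rates)) & (weights > 0)
    if rates.size != weights.size:
        raise ValueError("rate map and occupancy are not aligned")
    lam = rates[defined]
    p = weights[defined] / weights[defined].sum()
    mean_rate = float(np.sum(p * lam))
    if mean_rate == 0:
        return {
            "peak_rate": 0.0,
            "in_field_rate": float("nan"),
            "sparsity": float("nan"),
            "information_density": float("nan"),
            "mean_rate": 0.0,
        }
    sparsity = mean_rate**2 / float(np.sum(p * lam**2))
    ratio = lam / mean_rate
    nz = ratio > 0
    information = float(np.sum(p[nz] * ratio[nz] * np.log2(ratio[nz])))
    if field is not None:
        in_field = field.in_field_rate
        peak = field.peak_rate
    else:
        in_field = float("nan")
        peak = rmap.peak_rate
    return {
        "peak_rate": peak,
        "in_field_rate": in_field,
        "sparsity": float(sparsity),
        "information_density": information,
        "mean_rate": mean_rate,
    }


def field_size_fraction(
    class_map: RateMap, all_map: RateMap, min_pixels: int = 2, mode: str = "largest"
) -> float:
    """Field size of a spike-class map as a fraction of the all-spike field
    size.  ``mode`` picks the largest field (default) or the sum over fields."""
    def size_of(rm: RateMap) -> float:
        fields = detect_fields(rm, min_pixels=min_pixels)
        if not fields:
            return 0.0
        if mode == "largest":
            return fields[0].size_cm2
        return sum(f.size_cm2 for f in fields)

    denom = size_of(all_map)
    if denom == 0:
        return float("nan")
    return size_of(class_map) / denom


def map_correlation(map_a: RateMap, map_b: RateMap) -> dict[str, float]:
    """Fisher z-transformed Pearson correlation over jointly defined pixels."""
    a, b = map_a.rates.ravel(), map_b.rates.ravel()
    joint = ~np.isnan(a) & ~np.isnan(b)
    if joint.sum() < 10:
        raise ValueError("need at least 10 jointly defined pixels")
    av, bv = a[joint], b[joint]
    if np.allclose(av, av[0]) or np.allclose(bv, bv[0]):
        raise ValueError("constant map: correlation undefined")
    r = float(np.corrcoef(av, bv)[0, 1])
    r_clipped = np.clip(r, -0.999999, 0.999999)
    flagged = "perfect" if abs(r) >= 0.999999 else ""
    return {"r": r, "z": float(np.arctanh(r_clipped)), "n_pixels": int(joint.sum()),
            "flag": flagged}
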