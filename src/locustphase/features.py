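"""The eleven behavioral markers of the attraction–avoidance assay.

For one recorded trajectory the assay summarises behavior with:

========  =====================================================  =====
marker    meaning                                                units
========  =====================================================  =====
EFISA     entries into the stimulus-side zone                    count
LFOISA    latency of first occurrence in the stimulus zone       s
TDCW      total duration in the near-wall band                   s
EFCW      entries into the near-wall band                        count
EFIOSA    entries into the opposite-end zone                     count
LFOIOSA   latency of first occurrence in the opposite zone       s
MDTSG     mean distance to the stimulus group                    cm
TDM       total distance moved                                   cm
TDMV      total duration of movement                             s
FOM       frequency of movement (bout count)                     count
AI        attraction index: stimulus minus opposite duration     s
========  =====================================================  =====

Occupancy is sample-and-hold: each inter-sample interval is assigned
the zone of its leading sample, so zone durations are multiples of the
sampling step and the stimulus/opposite/middle durations sum exactly to
the recording duration.  A zone never visited is given the censored
latency equal to the recording duration.  Movement bouts are maximal
runs of smoothed instantaneous speed at or above a threshold lasting at
least a minimum duration; the bout mechanics of the original tracking
software are unreported, so these parameters are explicit and
configurable (:class:`BoutConfig`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .arena import (
    ArenaGeometry,
    BoxZone,
    Trajectory,
    WallBand,
    ZonePartition,
    build_zones,
)

__all__ = [
    "MARKERS",
    "FeatureVector",
    "BoutConfig",
    "zone_duration",
    "zone_entries",
    "first_entry_latency",
    "path_length",
    "movement_bouts",
    "mean_distance_to_stimulus",
    "attraction_index",
    "compute_features",
    "features_table",
]

#: Fixed marker order, used for table columns and selection tie-breaks.
MARKERS: tuple[str, ...] = (
    "EFISA",
    "LFOISA",
    "TDCW",
    "EFCW",
    "EFIOSA",
    "LFOIOSA",
    "MDTSG",
    "TDM",
    "TDMV",
    "FOM",
    "AI",
)


@dataclass(frozen=True)
class FeatureVector:
    """The eleven markers for one recording (fields in canonical order)."""

    EFISA: float
    LFOISA: float
    TDCW: float
    EFCW: float
    EFIOSA: float
    LFOIOSA: float
    MDTSG: float
    TDM: float
    TDMV: float
    FOM: float
    AI: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in MARKERS}


@dataclass(frozen=True)
class BoutConfig:
    """Movement-bout detection parameters.

    ``speed_threshold`` (cm/s) separates locomotion from rest after the
    instantaneous speed is smoothed by a centred moving average of
    ``smoothing_window`` samples; runs at or above threshold shorter
    than ``min_bout`` seconds are discarded.
    """

    speed_threshold: float = 0.5
    min_bout: float = 1.0
    smoothing_window: int = 5

    def __post_init__(self) -> None:
        if self.speed_threshold <= 0:
            raise ValueError("speed_threshold must be positive")
        if self.min_bout <= 0:
            raise ValueError("min_bout must be positive")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")


def _occupancy(traj: Trajectory, zone: BoxZone | WallBand) -> np.ndarray:
    return zone.mask(traj.positions)


def zone_duration(traj: Trajectory, zone: BoxZone | WallBand) -> float:
    """Seconds spent in ``zone`` (sample-and-hold over intervals)."""
    occ = _occupancy(traj, zone)
    return float(np.count_nonzero(occ[:-1])) * traj.dt


def zone_entries(traj: Trajectory, zone: BoxZone | WallBand) -> int:
    """Number of out->in transitions; starting inside counts as one entry."""
    occ = _occupancy(traj, zone)
    entries = int(occ[0]) + int(np.count_nonzero(~occ[:-1] & occ[1:]))
    return entries


def first_entry_latency(traj: Trajectory, zone: BoxZone | WallBand) -> float:
    """Time to the first in-zone sample; the full duration if never entered."""
    occ = _occupancy(traj, zone)
    idx = np.flatnonzero(occ)
    if idx.size == 0:
        return traj.duration
    return float(traj.times[idx[0]] - traj.times[0])


def path_length(traj: Trajectory) -> float:
    """Total distance moved: summed Euclidean steps between samples, cm."""
    d = np.diff(traj.positions, axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def _smoothed_speeds(traj: Trajectory, cfg: BoutConfig) -> np.ndarray:
    d = np.diff(traj.positions, axis=0)
    speeds = np.hypot(d[:, 0], d[:, 1]) / traj.dt
    if cfg.smoothing_window > 1:
        speeds = uniform_filter1d(speeds, size=cfg.smoothing_window, mode="nearest")
    return speeds


def movement_bouts(
    traj: Trajectory, cfg: BoutConfig = BoutConfig()
) -> list[tuple[float, float]]:
    """Maximal (start, end) time intervals of sustained locomotion.

    The interval between samples i and i+1 is "moving" when the smoothed
    speed is at or above ``cfg.speed_threshold``; maximal moving runs
    lasting at least ``cfg.min_bout`` seconds are returned.
    """
    speeds = _smoothed_speeds(traj, cfg)
    fast = speeds >= cfg.speed_threshold
    bouts: list[tuple[float, float]] = []
    dt = traj.dt
    i = 0
    n = len(fast)
    while i < n:
        if fast[i]:
            j = i
            while j + 1 < n and fast[j + 1]:
                j += 1
            length = (j - i + 1) * dt
            if length >= cfg.min_bout - 1e-12:
                bouts.append((float(traj.times[i]), float(traj.times[j + 1])))
            i = j + 1
        else:
            i += 1
    return bouts


def mean_distance_to_stimulus(traj: Trajectory, geom: ArenaGeometry) -> float:
    """Time-averaged Euclidean distance to the stimulus-wall centre, cm."""
    sx, sy = geom.stimulus_wall_center
    return float(np.mean(np.hypot(traj.x - sx, traj.y - sy)))


def attraction_index(traj: Trajectory, zones: ZonePartition) -> float:
    """Stimulus-zone duration minus opposite-zone duration, s."""
    return zone_duration(traj, zones.stimulus_zone) - zone_duration(
        traj, zones.opposite_zone
    )


def compute_features(
    traj: Trajectory,
    geom: ArenaGeometry,
    cfg: BoutConfig = BoutConfig(),
    zones: ZonePartition | None = None,
) -> FeatureVector:
    """Assemble all eleven markers for one trajectory."""
    if zones is None:
        zones = build_zones(geom)
    bouts = movement_bouts(traj, cfg)
    return FeatureVector(
        EFISA=zone_entries(traj, zones.stimulus_zone),
        LFOISA=first_entry_latency(traj, zones.stimulus_zone),
        TDCW=zone_duration(traj, zones.wall_zone),
        EFCW=zone_entries(traj, zones.wall_zone),
        EFIOSA=zone_entries(traj, zones.opposite_zone),
        LFOIOSA=first_entry_latency(traj, zones.opposite_zone),
        MDTSG=mean_distance_to_stimulus(traj, geom),
        TDM=path_length(traj),
        TDMV=float(sum(e - s for s, e in bouts)),
        FOM=len(bouts),
        AI=attraction_index(traj, zones),
    )


def features_table(
    trajectories: Iterable[Trajectory],
    geom: ArenaGeometry,
    cfg: BoutConfig = BoutConfig(),
) -> pd.DataFrame:
    """Feature table: one row per animal, metadata plus the 11 markers."""
    zones = build_zones(geom)
    rows = []
    for traj in trajectories:
        fv = compute_features(traj, geom, cfg, zones=zones)
        row = {"animal_id": traj.animal_id, "arm_label": traj.arm_label}
        row.update(fv.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["animal_id", "arm_label", *MARKERS])
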