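"""Arena geometry, zone partition, and the trajectory data model.

The attraction–avoidance assay records a single locust in a rectangular
open arena whose far chambers hold the conspecific stimulus group.  All
downstream marker extraction depends on three derived regions:

* ``stimulus_zone`` — the fraction of the open arena adjacent to the
  stimulus wall (default 25%),
* ``opposite_zone`` — the matching fraction at the far end,
* ``wall_zone`` — a thigmotaxis band of configurable thickness along
  every wall (this band overlaps the end zones; it is not part of the
  stimulus/opposite/middle partition).

Coordinate convention: origin at the lower corner of the stimulus-side
wall, x increasing away from the stimulus group, units cm, time in
seconds.  Zone membership along x uses half-open intervals ``[lo, hi)``
except at the far arena boundary, which is closed, so every in-arena
point belongs to exactly one of stimulus/opposite/middle.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "GeometryError",
    "TrackFormatError",
    "ArenaGeometry",
    "BoxZone",
    "WallBand",
    "ZonePartition",
    "Trajectory",
    "GEOMETRY_PRESETS",
    "build_zones",
    "point_in_zone",
    "read_track_file",
    "read_tracks",
    "write_track_file",
    "write_tracks",
]


class GeometryError(ValueError):
    """Arena geometry violates its invariants."""


class TrackFormatError(ValueError):
    """A track file or manifest could not be parsed into a valid trajectory."""


@dataclass(frozen=True)
class ArenaGeometry:
    """Open test-area geometry of the attraction–avoidance arena.

    Parameters
    ----------
    open_length_x
        Extent of the open (animal-accessible) arena along the stimulus
        axis, cm.  The default 25 cm is the open test area of a
        40 x 30 cm arena with two 7.5 cm end chambers; the full 40 cm
        footprint is available as the ``"full-arena"`` preset.
    width_y
        Arena width, cm.
    stimulus_zone_fraction
        Fraction of ``open_length_x`` forming each end zone (default
        0.25, i.e. the quarter of the arena nearest the stimulus group).
    wall_margin
        Thickness of the near-wall thigmotaxis band, cm.
    stimulus_wall_center
        Reference point for distance-to-stimulus measurements; defaults
        to the midpoint of the stimulus-side wall, ``(0, width_y / 2)``.
    """

    open_length_x: float = 25.0
    width_y: float = 30.0
    stimulus_zone_fraction: float = 0.25
    wall_margin: float = 3.0
    stimulus_wall_center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.stimulus_wall_center is None:
            object.__setattr__(
                self, "stimulus_wall_center", (0.0, self.width_y / 2.0)
            )
        if not (self.open_length_x > 0 and self.width_y > 0):
            raise GeometryError("arena extents must be positive")
        if not (0.0 < self.stimulus_zone_fraction <= 0.5):
            raise GeometryError("stimulus_zone_fraction must lie in (0, 0.5]")
        if not (0.0 < self.wall_margin < min(self.open_length_x, self.width_y) / 2):
            raise GeometryError(
                "wall_margin must lie in (0, min(length, width)/2)"
            )

    def contains(self, x: float, y: float) -> bool:
        return 0.0 <= x <= self.open_length_x and 0.0 <= y <= self.width_y


#: Named geometry presets.  ``"open-area"`` treats the end zones as
#: fractions of the 25 cm open test area; ``"full-arena"`` as fractions
#: of the full 40 cm footprint.
GEOMETRY_PRESETS: dict[str, ArenaGeometry] = {
    "open-area": ArenaGeometry(open_length_x=25.0, width_y=30.0),
    "full-arena": ArenaGeometry(open_length_x=40.0, width_y=30.0),
}


@dataclass(frozen=True)
class BoxZone:
    """Axis-aligned zone, half-open along x at ``x_hi`` unless closed."""

    name: str
    x_lo: float
    x_hi: float
    y_lo: float
    y_hi: float
    x_hi_closed: bool = False

    def contains(self, x: float, y: float) -> bool:
        if not (self.y_lo <= y <= self.y_hi):
            return False
        if self.x_hi_closed:
            return self.x_lo <= x <= self.x_hi
        return self.x_lo <= x < self.x_hi

    def mask(self, positions: np.ndarray) -> np.ndarray:
        """Vectorised membership for an (n, 2) position array."""
        x, y = positions[:, 0], positions[:, 1]
        ok_y = (y >= self.y_lo) & (y <= self.y_hi)
        if self.x_hi_closed:
            return ok_y & (x >= self.x_lo) & (x <= self.x_hi)
        return ok_y & (x >= self.x_lo) & (x < self.x_hi)

    @property
    def area(self) -> float:
        return max(self.x_hi - self.x_lo, 0.0) * max(self.y_hi - self.y_lo, 0.0)


@dataclass(frozen=True)
class WallBand:
    """Band of points within ``margin`` of any arena wall (inclusive)."""

    name: str
    length_x: float
    width_y: float
    margin: float

    def contains(self, x: float, y: float) -> bool:
        return (
            min(x, self.length_x - x, y, self.width_y - y) <= self.margin
        )

    def mask(self, positions: np.ndarray) -> np.ndarray:
        x, y = positions[:, 0], positions[:, 1]
        d = np.minimum.reduce([x, self.length_x - x, y, self.width_y - y])
        return d <= self.margin


@dataclass(frozen=True)
class ZonePartition:
    """Derived regions of the arena: end zones, middle, and wall band."""

    geometry: ArenaGeometry
    stimulus_zone: BoxZone
    opposite_zone: BoxZone
    middle: BoxZone
    wall_zone: WallBand


def build_zones(geom: ArenaGeometry) -> ZonePartition:
    """Partition the arena into stimulus / middle / opposite zones.

    The stimulus zone spans ``x in [0, f*L)``, the opposite zone
    ``x in [(1-f)*L, L]`` (far boundary closed), and the middle the
    remainder; with ``f = 0.5`` the two end zones tile the arena
    exactly.  The wall band overlaps all three.
    """
    L, W, f = geom.open_length_x, geom.width_y, geom.stimulus_zone_fraction
    return ZonePartition(
        geometry=geom,
        stimulus_zone=BoxZone("stimulus", 0.0, f * L, 0.0, W),
        opposite_zone=BoxZone("opposite", (1.0 - f) * L, L, 0.0, W, x_hi_closed=True),
        middle=BoxZone("middle", f * L, (1.0 - f) * L, 0.0, W),
        wall_zone=WallBand("wall", L, W, geom.wall_margin),
    )


def point_in_zone(p: Sequence[float], zone: BoxZone | WallBand) -> bool:
    """Whether 2-D point ``p`` lies in ``zone`` (half-open convention)."""
    x, y = float(p[0]), float(p[1])
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError("point coordinates must be finite")
    return zone.contains(x, y)


@dataclass
class Trajectory:
    """One animal's arena recording: uniformly sampled 2-D positions.

    ``times`` are seconds (strictly increasing, uniform step), and
    ``positions`` an (n, 2) array of (x, y) in cm.  ``n_clipped``
    records how many out-of-bounds samples were clipped at read time.
    """

    times: np.ndarray
    positions: np.ndarray
    animal_id: str = ""
    arm_label: str = ""
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise TrackFormatError("times must be 1-D and positions (n, 2)")
        if len(self.times) != len(self.positions):
            raise TrackFormatError("times and positions must have equal length")
        if len(self.times) < 2:
            raise TrackFormatError("a trajectory needs at least 2 samples")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise TrackFormatError("time must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise TrackFormatError("sampling step must be uniform")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def x(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.positions[:, 1]

    def validate_bounds(self, geom: ArenaGeometry) -> None:
        if (
            np.any(self.x < 0)
            or np.any(self.x > geom.open_length_x)
            or np.any(self.y < 0)
            or np.any(self.y > geom.width_y)
        ):
            raise TrackFormatError("trajectory leaves the arena bounds")

    def mirrored(self, geom: ArenaGeometry) -> "Trajectory":
        """Reflection about the arena midline perpendicular to x."""
        pos = self.positions.copy()
        pos[:, 0] = geom.open_length_x - pos[:, 0]
        return Trajectory(
            self.times.copy(), pos, self.animal_id, self.arm_label, self.n_clipped
        )


# ---------------------------------------------------------------------------
# Track-file IO.  Canonical dialect: delimited text with header time,x,y,
# one animal per file; floats written with shortest round-trip repr so a
# write/read cycle is bit-identical.  A cohort manifest (columns file,
# animal_id, arm_label) maps files to metadata.
# ---------------------------------------------------------------------------


def write_track_file(traj: Trajectory, path: str | Path, delimiter: str = ",") -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["time", "x", "y"])
        for t, (x, y) in zip(traj.times, traj.positions):
            w.writerow([repr(float(t)), repr(float(x)), repr(float(y))])


def read_track_file(
    path: str | Path,
    geom: ArenaGeometry | None = None,
    animal_id: str | None = None,
    arm_label: str = "",
) -> Trajectory:
    """Parse one delimited track file into a validated :class:`Trajectory`.

    The delimiter (comma or tab) is inferred from the header line.
    When ``geom`` is given, samples outside the arena are clipped to the
    boundary and counted in ``Trajectory.n_clipped`` (logged).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        header_line = fh.readline()
        if not header_line:
            raise TrackFormatError(f"{path}: empty file")
        delimiter = "\t" if "\t" in header_line else ","
        header = [h.strip().lower() for h in header_line.split(delimiter)]
        try:
            it, ix, iy = header.index("time"), header.index("x"), header.index("y")
        except ValueError as exc:
            raise TrackFormatError(f"{path}: header must name time, x and y") from exc
        times, xs, ys = [], [], []
        for lineno, row in enumerate(csv.reader(fh, delimiter=delimiter), start=2):
            if not row or not "".join(row).strip():
                continue
            try:
                times.append(float(row[it]))
                xs.append(float(row[ix]))
                ys.append(float(row[iy]))
            except (ValueError, IndexError) as exc:
                raise TrackFormatError(f"{path}:{lineno}: malformed row {row!r}") from exc
    if len(times) < 2:
        raise TrackFormatError(f"{path}: fewer than 2 samples")
    positions = np.column_stack([xs, ys])
    n_clipped = 0
    if geom is not None:
        clipped = np.column_stack(
            [
                np.clip(positions[:, 0], 0.0, geom.open_length_x),
                np.clip(positions[:, 1], 0.0, geom.width_y),
            ]
        )
        n_clipped = int(np.sum(np.any(clipped != positions, axis=1)))
        if n_clipped:
            log.info("%s: clipped %d out-of-bounds samples", path, n_clipped)
        positions = clipped
    return Trajectory(
        np.asarray(times),
        positions,
        animal_id=animal_id if animal_id is not None else path.stem,
        arm_label=arm_label,
        n_clipped=n_clipped,
    )


def write_tracks(
    trajectories: Iterable[Trajectory],
    directory: str | Path,
    manifest_name: str = "manifest.csv",
) -> Path:
    """Write a cohort as one file per animal plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / manifest_name
    with manifest.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["file", "animal_id", "arm_label"])
        for traj in trajectories:
            fname = f"{traj.animal_id or 'animal'}.csv"
            write_track_file(traj, directory / fname)
            w.writerow([fname, traj.animal_id, traj.arm_label])
    return manifest


def read_tracks(
    manifest_path: str | Path, geom: ArenaGeometry | None = None
) -> list[Trajectory]:
    """Read a cohort manifest and all track files it references."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    out: list[Trajectory] = []
    with manifest_path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "file" not in reader.fieldnames:
            raise TrackFormatError(f"{manifest_path}: manifest must have a 'file' column")
        for row in reader:
            out.append(
                read_track_file(
                    base / row["file"],
                    geom=geom,
                    animal_id=row.get("animal_id") or None,
                    arm_label=row.get("arm_label", ""),
                )
            )
    if not out:
        raise TrackFormatError(f"{manifest_path}: manifest lists no tracks")
    return out
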