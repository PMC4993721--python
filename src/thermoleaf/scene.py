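"""Core data types for radiometric thermal scenes.

A *radiometric* frame stores calibrated surface temperatures (°C) rather than
raw sensor counts.  Scenes are observed through named regions of interest
(ROIs): rectangles or ovals assigned to individual plants, plus a single 3x3
``air_cursor`` placed on background between the plants from which ambient air
temperature is read.

Coordinates are 0-based, half-open, ``(row, col)`` ordered throughout.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import (
    BoundsError,
    ConfigurationError,
    FrameParseError,
    ValidationError,
)

#: Physical plausibility range for chamber experiments, °C.
TEMP_MIN = 0.0
TEMP_MAX = 60.0

#: Plant material emissivity used for the whole experiment.
DEFAULT_EMISSIVITY = 0.95

ROI_SHAPES = ("rectangle", "oval", "point_cursor")
ROI_ROLES = ("plant", "air_cursor")


@dataclass(frozen=True)
class ThermalFrame:
    """One radiometric image: a 2-D temperature grid with acquisition metadata.

    Parameters
    ----------
    temperatures
        2-D array of surface temperatures, °C, row-major.
    timestamp_min
        Acquisition time in minutes since the start of the experiment.
    emissivity
        Scalar emissivity in (0, 1]; carried as metadata only (no radiometric
        correction is applied downstream).
    frame_id
        Unique identifier within a sequence.
    """

    temperatures: np.ndarray
    timestamp_min: float
    emissivity: float = DEFAULT_EMISSIVITY
    frame_id: str = ""

    def __post_init__(self) -> None:
        temps = np.asarray(self.temperatures, dtype=float)
        if temps.ndim != 2 or temps.size == 0:
            raise ValidationError(
                f"frame {self.frame_id!r}: temperatures must be a non-empty 2-D grid, "
                f"got shape {temps.shape}"
            )
        if not np.all(np.isfinite(temps)):
            raise ValidationError(
                f"frame {self.frame_id!r}: non-finite temperature values present"
            )
        if temps.min() < TEMP_MIN or temps.max() > TEMP_MAX:
            raise ValidationError(
                f"frame {self.frame_id!r}: temperatures outside physical range "
                f"[{TEMP_MIN}, {TEMP_MAX}] °C (min {temps.min():.2f}, max {temps.max():.2f})"
            )
        if not (0.0 < self.emissivity <= 1.0):
            raise ValidationError(
                f"frame {self.frame_id!r}: emissivity {self.emissivity} outside (0, 1]"
            )
        object.__setattr__(self, "temperatures", temps)

    @property
    def shape(self) -> tuple[int, int]:
        return self.temperatures.shape


@dataclass(frozen=True)
class RegionOfInterest:
    """A named pixel region assigned to a plant or the air cursor.

    ``bounds`` are ``(row_min, col_min, row_max, col_max)``, 0-based and
    half-open.  An ``oval`` covers the pixels whose centers fall inside the
    ellipse inscribed in the bounding rectangle.  A ``point_cursor`` with role
    ``air_cursor`` must cover exactly 3x3 pixels.
    """

    name: str
    shape: str
    bounds: tuple[int, int, int, int]
    role: str = "plant"
    #: Stem attachment point (row, col) used as protractor origin; plants only.
    stem_anchor: tuple[int, int] | None = None
    #: Treatment label ("control" / "treated"); informational.
    treatment: str | None = None

    def __post_init__(self) -> None:
        if self.shape not in ROI_SHAPES:
            raise ValidationError(f"ROI {self.name!r}: unknown shape {self.shape!r}")
        if self.role not in ROI_ROLES:
            raise ValidationError(f"ROI {self.name!r}: unknown role {self.role!r}")
        r0, c0, r1, c1 = self.bounds
        if not (r0 < r1 and c0 < c1) or min(r0, c0) < 0:
            raise ValidationError(
                f"ROI {self.name!r}: degenerate bounds {self.bounds}"
            )
        if self.shape == "point_cursor" and self.role == "air_cursor":
            if (r1 - r0, c1 - c0) != (3, 3):
                raise ValidationError(
                    f"ROI {self.name!r}: air cursor must cover exactly 3x3 pixels, "
                    f"got {(r1 - r0)}x{(c1 - c0)}"
                )

    def check_within(self, frame_shape: tuple[int, int]) -> None:
        r0, c0, r1, c1 = self.bounds
        nr, nc = frame_shape
        if r1 > nr or c1 > nc:
            raise BoundsError(
                f"ROI {self.name!r} bounds {self.bounds} exceed frame shape {frame_shape}"
            )

    def pixel_indices(self, frame_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Row/col index arrays of the pixels inside the ROI shape."""
        self.check_within(frame_shape)
        r0, c0, r1, c1 = self.bounds
        rows, cols = np.mgrid[r0:r1, c0:c1]
        if self.shape == "oval":
            cr = (r0 + r1 - 1) / 2.0
            cc = (c0 + c1 - 1) / 2.0
            a = (r1 - r0) / 2.0
            b = (c1 - c0) / 2.0
            inside = ((rows - cr) / a) ** 2 + ((cols - cc) / b) ** 2 <= 1.0
            return rows[inside], cols[inside]
        return rows.ravel(), cols.ravel()


def roi_extract(frame: ThermalFrame, roi: RegionOfInterest) -> np.ndarray:
    """Temperatures (°C) of all pixels inside the ROI shape, row-major order."""
    rows, cols = roi.pixel_indices(frame.shape)
    return frame.temperatures[rows, cols]


def validate_roi_set(rois: Sequence[RegionOfInterest]) -> None:
    """A scene needs >= 1 plant ROI and exactly one air cursor."""
    n_plant = sum(r.role == "plant" for r in rois)
    n_air = sum(r.role == "air_cursor" for r in rois)
    if n_plant < 1 or n_air != 1:
        raise ConfigurationError(
            f"a scene requires >=1 plant ROI and exactly 1 air cursor "
            f"(got {n_plant} plant, {n_air} air)"
        )
    names = [r.name for r in rois]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate ROI names: {names}")


@dataclass
class FrameSequence:
    """An ordered time-lapse of frames sharing geometry, ROIs and a light schedule.

    ``day_night_schedule`` lists ``(light_on_min, light_off_min)`` pairs in
    absolute minutes since experiment start, one pair per day.
    """

    frames: list[ThermalFrame]
    cadence_min: float = 10.0
    rois: list[RegionOfInterest] = field(default_factory=list)
    day_night_schedule: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError("sequence contains no frames")
        times = np.array([f.timestamp_min for f in self.frames], dtype=float)
        if not np.all(np.diff(times) > 0):
            raise ValidationError("frame timestamps must be strictly increasing")
        steps = np.diff(times)
        if steps.size and np.any(np.abs(steps - self.cadence_min) > 0.01 * self.cadence_min):
            raise ValidationError(
                f"timestamp steps deviate from cadence {self.cadence_min} min "
                f"by more than 1 % (range {steps.min():.3f}-{steps.max():.3f})"
            )
        shape0 = self.frames[0].shape
        for f in self.frames:
            if f.shape != shape0:
                raise ValidationError(
                    f"frame {f.frame_id!r} shape {f.shape} != sequence shape {shape0}"
                )
        if self.rois:
            validate_roi_set(self.rois)
            for roi in self.rois:
                roi.check_within(shape0)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.timestamp_min for f in self.frames], dtype=float)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def is_daytime(self, t_min: float) -> bool:
        return any(on <= t_min < off for on, off in self.day_night_schedule)

    def air_cursor(self) -> RegionOfInterest:
        for roi in self.rois:
            if roi.role == "air_cursor":
                return roi
        raise ConfigurationError("sequence has no air cursor ROI")

    def plant_rois(self) -> list[RegionOfInterest]:
        return [r for r in self.rois if r.role == "plant"]


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

FRAME_FORMATS = ("temperature_csv", "float_tiff")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def read_frame(path: str | Path, format: str = "temperature_csv") -> ThermalFrame:
    """Read a radiometric frame from a plain-text CSV grid or float TIFF.

    A JSON sidecar ``<path>.json`` (written by :func:`write_frame`) supplies
    timestamp, emissivity and frame id when present.
    """
    path = Path(path)
    if format not in FRAME_FORMATS:
        raise ValidationError(f"unknown frame format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "temperature_csv":
        rows: list[list[float]] = []
        with open(path, newline="") as fh:
            for i, row in enumerate(csv.reader(fh)):
                if not row:
                    continue
                try:
                    rows.append([float(v) for v in row])
                except ValueError as exc:
                    raise FrameParseError(f"{path}: row {i}: non-numeric cell ({exc})")
                if rows and len(rows[-1]) != len(rows[0]):
                    raise FrameParseError(
                        f"{path}: row {i}: ragged row of length {len(rows[-1])} "
                        f"(expected {len(rows[0])})"
                    )
        if not rows:
            raise FrameParseError(f"{path}: empty grid")
        temps = np.asarray(rows, dtype=float)
    else:
        import tifffile

        temps = np.asarray(tifffile.imread(path), dtype=float)

    meta = {"timestamp_min": 0.0, "emissivity": DEFAULT_EMISSIVITY, "frame_id": path.stem}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return ThermalFrame(
        temperatures=temps,
        timestamp_min=float(meta["timestamp_min"]),
        emissivity=float(meta["emissivity"]),
        frame_id=str(meta["frame_id"]),
    )


def write_frame(frame: ThermalFrame, path: str | Path, format: str = "temperature_csv") -> None:
    """Write a frame plus a JSON metadata sidecar; round-trips within 1e-4 °C."""
    path = Path(path)
    if format not in FRAME_FORMATS:
        raise ValidationError(f"unknown frame format {format!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "temperature_csv":
        np.savetxt(path, frame.temperatures, delimiter=",", fmt="%.6f")
    else:
        import tifffile

        tifffile.imwrite(path, frame.temperatures.astype(np.float32))
    meta = {
        "frame_id": frame.frame_id,
        "timestamp_min": frame.timestamp_min,
        "emissivity": frame.emissivity,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Manifest and ROI config
# ---------------------------------------------------------------------------

def write_manifest(sequence: FrameSequence, out_dir: str | Path,
                   format: str = "temperature_csv") -> Path:
    """Write every frame plus a ``manifest.csv`` (frame_id, path, timestamp_min)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "csv" if format == "temperature_csv" else "tiff"
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_id", "path", "timestamp_min"])
        for frame in sequence.frames:
            rel = f"frames/{frame.frame_id}.{ext}"
            write_frame(frame, out_dir / rel, format=format)
            writer.writerow([frame.frame_id, rel, f"{frame.timestamp_min:g}"])
    return manifest


def read_manifest(manifest_path: str | Path, format: str = "temperature_csv",
                  rois: Sequence[RegionOfInterest] | None = None,
                  day_night_schedule: Iterable[tuple[float, float]] | None = None,
                  ) -> FrameSequence:
    """Load a frame sequence from a ``manifest.csv`` written by :func:`write_manifest`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    frames: list[ThermalFrame] = []
    with open(manifest_path, newline="") as fh:
        for rec in csv.DictReader(fh):
            fpath = base / rec["path"]
            if not fpath.exists():
                raise FileNotFoundError(
                    f"manifest entry {rec['frame_id']!r}: missing frame file {fpath}"
                )
            frame = read_frame(fpath, format=format)
            frames.append(replace(frame, frame_id=rec["frame_id"],
                                  timestamp_min=float(rec["timestamp_min"])))
    if len(frames) < 2:
        cadence = 10.0
    else:
        cadence = float(frames[1].timestamp_min - frames[0].timestamp_min)
    return FrameSequence(
        frames=frames,
        cadence_min=cadence,
        rois=list(rois) if rois else [],
        day_night_schedule=list(day_night_schedule) if day_night_schedule else [],
    )


def save_roi_config(rois: Sequence[RegionOfInterest], path: str | Path) -> None:
    """Persist ROIs as JSON/YAML (by extension)."""
    path = Path(path)
    records = []
    for r in rois:
        rec: dict = {"name": r.name, "shape": r.shape, "role": r.role,
                     "bounds": list(r.bounds)}
        if r.stem_anchor is not None:
            rec["stem_anchor"] = list(r.stem_anchor)
        if r.treatment is not None:
            rec["treatment"] = r.treatment
        records.append(rec)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(records, sort_keys=False))
    else:
        path.write_text(json.dumps(records, indent=1))


def load_roi_config(path: str | Path) -> list[RegionOfInterest]:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        records = yaml.safe_load(text)
    else:
        records = json.loads(text)
    rois = []
    for rec in records:
        rois.append(RegionOfInterest(
            name=rec["name"],
            shape=rec["shape"],
            bounds=tuple(rec["bounds"]),
            role=rec.get("role", "plant"),
            stem_anchor=tuple(rec["stem_anchor"]) if rec.get("stem_anchor") else None,
            treatment=rec.get("treatment"),
        ))
    validate_roi_set(rois)
    return rois
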