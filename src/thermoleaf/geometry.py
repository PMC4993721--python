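"""Plant segmentation and the digital-protractor leaf-angle measurement.

A transpiring (or overheated) canopy contrasts thermally with the
background, so plant pixels are segmented as those differing from air
temperature by more than a contrast threshold, keeping the largest
connected component.  The leaf angle is the angle between the mask's
principal axis (leading eigenvector of the pixel-coordinate covariance,
oriented away from the stem attachment point) and the downward vertical
stem axis: 0° hangs along the stem, 90° is horizontal.  Turgor is mapped
linearly from angle: 90° = full turgor (100 %), 0° = none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .exceptions import ValidationError
from .scene import FrameSequence, RegionOfInterest, ThermalFrame

#: Thermal contrast (°C, either sign) separating plant from background.
CONTRAST_THRESHOLD_C = 0.8

#: Smallest mask considered measurable.
MIN_MASK_PIXELS = 30

#: Principal/secondary eigenvalue ratio below which the axis is ambiguous.
MIN_EIGEN_RATIO = 1.2

QUALITY_OK = "ok"
QUALITY_SMALL = "small_mask"
QUALITY_AMBIGUOUS = "ambiguous_axis"


@dataclass(frozen=True)
class LeafAngleMeasurement:
    """Leaf angle (degrees from the downward stem axis) and derived turgor."""

    plant: str
    angle_deg: float | None
    turgor_pct: float | None
    n_pixels: int
    quality: str


def angle_to_turgor(angle_deg: float) -> float:
    """Linear angle->turgor map: 0° -> 0 %, 90° -> 100 %, clamped above 90°."""
    if angle_deg < 0:
        raise ValidationError(f"negative leaf angle {angle_deg}°")
    return float(np.clip(angle_deg / 90.0 * 100.0, 0.0, 100.0))


def segment_plant(frame: ThermalFrame, roi: RegionOfInterest, air_temp: float,
                  contrast_c: float = CONTRAST_THRESHOLD_C,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Plant pixel mask: thermal contrast > threshold, largest 8-connected blob.

    Returns global (rows, cols) index arrays; empty arrays when nothing
    contrasts with the air (thermal equilibrium).
    """
    r0, c0, r1, c1 = roi.bounds
    roi.check_within(frame.shape)
    window = frame.temperatures[r0:r1, c0:c1]
    local = np.abs(window - air_temp) > contrast_c
    if roi.shape == "oval":
        keep = np.zeros_like(local)
        rr, cc = roi.pixel_indices(frame.shape)
        keep[rr - r0, cc - c0] = True
        local &= keep
    if not local.any():
        empty = np.array([], dtype=int)
        return empty, empty
    labels = measure.label(local, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    biggest = int(np.argmax(counts))
    rows, cols = np.nonzero(labels == biggest)
    return rows + r0, cols + c0


def estimate_leaf_angle(mask: tuple[np.ndarray, np.ndarray],
                        stem_anchor: tuple[float, float],
                        plant: str = "",
                        min_pixels: int = MIN_MASK_PIXELS,
                        min_eigen_ratio: float = MIN_EIGEN_RATIO,
                        ) -> LeafAngleMeasurement:
    """Principal-axis protractor: angle of the mask against the downward vertical.

    The leading covariance eigenvector is oriented away from the stem anchor
    so hanging (0°) and upright (>90°) leaves are distinguished; results are
    reported in [0, 120]°.  Nearly isotropic masks are flagged
    ``ambiguous_axis``; masks below ``min_pixels`` report no angle.
    """
    rows, cols = (np.asarray(mask[0], dtype=float), np.asarray(mask[1], dtype=float))
    n = rows.size
    if n < min_pixels:
        return LeafAngleMeasurement(plant, None, None, int(n), QUALITY_SMALL)
    pts = np.column_stack([rows, cols])
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / n
    evals, evecs = np.linalg.eigh(cov)          # ascending
    if evals[0] <= 0 or evals[1] / max(evals[0], 1e-12) < min_eigen_ratio:
        return LeafAngleMeasurement(plant, None, None, int(n), QUALITY_AMBIGUOUS)
    axis = evecs[:, 1]
    away = pts.mean(axis=0) - np.asarray(stem_anchor, dtype=float)
    if axis @ away < 0:
        axis = -axis
    # angle against downward vertical (+row direction)
    angle = float(np.degrees(np.arccos(np.clip(axis[0], -1.0, 1.0))))
    angle = float(np.clip(angle, 0.0, 120.0))
    return LeafAngleMeasurement(plant, angle, angle_to_turgor(angle),
                                int(n), QUALITY_OK)


def measure_angles(sequence: FrameSequence, air_series: pd.DataFrame,
                   contrast_c: float = CONTRAST_THRESHOLD_C,
                   min_pixels: int = MIN_MASK_PIXELS) -> pd.DataFrame:
    """Segment and measure every plant in every frame.

    ``air_series`` maps ``time_min`` to ``air_temp`` (e.g. from
    :func:`thermoleaf.thermometry.extract_readings`).
    """
    air_map = (air_series.drop_duplicates("time_min")
               .set_index("time_min")["air_temp"])
    plants = sequence.plant_rois()
    records = []
    for frame in sequence.frames:
        air = float(air_map.loc[frame.timestamp_min])
        for roi in plants:
            mask = segment_plant(frame, roi, air, contrast_c)
            anchor = roi.stem_anchor or ((roi.bounds[0] + roi.bounds[2]) // 2,
                                         (roi.bounds[1] + roi.bounds[3]) // 2)
            m = estimate_leaf_angle(mask, anchor, plant=roi.name,
                                    min_pixels=min_pixels)
            records.append({
                "time_min": frame.timestamp_min, "plant": roi.name,
                "angle_deg": m.angle_deg, "turgor_pct": m.turgor_pct,
                "n_pixels": m.n_pixels, "quality": m.quality,
            })
    return pd.DataFrame(records)
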