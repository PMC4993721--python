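"""Leaf and air temperature extraction from ROI statistics.

Thermal ROI extremes change meaning across a wilting event: while the
canopy transpires it is the *coolest* thing in the ROI (minimum = leaf,
maximum = background air); once it wilts and heats past ambient the roles
invert (minimum = air, maximum = leaf).  :class:`ModeTracker` implements
that interpretation switch with a margin-plus-hysteresis rule so the mode
cannot chatter while the leaf crosses air temperature.

Raw extremes are replaced by robust (2nd/98th percentile) extremes before
interpretation; this automates the manual correction applied when a wilting
apical point bends into the ROI and contaminates the raw maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .scene import FrameSequence, roi_extract

MIN_IS_LEAF = "min_is_leaf"
MAX_IS_LEAF = "max_is_leaf"

#: Leaf must sit this far (°C) below air to count as actively transpiring.
SWITCH_MARGIN_C = 0.5

#: Minimum dwell (minutes) before the interpretation may switch back.
HYSTERESIS_MIN = 60.0

#: Pixels needed before the percentile correction is trusted.
MIN_PIXELS_FOR_CORRECTION = 20

#: |raw - robust| above this flags an apical-interference correction.
CORRECTION_FLAG_C = 0.3


@dataclass(frozen=True)
class FrameReading:
    """Per-frame, per-plant temperature reading."""

    frame_id: str
    plant: str
    time_min: float
    roi_min: float
    roi_max: float
    air_temp: float
    leaf_temp: float
    assignment_mode: str
    corrected: bool

    def __post_init__(self) -> None:
        if not (self.roi_min - 1e-9 <= self.leaf_temp <= self.roi_max + 1e-9):
            raise ValidationError(
                f"{self.frame_id}/{self.plant}: leaf_temp {self.leaf_temp} outside "
                f"ROI range [{self.roi_min}, {self.roi_max}]"
            )


def apical_interference_correct(values: np.ndarray, mode: str) -> tuple[float, bool]:
    """Robust extreme of ROI pixel values for the given assignment mode.

    Returns ``(extreme, corrected)``: the 2nd percentile (min mode) or 98th
    percentile (max mode), with ``corrected=True`` when the robust extreme
    differs from the raw one by more than 0.3 °C.  With fewer than 20 pixels
    the raw extreme is returned unflagged.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("empty ROI")
    raw = float(values.min() if mode == MIN_IS_LEAF else values.max())
    if values.size < MIN_PIXELS_FOR_CORRECTION:
        return raw, False
    pct = 2.0 if mode == MIN_IS_LEAF else 98.0
    robust = float(np.percentile(values, pct))
    return robust, abs(raw - robust) > CORRECTION_FLAG_C


class ModeTracker:
    """Stateful min/max interpretation switch for one plant.

    Starts in ``min_is_leaf`` (pre-stress).  Switches to ``max_is_leaf``
    once the cool tail of the ROI has collapsed to within ``margin`` of air
    temperature *and* the warm tail exceeds air (the canopy now heats past
    ambient).  Switch-back requires the reverse configuration and at least
    ``hysteresis_min`` minutes since the last transition.
    """

    def __init__(self, margin_c: float = SWITCH_MARGIN_C,
                 hysteresis_min: float = HYSTERESIS_MIN):
        self.margin = margin_c
        self.hysteresis = hysteresis_min
        self.mode = MIN_IS_LEAF
        self._last_switch: float | None = None
        self.n_switches = 0

    def update(self, t_min: float, roi_min: float, roi_max: float,
               air_temp: float) -> tuple[str, float]:
        """Advance to frame at ``t_min``; returns (mode, leaf_temp)."""
        if roi_min > roi_max:
            raise ValidationError(f"roi_min {roi_min} > roi_max {roi_max}")
        can_switch = (self._last_switch is None
                      or t_min - self._last_switch >= self.hysteresis)
        if self.mode == MIN_IS_LEAF:
            if roi_min >= air_temp - self.margin and roi_max > air_temp:
                self.mode = MAX_IS_LEAF
                self._last_switch = t_min
                self.n_switches += 1
        else:
            if (can_switch and roi_min < air_temp - self.margin
                    and roi_max <= air_temp):
                self.mode = MIN_IS_LEAF
                self._last_switch = t_min
                self.n_switches += 1
        leaf = roi_min if self.mode == MIN_IS_LEAF else roi_max
        return self.mode, leaf


def assign_leaf_temperature(roi_min: float, roi_max: float, air_temp: float,
                            tracker: ModeTracker | None = None,
                            t_min: float = 0.0) -> tuple[str, float]:
    """One-shot interpretation of a (roi_min, roi_max, air) triple.

    Convenience wrapper over :class:`ModeTracker` for stateless use; supply
    a tracker to carry history across frames.
    """
    tracker = tracker or ModeTracker()
    return tracker.update(t_min, roi_min, roi_max, air_temp)


def extract_readings(sequence: FrameSequence,
                     margin_c: float = SWITCH_MARGIN_C,
                     hysteresis_min: float = HYSTERESIS_MIN) -> pd.DataFrame:
    """Per-frame, per-plant readings for a whole sequence.

    Air temperature is the mean of the 3x3 air-cursor pixels.  Robust
    (percentile) extremes feed both the switch logic and the assigned leaf
    temperature.
    """
    air_roi = sequence.air_cursor()
    plants = sequence.plant_rois()
    if not plants:
        raise ConfigurationError("sequence has no plant ROIs")
    trackers = {p.name: ModeTracker(margin_c, hysteresis_min) for p in plants}
    records = []
    for frame in sequence.frames:
        air = float(np.mean(roi_extract(frame, air_roi)))
        for roi in plants:
            values = roi_extract(frame, roi)
            rmin, cmin = apical_interference_correct(values, MIN_IS_LEAF)
            rmax, cmax = apical_interference_correct(values, MAX_IS_LEAF)
            mode, leaf = trackers[roi.name].update(
                frame.timestamp_min, rmin, rmax, air)
            records.append(FrameReading(
                frame_id=frame.frame_id, plant=roi.name,
                time_min=frame.timestamp_min, roi_min=rmin, roi_max=rmax,
                air_temp=air, leaf_temp=leaf, assignment_mode=mode,
                corrected=cmin if mode == MIN_IS_LEAF else cmax))
    df = pd.DataFrame([r.__dict__ for r in records])
    df["n_switches"] = df["plant"].map(
        {name: tr.n_switches for name, tr in trackers.items()})
    return df


def build_time_series(readings: pd.DataFrame,
                      angles: pd.DataFrame | None = None,
                      treatments: dict[str, str] | None = None,
                      sequence: FrameSequence | None = None) -> pd.DataFrame:
    """Assemble per-plant time series (leaf/air temperature, ΔT, angle, turgor).

    ``angles`` (optional) must carry ``time_min, plant, angle_deg, turgor_pct``.
    """
    df = readings[["time_min", "plant", "leaf_temp", "air_temp",
                   "assignment_mode", "corrected"]].copy()
    df["leaf_air_delta"] = df["leaf_temp"] - df["air_temp"]
    if angles is not None:
        df = df.merge(
            angles[["time_min", "plant", "angle_deg", "turgor_pct"]],
            on=["time_min", "plant"], how="left")
        df = df.rename(columns={"angle_deg": "leaf_angle", "turgor_pct": "turgor"})
    if treatments:
        df["treatment"] = df["plant"].map(treatments)
    if sequence is not None:
        df["is_day"] = df["time_min"].map(sequence.is_daytime)
    return df.sort_values(["plant", "time_min"]).reset_index(drop=True)


def hourly_aggregate(series: pd.DataFrame,
                     schedule: list[tuple[float, float]],
                     value_cols: tuple[str, ...] = ("leaf_temp", "turgor"),
                     cadence_min: float = 10.0) -> pd.DataFrame:
    """Mean of the frames within each daytime hour (six at 10-min cadence).

    Hours are counted from each light-on time.  Hours with fewer frames than
    ``60/cadence`` (light transitions, gaps) are flagged ``partial``; hours
    with no frames appear with missing values and ``partial=True``.
    """
    if 60.0 % cadence_min != 0:
        raise ValidationError(f"cadence {cadence_min} min does not divide 60 min")
    expected = int(round(60.0 / cadence_min))
    value_cols = tuple(c for c in value_cols if c in series.columns)
    out = []
    for plant, grp in series.groupby("plant"):
        t = grp["time_min"].to_numpy(dtype=float)
        for day_idx, (on, off) in enumerate(schedule):
            n_hours = int(np.ceil((off - on) / 60.0))
            for h in range(n_hours):
                lo, hi = on + 60.0 * h, min(on + 60.0 * (h + 1), off)
                sel = grp[(t >= lo) & (t < hi)]
                rec = {"plant": plant, "day": day_idx + 1, "hour": h,
                       "time_mid_min": (lo + hi) / 2.0,
                       "n_frames": len(sel),
                       "partial": len(sel) < expected}
                for c in value_cols:
                    vals = sel[c].dropna()
                    rec[c] = float(vals.mean()) if len(vals) else float("nan")
                out.append(rec)
    return pd.DataFrame(out)
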