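"""Ground-truthed synthetic thermal scenes of a two-plant drought trial.

Emulates a 5-day stress-recovery experiment in a growth chamber: two soybean
plants (one control, one treated with a stress-mitigating biostimulant)
imaged every 10 minutes against a background at air temperature, under a
16:8 light cycle with air at 27 °C (night) rising to 33 °C under the lamps.

Well-watered leaves transpire and sit ~3 °C below air.  On Day 3, after
5.5 h of light, the control plant wilts: its leaf temperature relaxes
asymptotically (first-order kinetics) to thermal equilibrium while its leaf
angle collapses from ~55° to ~5° within an hour.  The treated plant keeps
stomatal control: its temperature rises along a near-linear trajectory
(the same asymptotic family with a tiny rate) and its angle declines slowly.
Re-watering at the start of Day 5 restores the treated plant over ~2.5 h;
the control remains at air-temperature equilibrium.

Every frame's true leaf temperature, leaf angle, leaf pixel mask and the
wilting-onset time are returned alongside the rendered frames, so the whole
downstream pipeline can be validated against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .exceptions import ConfigurationError, ValidationError
from .kinetics import AsymptoticParams, evaluate_asymptotic
from .scene import (
    TEMP_MAX,
    TEMP_MIN,
    FrameSequence,
    RegionOfInterest,
    ThermalFrame,
)

MIN_PER_DAY = 1440.0


def _default_control_kinetics() -> AsymptoticParams:
    # Asymptote 1 °C above daytime air so the wilted canopy reads as the ROI
    # maximum (post-stress leaves heat above ambient under the lamps);
    # onset value air-5 °C and the relaxation rate follow the observed wilt.
    return AsymptoticParams(theta1=34.0, theta2=6.0, theta3=0.523)


def _default_treated_kinetics() -> AsymptoticParams:
    # Near-linear regime: large nominal asymptote/amplitude, tiny rate.
    return AsymptoticParams(theta1=82.81, theta2=55.1, theta3=0.0098)


@dataclass
class ScenarioConfig:
    """Parameters of the synthetic stress-recovery experiment."""

    n_days: int = 5
    day_air_temp: float = 33.0
    night_air_temp: float = 27.0
    photoperiod: tuple[float, float] = (16.0, 8.0)   # light:dark hours
    cadence_min: float = 10.0
    leaf_air_offset_prestress: float = 3.0           # °C below air, daytime
    wilt_day: int = 3                                # 1-based day of control wilt
    wilt_hours_after_light: float = 5.5
    control_kinetics: AsymptoticParams = field(default_factory=_default_control_kinetics)
    treated_kinetics: AsymptoticParams = field(default_factory=_default_treated_kinetics)
    angle_day: float = 55.0                          # degrees, turgid daytime
    angle_night: float = 20.0                        # leaves in low night position
    noise_sd: float = 0.1                            # °C, sensor resolution
    seed: int = 0
    frame_shape: tuple[int, int] = (120, 160)
    # secondary scenario constants
    night_leaf_offset: float = 1.0       # °C below air at night (turgid plants)
    day1_transient_c: float = 2.0        # initial cooling amplitude on Day 1
    day1_transient_h: float = 2.0        # ~complete within this many hours
    kinetics_window_h: float = 8.0       # Eq. tracking window after onset
    treated_adapted_offset: float = 0.5  # °C below air, treated Day-4 plateau
    recovery_offset: float = 2.5         # °C below air after treated recovery
    recovery_h: float = 2.5              # re-watering to restored turgor
    wilt_collapse_min: float = 60.0      # control angle collapse duration
    angle_wilted: float = 5.0
    treated_angle_peak: float = 65.0     # short-term rise before onset
    treated_angle_day3_end: float = 35.0
    treated_angle_day4: float = 35.0
    treated_angle_recovered: float = 50.0
    leaf_length_px: int = 30
    leaf_width_px: int = 7

    def __post_init__(self) -> None:
        if abs(sum(self.photoperiod) - 24.0) > 1e-9:
            raise ValidationError("photoperiod hours must sum to 24")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        for name in ("day_air_temp", "night_air_temp"):
            v = getattr(self, name)
            if not (TEMP_MIN <= v <= TEMP_MAX):
                raise ValidationError(f"{name}={v} outside physical range")
        if not (1 <= self.wilt_day <= self.n_days):
            raise ValidationError("wilt_day must lie within the experiment")
        if self.n_days < 1 or self.cadence_min <= 0:
            raise ValidationError("need n_days >= 1 and positive cadence")

    # -- schedule helpers ----------------------------------------------

    @property
    def day_length_min(self) -> float:
        return self.photoperiod[0] * 60.0

    def schedule(self) -> list[tuple[float, float]]:
        return [(d * MIN_PER_DAY, d * MIN_PER_DAY + self.day_length_min)
                for d in range(self.n_days)]

    def is_day(self, t_min: float) -> bool:
        return (t_min % MIN_PER_DAY) < self.day_length_min

    @property
    def wilt_onset_min(self) -> float:
        return (self.wilt_day - 1) * MIN_PER_DAY + self.wilt_hours_after_light * 60.0

    @property
    def rewater_min(self) -> float:
        """Re-watering at light-on of Day 5; never, for shorter scenarios."""
        if self.n_days < 5:
            return float("inf")
        return 4 * MIN_PER_DAY


@dataclass
class SceneGroundTruth:
    """True per-frame state of the generated scene."""

    times_min: np.ndarray
    air_temp: np.ndarray
    leaf_temp: dict                 # plant -> array (°C)
    leaf_angle: dict                # plant -> array (degrees)
    leaf_masks: dict                # plant -> list of (rows, cols) arrays
    wilt_onset_min: dict            # plant -> minutes or None
    treatments: dict                # plant -> 'control' | 'treated'

    def as_dataframe(self):
        import pandas as pd

        parts = []
        for plant in self.leaf_temp:
            parts.append(pd.DataFrame({
                "time_min": self.times_min,
                "plant": plant,
                "treatment": self.treatments[plant],
                "air_temp": self.air_temp,
                "leaf_temp": self.leaf_temp[plant],
                "leaf_angle": self.leaf_angle[plant],
            }))
        return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Leaf rendering
# ---------------------------------------------------------------------------

def render_leaf_mask(angle_deg: float, stem_anchor: tuple[int, int],
                     length_px: int, width_px: int,
                     frame_shape: tuple[int, int],
                     lateral_sign: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Pixels of a straight elongated leaf attached to a vertical stem.

    The leaf's principal axis makes ``angle_deg`` with the *downward*
    vertical stem axis: 0° hangs along the stem, 90° is horizontal.
    ``lateral_sign`` chooses which side of the stem the leaf extends to.
    Returns (rows, cols) arrays; raises if the leaf would be clipped by the
    frame boundary.
    """
    if not (0.0 <= angle_deg <= 120.0):
        raise ValidationError(f"angle {angle_deg}° outside [0, 120]")
    nr, nc = frame_shape
    a = np.deg2rad(angle_deg)
    # downward vertical is +row; rotate toward +/- col
    axis = np.array([np.cos(a), lateral_sign * np.sin(a)])
    r0, c0 = stem_anchor
    pad = length_px + width_px
    rows, cols = np.mgrid[max(r0 - pad, 0):min(r0 + pad + 1, nr),
                          max(c0 - pad, 0):min(c0 + pad + 1, nc)]
    dr = rows - r0
    dc = cols - c0
    along = dr * axis[0] + dc * axis[1]
    across = -dr * axis[1] + dc * axis[0]
    inside = (along >= 0) & (along <= length_px) & (np.abs(across) <= width_px / 2.0)
    rr, cc = rows[inside], cols[inside]
    if rr.size == 0:
        raise ValidationError("degenerate leaf mask (zero pixels)")
    # clipping check: the ideal endpoints must lie inside the frame
    tip = np.array([r0, c0]) + length_px * axis
    if not (0 <= tip[0] < nr and 0 <= tip[1] < nc and 0 <= r0 < nr and 0 <= c0 < nc):
        raise ValidationError(
            f"leaf mask clipped by frame boundary (tip {tip}, shape {frame_shape})"
        )
    return rr, cc


# ---------------------------------------------------------------------------
# Ground-truth trajectories
# ---------------------------------------------------------------------------

def _air_trajectory(cfg: ScenarioConfig, t: np.ndarray) -> np.ndarray:
    return np.where([cfg.is_day(v) for v in t], cfg.day_air_temp, cfg.night_air_temp)


def _leaf_trajectory(cfg: ScenarioConfig, t: np.ndarray, air: np.ndarray,
                     treatment: str) -> np.ndarray:
    """True leaf temperature for one plant at every frame time."""
    kin = cfg.control_kinetics if treatment == "control" else cfg.treated_kinetics
    onset = cfg.wilt_onset_min
    onset_value = kin.theta1 - kin.theta2     # model value at hour 0
    leaf = np.empty_like(t, dtype=float)
    for i, ti in enumerate(t):
        a = air[i]
        day_idx = int(ti // MIN_PER_DAY)           # 0-based day
        in_day = cfg.is_day(ti)
        h_in_day = (ti % MIN_PER_DAY) / 60.0
        post_onset = ti >= onset
        wilted = treatment == "control" and post_onset
        if not in_day:
            leaf[i] = a if wilted else a - cfg.night_leaf_offset
            continue
        if day_idx == 0 and not post_onset:
            # settling transient after initial soil saturation
            tau = cfg.day1_transient_h / 3.0
            leaf[i] = (a - cfg.leaf_air_offset_prestress
                       + cfg.day1_transient_c * np.exp(-h_in_day / tau))
        elif day_idx < cfg.wilt_day - 1:
            leaf[i] = a - cfg.leaf_air_offset_prestress
        elif day_idx == cfg.wilt_day - 1 and not post_onset:
            # pre-wilt stomatal surge: offset deepens toward the hour-0 value
            frac = h_in_day / cfg.wilt_hours_after_light
            start = a - cfg.leaf_air_offset_prestress
            leaf[i] = start + frac * (onset_value - start)
        elif treatment == "control":
            leaf[i] = evaluate_asymptotic(kin, (ti - onset) / 60.0)
        else:
            h_since = (ti - onset) / 60.0
            if h_since <= cfg.kinetics_window_h:
                leaf[i] = evaluate_asymptotic(kin, h_since)
            elif ti < cfg.rewater_min:
                if day_idx == cfg.wilt_day - 1:
                    leaf[i] = evaluate_asymptotic(kin, cfg.kinetics_window_h)
                else:
                    leaf[i] = a - cfg.treated_adapted_offset
            else:
                h_rec = (ti - cfg.rewater_min) / 60.0
                frac = min(h_rec / cfg.recovery_h, 1.0)
                start = cfg.treated_adapted_offset
                off = start + frac * (cfg.recovery_offset - start)
                leaf[i] = a - off
    return leaf


def _angle_trajectory(cfg: ScenarioConfig, t: np.ndarray, treatment: str) -> np.ndarray:
    onset = cfg.wilt_onset_min
    angle = np.empty_like(t, dtype=float)
    for i, ti in enumerate(t):
        in_day = cfg.is_day(ti)
        day_idx = int(ti // MIN_PER_DAY)
        h_in_day = (ti % MIN_PER_DAY) / 60.0
        if treatment == "control":
            if ti >= onset + cfg.wilt_collapse_min:
                angle[i] = cfg.angle_wilted
            elif ti >= onset:
                frac = (ti - onset) / cfg.wilt_collapse_min
                angle[i] = cfg.angle_day + frac * (cfg.angle_wilted - cfg.angle_day)
            elif not in_day:
                angle[i] = cfg.angle_night
            else:
                angle[i] = cfg.angle_day
        else:
            if not in_day:
                angle[i] = cfg.angle_night
            elif day_idx < cfg.wilt_day - 1:
                angle[i] = cfg.angle_day
            elif day_idx == cfg.wilt_day - 1:
                if ti < onset:
                    # short-term angle rise under early stress
                    frac = min(h_in_day / 2.0, 1.0)
                    angle[i] = cfg.angle_day + frac * (cfg.treated_angle_peak
                                                       - cfg.angle_day)
                else:
                    day_end_h = cfg.photoperiod[0]
                    frac = (h_in_day - cfg.wilt_hours_after_light) / \
                        (day_end_h - cfg.wilt_hours_after_light)
                    angle[i] = cfg.treated_angle_peak + frac * (
                        cfg.treated_angle_day3_end - cfg.treated_angle_peak)
            elif ti < cfg.rewater_min:
                angle[i] = cfg.treated_angle_day4
            else:
                frac = min((ti - cfg.rewater_min) / 60.0 / cfg.recovery_h, 1.0)
                angle[i] = cfg.treated_angle_day4 + frac * (
                    cfg.treated_angle_recovered - cfg.treated_angle_day4)
    return angle


# ---------------------------------------------------------------------------
# Scene assembly
# ---------------------------------------------------------------------------

def default_rois(cfg: ScenarioConfig) -> list[RegionOfInterest]:
    nr, nc = cfg.frame_shape
    if nr < 110 or nc < 160:
        raise ConfigurationError(
            f"default ROI layout needs a frame of at least 110x160, got {cfg.frame_shape}"
        )
    return [
        RegionOfInterest("control", "rectangle", (30, 8, 110, 72), role="plant",
                         stem_anchor=(72, 40), treatment="control"),
        RegionOfInterest("treated", "rectangle", (30, 88, 110, 152), role="plant",
                         stem_anchor=(72, 120), treatment="treated"),
        RegionOfInterest("air", "point_cursor", (54, 78, 57, 81), role="air_cursor"),
    ]


def generate_sequence(cfg: ScenarioConfig | None = None,
                      rois: Iterable[RegionOfInterest] | None = None,
                      ) -> tuple[FrameSequence, SceneGroundTruth]:
    """Render the full ground-truthed frame sequence for a scenario.

    Identical config and seed give bit-identical output.
    """
    cfg = cfg or ScenarioConfig()
    rois = list(rois) if rois is not None else default_rois(cfg)
    plants = [r for r in rois if r.role == "plant"]
    if not plants:
        raise ConfigurationError("scenario needs at least one plant ROI")
    for i, a in enumerate(plants):
        for b in plants[i + 1:]:
            ar0, ac0, ar1, ac1 = a.bounds
            br0, bc0, br1, bc1 = b.bounds
            if ar0 < br1 and br0 < ar1 and ac0 < bc1 and bc0 < ac1:
                raise ConfigurationError(
                    f"plant ROIs {a.name!r} and {b.name!r} overlap")

    rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, cfg.n_days * MIN_PER_DAY, cfg.cadence_min)
    air = _air_trajectory(cfg, t)

    leaf_temp, leaf_angle, masks, onsets, treatments = {}, {}, {}, {}, {}
    for k, roi in enumerate(plants):
        treatment = roi.treatment or ("control" if k == 0 else "treated")
        treatments[roi.name] = treatment
        leaf_temp[roi.name] = _leaf_trajectory(cfg, t, air, treatment)
        leaf_angle[roi.name] = _angle_trajectory(cfg, t, treatment)
        onsets[roi.name] = cfg.wilt_onset_min if treatment == "control" else None
        if roi.stem_anchor is None:
            raise ConfigurationError(f"plant ROI {roi.name!r} lacks a stem anchor")

    nr, nc = cfg.frame_shape
    frames: list[ThermalFrame] = []
    all_masks: dict[str, list] = {p.name: [] for p in plants}
    n_digits = max(4, len(str(t.size)))
    for i, ti in enumerate(t):
        grid = np.full((nr, nc), air[i], dtype=float)
        if cfg.noise_sd > 0:
            grid += rng.normal(0.0, cfg.noise_sd, size=grid.shape)
        for k, roi in enumerate(plants):
            sign = 1 if k % 2 == 0 else -1
            rr, cc = render_leaf_mask(
                leaf_angle[roi.name][i], roi.stem_anchor,
                cfg.leaf_length_px, cfg.leaf_width_px, cfg.frame_shape,
                lateral_sign=sign)
            grid[rr, cc] = leaf_temp[roi.name][i]
            if cfg.noise_sd > 0:
                grid[rr, cc] += rng.normal(0.0, cfg.noise_sd, size=rr.shape)
            all_masks[roi.name].append((rr, cc))
        np.clip(grid, TEMP_MIN, TEMP_MAX, out=grid)
        frames.append(ThermalFrame(
            temperatures=grid, timestamp_min=float(ti),
            frame_id=f"frame_{i:0{n_digits}d}"))

    sequence = FrameSequence(frames=frames, cadence_min=cfg.cadence_min,
                             rois=rois, day_night_schedule=cfg.schedule())
    truth = SceneGroundTruth(
        times_min=t, air_temp=air, leaf_temp=leaf_temp, leaf_angle=leaf_angle,
        leaf_masks=all_masks, wilt_onset_min=onsets, treatments=treatments)
    return sequence, truth
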