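"""Thermal stress indices: CWSI, the relative stomatal-conductance index Ig,
and the linear Ig -> stomatal conductance calibration.

CWSI = (T_canopy - T_nws) / (T_max - T_nws) is 0 at the non-water-stressed
(well-watered) reference and 1 at the dry reference.  Ig =
(T_dry - T_leaf) / (T_leaf - T_wet) is 0 for a dry canopy and grows without
bound as the leaf approaches the wet reference; under constant boundary
conditions it is proportional to stomatal conductance, gs = G * Ig.

Reference temperatures must be supplied: they are experimental inputs (wet
and dry reference surfaces), not derivable from the imagery itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError, ValidationError


@dataclass(frozen=True)
class IndexReferences:
    """Reference temperatures (°C) and the optional conductance slope G."""

    t_dry: float          # dry-surface reference (T_max of CWSI)
    t_wet: float          # wet / non-water-stressed reference (T_nws)
    g_slope: float | None = None   # (m/s) per unit Ig

    def __post_init__(self) -> None:
        if not self.t_wet < self.t_dry:
            raise ValidationError(
                f"degenerate references: t_wet {self.t_wet} >= t_dry {self.t_dry}")
        if self.g_slope is not None and self.g_slope <= 0:
            raise ValidationError("calibration slope G must be positive")


def cwsi(t_canopy, t_nws, t_max):
    """Crop water stress index (unclamped; out-of-range values are the
    caller's diagnostic that the references do not bracket the canopy)."""
    t_canopy = np.asarray(t_canopy, dtype=float)
    if np.any(np.asarray(t_max) <= np.asarray(t_nws)):
        raise ValidationError("degenerate references: T_max <= T_nws")
    return (t_canopy - t_nws) / (t_max - t_nws)


def ig_index(t_leaf, t_dry, t_wet):
    """Index of relative stomatal conductance (T_dry - T_leaf)/(T_leaf - T_wet)."""
    t_leaf = np.asarray(t_leaf, dtype=float)
    if np.any(np.asarray(t_dry) <= np.asarray(t_wet)):
        raise ValidationError("degenerate references: T_dry <= T_wet")
    if np.any(t_leaf <= t_wet):
        raise DomainError("Ig undefined: T_leaf <= T_wet (denominator <= 0)")
    return (t_dry - t_leaf) / (t_leaf - t_wet)


def stomatal_conductance(ig, g_slope: float):
    """gs = G * Ig (m/s); linear calibration through the origin."""
    if g_slope <= 0:
        raise ValidationError("calibration slope G must be positive")
    return g_slope * np.asarray(ig, dtype=float)


def compute_indices(series: pd.DataFrame, refs: IndexReferences) -> pd.DataFrame:
    """Per-frame index table from a plant time series.

    Uses ``leaf_temp`` for both CWSI (canopy) and Ig (leaf), with
    ``refs.t_wet`` as the non-water-stressed/wet reference and ``refs.t_dry``
    as the dry/maximum reference.  CWSI values outside [0, 1] are flagged,
    not clamped; Ig is missing where its domain condition fails.
    """
    out = series[["time_min", "plant", "leaf_temp", "air_temp"]].copy()
    out["delta"] = out["leaf_temp"] - out["air_temp"]
    out["cwsi"] = cwsi(out["leaf_temp"].to_numpy(), refs.t_wet, refs.t_dry)
    out["cwsi_out_of_range"] = (out["cwsi"] < 0) | (out["cwsi"] > 1)
    leaf = out["leaf_temp"].to_numpy()
    ig = np.full(leaf.shape, np.nan)
    ok = leaf > refs.t_wet
    ig[ok] = (refs.t_dry - leaf[ok]) / (leaf[ok] - refs.t_wet)
    out["ig"] = ig
    if refs.g_slope is not None:
        out["gs"] = stomatal_conductance(ig, refs.g_slope)
    return out


def demo_references(series: pd.DataFrame,
                    day1_end_min: float = 960.0) -> IndexReferences:
    """Convention for demo pipelines lacking measured references.

    T_dry/T_max := mean daytime air temperature; T_wet/T_nws := mean Day-1
    leaf temperature (well-watered baseline).  A convention, not a measured
    reference protocol.
    """
    day1 = series[series["time_min"] < day1_end_min]
    t_wet = float(day1["leaf_temp"].mean())
    t_dry = float(series["air_temp"].max())
    if not t_wet < t_dry:
        t_wet = t_dry - 1.0
    return IndexReferences(t_dry=t_dry, t_wet=t_wet)
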