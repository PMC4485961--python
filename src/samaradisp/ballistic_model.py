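"""Ballistic comparison model: d = U * H / V_t.

A fruit released at height H into a constant lateral wind U falls at its
terminal velocity V_t, so it travels horizontally for H / V_t seconds and
lands U * H / V_t metres away.  For auto-gyrating samaras, descent rate is
well described as linear in the square root of wing loading (weight per
wing area), V_t = a + b * sqrt(WL).

The (a, b) line for "helicopter"-class fruit comes from published drop
experiments whose coefficients are not restated here; instead
``calibrate_from_anchors`` recovers the line from any >= 2 species whose
sqrt-wing-loading and predicted ballistic distance are both known (each
anchor implies V_t = U * H / d), so a published comparison table can be
reproduced and extended from two of its own rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dispersal_lmm import ModelParameters, predict_median_distance
from .morphometrics import iwl_to_sqrt_wing_loading

__all__ = [
    "BallisticParams",
    "CalibrationError",
    "terminal_velocity",
    "ballistic_distance",
    "calibrate_from_anchors",
    "comparison_table",
]


class CalibrationError(ValueError):
    """Raised when the terminal-velocity line cannot be determined."""


@dataclass(frozen=True)
class BallisticParams:
    """Terminal-velocity line and release conditions."""

    vt_intercept: float  # a, m/s
    vt_slope: float  # b, m/s per sqrt(mdyn/cm^2)
    release_height: float = 30.0  # H, m
    wind_speed: float = 1.72  # U, m/s
    max_calibration_residual: float = 0.0  # m, diagnostics from least squares

    def __post_init__(self) -> None:
        if not (self.release_height > 0):
            raise CalibrationError("release_height must be positive")
        if self.wind_speed < 0:
            raise CalibrationError("wind_speed must be non-negative")


def terminal_velocity(params: BallisticParams, sqrt_wl: float) -> float:
    """V_t = a + b * sqrt(WL); errors if outside the calibrated range (V_t <= 0)."""
    sqrt_wl = float(sqrt_wl)
    if not (sqrt_wl > 0) or not math.isfinite(sqrt_wl):
        raise CalibrationError(f"sqrt_wl must be positive, got {sqrt_wl}")
    vt = params.vt_intercept + params.vt_slope * sqrt_wl
    if vt <= 0:
        raise CalibrationError(
            f"terminal velocity {vt:.4f} m/s <= 0 at sqrt_wl={sqrt_wl}: "
            "outside the calibration range"
        )
    return vt


def ballistic_distance(params: BallisticParams, vt: float) -> float:
    """d = U * H / V_t, metres."""
    if not (vt > 0):
        raise CalibrationError(f"terminal velocity must be positive, got {vt}")
    return params.wind_speed * params.release_height / vt


def calibrate_from_anchors(
    anchor_rows: Sequence[tuple[float, float]],
    wind_speed: float = 1.72,
    release_height: float = 30.0,
) -> BallisticParams:
    """Recover (a, b) from anchor (sqrt_wl, ballistic distance) pairs.

    Each anchor implies V_t = U * H / d; two anchors give an exact solve,
    more give least squares.  The largest absolute distance residual over
    the anchors is stored as a calibration diagnostic.
    """
    rows = [(float(s), float(d)) for s, d in anchor_rows]
    if len(rows) < 2:
        raise CalibrationError("need >= 2 anchor rows")
    s = np.array([r[0] for r in rows])
    d = np.array([r[1] for r in rows])
    if np.any(s <= 0) or np.any(d <= 0):
        raise CalibrationError("anchor sqrt_wl and distances must be positive")
    if np.ptp(s) == 0:
        raise CalibrationError("anchor sqrt_wl values are coincident")
    vt = wind_speed * release_height / d
    A = np.column_stack([np.ones_like(s), s])
    (a, b), *_ = np.linalg.lstsq(A, vt, rcond=None)
    params = BallisticParams(
        vt_intercept=float(a),
        vt_slope=float(b),
        release_height=release_height,
        wind_speed=wind_speed,
    )
    pred = np.array([ballistic_distance(params, terminal_velocity(params, x)) for x in s])
    object.__setattr__(params, "max_calibration_residual", float(np.max(np.abs(pred - d))))
    return params


def comparison_table(
    params_lmm: ModelParameters,
    ballistic: BallisticParams,
    species_rows: Sequence[tuple],
) -> pd.DataFrame:
    """Side-by-side LMM-median vs ballistic distances per species.

    ``species_rows`` are ``(name, mean_iwl)`` or ``(name, mean_iwl, sqrt_wl)``
    tuples; when a printed sqrt-wing-loading is supplied it is used directly
    (it may embed per-fruit averaging), otherwise sqrt_wl is derived from the
    mean IWL.  Wingless species (IWL = 0) get NaN in the ballistic column.
    """
    records = []
    for row in species_rows:
        name, mean_iwl = row[0], float(row[1])
        sqrt_wl = float(row[2]) if len(row) > 2 and row[2] is not None else math.nan
        if math.isnan(sqrt_wl) and mean_iwl > 0:
            sqrt_wl = iwl_to_sqrt_wing_loading(mean_iwl).sqrt_wing_loading
        lmm_d = predict_median_distance(params_lmm, mean_iwl, ballistic.wind_speed)
        if mean_iwl == 0 or math.isnan(sqrt_wl):
            bal_d = math.nan
        else:
            bal_d = ballistic_distance(ballistic, terminal_velocity(ballistic, sqrt_wl))
        records.append(
            {
                "species": name,
                "mean_iwl_cm2_per_g": mean_iwl,
                "sqrt_wing_loading": sqrt_wl if mean_iwl > 0 else math.nan,
                "lmm_median_m": lmm_d,
                "ballistic_m": bal_d,
                "ratio_ballistic_to_lmm": bal_d / lmm_d if not math.isnan(bal_d) else math.nan,
            }
        )
    return pd.DataFrame(records)
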