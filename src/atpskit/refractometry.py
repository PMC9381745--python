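"""Refractometric determination of polymer content in equilibrium phases.

For dilute aqueous polymer + salt solutions the refractive index is linear
in both solute mass fractions,

    n_D = n0 + a_p * w_p + a_s * w_s,

with n0 the refractive index of pure water (1.3325 at 298.15 K).  The two
coefficients are calibrated from single-solute dilution series by
through-origin least squares on (n_D - n0); the polymer fraction of an
unknown phase then follows by inversion given its refractive index and an
independently assayed salt fraction (e.g. from flame photometry).

Mass fractions here are on the fractional (0-1) scale, the natural scale of
dilute calibration series; conversion from wt% happens at I/O boundaries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "RefractometryCalibration",
    "RefractiveReading",
    "calibrate",
    "invert_to_polymer_fraction",
    "N0_WATER",
]

#: Refractive index of pure water at 298.15 K.
N0_WATER = 1.3325


@dataclass(frozen=True)
class RefractometryCalibration:
    """Calibrated coefficients of the linear refractive-index model."""

    n0: float
    a_p: float
    a_s: float
    r_squared_p: float
    r_squared_s: float
    valid_range_p: tuple[float, float]
    valid_range_s: tuple[float, float]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class RefractiveReading:
    """A measured refractive index with its independently assayed salt fraction."""

    n_d: float
    w_s_known: float = 0.0

    def __post_init__(self) -> None:
        if not self.n_d > 1:
            raise ValueError(f"refractive index must exceed 1, got {self.n_d}")


def _through_origin(w: np.ndarray, dn: np.ndarray) -> tuple[float, float]:
    """Slope and r-squared of the no-intercept regression dn = a * w."""
    if np.ptp(w) == 0:
        raise ValueError("degenerate calibration series: all mass fractions equal")
    a = float(np.dot(w, dn) / np.dot(w, w))
    ss_tot = float(np.dot(dn, dn))
    r2 = 1.0 if ss_tot == 0 else float(1.0 - np.sum((dn - a * w) ** 2) / ss_tot)
    return a, r2


def calibrate(series_p, series_s, n0: float = N0_WATER) -> RefractometryCalibration:
    """Estimate a_p and a_s from single-solute dilution series.

    Each series is an iterable of (mass_fraction, n_d) pairs.  The model
    intercept is fixed at ``n0`` (itself measured on pure water), so each
    coefficient is the through-origin OLS slope of (n_d - n0) on w.  The
    valid ranges are the spans of the calibration mass fractions.
    """
    out = {}
    for label, series in (("p", series_p), ("s", series_s)):
        w = np.array([p[0] for p in series], dtype=float)
        nd = np.array([p[1] for p in series], dtype=float)
        if w.size < 2:
            raise ValueError(f"series_{label}: need >= 2 calibration points")
        a, r2 = _through_origin(w, nd - n0)
        out[label] = (a, r2, (float(w.min()), float(w.max())))
    return RefractometryCalibration(
        n0=n0,
        a_p=out["p"][0], a_s=out["s"][0],
        r_squared_p=out["p"][1], r_squared_s=out["s"][1],
        valid_range_p=out["p"][2], valid_range_s=out["s"][2],
    )


def invert_to_polymer_fraction(
    reading: RefractiveReading,
    cal: RefractometryCalibration,
    negative_tolerance: float = 1e-6,
) -> float:
    """Polymer mass fraction from a refractive reading: invert the linear model.

    w_p = (n_d - n0 - a_s * w_s_known) / a_p.  Warns when the result or the
    salt fraction falls outside the calibrated range (extrapolation);
    raises when ``a_p`` is 0 or the inversion is negative beyond tolerance.
    """
    if cal.a_p == 0:
        raise ValueError("calibration has a_p = 0: inversion unusable")
    w_p = (reading.n_d - cal.n0 - cal.a_s * reading.w_s_known) / cal.a_p
    if w_p < -negative_tolerance:
        raise ValueError(f"inversion gives negative polymer fraction {w_p:.4g}")
    w_p = max(w_p, 0.0)
    lo_p, hi_p = cal.valid_range_p
    lo_s, hi_s = cal.valid_range_s
    if not lo_p <= w_p <= hi_p:
        warnings.warn(
            f"inverted w_p={w_p:.4g} outside calibrated range [{lo_p:.4g}, {hi_p:.4g}]",
            UserWarning, stacklevel=2,
        )
    if reading.w_s_known and not lo_s <= reading.w_s_known <= hi_s:
        warnings.warn(
            f"w_s={reading.w_s_known:.4g} outside calibrated range [{lo_s:.4g}, {hi_s:.4g}]",
            UserWarning, stacklevel=2,
        )
    return float(w_p)
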