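"""Shared domain types, unit conventions and goodness-of-fit utilities.

All compositions in the public API are ternary (polymer, salt, water)
mass fractions on the weight-percent scale (0-100), the convention of the
liquid-liquid-equilibrium tables this package analyses.  Helpers convert
to the fractional (0-1) scale where a model requires it (e.g. the
``1 - w`` terms of the Othmer-Tobias linearization) and to molality for
Setschenow-type salting-out correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Composition",
    "TieLine",
    "GoodnessOfFit",
    "SpeciesInfo",
    "ClosureError",
    "ClosureWarning",
    "validate_composition",
    "mass_fraction_to_molality",
    "molality_to_mass_fraction",
    "compute_sd",
    "wtpct_to_fraction",
    "fraction_to_wtpct",
    "PEG600",
    "KOH",
]

#: Default mass-balance closure tolerance in wt%.  Components of a ternary
#: mixture must sum to 100 within this tolerance to be accepted silently;
#: between 1x and 2x the tolerance a warning is emitted, beyond 2x it is an
#: error.  The default reflects the ~0.8 wt% per-component uncertainty
#: typical of gravimetric/refractometric phase analysis.
DEFAULT_CLOSURE_TOL = 0.5


class ClosureError(ValueError):
    """Raised when a ternary composition violates mass-balance closure."""


class ClosureWarning(UserWarning):
    """Emitted when closure holds only loosely (within 2x tolerance)."""


@dataclass(frozen=True)
class SpeciesInfo:
    """A chemical species with the molar mass needed for molality conversion."""

    name: str
    molar_mass: float  # g/mol

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValueError(f"molar_mass must be positive, got {self.molar_mass}")


#: Poly(ethylene glycol) with nominal molar mass 600 g/mol.
PEG600 = SpeciesInfo("PEG600", 600.0)
#: Potassium hydroxide, molar mass from atomic masses.
KOH = SpeciesInfo("KOH", 56.11)


@dataclass(frozen=True)
class Composition:
    """Ternary (polymer, salt, water) composition in wt% (0-100).

    ``w_w`` may be omitted, in which case it is filled by difference
    (``100 - w_p - w_s``), the convention of equilibrium tables that print
    only the two solute columns.
    """

    w_p: float
    w_s: float
    w_w: float | None = None

    def __post_init__(self) -> None:
        if self.w_w is None:
            object.__setattr__(self, "w_w", 100.0 - self.w_p - self.w_s)

    @property
    def closure_residual(self) -> float:
        """Signed deviation of the component sum from 100 wt%."""
        return self.w_p + self.w_s + self.w_w - 100.0

    def as_fractions(self) -> tuple[float, float, float]:
        """Return (polymer, salt, water) on the 0-1 mass-fraction scale."""
        return self.w_p / 100.0, self.w_s / 100.0, self.w_w / 100.0


def validate_composition(
    c: Composition, tolerance: float = DEFAULT_CLOSURE_TOL
) -> Composition:
    """Validate component ranges and mass-balance closure of ``c``.

    Returns ``c`` unchanged when all invariants hold.  A closure residual
    between ``tolerance`` and ``2 * tolerance`` raises a
    :class:`ClosureWarning`; beyond ``2 * tolerance`` (or any component
    outside [0, 100]) the composition is rejected.
    """
    for name, w in (("w_p", c.w_p), ("w_s", c.w_s), ("w_w", c.w_w)):
        if not np.isfinite(w):
            raise ValueError(f"{name} is not finite: {w}")
        if w < 0.0 or w > 100.0:
            raise ValueError(f"{name}={w} outside the [0, 100] wt% range")
    resid = abs(c.closure_residual)
    if resid > 2.0 * tolerance:
        raise ClosureError(
            f"components sum to {100.0 + c.closure_residual:.4g} wt%; "
            f"|residual| {resid:.4g} exceeds 2x tolerance {tolerance:.4g}"
        )
    if resid > tolerance:
        warnings.warn(
            f"loose mass-balance closure: |residual| {resid:.4g} wt% "
            f"(tolerance {tolerance:.4g})",
            ClosureWarning,
            stacklevel=2,
        )
    return c


@dataclass(frozen=True)
class TieLine:
    """A tie-line: overall mixture plus the two coexisting phase compositions.

    Convention: ``top`` is the polymer-rich phase, ``bottom`` the salt-rich
    phase.  Inputs violating the convention are swapped with a warning at
    construction (robustness to column order in user files).
    """

    overall: Composition
    top: Composition
    bottom: Composition

    def __post_init__(self) -> None:
        if self.top.w_p < self.bottom.w_p and self.bottom.w_s < self.top.w_s:
            warnings.warn(
                "tie-line phases violate the polymer-rich-top convention; "
                "swapping top and bottom",
                UserWarning,
                stacklevel=2,
            )
            top, bottom = self.bottom, self.top
            object.__setattr__(self, "top", top)
            object.__setattr__(self, "bottom", bottom)
        if not (self.top.w_p >= self.bottom.w_p and self.bottom.w_s >= self.top.w_s):
            raise ValueError(
                "tie-line phases violate the phase-labelling convention: "
                "top must be polymer-rich and bottom salt-rich"
            )

    @property
    def tll(self) -> float:
        """Tie-line length in wt% (Euclidean, in the (w_s, w_p) plane)."""
        return float(
            np.hypot(self.top.w_p - self.bottom.w_p, self.top.w_s - self.bottom.w_s)
        )

    @property
    def delta_w_p(self) -> float:
        """Polymer composition difference top - bottom (wt%), >= 0."""
        return self.top.w_p - self.bottom.w_p


@dataclass(frozen=True)
class GoodnessOfFit:
    """Root-mean-square residual diagnostics of a fitted model.

    ``sd`` is the RMS deviation sqrt(sum((obs - pred)^2) / n) in the fitted
    variable's own units, with divisor ``n`` (the convention of the
    phase-equilibrium correlation literature).
    """

    sd: float
    n_points: int
    residuals: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def compute_sd(observed, predicted) -> GoodnessOfFit:
    """RMS residual between observed and predicted values.

    Raises on empty or length-mismatched input.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.ndim != 1 or pred.ndim != 1:
        obs, pred = obs.ravel(), pred.ravel()
    if obs.size == 0:
        raise ValueError("cannot compute sd of empty vectors")
    if obs.size != pred.size:
        raise ValueError(f"length mismatch: {obs.size} observed vs {pred.size} predicted")
    resid = obs - pred
    sd = float(np.sqrt(np.mean(resid**2)))
    return GoodnessOfFit(sd=sd, n_points=obs.size, residuals=resid)


def mass_fraction_to_molality(
    w_solute: float, w_water: float, species: SpeciesInfo
) -> float:
    """Convert a wt% solute fraction to molality (mol solute / kg water).

    Masses are taken per 100 g of solution: ``(w_solute / M) / (w_water / 1000)``.
    """
    w_solute = np.asarray(w_solute, dtype=float)
    w_water = np.asarray(w_water, dtype=float)
    if np.any(w_water <= 0):
        raise ValueError("water mass fraction must be positive for molality")
    out = (w_solute / species.molar_mass) / (w_water / 1000.0)
    return float(out) if out.ndim == 0 else out


def molality_to_mass_fraction(
    molality: float, w_water: float, species: SpeciesInfo
) -> float:
    """Inverse of :func:`mass_fraction_to_molality` at fixed water wt%."""
    if w_water <= 0:
        raise ValueError("water mass fraction must be positive")
    return molality * species.molar_mass * (w_water / 1000.0)


def wtpct_to_fraction(w: float) -> float:
    """wt% (0-100) -> mass fraction (0-1)."""
    return np.asarray(w, dtype=float) / 100.0


def fraction_to_wtpct(f: float) -> float:
    """Mass fraction (0-1) -> wt% (0-100)."""
    return np.asarray(f, dtype=float) * 100.0
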