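"""Tie-line characterization and consistency correlations.

Given coexisting-phase compositions of a polymer-salt aqueous two-phase
system this module computes tie-line lengths, checks the lever-rule mass
balance of the overall mixture, and fits the three classical consistency
correlations:

* Othmer-Tobias:  (1 - w_p_top)/w_p_top = k * ((1 - w_s_bot)/w_s_bot)**n
* Bancroft:       w_w_bot/w_s_bot = k1 * (w_w_top/w_p_top)**r
* Setschenow:     ln(Cp_top/Cp_bot) = k_p + k_s * (Cs_bot - Cs_top)

The first two are fitted on base-10 log-linearized fractional (0-1)
compositions, as the consistency plots are traditionally constructed; the
Setschenow correlation uses natural logs and phase molalities (mol/kg of
water in that phase).  A linear log-log plot (high r-squared) indicates an
internally consistent tie-line data set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    GoodnessOfFit,
    SpeciesInfo,
    TieLine,
    compute_sd,
    mass_fraction_to_molality,
)

__all__ = [
    "OthmerTobiasFit",
    "BancroftFit",
    "SetschenowFit",
    "LeverRuleReport",
    "compute_tll",
    "lever_rule_check",
    "fit_othmer_tobias",
    "fit_bancroft",
    "fit_setschenow",
]

#: Default r-squared gate above which a linearized consistency regression is
#: reported as "consistent".
DEFAULT_R2_GATE = 0.95


@dataclass(frozen=True)
class OthmerTobiasFit:
    k: float
    n: float
    fit: GoodnessOfFit
    r_squared: float

    @property
    def consistent(self) -> bool:
        return self.r_squared >= DEFAULT_R2_GATE


@dataclass(frozen=True)
class BancroftFit:
    k1: float
    r: float
    fit: GoodnessOfFit
    r_squared: float

    @property
    def consistent(self) -> bool:
        return self.r_squared >= DEFAULT_R2_GATE


@dataclass(frozen=True)
class SetschenowFit:
    """Salting-out fit; ``k_s`` (kg/mol) > 0 for a salting-out system."""

    k_p: float
    k_s: float
    fit: GoodnessOfFit


@dataclass(frozen=True)
class LeverRuleReport:
    """Mass-balance diagnostics of one overall composition against its tie-line.

    ``phase_fraction_top`` is the inferred mass fraction of the total mixture
    residing in the polymer-rich top phase (average of the per-component
    lever parameters); ``max_deviation`` is the perpendicular distance (wt%)
    of the overall point from the tie-line segment in the (w_s, w_p) plane.
    """

    phase_fraction_top: float
    component_fractions: dict[str, float]
    max_deviation: float
    passed: bool


def compute_tll(t: TieLine) -> float:
    """Tie-line length: Euclidean distance between the phase compositions.

    TLL = sqrt((w_p_top - w_p_bot)**2 + (w_s_top - w_s_bot)**2), in wt%.
    """
    return t.tll


def lever_rule_check(t: TieLine, tolerance: float = 0.8) -> LeverRuleReport:
    """Check that the overall composition lies on the tie-line segment.

    For each solute the lever parameter f = (overall - bottom)/(top - bottom)
    estimates the top-phase mass fraction; their agreement and the
    perpendicular distance of the overall point from the segment measure
    internal consistency.  Passes iff ``max_deviation <= tolerance`` (wt%)
    and the inferred phase split lies in [0, 1].
    """
    top = np.array([t.top.w_s, t.top.w_p])
    bot = np.array([t.bottom.w_s, t.bottom.w_p])
    ovl = np.array([t.overall.w_s, t.overall.w_p])
    seg = top - bot
    seg_len = np.linalg.norm(seg)
    if seg_len == 0:
        raise ValueError("degenerate tie-line (TLL = 0): lever rule undefined")
    fractions: dict[str, float] = {}
    for i, name in enumerate(("salt", "polymer")):
        if seg[i] != 0:
            fractions[name] = float((ovl[i] - bot[i]) / seg[i])
    # perpendicular distance from the overall point to the infinite tie-line
    proj = np.dot(ovl - bot, seg) / seg_len**2
    deviation = float(np.linalg.norm(ovl - (bot + proj * seg)))
    f_top = float(np.mean(list(fractions.values())))
    passed = deviation <= tolerance and 0.0 <= f_top <= 1.0
    return LeverRuleReport(
        phase_fraction_top=f_top,
        component_fractions=fractions,
        max_deviation=deviation,
        passed=passed,
    )


def _linear_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS y = intercept + slope * x; returns (slope, intercept, r_squared)."""
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: all tie-lines give the same x")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = intercept + slope * x
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else float(1.0 - ss_res / ss_tot)
    return float(slope), float(intercept), r2


def fit_othmer_tobias(tielines) -> OthmerTobiasFit:
    """Othmer-Tobias consistency regression on log-linearized compositions.

    Fits log10((1-f_p_top)/f_p_top) against log10((1-f_s_bot)/f_s_bot) with
    fractional compositions f = w/100; ``k = 10**intercept``, ``n = slope``.
    ``sd`` is reported on the back-transformed (ratio) scale.
    """
    tl = list(tielines)
    if len(tl) < 2:
        raise ValueError("need >= 2 tie-lines")
    fp_top = np.array([t.top.w_p for t in tl]) / 100.0
    fs_bot = np.array([t.bottom.w_s for t in tl]) / 100.0
    if np.any((fp_top <= 0) | (fp_top >= 1) | (fs_bot <= 0) | (fs_bot >= 1)):
        raise ValueError("compositions of 0 or 100 wt% make the log ratios singular")
    y = np.log10((1 - fp_top) / fp_top)
    x = np.log10((1 - fs_bot) / fs_bot)
    slope, intercept, r2 = _linear_fit(x, y)
    k, n = 10.0**intercept, slope
    lhs_pred = k * ((1 - fs_bot) / fs_bot) ** n
    gof = compute_sd((1 - fp_top) / fp_top, lhs_pred)
    return OthmerTobiasFit(k=k, n=n, fit=gof, r_squared=r2)


def fit_bancroft(tielines) -> BancroftFit:
    """Bancroft consistency regression, water fractions by closure.

    Fits log10(w_w_bot/w_s_bot) against log10(w_w_top/w_p_top);
    ``k1 = 10**intercept``, ``r = slope``.
    """
    tl = list(tielines)
    if len(tl) < 2:
        raise ValueError("need >= 2 tie-lines")
    ww_bot = np.array([t.bottom.w_w for t in tl])
    ws_bot = np.array([t.bottom.w_s for t in tl])
    ww_top = np.array([t.top.w_w for t in tl])
    wp_top = np.array([t.top.w_p for t in tl])
    if np.any(ws_bot <= 0) or np.any(wp_top <= 0) or np.any(ww_bot <= 0) or np.any(ww_top <= 0):
        raise ValueError("zero composition makes the Bancroft ratios singular")
    y = np.log10(ww_bot / ws_bot)
    x = np.log10(ww_top / wp_top)
    slope, intercept, r2 = _linear_fit(x, y)
    k1, r = 10.0**intercept, slope
    gof = compute_sd(ww_bot / ws_bot, k1 * (ww_top / wp_top) ** r)
    return BancroftFit(k1=k1, r=r, fit=gof, r_squared=r2)


def fit_setschenow(
    tielines, polymer: SpeciesInfo, salt: SpeciesInfo
) -> SetschenowFit:
    """Setschenow salting-out regression on phase molalities.

    Each phase composition is converted to molalities (mol solute per kg of
    water in that phase); ln(Cp_top/Cp_bot) is regressed on
    (Cs_bot - Cs_top).  Slope = k_s (salting-out coefficient, kg/mol),
    intercept = k_p; ``sd`` on the ln-ratio scale.
    """
    tl = list(tielines)
    if len(tl) < 2:
        raise ValueError("need >= 2 tie-lines")
    cp_top = np.array([mass_fraction_to_molality(t.top.w_p, t.top.w_w, polymer) for t in tl])
    cp_bot = np.array([mass_fraction_to_molality(t.bottom.w_p, t.bottom.w_w, polymer) for t in tl])
    cs_top = np.array([mass_fraction_to_molality(t.top.w_s, t.top.w_w, salt) for t in tl])
    cs_bot = np.array([mass_fraction_to_molality(t.bottom.w_s, t.bottom.w_w, salt) for t in tl])
    if np.any(cp_bot <= 0):
        raise ValueError("zero polymer in the bottom phase: ln ratio singular")
    y = np.log(cp_top / cp_bot)
    x = cs_bot - cs_top
    slope, intercept, _ = _linear_fit(x, y)
    gof = compute_sd(y, intercept + slope * x)
    if slope <= 0:
        warnings.warn(
            f"Setschenow k_s = {slope:.4g} <= 0: unexpected for a salting-out "
            "system under the per-kg-of-phase-water molality basis",
            UserWarning,
            stacklevel=2,
        )
    return SetschenowFit(k_p=intercept, k_s=slope, fit=gof)
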