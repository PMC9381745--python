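"""Drug-partitioning analytics for aqueous two-phase extraction.

The partition coefficient of a solute between the polymer-rich top phase
and the salt-rich bottom phase is K = w_top_drug / w_bot_drug; for
equal-mass sampling the extraction efficiency is EE% = 100 * K / (K + 1).
ln K correlates with the polymer composition difference across the matched
tie-line, dw = w_p_top - w_p_bot, through the Diamond-Hsu relation

    ln K = A * dw + B * dw**2                     (two-parameter, no intercept)

and its three-parameter extension

    ln K = A1 + B1 * dw + C1 * dw**2.

Both are linear in their coefficients and solved in closed form.  Because
the models are nested, the extended fit can never have a larger RMS
residual on the same records.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import Composition, GoodnessOfFit, compute_sd

__all__ = [
    "PartitionRecord",
    "DiamondHsuFit",
    "ModifiedDiamondHsuFit",
    "compute_K",
    "compute_EE",
    "fit_diamond_hsu",
    "fit_modified_diamond_hsu",
    "rank_drugs_by_hydrophobicity",
    "match_records_to_tielines",
]

#: Octanol-water log partition coefficients (hydrophobicity scale) of the
#: reference analgesics studied with PEG600 + KOH systems.
DEFAULT_LOG_KOW = {"ibuprofen": 3.97, "acetaminophen": 2.34}


@dataclass(frozen=True)
class PartitionRecord:
    """One drug-partitioning measurement on a known overall composition.

    ``delta_w_peg`` is the polymer wt% difference (top - bottom) of the
    tie-line matched to this record's overall composition; it is the
    regressor of the Diamond-Hsu correlations and may be attached after
    construction via :func:`match_records_to_tielines`.
    """

    drug: str
    overall: Composition
    K: float
    w_top_drug: float | None = None
    w_bot_drug: float | None = None
    delta_w_peg: float | None = None

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValueError(f"partition coefficient must be positive, got {self.K}")

    @property
    def EE(self) -> float:
        """Extraction efficiency (%) implied by K."""
        return compute_EE(self.K)


@dataclass(frozen=True)
class DiamondHsuFit:
    """ln K = A * dw + B * dw**2 (no intercept); sd on the ln K scale."""

    A: float
    B: float
    fit: GoodnessOfFit

    def predict_lnK(self, delta_w):
        dw = np.asarray(delta_w, dtype=float)
        return self.A * dw + self.B * dw**2


@dataclass(frozen=True)
class ModifiedDiamondHsuFit:
    """ln K = A1 + B1 * dw + C1 * dw**2; sd on the ln K scale."""

    A1: float
    B1: float
    C1: float
    fit: GoodnessOfFit

    def predict_lnK(self, delta_w):
        dw = np.asarray(delta_w, dtype=float)
        return self.A1 + self.B1 * dw + self.C1 * dw**2


def compute_K(w_top_drug: float, w_bot_drug: float) -> float:
    """Partition coefficient K = w_top_drug / w_bot_drug (dimensionless)."""
    if not w_bot_drug > 0:
        raise ValueError("bottom-phase drug fraction must be positive")
    if w_top_drug < 0:
        raise ValueError("top-phase drug fraction must be non-negative")
    return w_top_drug / w_bot_drug


def compute_EE(K) -> float:
    """Extraction efficiency EE% = 100 * K / (K + 1), strictly increasing in K."""
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("K must be positive")
    out = 100.0 * K / (K + 1.0)
    return float(out) if out.ndim == 0 else out


def _regression_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    recs = list(records)
    missing = [r.drug for r in recs if r.delta_w_peg is None]
    if missing:
        raise ValueError(
            f"records without matched delta_w_peg: {missing}; "
            "run match_records_to_tielines first"
        )
    dw = np.array([r.delta_w_peg for r in recs], dtype=float)
    lnk = np.log([r.K for r in recs])
    return dw, lnk


def fit_diamond_hsu(records) -> DiamondHsuFit:
    """Two-parameter Diamond-Hsu fit: least squares of ln K on (dw, dw^2).

    No intercept — a tie-line of zero length (dw = 0) forces K = 1,
    i.e. no preferential partitioning between identical phases.
    """
    dw, lnk = _regression_arrays(records)
    if np.unique(dw).size < 2:
        raise ValueError("need >= 2 distinct delta_w_peg values")
    X = np.column_stack([dw, dw**2])
    coef, *_ = np.linalg.lstsq(X, lnk, rcond=None)
    gof = compute_sd(lnk, X @ coef)
    return DiamondHsuFit(A=float(coef[0]), B=float(coef[1]), fit=gof)


def fit_modified_diamond_hsu(records) -> ModifiedDiamondHsuFit:
    """Three-parameter fit: least squares of ln K on (1, dw, dw^2)."""
    dw, lnk = _regression_arrays(records)
    if np.unique(dw).size < 3:
        raise ValueError("need >= 3 distinct delta_w_peg values")
    X = np.column_stack([np.ones_like(dw), dw, dw**2])
    coef, *_ = np.linalg.lstsq(X, lnk, rcond=None)
    gof = compute_sd(lnk, X @ coef)
    return ModifiedDiamondHsuFit(
        A1=float(coef[0]), B1=float(coef[1]), C1=float(coef[2]), fit=gof
    )


def match_records_to_tielines(records, tielines, tolerance: float = 0.01):
    """Attach each record's tie-line polymer difference by overall composition.

    A record matches a tie-line when both overall solute wt% agree within
    ``tolerance`` (the mixtures for partitioning are prepared at the same
    overall compositions as the tie-line study).  Raises when any record
    has no match.
    """
    out = []
    for r in records:
        match = None
        for t in tielines:
            if (
                abs(r.overall.w_p - t.overall.w_p) <= tolerance
                and abs(r.overall.w_s - t.overall.w_s) <= tolerance
            ):
                match = t
                break
        if match is None:
            raise ValueError(
                f"no tie-line with overall composition matching record "
                f"({r.drug}, w_s={r.overall.w_s}, w_p={r.overall.w_p})"
            )
        out.append(replace(r, delta_w_peg=match.delta_w_p))
    return out


def rank_drugs_by_hydrophobicity(records, log_kow: dict[str, float]) -> dict:
    """Compare per-drug extraction with the octanol-water hydrophobicity order.

    Returns a report with per-drug mean K and EE% and a verdict on whether
    the EE ordering across drugs matches the log Kow ordering (the more
    hydrophobic drug should favour the polymer-rich, less polar phase).
    """
    by_drug: dict[str, list[PartitionRecord]] = {}
    for r in records:
        by_drug.setdefault(r.drug, []).append(r)
    summary = {
        drug: {
            "mean_K": float(np.mean([r.K for r in recs])),
            "mean_EE": float(np.mean([r.EE for r in recs])),
            "n": len(recs),
            "log_kow": log_kow.get(drug),
        }
        for drug, recs in by_drug.items()
    }
    ranked = [d for d in summary if summary[d]["log_kow"] is not None]
    ee_order = sorted(ranked, key=lambda d: summary[d]["mean_EE"], reverse=True)
    kow_order = sorted(ranked, key=lambda d: summary[d]["log_kow"], reverse=True)
    return {
        "per_drug": summary,
        "ee_order": ee_order,
        "log_kow_order": kow_order,
        "consistent": ee_order == kow_order,
    }
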