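"""CSV readers and writers for the tabular formats of the pipeline.

All files are comma-delimited with a header row and dot decimals.
Compositions are wt%; refractometry calibration series are on the 0-1
mass-fraction scale.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .binodal import BinodalPoint
from .core import Composition, TieLine
from .partitioning import PartitionRecord, compute_K

__all__ = [
    "read_binodal_csv",
    "read_tielines_csv",
    "read_partition_csv",
    "read_refractometry_csv",
]


def _require(df: pd.DataFrame, cols: tuple[str, ...], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")


def read_binodal_csv(path: str | Path) -> list[BinodalPoint]:
    """Columns: w_s_wt_pct, w_p_wt_pct."""
    df = pd.read_csv(path)
    _require(df, ("w_s_wt_pct", "w_p_wt_pct"), path)
    return [
        BinodalPoint(w_s=float(r.w_s_wt_pct), w_p=float(r.w_p_wt_pct))
        for r in df.itertuples()
    ]


def read_tielines_csv(path: str | Path) -> list[TieLine]:
    """Columns: overall_ws, overall_wp, top_ws, top_wp, bot_ws, bot_wp (wt%).

    Water fractions are filled by difference; extra columns are ignored.
    """
    df = pd.read_csv(path)
    _require(df, ("overall_ws", "overall_wp", "top_ws", "top_wp", "bot_ws", "bot_wp"), path)
    return [
        TieLine(
            overall=Composition(w_p=float(r.overall_wp), w_s=float(r.overall_ws)),
            top=Composition(w_p=float(r.top_wp), w_s=float(r.top_ws)),
            bottom=Composition(w_p=float(r.bot_wp), w_s=float(r.bot_ws)),
        )
        for r in df.itertuples()
    ]


def read_partition_csv(path: str | Path) -> list[PartitionRecord]:
    """Columns: drug, overall_ws, overall_wp and either (w_top_drug, w_bot_drug) or K."""
    df = pd.read_csv(path)
    _require(df, ("drug", "overall_ws", "overall_wp"), path)
    has_fracs = {"w_top_drug", "w_bot_drug"}.issubset(df.columns)
    if not has_fracs and "K" not in df.columns:
        raise ValueError(f"{path}: need either (w_top_drug, w_bot_drug) or K column")
    records = []
    for r in df.itertuples():
        overall = Composition(w_p=float(r.overall_wp), w_s=float(r.overall_ws))
        if has_fracs:
            K = compute_K(float(r.w_top_drug), float(r.w_bot_drug))
            records.append(
                PartitionRecord(
                    drug=str(r.drug), overall=overall, K=K,
                    w_top_drug=float(r.w_top_drug), w_bot_drug=float(r.w_bot_drug),
                )
            )
        else:
            records.append(PartitionRecord(drug=str(r.drug), overall=overall, K=float(r.K)))
    return records


def read_refractometry_csv(path: str | Path):
    """Columns: component ('polymer'|'salt'), w_mass_fraction, n_d (0-1 scale).

    Returns (polymer series, salt series) as lists of (w, n_d) pairs.
    """
    df = pd.read_csv(path)
    _require(df, ("component", "w_mass_fraction", "n_d"), path)
    series = {"polymer": [], "salt": []}
    for r in df.itertuples():
        comp = str(r.component).lower()
        if comp not in series:
            raise ValueError(f"{path}: unknown component {r.component!r}")
        series[comp].append((float(r.w_mass_fraction), float(r.n_d)))
    return series["polymer"], series["salt"]
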