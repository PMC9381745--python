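"""End-to-end orchestration: CSV inputs to a machine-readable report.

`run_full_analysis` chains every stage of the liquid-liquid-equilibrium
workflow — binodal fits (both empirical models), tie-line lengths, lever
rule, the three consistency correlations, partition coefficients and
extraction efficiencies, both Diamond-Hsu correlations and the
hydrophobicity-ordering check — and collects the results in one nested
dict, serialisable to JSON, plus a short markdown summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

from . import io as _io
from .binodal import fit_merchuk, fit_zm
from .core import KOH, PEG600, SpeciesInfo, validate_composition
from .partitioning import (
    DEFAULT_LOG_KOW,
    fit_diamond_hsu,
    fit_modified_diamond_hsu,
    match_records_to_tielines,
    rank_drugs_by_hydrophobicity,
)
from .tielines import (
    DEFAULT_R2_GATE,
    compute_tll,
    fit_bancroft,
    fit_othmer_tobias,
    fit_setschenow,
    lever_rule_check,
)

__all__ = ["RunConfig", "run_full_analysis", "AnalysisError"]

log = logging.getLogger("atpskit")


class AnalysisError(RuntimeError):
    """Raised when one or more pipeline stages fail; carries the error list."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


@dataclasses.dataclass
class RunConfig:
    """Inputs and tolerances of a full pipeline run.

    Any of the three input paths may be None to skip that stage.  The
    reference analgesic hydrophobicities are the default ``log_kow`` map;
    pass your own for other solutes.
    """

    binodal_csv: str | Path | None = None
    tielines_csv: str | Path | None = None
    partition_csv: str | Path | None = None
    polymer: SpeciesInfo = PEG600
    salt: SpeciesInfo = KOH
    closure_tolerance: float = 0.5  # wt%
    lever_tolerance: float = 0.8  # wt%
    r2_gate: float = DEFAULT_R2_GATE
    log_kow: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_LOG_KOW))
    match_tolerance: float = 0.01  # wt%, record-to-tie-line matching
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        for name in ("closure_tolerance", "lever_tolerance", "match_tolerance"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def _gof(fitted) -> dict:
    return {"sd": fitted.sd, "n_points": fitted.n_points}


def run_full_analysis(config: RunConfig) -> dict:
    """Run every configured stage and return the report dict.

    The report's ``"passed"`` flag is true iff no stage failed and all
    consistency verdicts hold; stage failures are accumulated and raised
    together as :class:`AnalysisError` only when nothing could be computed.
    """
    report: dict = {"errors": [], "passed": True}

    if config.binodal_csv is not None:
        log.info("binodal: fitting both empirical models from %s", config.binodal_csv)
        try:
            points = _io.read_binodal_csv(config.binodal_csv)
            mk = fit_merchuk(points)
            zm = fit_zm(points)
            report["binodal"] = {
                "n_points": len(points),
                "merchuk": {"a": mk.a, "b": mk.b, "c": mk.c, **_gof(mk.fit)},
                "zafarani_moattar": {
                    "alpha": zm.alpha, "beta": zm.beta, "gamma": zm.gamma, **_gof(zm.fit)
                },
            }
        except Exception as e:  # noqa: BLE001 - collected into the report
            report["errors"].append(f"binodal: {e}")

    tielines = None
    if config.tielines_csv is not None:
        log.info("tielines: characterization and consistency from %s", config.tielines_csv)
        try:
            tielines = _io.read_tielines_csv(config.tielines_csv)
            for t in tielines:
                for c in (t.overall, t.top, t.bottom):
                    validate_composition(c, tolerance=config.closure_tolerance)
            lever = [lever_rule_check(t, tolerance=config.lever_tolerance) for t in tielines]
            ot = fit_othmer_tobias(tielines)
            bc = fit_bancroft(tielines)
            st = fit_setschenow(tielines, config.polymer, config.salt)
            report["tielines"] = {
                "n": len(tielines),
                "tll": [compute_tll(t) for t in tielines],
                "lever_rule": [
                    {"phase_fraction_top": r.phase_fraction_top,
                     "max_deviation": r.max_deviation, "passed": r.passed}
                    for r in lever
                ],
                "othmer_tobias": {
                    "k": ot.k, "n": ot.n, "r_squared": ot.r_squared, **_gof(ot.fit),
                    "verdict": "consistent" if ot.r_squared >= config.r2_gate else "inconsistent",
                },
                "bancroft": {
                    "k1": bc.k1, "r": bc.r, "r_squared": bc.r_squared, **_gof(bc.fit),
                    "verdict": "consistent" if bc.r_squared >= config.r2_gate else "inconsistent",
                },
                "setschenow": {"k_p": st.k_p, "k_s": st.k_s, **_gof(st.fit),
                               "salting_out": st.k_s > 0},
            }
            if not all(r.passed for r in lever):
                report["passed"] = False
        except Exception as e:  # noqa: BLE001
            report["errors"].append(f"tielines: {e}")

    if config.partition_csv is not None:
        log.info("partitioning: K/EE and Diamond-Hsu from %s", config.partition_csv)
        try:
            records = _io.read_partition_csv(config.partition_csv)
            if tielines is not None:
                records = match_records_to_tielines(
                    records, tielines, tolerance=config.match_tolerance
                )
            per_record = [
                {"drug": r.drug, "overall_ws": r.overall.w_s, "overall_wp": r.overall.w_p,
                 "K": r.K, "EE_pct": r.EE, "delta_w_peg": r.delta_w_peg}
                for r in records
            ]
            report["partitioning"] = {"records": per_record}
            if all(r.delta_w_peg is not None for r in records):
                by_drug = {}
                for drug in sorted({r.drug for r in records}):
                    recs = [r for r in records if r.drug == drug]
                    dh = fit_diamond_hsu(recs)
                    mdh = fit_modified_diamond_hsu(recs)
                    by_drug[drug] = {
                        "diamond_hsu": {"A": dh.A, "B": dh.B, **_gof(dh.fit)},
                        "modified_diamond_hsu": {
                            "A1": mdh.A1, "B1": mdh.B1, "C1": mdh.C1, **_gof(mdh.fit)
                        },
                    }
                report["partitioning"]["correlations"] = by_drug
            ranking = rank_drugs_by_hydrophobicity(records, config.log_kow)
            report["partitioning"]["hydrophobicity"] = ranking
        except Exception as e:  # noqa: BLE001
            report["errors"].append(f"partitioning: {e}")

    if report["errors"]:
        report["passed"] = False
    if not any(k in report for k in ("binodal", "tielines", "partitioning")):
        raise AnalysisError(report["errors"] or ["no input stages configured"])

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
        (outdir / "report.md").write_text(summarize_markdown(report))
        log.info("report written to %s", outdir)
    return report


def summarize_markdown(report: dict) -> str:
    """Human-readable digest of a pipeline report."""
    lines = ["# ATPS liquid-liquid-equilibrium analysis", ""]
    if "binodal" in report:
        mk, zm = report["binodal"]["merchuk"], report["binodal"]["zafarani_moattar"]
        lines += [
            "## Binodal",
            f"- Merchuk: a={mk['a']:.4g}, b={mk['b']:.4g}, c={mk['c']:.4g} (sd {mk['sd']:.3g} wt%)",
            f"- Zafarani-Moattar: alpha={zm['alpha']:.4g}, beta={zm['beta']:.4g}, "
            f"gamma={zm['gamma']:.4g} (sd {zm['sd']:.3g} wt%)",
            "",
        ]
    if "tielines" in report:
        t = report["tielines"]
        tll = ", ".join(f"{v:.2f}" for v in t["tll"])
        lines += [
            "## Tie-lines",
            f"- TLL (wt%): {tll}",
            f"- Othmer-Tobias: k={t['othmer_tobias']['k']:.4g}, n={t['othmer_tobias']['n']:.4g}, "
            f"r2={t['othmer_tobias']['r_squared']:.4f} -> {t['othmer_tobias']['verdict']}",
            f"- Bancroft: k1={t['bancroft']['k1']:.4g}, r={t['bancroft']['r']:.4g}, "
            f"r2={t['bancroft']['r_squared']:.4f} -> {t['bancroft']['verdict']}",
            f"- Setschenow: k_p={t['setschenow']['k_p']:.4g}, "
            f"k_s={t['setschenow']['k_s']:.4g} kg/mol",
            "",
        ]
    if "partitioning" in report:
        lines += ["## Partitioning"]
        for rec in report["partitioning"]["records"]:
            lines.append(
                f"- {rec['drug']}: K={rec['K']:.2f}, EE={rec['EE_pct']:.2f}%"
            )
        hyd = report["partitioning"].get("hydrophobicity", {})
        if hyd:
            lines.append(
                f"- EE order {hyd['ee_order']} vs log Kow order {hyd['log_kow_order']}: "
                + ("consistent" if hyd["consistent"] else "inconsistent")
            )
        lines.append("")
    if report["errors"]:
        lines += ["## Errors"] + [f"- {e}" for e in report["errors"]]
    return "\n".join(lines)
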