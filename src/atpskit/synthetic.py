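"""Synthetic aqueous-two-phase-system datasets with known ground truth.

Laboratory phase-equilibrium studies produce four kinds of tables: binodal
points from cloud-point titration, tie-line phase compositions, drug
partition coefficients, and refractometer calibration series.  This module
generates all four from explicit truth parameters so that every analysis
stage can be benchmarked for parameter recovery, with noise models chosen
to mirror the measurement process:

* binodal points: additive Gaussian noise on polymer wt% around a Merchuk
  truth curve (default sigma 0.3 wt%);
* tie-lines: endpoints exactly on the truth binodal, overall composition
  on the segment by the lever rule (alternative exact-model modes place
  compositions exactly on an Othmer-Tobias or Setschenow truth line);
* partition records: Gaussian noise on ln K (multiplicative on K, keeping
  it positive), phase drug fractions back-solved from a 0.002 total drug
  mass fraction under the lever-rule phase split;
* refractometry: additive Gaussian noise on the refractive index, default
  sigma 0.0002, a typical refractometer measurement uncertainty.

Default truth parameters emulate a PEG600 + KOH + water system at 298 K:
binodal from ~60 wt% polymer at low salt down to ~10 wt% at ~30 wt% salt,
tie-line lengths in the 45-65 wt% range, partition coefficients of a few
to ~15 for hydrophobic analgesics.

Determinism: one integer seed drives one named, independent pseudo-random
stream per generator stage, so regenerating any one table never perturbs
the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .binodal import BinodalPoint, MerchukParameters, evaluate_merchuk
from .core import (
    KOH,
    PEG600,
    Composition,
    SpeciesInfo,
    TieLine,
    mass_fraction_to_molality,
)
from .partitioning import PartitionRecord
from .refractometry import N0_WATER, RefractiveReading, RefractometryCalibration
from .tielines import lever_rule_check

__all__ = [
    "GeneratorConfig",
    "generate_binodal",
    "generate_tielines",
    "generate_partition",
    "generate_refractometry",
    "write_dataset",
]

# stable per-stage stream offsets (stage reproducibility)
_STREAMS = {"binodal": 1, "tielines": 2, "partition": 3, "refractometry": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], seed])


@dataclass(frozen=True)
class GeneratorConfig:
    """Truth parameters and noise levels for synthetic dataset generation."""

    seed: int = 0
    # --- binodal ---
    binodal_truth: MerchukParameters = field(
        default_factory=lambda: MerchukParameters(a=250.0, b=-0.5, c=1.5e-5)
    )
    n_binodal_points: int = 24
    binodal_noise_sd: float = 0.3  # wt% on polymer composition
    binodal_salt_range: tuple[float, float] = (8.0, 32.0)
    # --- tie-lines ---
    n_tielines: int = 5
    top_salt_anchors: tuple[float, ...] = (8.0, 7.8, 7.6, 7.4, 7.2)
    bottom_salt_anchors: tuple[float, ...] = (24.0, 26.0, 28.0, 30.0, 32.0)
    endpoint_noise_sd: float = 0.0  # wt%, optional perturbation of endpoints
    # exact-model alternatives for consistency-fit benchmarking
    othmer_tobias_truth: tuple[float, float] = (0.5, 1.2)  # (k, n)
    setschenow_truth: tuple[float, float] = (0.5, 2.0)  # (k_p, k_s) kg/mol
    # --- partitioning ---
    partition_truth: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ibuprofen": (0.0457, -5.6e-5),  # Diamond-Hsu (A, B)
            "acetaminophen": (0.0275, 1.9e-4),
        }
    )
    partition_noise_sd: float = 0.015  # on ln K; ~sigma(K)=0.15 at K~10
    total_drug_fraction: float = 0.002
    # --- refractometry ---
    refractometry_truth: RefractometryCalibration = field(
        default_factory=lambda: RefractometryCalibration(
            n0=N0_WATER, a_p=0.135, a_s=0.18,
            r_squared_p=1.0, r_squared_s=1.0,
            valid_range_p=(0.0, 0.10), valid_range_s=(0.0, 0.10),
        )
    )
    refractometry_noise_sd: float = 0.0002  # refractive-index units
    polymer: SpeciesInfo = PEG600
    salt: SpeciesInfo = KOH

    def __post_init__(self) -> None:
        for name in ("binodal_noise_sd", "endpoint_noise_sd",
                     "partition_noise_sd", "refractometry_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_binodal_points < 1 or self.n_tielines < 1:
            raise ValueError("counts must be >= 1")


def generate_binodal(config: GeneratorConfig) -> list[BinodalPoint]:
    """Binodal points: a salt grid with Gaussian noise on the polymer wt%."""
    rng = _rng(config.seed, "binodal")
    lo, hi = config.binodal_salt_range
    ws = np.linspace(lo, hi, config.n_binodal_points)
    wp_mean = evaluate_merchuk(config.binodal_truth, ws)
    if np.any(wp_mean <= 0):
        raise ValueError("binodal truth gives non-positive polymer wt% on the grid")
    wp = wp_mean + rng.normal(0.0, config.binodal_noise_sd, size=ws.size)
    wp = np.clip(wp, 0.0, None)
    return [BinodalPoint(w_s=float(s), w_p=float(p)) for s, p in zip(ws, wp)]


def _tieline_from_endpoints(top: Composition, bottom: Composition,
                            lever: float) -> TieLine:
    overall = Composition(
        w_p=lever * top.w_p + (1 - lever) * bottom.w_p,
        w_s=lever * top.w_s + (1 - lever) * bottom.w_s,
    )
    return TieLine(overall=overall, top=top, bottom=bottom)


def generate_tielines(config: GeneratorConfig, mode: str = "binodal") -> list[TieLine]:
    """Tie-lines in one of three construction modes.

    ``"binodal"`` (default): endpoints exactly on the truth binodal at the
    anchor salt fractions (top low-salt, bottom high-salt), overall drawn
    on the segment at a lever fraction in [0.3, 0.7]; such lines satisfy
    the lever rule exactly but no consistency correlation exactly.

    ``"othmer_tobias"``: phase compositions back-solved from the
    (k, n) truth so the Othmer-Tobias relation holds exactly.

    ``"setschenow"``: phase molalities placed exactly on the
    (k_p, k_s) truth line, then converted back to mass fractions.
    """
    rng = _rng(config.seed, "tielines")
    n = config.n_tielines
    tops = np.asarray(config.top_salt_anchors, dtype=float)[:n]
    bots = np.asarray(config.bottom_salt_anchors, dtype=float)[:n]
    if tops.size < n or bots.size < n:
        raise ValueError("not enough salt anchors for n_tielines")
    levers = rng.uniform(0.3, 0.7, size=n)

    out: list[TieLine] = []
    if mode == "binodal":
        for ws_t, ws_b, lever in zip(tops, bots, levers):
            wp_t = float(evaluate_merchuk(config.binodal_truth, ws_t))
            wp_b = float(evaluate_merchuk(config.binodal_truth, ws_b))
            if config.endpoint_noise_sd > 0:
                wp_t, wp_b, ws_t, ws_b = (
                    v + rng.normal(0.0, config.endpoint_noise_sd)
                    for v in (wp_t, wp_b, ws_t, ws_b)
                )
            top = Composition(w_p=wp_t, w_s=float(ws_t))
            bottom = Composition(w_p=wp_b, w_s=float(ws_b))
            if not (top.w_p > bottom.w_p and bottom.w_s > top.w_s):
                raise ValueError("generated endpoints violate the phase convention")
            out.append(_tieline_from_endpoints(top, bottom, float(lever)))
    elif mode == "othmer_tobias":
        k, n_exp = config.othmer_tobias_truth
        for ws_b, lever, i in zip(bots, levers, range(n)):
            fs_bot = ws_b / 100.0
            lhs = k * ((1 - fs_bot) / fs_bot) ** n_exp
            fp_top = 1.0 / (1.0 + lhs)  # exact inversion of the correlation
            top = Composition(w_p=100.0 * fp_top, w_s=8.0 - 0.2 * i)
            bottom = Composition(w_p=10.5 - 0.5 * i, w_s=ws_b)
            out.append(_tieline_from_endpoints(top, bottom, float(lever)))
    elif mode == "setschenow":
        k_p, k_s = config.setschenow_truth
        Mp, Ms = config.polymer, config.salt
        for ws_b, lever, i in zip(bots, levers, range(n)):
            bottom = Composition(w_p=10.5 - 0.5 * i, w_s=ws_b)
            cp_bot = mass_fraction_to_molality(bottom.w_p, bottom.w_w, Mp)
            cs_bot = mass_fraction_to_molality(bottom.w_s, bottom.w_w, Ms)
            cs_top = cs_bot - (0.8 + 0.1 * i)  # molality gap spread across lines
            cp_top = cp_bot * np.exp(k_p + k_s * (cs_bot - cs_top))
            # molalities -> mass fractions: grams per kg of water
            g_p, g_s = cp_top * Mp.molar_mass, cs_top * Ms.molar_mass
            total = 1000.0 + g_p + g_s
            top = Composition(w_p=100.0 * g_p / total, w_s=100.0 * g_s / total)
            out.append(_tieline_from_endpoints(top, bottom, float(lever)))
    else:
        raise ValueError(f"unknown tie-line generation mode {mode!r}")
    return out


def generate_partition(
    config: GeneratorConfig, tielines: list[TieLine]
) -> list[PartitionRecord]:
    """Partition records from a per-drug Diamond-Hsu truth model.

    For each tie-line and drug, ln K is the truth polynomial in the
    tie-line's polymer difference plus Gaussian noise; the phase drug
    fractions are back-solved so that the total drug mass fraction equals
    ``total_drug_fraction`` under the lever-rule phase split.
    """
    if not tielines:
        raise ValueError("tie-lines required to generate partition records")
    rng = _rng(config.seed, "partition")
    w_total = config.total_drug_fraction
    records: list[PartitionRecord] = []
    for drug, (A, B) in config.partition_truth.items():
        for t in tielines:
            dw = t.delta_w_p
            lnk = A * dw + B * dw**2 + rng.normal(0.0, config.partition_noise_sd)
            K = float(np.exp(lnk))
            f_top = lever_rule_check(t).phase_fraction_top
            w_bot = w_total / (f_top * K + (1 - f_top))
            w_top = K * w_bot
            if w_top <= 0 or w_bot <= 0:
                raise ValueError("unattainable drug mass balance")
            records.append(
                PartitionRecord(
                    drug=drug, overall=t.overall, K=K,
                    w_top_drug=float(w_top), w_bot_drug=float(w_bot),
                    delta_w_peg=float(dw),
                )
            )
    return records


def generate_refractometry(
    config: GeneratorConfig, compositions: list[Composition]
) -> tuple[list[RefractiveReading], list[tuple[float, float]], list[tuple[float, float]]]:
    """Refractive readings for phase samples plus two calibration series.

    Readings follow n_D = n0 + a_p*w_p + a_s*w_s with Gaussian noise
    (compositions here are wt%; the linear model uses 0-1 fractions).
    Returns (readings, polymer calibration series, salt calibration series),
    the series as (mass_fraction, n_d) pairs over the calibrated ranges.
    """
    rng = _rng(config.seed, "refractometry")
    cal = config.refractometry_truth
    sd = config.refractometry_noise_sd
    readings = []
    for c in compositions:
        fp, fs, _ = c.as_fractions()
        nd = cal.n0 + cal.a_p * fp + cal.a_s * fs + rng.normal(0.0, sd)
        readings.append(RefractiveReading(n_d=float(nd), w_s_known=fs))
    series = {}
    for label, a, rng_hi in (("p", cal.a_p, cal.valid_range_p[1]),
                             ("s", cal.a_s, cal.valid_range_s[1])):
        w = np.linspace(rng_hi / 8.0, rng_hi, 8)
        nd = cal.n0 + a * w + rng.normal(0.0, sd, size=w.size)
        series[label] = list(zip(w.tolist(), nd.tolist()))
    return readings, series["p"], series["s"]


def write_dataset(config: GeneratorConfig, outdir: str | Path,
                  tieline_mode: str = "binodal") -> dict[str, Path]:
    """Write the full synthetic bundle (CSV tables + truth.json) to ``outdir``.

    Deterministic: identical config (including seed) yields byte-identical
    files.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    binodal = generate_binodal(config)
    paths["binodal"] = outdir / "binodal.csv"
    pd.DataFrame(
        {"w_s_wt_pct": [p.w_s for p in binodal], "w_p_wt_pct": [p.w_p for p in binodal]}
    ).to_csv(paths["binodal"], index=False)

    tielines = generate_tielines(config, mode=tieline_mode)
    paths["tielines"] = outdir / "tielines.csv"
    pd.DataFrame(
        {
            "overall_ws": [t.overall.w_s for t in tielines],
            "overall_wp": [t.overall.w_p for t in tielines],
            "top_ws": [t.top.w_s for t in tielines],
            "top_wp": [t.top.w_p for t in tielines],
            "bot_ws": [t.bottom.w_s for t in tielines],
            "bot_wp": [t.bottom.w_p for t in tielines],
        }
    ).to_csv(paths["tielines"], index=False)

    records = generate_partition(config, tielines)
    paths["partition"] = outdir / "partition.csv"
    pd.DataFrame(
        {
            "drug": [r.drug for r in records],
            "overall_ws": [r.overall.w_s for r in records],
            "overall_wp": [r.overall.w_p for r in records],
            "w_top_drug": [r.w_top_drug for r in records],
            "w_bot_drug": [r.w_bot_drug for r in records],
        }
    ).to_csv(paths["partition"], index=False)

    phase_comps = [t.top for t in tielines] + [t.bottom for t in tielines]
    readings, series_p, series_s = generate_refractometry(config, phase_comps)
    paths["refractometry"] = outdir / "refractometry.csv"
    rows = [("polymer", w, nd) for w, nd in series_p]
    rows += [("salt", w, nd) for w, nd in series_s]
    pd.DataFrame(rows, columns=["component", "w_mass_fraction", "n_d"]).to_csv(
        paths["refractometry"], index=False
    )

    truth = {
        "seed": config.seed,
        "binodal": {"a": config.binodal_truth.a, "b": config.binodal_truth.b,
                    "c": config.binodal_truth.c},
        "othmer_tobias": dict(zip(("k", "n"), config.othmer_tobias_truth)),
        "setschenow": dict(zip(("k_p", "k_s"), config.setschenow_truth)),
        "partition": {d: dict(zip(("A", "B"), ab))
                      for d, ab in config.partition_truth.items()},
        "refractometry": {"n0": config.refractometry_truth.n0,
                          "a_p": config.refractometry_truth.a_p,
                          "a_s": config.refractometry_truth.a_s},
        "noise": {"binodal_sd": config.binodal_noise_sd,
                  "partition_lnK_sd": config.partition_noise_sd,
                  "refractometry_sd": config.refractometry_noise_sd},
        "tieline_mode": tieline_mode,
    }
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths
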