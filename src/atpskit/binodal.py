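"""Empirical binodal-curve models for polymer-salt aqueous two-phase systems.

Two three-parameter correlations are supported, both expressing the polymer
wt% ``w_p`` on the binodal as a function of the salt wt% ``w_s``:

* Merchuk:            w_p = a * exp(b * w_s**0.5 - c * w_s**3)
* Zafarani-Moattar:   w_p = alpha + beta * ln(w_s) + gamma * w_s

The Merchuk form is fitted by nonlinear least squares with a deterministic
multi-start fallback; the Zafarani-Moattar form is linear in its parameters
and solved in closed form.  Both fits report the RMS residual ``sd`` in
polymer wt%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import GoodnessOfFit, compute_sd

__all__ = [
    "BinodalPoint",
    "MerchukParameters",
    "ZafaraniMoattarParameters",
    "MerchukFitOptions",
    "evaluate_merchuk",
    "evaluate_zm",
    "fit_merchuk",
    "fit_zm",
]


@dataclass(frozen=True)
class BinodalPoint:
    """One experimental point on the binodal, (salt wt%, polymer wt%)."""

    w_s: float
    w_p: float

    def __post_init__(self) -> None:
        if self.w_s < 0 or self.w_p < 0:
            raise ValueError(f"binodal point has negative component: {self}")


@dataclass(frozen=True)
class MerchukParameters:
    """Fitted Merchuk coefficients; ``a`` is the w_s -> 0 polymer intercept (wt%)."""

    a: float
    b: float
    c: float
    fit: GoodnessOfFit | None = None


@dataclass(frozen=True)
class ZafaraniMoattarParameters:
    """Fitted Zafarani-Moattar coefficients (alpha wt%, beta wt%, gamma slope)."""

    alpha: float
    beta: float
    gamma: float
    fit: GoodnessOfFit | None = None


@dataclass(frozen=True)
class MerchukFitOptions:
    """Optimizer settings for :func:`fit_merchuk`.

    The curve is smooth and cheap to evaluate, so tight tolerances cost
    nothing; ``n_starts`` jittered restarts guard against a bad basin from
    the heuristic initial guess.  ``jitter_seed`` makes the restarts
    deterministic.
    """

    b0: float = -0.3
    c0: float = 1e-5
    xtol: float = 1e-10
    ftol: float = 1e-10
    max_nfev: int = 10_000
    n_starts: int = 5
    jitter_seed: int = 0
    positive_a: bool = False


def evaluate_merchuk(params: MerchukParameters, w_s) -> np.ndarray | float:
    """Polymer wt% on the Merchuk curve at salt wt% ``w_s`` (>= 0)."""
    w_s = np.asarray(w_s, dtype=float)
    if np.any(w_s < 0):
        raise ValueError("w_s must be non-negative")
    out = params.a * np.exp(params.b * np.sqrt(w_s) - params.c * w_s**3)
    return float(out) if out.ndim == 0 else out


def evaluate_zm(params: ZafaraniMoattarParameters, w_s) -> np.ndarray | float:
    """Polymer wt% on the Zafarani-Moattar curve at salt wt% ``w_s`` (> 0)."""
    w_s = np.asarray(w_s, dtype=float)
    if np.any(w_s <= 0):
        raise ValueError("w_s must be positive (logarithmic term)")
    out = params.alpha + params.beta * np.log(w_s) + params.gamma * w_s
    return float(out) if out.ndim == 0 else out


def _points_to_arrays(points) -> tuple[np.ndarray, np.ndarray]:
    ws = np.array([p.w_s for p in points], dtype=float)
    wp = np.array([p.w_p for p in points], dtype=float)
    return ws, wp


def fit_merchuk(
    points, options: MerchukFitOptions | None = None
) -> MerchukParameters:
    """Fit the Merchuk equation to binodal points by nonlinear least squares.

    Minimizes sum((w_p_obs - w_p_pred)^2) over (a, b, c).  The initial
    amplitude is the largest observed polymer fraction (the binodal
    intercept proxy); on non-convergence up to ``n_starts`` deterministic
    jittered restarts are attempted and the best cost wins.

    Raises ``ValueError`` for fewer than 4 points and ``RuntimeError`` when
    no start converges.
    """
    opts = options or MerchukFitOptions()
    ws, wp = _points_to_arrays(points)
    if ws.size < 4:
        raise ValueError(f"fit_merchuk needs >= 4 points, got {ws.size}")
    if np.any(ws < 0):
        raise ValueError("w_s must be non-negative")
    sq, cb = np.sqrt(ws), ws**3

    def resid(theta):
        a, b, c = theta
        return a * np.exp(b * sq - c * cb) - wp

    x0 = np.array([wp.max(), opts.b0, opts.c0])
    bounds = ((1e-12, -np.inf, -np.inf), np.inf) if opts.positive_a else (-np.inf, np.inf)
    rng = np.random.default_rng(opts.jitter_seed)
    best = None
    for start in range(opts.n_starts):
        guess = x0 if start == 0 else x0 * rng.uniform(0.7, 1.3, size=3)
        try:
            sol = least_squares(
                resid, guess, xtol=opts.xtol, ftol=opts.ftol, gtol=None,
                max_nfev=opts.max_nfev, bounds=bounds,
            )
        except ValueError:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
        if best is not None and start == 0:
            break  # default start converged; restarts are a fallback only
    if best is None:
        raise RuntimeError(
            "Merchuk fit failed to converge from all starts "
            f"(n_starts={opts.n_starts}, max_nfev={opts.max_nfev})"
        )
    a, b, c = best.x
    params = MerchukParameters(a=float(a), b=float(b), c=float(c))
    gof = compute_sd(wp, evaluate_merchuk(params, ws))
    return MerchukParameters(a=params.a, b=params.b, c=params.c, fit=gof)


def fit_zm(points) -> ZafaraniMoattarParameters:
    """Fit the Zafarani-Moattar equation by exact linear least squares.

    Regressors are (1, ln w_s, w_s); the solution is the closed-form
    normal-equations minimizer, no iteration.  Raises ``ValueError`` for
    fewer than 3 points, non-positive w_s, or a rank-deficient design
    (e.g. fewer than 3 distinct salt fractions).
    """
    ws, wp = _points_to_arrays(points)
    if ws.size < 3:
        raise ValueError(f"fit_zm needs >= 3 points, got {ws.size}")
    if np.any(ws <= 0):
        raise ValueError("w_s must be positive for the logarithmic regressor")
    X = np.column_stack([np.ones_like(ws), np.log(ws), ws])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError(
            "collinear design: need >= 3 distinct w_s values to identify "
            "(alpha, beta, gamma)"
        )
    coef, *_ = np.linalg.lstsq(X, wp, rcond=None)
    params = ZafaraniMoattarParameters(*map(float, coef))
    gof = compute_sd(wp, evaluate_zm(params, ws))
    return ZafaraniMoattarParameters(params.alpha, params.beta, params.gamma, fit=gof)
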