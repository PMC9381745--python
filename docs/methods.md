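# Methods

## Scope and data model

The package analyses isothermal liquid–liquid equilibria of ternary
polymer + salt + water systems. All compositions are mass fractions on
the weight-percent scale (0–100), the convention of published ATPS
tables; helpers convert to the fractional (0–1) scale where a model
requires well-formed `1 − w` terms (Othmer-Tobias, Bancroft) and to
molality where a model is defined on moles (Setschenow). Water fractions
absent from input tables are filled by difference, `w_w = 100 − w_p − w_s`.

A `Composition` must close to 100 wt% within a configurable tolerance
(default 0.5 wt%): a residual between one and two tolerances warns, beyond
two tolerances it is an error. The default reflects the ~0.8 wt%
per-component uncertainty typical of gravimetric/refractometric phase
analysis. A `TieLine` obeys the phase-labelling convention that the top
phase is polymer-rich and the bottom phase salt-rich; inputs violating it
are swapped with a warning rather than rejected, since column order in
user files is a common accident.

Goodness of fit is reported throughout as the root-mean-square residual
`sd = sqrt(Σ(obs − pred)²/n)` in the fitted variable's own units, with
divisor `n` rather than `n − 1`, the convention of the phase-equilibrium
correlation literature.

## Estimators

**Merchuk fit.** `w_p = a·exp(b·√w_s − c·w_s³)` is fitted by
`scipy.optimize.least_squares` on the wt% scale with tight tolerances
(xtol = ftol = 1e−10, ≤10 000 evaluations; the curve is smooth and cheap,
so precision costs nothing). Initialization: `a₀` = largest observed
polymer fraction (the `w_s → 0` intercept proxy), `b₀ = −0.3`,
`c₀ = 1e−5`. If the default start fails to converge, up to four
deterministically jittered restarts (seeded, ±30 %) are tried and the best
cost wins, so identical inputs always give identical fits. Parameters are
unbounded by default; a physical `a > 0` bound is available in the
options.

**Zafarani-Moattar fit.** `w_p = α + β·ln w_s + γ·w_s` is linear in its
parameters and solved exactly by least squares on the design
`(1, ln w_s, w_s)`; a rank check rejects designs with fewer than three
distinct salt fractions.

**Consistency fits.** Othmer-Tobias and Bancroft are fitted on their
base-10 log-linearizations of fractional compositions — this is how the
consistency plots are traditionally constructed and judged — with
`k = 10^intercept` (hence always positive) and the exponent as slope. The
reported `sd` is computed on the back-transformed ratio scale. The
r² of the linearized regression operationalizes the qualitative
"acceptable consistency" verdict; the default gate is r² ≥ 0.95,
configurable. The Setschenow regression uses natural logs and molalities
in **moles of solute per kilogram of water in that phase**, computed as
`(w/M)/(w_w/1000)` per 100 g of solution.

A consequence worth knowing: on the packaged reference tie-lines this
molality basis yields a *negative* fitted `k_s` (≈ −1.02 kg/mol), because
the concentrated polymer-rich top phase contains little water, which
inflates its salt molality until the gap `C_s^bot − C_s^top` shrinks and
changes sign down the table. A per-kilogram-of-solution basis would give a
positive slope. The per-kg-water basis is the standard Setschenow usage
and is kept; `fit_setschenow` warns when the fitted slope is not positive
so the user sees the basis-dependence explicitly.

**Lever rule.** For each solute the parameter
`f = (overall − bottom)/(top − bottom)` estimates the fraction of total
mass in the top phase; `phase_fraction_top` is their mean. The reported
`max_deviation` is the perpendicular distance (wt%) of the overall point
from the tie-line in the (w_s, w_p) plane; the default pass tolerance is
0.8 wt%, matching the per-component composition uncertainty.

**Partition correlations.** Both Diamond-Hsu forms are linear in their
coefficients and solved in closed form on the natural-log scale. The
two-parameter form has no intercept by construction — a tie-line of zero
length implies identical phases and hence `K = 1`. Because the forms are
nested, the three-parameter `sd` can never exceed the two-parameter `sd`
on the same records; the test suite asserts this on both printed and
synthetic data. Partition records are matched to tie-lines by identical
overall composition within 0.01 wt%. Each drug is fitted separately.

**Refractometry.** The intercept of `n_D = n₀ + a_p·w_p + a_s·w_s` is
fixed at the separately measured pure-water value (default 1.3325 at
298.15 K), so each coefficient is a through-origin least-squares slope of
`(n_D − n₀)` on `w`. Readings outside the calibrated dilution range warn
rather than fail: equilibrium phases are routinely diluted before
measurement, and enforcing the range hard would reject legitimate
workflows. Internally this module works on the 0–1 mass-fraction scale,
the natural scale of dilute calibration series.

## Synthetic data generator

The generator emulates the four laboratory tables of an ATPS study.
Defaults mimic a PEG600 + KOH system at 298 K:

| channel | default | rationale |
| --- | --- | --- |
| binodal truth (Merchuk a, b, c) | 250, −0.5, 1.5e−5 | ~60 wt% polymer at 8 wt% salt falling to ~10 wt% at 32 wt% salt |
| binodal points / noise | 24 points, σ = 0.3 wt% additive Gaussian | cloud-point titration scatter |
| tie-lines | 5, top anchors 7.2–8 wt% salt, bottom 24–32 wt% | TLL ≈ 46–61 wt%, lever fraction U[0.3, 0.7] |
| ln K noise | σ = 0.015 | equivalent to σ(K) = 0.15 at K ≈ 10; log-scale noise keeps K positive |
| total drug loading | 0.002 mass fraction | typical spiking level |
| refractive-index noise | σ = 0.0002 | refractometer measurement uncertainty |

Tie-line endpoints are placed exactly on the truth binodal and the overall
composition exactly on the segment, so lever-rule checks pass with zero
deviation; such lines do **not** satisfy any consistency correlation
exactly, which is why two alternative construction modes back-solve phase
compositions from an exact Othmer-Tobias `(k, n)` or Setschenow
`(k_p, k_s)` truth for machine-precision recovery tests. Drug phase
fractions are back-solved from `w_top = K·w_bot` and the lever-rule mass
balance, so the total drug mass fraction is exact by construction.

One integer seed drives one named, independent random stream per stage
(`binodal`, `tielines`, `partition`, `refractometry`), so regenerating one
table never perturbs another and bundles are byte-identical across runs.

What the generator does *not* emulate: correlated composition errors
between phases of the same tie-line, instrument drift, titration
kinetics, or any departure of real binodals from the Merchuk family.
Passing recovery tests therefore show that the estimators are correct and
well-calibrated on their assumed error model, not that the empirical
correlations describe any particular real system.

## Recovery benchmarking

`atpskit.benchmark` measures estimator calibration under the default
noise: for each of 200 seeded replicates it fits the model, builds 95 %
confidence intervals by **studentized residual bootstrap** (200 resamples)
and records whether each truth parameter is covered. Residuals are
inflated by `sqrt(n/(n−p))` before resampling (degrees-of-freedom
correction) and intervals are bootstrap-t: plain percentile intervals
undercover badly on designs as small as five tie-lines, where the
estimate's sampling distribution has heavy t-tails. For the
Zafarani-Moattar study, whose fitted family differs from the generating
Merchuk curve, "truth" is the projection of the noiseless curve onto the
ZM basis at the same design — the estimand the fit actually targets.
Observed coverage is 91–96 % per parameter across all four studied models
(Merchuk, Zafarani-Moattar, both Diamond-Hsu forms).

These problem sizes — 200 replicates × 200 bootstrap resamples, 24-point
binodals, 5-line partition designs — were chosen as the smallest study
that estimates coverage to a few percent (binomial standard error ≈1.6 %
at n = 200).

## Numerical and degenerate-input behaviour

* Linear systems are solved with `numpy.linalg.lstsq`; rank and
  degeneracy (all-equal regressors, single distinct salt fraction,
  identical tie-lines) raise informative `ValueError`s rather than
  returning garbage.
* Log singularities (compositions of exactly 0 or 100 wt% in ratio
  models, zero polymer in the bottom phase) are rejected explicitly.
* `compute_EE` is a strictly monotone bijection (0, ∞) → (0, 100) with
  `EE(K) + EE(1/K) = 100`; the inverse `K = EE/(100 − EE)` is exact.
* Merchuk fitting is deterministic: the restart jitter stream is seeded
  from the fit options, never from global state.

## Known limitations

* No thermodynamic (activity-coefficient) models — NRTL/UNIQUAC-class
  correlation and temperature dependence are out of scope; everything is
  isothermal and empirical.
* Tie-lines are characterized, not predicted: there is no flash solver
  that splits an overall composition using only the binodal.
* The refractometry module ignores wavelength and temperature dependence
  of the refractive index.
* Consistency verdicts are threshold-based (r² gate); they flag, but do
  not diagnose, inconsistent tie-lines.
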