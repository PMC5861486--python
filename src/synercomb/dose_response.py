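"""Mono-therapy dose-response modelling.

Fits the three-parameter Hill (log-logistic) curve

    E(d) = Einf + (1 - Einf) / (1 + (d / EC50)^h)

to viability measurements (fraction of untreated control, E0 fixed at 1)
and derives the per-drug pharmacology summaries used downstream as
features: IC50 (dose giving 50% viability, capped at the top tested
dose), the Drug Sensitivity Score (DSS; normalized area of inhibition
above an activity threshold over the tested log-dose range) and Einf
(asymptotic viability at infinite dose).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "MonoSummary",
    "hill_response",
    "fit_hill",
    "ic50",
    "dss",
    "summarize_mono",
]

HILL_SLOPE_BOUNDS = (0.2, 10.0)


@dataclass(frozen=True)
class DoseResponseCurve:
    """Mono-therapy viability measurements for one drug on one cell line.

    ``doses`` are concentrations in µM (strictly positive, strictly
    ascending); ``responses`` are viability fractions of the untreated
    control (1.0 = no effect).
    """

    drug_id: str
    cell_line_id: str
    doses: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        responses = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "responses", responses)
        if doses.ndim != 1 or responses.ndim != 1 or len(doses) != len(responses):
            raise ValueError("doses and responses must be 1-D and of equal length")
        if len(doses) < 4:
            raise ValueError("a dose-response curve needs at least 4 points")
        if not np.all(np.isfinite(doses)) or not np.all(np.isfinite(responses)):
            raise ValueError("doses and responses must be finite")
        if np.any(doses <= 0):
            raise ValueError("doses must be strictly positive")
        if np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be strictly ascending")


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters: viability floor, midpoint and slope."""

    e_inf: float
    ec50: float
    h: float
    rss: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.e_inf <= 1.0:
            raise ValueError("e_inf must lie in [0, 1]")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if not HILL_SLOPE_BOUNDS[0] <= self.h <= HILL_SLOPE_BOUNDS[1]:
            raise ValueError("Hill slope out of bounds")
        if self.rss < 0:
            raise ValueError("rss must be non-negative")

    def response(self, dose):
        """Model viability at ``dose`` (scalar or array, µM)."""
        return hill_response(dose, self.e_inf, self.ec50, self.h)


@dataclass(frozen=True)
class MonoSummary:
    """Per-(cell line, drug) pharmacology summary used as model features."""

    ic50: float
    dss: float
    e_inf: float


def hill_response(dose, e_inf: float, ec50: float, h: float):
    """Viability under the 3-parameter Hill model; vectorized over dose."""
    d = np.asarray(dose, dtype=float)
    with np.errstate(over="ignore"):
        out = e_inf + (1.0 - e_inf) / (1.0 + (d / ec50) ** h)
    return out if out.ndim else float(out)


def _rss(params: np.ndarray, doses: np.ndarray, responses: np.ndarray) -> float:
    e_inf, log_ec50, h = params
    resid = hill_response(doses, e_inf, 10.0**log_ec50, h) - responses
    return float(resid @ resid)


def fit_hill(curve: DoseResponseCurve) -> HillFit:
    """Least-squares Hill fit under bounded parameters.

    Deterministic: a coarse grid over e_inf x log10(EC50) x h seeds a
    derivative-free (Nelder-Mead) refinement from the best grid points;
    bounds are e_inf in [0, 1], h in [0.2, 10] and log10(EC50) within two
    decades of the tested dose range.
    """
    doses, responses = curve.doses, curve.responses
    lo_lec, hi_lec = np.log10(doses[0]) - 2.0, np.log10(doses[-1]) + 2.0

    # descending e_inf so grid ties on degenerate (flat) curves resolve
    # to the no-effect convention e_inf = 1
    e_grid = np.linspace(1.0, 0.0, 5)
    lec_grid = np.linspace(lo_lec, hi_lec, 7)
    h_grid = np.logspace(np.log10(HILL_SLOPE_BOUNDS[0]), 1.0, 5)

    # vectorized grid evaluation (5*7*5 candidate parameter triples)
    ee, ll, hh = np.meshgrid(e_grid, lec_grid, h_grid, indexing="ij")
    cand = np.column_stack([ee.ravel(), ll.ravel(), hh.ravel()])
    pred = cand[:, 0:1] + (1.0 - cand[:, 0:1]) / (
        1.0 + (doses[None, :] / 10.0 ** cand[:, 1:2]) ** cand[:, 2:3]
    )
    grid_rss = np.sum((pred - responses[None, :]) ** 2, axis=1)

    bounds = [(0.0, 1.0), (lo_lec, hi_lec), HILL_SLOPE_BOUNDS]
    opts = {"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000}
    best_params, best_rss = None, np.inf
    for idx in np.argsort(grid_rss, kind="stable")[:8]:
        res = minimize(_rss, cand[idx], args=(doses, responses),
                       method="Nelder-Mead", bounds=bounds, options=opts)
        if res.fun < best_rss:
            best_rss, best_params = float(res.fun), res.x
    # one polishing restart from the incumbent (re-seeds the simplex)
    res = minimize(_rss, best_params, args=(doses, responses),
                   method="Nelder-Mead", bounds=bounds, options=opts)
    if res.fun < best_rss:
        best_rss, best_params = float(res.fun), res.x
    e_inf, log_ec50, h = best_params
    return HillFit(e_inf=float(e_inf), ec50=float(10.0**log_ec50), h=float(h), rss=best_rss)


def ic50(fit: HillFit, max_dose: float) -> float:
    """Dose at which modelled viability crosses 0.5, capped at ``max_dose``.

    When the curve never reaches 50% viability (e_inf >= 0.5) the cap is
    returned as a finite, order-preserving sentinel.
    """
    if max_dose <= 0:
        raise ValueError("max_dose must be positive")
    if fit.e_inf >= 0.5:
        return float(max_dose)
    # E(d) = 0.5  =>  (d/ec50)^h = 0.5 / (0.5 - e_inf)
    d = fit.ec50 * (0.5 / (0.5 - fit.e_inf)) ** (1.0 / fit.h)
    return float(min(d, max_dose))


def dss(curve: DoseResponseCurve, fit: HillFit, threshold_pct: float = 10.0) -> float:
    """Drug Sensitivity Score over the tested log10-dose range.

    Inhibition is 100*(1 - E_fit(d)). The area of inhibition where it
    exceeds the activity threshold t (percent) is integrated on a
    1000-point trapezoidal grid in log10(dose) and normalized:

        DSS = 100 * (A - t * Dx) / ((100 - t) * Dx),  clipped to [0, 100]

    with Dx the tested log-dose span.
    """
    if not 0.0 <= threshold_pct < 100.0:
        raise ValueError("threshold_pct must lie in [0, 100)")
    lo, hi = np.log10(curve.doses[0]), np.log10(curve.doses[-1])
    if hi <= lo:
        raise ValueError("dss needs a non-degenerate dose range")
    x = np.linspace(lo, hi, 1000)
    inhibition = 100.0 * (1.0 - fit.response(10.0**x))
    integrand = np.where(inhibition > threshold_pct, np.maximum(inhibition, 0.0), 0.0)
    area = float(np.trapezoid(integrand, x))
    dx = hi - lo
    score = 100.0 * (area - threshold_pct * dx) / ((100.0 - threshold_pct) * dx)
    return float(np.clip(score, 0.0, 100.0))


def summarize_mono(curve: DoseResponseCurve, fit: HillFit | None = None) -> MonoSummary:
    """IC50 / DSS / Einf summary of one mono-therapy curve."""
    if fit is None:
        fit = fit_hill(curve)
    return MonoSummary(
        ic50=ic50(fit, float(curve.doses[-1])),
        dss=dss(curve, fit),
        e_inf=fit.e_inf,
    )
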