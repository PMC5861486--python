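"""Loewe-additivity expected-response surfaces and synergy scoring.

The Loewe null model treats a combination as a drug "combined with
itself": the expected viability E at doses (d_a, d_b) solves the
dose-equivalence equation

    d_a / D_a(E) + d_b / D_b(E) = 1,

where D_i(E) is the dose of drug i alone producing viability E under its
fitted Hill curve. The synergy score of an experiment is 100x the mean
excess of the Loewe-expected surface over the observed viabilities across
all combination wells (positive = observed kill stronger than additive =
synergy); the addition score is 100x the mean shortfall of the expected
surface below the untreated control and uses mono-therapy data only.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .dose_response import DoseResponseCurve, HillFit, fit_hill, hill_response

__all__ = [
    "CombinationExperiment",
    "SynergySample",
    "loewe_expected",
    "loewe_surface",
    "synergy_score",
    "addition_score",
]

_EPS = 1e-9
_MAX_BISECT = 100
_RESID_TOL = 1e-8


@dataclass(frozen=True)
class CombinationExperiment:
    """One (cell line, drug A, drug B) dose matrix plus its mono curves.

    ``observed`` has shape (len(doses_a), len(doses_b)); entries are
    viability fractions in [0, 1.5] (values above 1 = stimulation are
    kept). The drug pair is stored in lexicographic order.
    """

    cell_line_id: str
    drug_a: str
    drug_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    observed: np.ndarray
    mono_a: DoseResponseCurve
    mono_b: DoseResponseCurve

    def __post_init__(self) -> None:
        da = np.asarray(self.doses_a, dtype=float)
        db = np.asarray(self.doses_b, dtype=float)
        obs = np.asarray(self.observed, dtype=float)
        object.__setattr__(self, "doses_a", da)
        object.__setattr__(self, "doses_b", db)
        object.__setattr__(self, "observed", obs)
        if self.drug_a > self.drug_b:
            raise ValueError("drug pair must be stored in lexicographic order")
        if da.size == 0 or db.size == 0:
            raise ValueError("combination dose grid is empty")
        for d in (da, db):
            if np.any(d <= 0) or np.any(np.diff(d) <= 0):
                raise ValueError("combination doses must be positive and ascending")
        if obs.shape != (len(da), len(db)):
            raise ValueError("observed matrix shape does not match dose grid")
        if not np.all(np.isfinite(obs)) or np.any(obs < 0) or np.any(obs > 1.5):
            raise ValueError("observed viabilities must be finite and in [0, 1.5]")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.cell_line_id, self.drug_a, self.drug_b)


@dataclass(frozen=True)
class SynergySample:
    """Synergy and addition scores of one combination experiment."""

    cell_line_id: str
    drug_a: str
    drug_b: str
    synergy_score: float
    addition_score: float

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.cell_line_id, self.drug_a, self.drug_b)


def _inverse_dose(E, e_inf: float, ec50: float, h: float):
    """Dose producing viability E under a Hill curve; +inf where E <= e_inf."""
    E = np.asarray(E, dtype=float)
    out = np.full_like(E, np.inf)
    ok = E > e_inf
    with np.errstate(divide="ignore", over="ignore"):
        out[ok] = ec50 * ((1.0 - E[ok]) / (E[ok] - e_inf)) ** (1.0 / h)
    return out


def _loewe_residual(E, fa: HillFit, fb: HillFit, d_a, d_b):
    Da = _inverse_dose(E, fa.e_inf, fa.ec50, fa.h)
    Db = _inverse_dose(E, fb.e_inf, fb.ec50, fb.h)
    with np.errstate(divide="ignore"):  # d / inf -> 0, d / 0 -> +inf are both wanted
        return d_a / Da + d_b / Db - 1.0


def _solve_grid(fa: HillFit, fb: HillFit, d_a: np.ndarray, d_b: np.ndarray) -> np.ndarray:
    """Vectorized bisection for the Loewe equation on arrays of dose pairs."""
    d_a = np.asarray(d_a, dtype=float)
    d_b = np.asarray(d_b, dtype=float)
    if np.any(d_a < 0) or np.any(d_b < 0):
        raise ValueError("doses must be non-negative")
    out = np.empty(np.broadcast(d_a, d_b).shape, dtype=float)
    d_a, d_b = np.broadcast_arrays(d_a, d_b)

    both_zero = (d_a == 0) & (d_b == 0)
    a_zero = (d_a == 0) & ~both_zero
    b_zero = (d_b == 0) & ~both_zero
    interior = ~(both_zero | a_zero | b_zero)

    out[both_zero] = 1.0
    out[a_zero] = hill_response(d_b[a_zero], fb.e_inf, fb.ec50, fb.h)
    out[b_zero] = hill_response(d_a[b_zero], fa.e_inf, fa.ec50, fa.h)

    if np.any(interior):
        da_i, db_i = d_a[interior], d_b[interior]
        floor = max(fa.e_inf, fb.e_inf) + _EPS
        lo = np.full(da_i.shape, floor)
        hi = np.full(da_i.shape, 1.0 - _EPS)
        g_lo = _loewe_residual(lo, fa, fb, da_i, db_i)
        g_hi = _loewe_residual(hi, fa, fb, da_i, db_i)
        # g is increasing in E; no sign change -> nearer bracket endpoint
        capped_lo = g_lo >= 0
        capped_hi = g_hi <= 0
        sol = np.where(capped_lo, lo, np.where(capped_hi, hi, np.nan))
        active = ~(capped_lo | capped_hi)
        lo_a, hi_a = lo[active], hi[active]
        da_a, db_a = da_i[active], db_i[active]
        mid = 0.5 * (lo_a + hi_a)
        for _ in range(_MAX_BISECT):
            g = _loewe_residual(mid, fa, fb, da_a, db_a)
            lo_a = np.where(g < 0, mid, lo_a)
            hi_a = np.where(g >= 0, mid, hi_a)
            if np.all(np.abs(g) <= _RESID_TOL):
                break
            mid = 0.5 * (lo_a + hi_a)
        sol[active] = mid
        out[interior] = sol
    return out


def loewe_expected(fit_a: HillFit, fit_b: HillFit, d_a: float, d_b: float) -> float:
    """Loewe-expected viability at a single dose pair.

    Solved by bisection on E in (max(e_inf)+1e-9, 1-1e-9); when the dose
    pair lies beyond both drugs' reachable effect (no sign change) the
    nearer bracket endpoint is returned, capping E at the viability floor.
    ``d_a = d_b = 0`` gives 1; a single zero dose reduces to the other
    drug's mono Hill response.
    """
    if d_a < 0 or d_b < 0:
        raise ValueError("doses must be non-negative")
    return float(_solve_grid(fit_a, fit_b, np.array([d_a]), np.array([d_b]))[0])


def loewe_surface(fit_a: HillFit, fit_b: HillFit, doses_a, doses_b) -> np.ndarray:
    """Loewe-expected viability matrix over a dose grid (n_a x n_b)."""
    da = np.asarray(doses_a, dtype=float)[:, None]
    db = np.asarray(doses_b, dtype=float)[None, :]
    return _solve_grid(fit_a, fit_b, da, db)


@lru_cache(maxsize=4096)
def _cached_fit(drug_id: str, cell_line_id: str, doses: tuple, responses: tuple) -> HillFit:
    curve = DoseResponseCurve(drug_id, cell_line_id, np.array(doses), np.array(responses))
    return fit_hill(curve)


def fit_mono(curve: DoseResponseCurve) -> HillFit:
    """Hill fit with content-addressed caching (mono curves are shared
    across the many combinations of one cell line)."""
    return _cached_fit(
        curve.drug_id, curve.cell_line_id, tuple(curve.doses), tuple(curve.responses)
    )


def synergy_score(exp: CombinationExperiment) -> SynergySample:
    """Loewe synergy and addition scores of one experiment.

    Fits Hill curves to both mono-therapy rows, evaluates the expected
    surface over the combination wells (both doses > 0 only) and returns
    S = 100 * mean(E_loewe - observed): positive when the combination
    kills more than additivity predicts.
    """
    fa = fit_mono(exp.mono_a)
    fb = fit_mono(exp.mono_b)
    expected = loewe_surface(fa, fb, exp.doses_a, exp.doses_b)
    s = 100.0 * float(np.mean(expected - exp.observed))
    a = 100.0 * float(np.mean(1.0 - expected))
    return SynergySample(exp.cell_line_id, exp.drug_a, exp.drug_b, s, a)


def addition_score(exp: CombinationExperiment) -> float:
    """Additive-potency summary from mono data only: 100 * mean(1 - E_loewe)."""
    fa = fit_mono(exp.mono_a)
    fb = fit_mono(exp.mono_b)
    expected = loewe_surface(fa, fb, exp.doses_a, exp.doses_b)
    return 100.0 * float(np.mean(1.0 - expected))
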