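"""Reference-model expectation surfaces and summed synergy scores.

Four non-interaction references are supported, spanning the two families in
use for checkerboard screens:

* dose equivalence — Loewe additivity (doses of the two drugs trade off
  along iso-effect contours, ``da/A(v) + db/B(v) = 1``) and HSA (expected
  viability is that of the better single agent);
* multiplicative survival — Bliss independence (expected viability is the
  product of the monotherapy viabilities) and the Chou–Talalay combination
  index in its mutually non-exclusive form.

Each combination matrix is reduced to a signed score: the sum over
combination wells of (expected − observed) viability in percentage points,
so positive totals indicate synergy and negative totals antagonism, with
synergy-only and antagonism-only partial sums carried alongside. Minimum
viability (the tumoricidal-effect readout) completes the metric set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .doseresponse import HillFit, fit_hill
from .grids import DoseMatrix

__all__ = [
    "SynergyResult",
    "bliss_expected",
    "hsa_expected",
    "loewe_expected",
    "loewe_surface",
    "chou_talalay_ci",
    "chou_talalay_surface",
    "score_matrix",
    "min_viability",
    "fit_edges",
    "score_all_models",
]

MODELS = ("loewe", "hsa", "bliss", "chou_talalay")
_EPS = 1e-9


@dataclass(frozen=True)
class SynergyResult:
    """Per-model summed synergy/antagonism for one combination on one culture."""

    combination: str
    culture: str
    model: str
    score_sum: float  # percentage points; positive = synergy
    score_synergy_only: float
    score_antagonism_only: float
    min_viability: float
    n_wells: int
    n_fallback_wells: int = 0  # Loewe wells capped to HSA at the Emax floor


def _check_fractions(va: float, vb: float) -> tuple[float, float]:
    if va < 0 or vb < 0:
        raise ValueError("viability fractions must be non-negative")
    if va > 1 or vb > 1:
        warnings.warn("viability fraction > 1 clamped to 1 for the reference "
                      "model", stacklevel=3)
    return min(va, 1.0), min(vb, 1.0)


def bliss_expected(va: float, vb: float) -> float:
    """Bliss independence: expected combined viability is the product."""
    va, vb = _check_fractions(va, vb)
    return va * vb


def hsa_expected(va: float, vb: float) -> float:
    """Highest single agent: expected viability is the better monotherapy."""
    va, vb = _check_fractions(va, vb)
    return min(va, vb)


def loewe_expected(fit_a: HillFit, fit_b: HillFit, dose_a: float,
                   dose_b: float) -> float:
    """Loewe-additive expected viability at (dose_a, dose_b).

    Solves ``dose_a/A(v) + dose_b/B(v) = 1`` for v by bracketed root
    finding, where A and B invert the two Hill curves. When the implied
    effect lies below the reachable floor of either curve (no root), the
    HSA expectation is returned instead — use :func:`loewe_surface` to
    track how often that cap fires.
    """
    v, _ = _loewe_well(fit_a, fit_b, dose_a, dose_b)
    return v


def _loewe_well(fit_a: HillFit, fit_b: HillFit, dose_a: float,
                dose_b: float) -> tuple[float, bool]:
    if not (fit_a.identifiable and fit_b.identifiable):
        raise ValueError("Loewe expectation requires identifiable Hill fits")
    if dose_a < 0 or dose_b < 0:
        raise ValueError("doses must be non-negative")
    if dose_a == 0 and dose_b == 0:
        return 0.5 * (fit_a.e0 + fit_b.e0), False
    if dose_b == 0:
        return fit_a.predict(dose_a), False
    if dose_a == 0:
        return fit_b.predict(dose_b), False

    lo = max(fit_a.einf, fit_b.einf)
    hi = min(fit_a.e0, fit_b.e0)
    if hi - lo < 10 * _EPS:
        return _hsa_well(fit_a, fit_b, dose_a, dose_b), True
    lo += _EPS * max(1.0, hi - lo)
    hi -= _EPS * max(1.0, hi - lo)

    # scalar Hill inversion inlined: brentq calls f hundreds of times per grid
    e0a, einfa, ec50a, inva = fit_a.e0, fit_a.einf, fit_a.ec50, 1.0 / fit_a.h
    e0b, einfb, ec50b, invb = fit_b.e0, fit_b.einf, fit_b.ec50, 1.0 / fit_b.h

    def f(v: float) -> float:
        da_needed = ec50a * ((e0a - v) / (v - einfa)) ** inva
        db_needed = ec50b * ((e0b - v) / (v - einfb)) ** invb
        return dose_a / da_needed + dose_b / db_needed - 1.0

    if f(lo) >= 0:  # effect deeper than either curve can reach: Emax floor
        return _hsa_well(fit_a, fit_b, dose_a, dose_b), True
    if f(hi) <= 0:  # doses too small to move off the control plateau
        return hi, False
    return brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16), False


def _hsa_well(fit_a: HillFit, fit_b: HillFit, dose_a: float,
              dose_b: float) -> float:
    return min(fit_a.predict(dose_a), fit_b.predict(dose_b))


def loewe_surface(fit_a: HillFit, fit_b: HillFit, doses_a: np.ndarray,
                  doses_b: np.ndarray) -> tuple[np.ndarray, int]:
    """Loewe expectation over a dose grid; returns (surface, n_fallback)."""
    surface = np.empty((len(doses_a), len(doses_b)))
    n_fallback = 0
    for i, da in enumerate(doses_a):
        for j, db in enumerate(doses_b):
            surface[i, j], fb = _loewe_well(fit_a, fit_b, da, db)
            n_fallback += fb
    return surface, n_fallback


def chou_talalay_ci(fit_a: HillFit, fit_b: HillFit, dose_a: float,
                    dose_b: float, observed_fa: float) -> float:
    """Combination index, mutually non-exclusive form.

    Median-effect parameters come from each Hill fit (Dm = ec50, m = h).
    The dose required by drug x alone to reach affected fraction fa is
    ``D_x = Dm_x * (fa/(1-fa))**(1/m_x)`` and

        CI = dose_a/D_a + dose_b/D_b + dose_a*dose_b/(D_a*D_b).

    CI < 1 indicates synergy, CI > 1 antagonism. ``observed_fa`` is clamped
    to [0.005, 0.995] to bound the index at extreme effects.
    """
    if not (fit_a.identifiable and fit_b.identifiable):
        raise ValueError("combination index requires identifiable fits")
    if dose_a < 0 or dose_b < 0 or (dose_a == 0 and dose_b == 0):
        raise ValueError("need non-negative doses with at least one positive")
    fa = float(np.clip(observed_fa, 0.005, 0.995))
    ratio = fa / (1.0 - fa)
    d_a = fit_a.ec50 * ratio ** (1.0 / fit_a.h)
    d_b = fit_b.ec50 * ratio ** (1.0 / fit_b.h)
    return dose_a / d_a + dose_b / d_b + (dose_a * dose_b) / (d_a * d_b)


def chou_talalay_surface(fit_a: HillFit, fit_b: HillFit, matrix: DoseMatrix
                         ) -> np.ndarray:
    """CI for every combination well, from the replicate-mean viability.

    The observed viability is converted to an affected fraction on the
    average response scale of the two fits,
    ``fa = (e0_bar - v) / (e0_bar - einf_bar)``.
    """
    e0 = 0.5 * (fit_a.e0 + fit_b.e0)
    einf = 0.5 * (fit_a.einf + fit_b.einf)
    obs = matrix.combo_block()
    ax_a, ax_b = matrix.axis_a[1:], matrix.axis_b[1:]
    ci = np.full_like(obs, np.nan)
    for i, da in enumerate(ax_a):
        for j, db in enumerate(ax_b):
            v = obs[i, j]
            if np.isnan(v):
                continue
            fa = (e0 - v) / (e0 - einf)
            ci[i, j] = chou_talalay_ci(fit_a, fit_b, da, db, fa)
    return ci


def score_matrix(matrix: DoseMatrix, expected: np.ndarray, model: str,
                 combination: str = "", n_fallback: int = 0) -> SynergyResult:
    """Sum per-well deviations from a reference surface over a matrix.

    ``expected`` covers the n×n nonzero-dose block. For viability models
    the per-well quantity is (expected − observed) × 100 percentage points;
    for ``model="chou_talalay"`` the ``expected`` argument is the CI grid
    and the per-well quantity is (1 − CI) × 100. Missing wells are skipped
    with the well count reported.
    """
    obs = matrix.combo_block()
    if expected.shape != obs.shape:
        raise ValueError(
            f"expected surface shape {expected.shape} does not match the "
            f"combination block {obs.shape}"
        )
    if model == "chou_talalay":
        dev = (1.0 - expected) * 100.0
        dev = np.where(np.isnan(obs), np.nan, dev)
    else:
        dev = (expected - obs) * 100.0
    valid = ~np.isnan(dev)
    if not valid.any():
        raise ValueError("no scoreable wells")
    d = dev[valid]
    return SynergyResult(
        combination=combination,
        culture=matrix.culture,
        model=model,
        score_sum=float(d.sum()),
        score_synergy_only=float(d[d > 0].sum()),
        score_antagonism_only=float(d[d < 0].sum()),
        min_viability=min_viability(matrix),
        n_wells=int(valid.sum()),
        n_fallback_wells=n_fallback,
    )


def min_viability(matrix: DoseMatrix) -> float:
    """Lowest replicate-mean viability over the combination wells."""
    block = matrix.combo_block()
    if np.isnan(block).all():
        raise ValueError("all combination wells missing")
    return float(np.nanmin(block))


def fit_edges(matrix: DoseMatrix) -> tuple[HillFit, HillFit]:
    """Fit each drug's Hill curve from the matrix's monotherapy edges.

    All replicate wells enter the fit jointly.
    """
    fits = []
    for axis, take in (("a", lambda v, r: v[r, 1:, 0]),
                       ("b", lambda v, r: v[r, 0, 1:])):
        doses = matrix.axis_a[1:] if axis == "a" else matrix.axis_b[1:]
        ds, vs = [], []
        for r in range(matrix.n_replicates):
            edge = take(matrix.viability, r)
            ok = ~np.isnan(edge)
            ds.append(doses[ok])
            vs.append(edge[ok])
        fits.append(fit_hill(np.concatenate(ds),
                             np.clip(np.concatenate(vs), 0, 1.5)))
    return fits[0], fits[1]


def score_all_models(matrix: DoseMatrix, fit_a: HillFit | None = None,
                     fit_b: HillFit | None = None,
                     combination: str = "") -> dict[str, SynergyResult]:
    """Score one matrix under every reference model.

    Monotherapy fits are taken from the matrix edges unless supplied.
    Monotherapy viabilities feeding Bliss/HSA are clipped at 1 (outgrowth
    above control carries no extra protection in either reference).
    """
    if fit_a is None or fit_b is None:
        ea, eb = fit_edges(matrix)
        fit_a = fit_a or ea
        fit_b = fit_b or eb
    name = combination or f"{matrix.drug_a}+{matrix.drug_b}"
    va = np.minimum(matrix.mono_a(), 1.0)
    vb = np.minimum(matrix.mono_b(), 1.0)
    bliss = np.outer(va, vb)
    hsa = np.minimum.outer(va, vb)
    results = {
        "bliss": score_matrix(matrix, bliss, "bliss", name),
        "hsa": score_matrix(matrix, hsa, "hsa", name),
    }
    if fit_a.identifiable and fit_b.identifiable:
        loewe, n_fb = loewe_surface(fit_a, fit_b, matrix.axis_a[1:],
                                    matrix.axis_b[1:])
        results["loewe"] = score_matrix(matrix, loewe, "loewe", name,
                                        n_fallback=n_fb)
        ci = chou_talalay_surface(fit_a, fit_b, matrix)
        results["chou_talalay"] = score_matrix(matrix, ci, "chou_talalay", name)
    return results
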