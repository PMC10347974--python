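"""Monotherapy dose-response fitting and sensitivity filtering.

Viability is expressed as a fraction of the vehicle (DMSO) control, doses in
micromolar. Each drug/culture pair is summarised by a four-parameter Hill
curve

    v(d) = einf + (e0 - einf) / (1 + (d / ec50)^h)

with ``e0`` the zero-dose plateau, ``einf`` the infinite-dose floor, ``ec50``
the dose at the half-transition and ``h`` the Hill slope. The *absolute* IC50
(dose at which normalized viability crosses 50%) is derived in closed form
and drives the screen-entry filter: drugs that never reach 50% viability
within the tested range on a sufficient fraction of cultures are dropped,
along with every combination that contains them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "HillFit",
    "SensitivityCall",
    "fit_hill",
    "absolute_ic50",
    "make_sensitivity_call",
    "sensitivity_filter",
    "filter_combinations",
]

# box constraints for the 4PL fit; ec50 bounds are data dependent
E0_BOUNDS = (0.7, 1.2)
EINF_BOUNDS = (0.0, 1.0)
HILL_BOUNDS = (0.1, 10.0)
FLAT_RANGE = 0.1  # viability range below which ec50 is unidentifiable


@dataclass(frozen=True)
class HillFit:
    """Fitted four-parameter dose-response curve for one drug on one culture.

    ``identifiable`` is False for flat responses, where ``ec50`` and ``h``
    are NaN rather than fabricated.
    """

    e0: float
    einf: float
    ec50: float
    h: float
    rss: float
    n_points: int
    converged: bool
    identifiable: bool = True

    def predict(self, dose):
        """Predicted viability fraction at ``dose`` (scalar or array, µM)."""
        d = np.asarray(dose, dtype=float)
        if not self.identifiable:
            out = np.full_like(d, self.e0, dtype=float)
            return float(out) if np.isscalar(dose) else out
        with np.errstate(divide="ignore"):
            ratio = np.where(d > 0, (d / self.ec50) ** self.h, 0.0)
        v = self.einf + (self.e0 - self.einf) / (1.0 + ratio)
        return float(v) if np.isscalar(dose) else v

    def inverse(self, v):
        """Dose producing viability ``v`` (the Hill curve inverted).

        Valid for ``einf < v < e0``; returns +inf at or below the floor and
        0 at or above the plateau.
        """
        if not self.identifiable:
            raise ValueError("cannot invert an unidentifiable fit")
        v = np.asarray(v, dtype=float)
        scalar = v.ndim == 0
        v = np.atleast_1d(v)
        out = np.empty_like(v)
        out[v >= self.e0] = 0.0
        out[v <= self.einf] = np.inf
        mid = (v > self.einf) & (v < self.e0)
        out[mid] = self.ec50 * ((self.e0 - v[mid]) / (v[mid] - self.einf)) ** (
            1.0 / self.h
        )
        return float(out[0]) if scalar else out


@dataclass(frozen=True)
class SensitivityCall:
    """Screen-entry decision for one drug on one culture."""

    drug: str
    culture: str
    ic50_abs: Optional[float]  # µM; None = 50% viability never reached
    sensitive: bool
    extrapolated: bool = False  # IC50 lies above the tested dose range


def _hill(d, e0, einf, log10_ec50, h):
    return einf + (e0 - einf) / (1.0 + (d / 10.0**log10_ec50) ** h)


def _hill_jac(d, e0, einf, log10_ec50, h):
    # analytic jacobian of _hill; keeps the multi-start fit cheap
    ec50 = 10.0**log10_ec50
    u = (d / ec50) ** h
    denom = 1.0 + u
    span = e0 - einf
    d_e0 = 1.0 / denom
    d_einf = u / denom
    d_log = span * u * h * np.log(10.0) / denom**2
    d_h = -span * u * np.log(d / ec50) / denom**2
    return np.stack([d_e0, d_einf, d_log, d_h], axis=-1)


def fit_hill(doses: Sequence[float], viabilities: Sequence[float]) -> HillFit:
    """Fit the 4PL curve to paired (dose, viability) observations.

    Replicates are passed as repeated dose entries and enter the fit jointly
    (no pre-averaging). Requires at least 4 distinct positive doses and
    viabilities within [0, 1.5]. A flat response (range of per-dose mean
    viabilities below 0.1) returns an unidentifiable fit instead of a
    spurious ec50.
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    if d.shape != v.shape or d.ndim != 1:
        raise ValueError("doses and viabilities must be 1-D arrays of equal length")
    if np.any(d <= 0):
        raise ValueError("doses must be strictly positive (dose-0 wells set e0 "
                         "through the fit bounds, not the data)")
    if np.any((v < 0) | (v > 1.5)):
        raise ValueError("viabilities must lie in [0, 1.5]")
    uniq = np.unique(d)
    if uniq.size < 4:
        raise ValueError(f"need >=4 distinct positive doses, got {uniq.size}")

    dose_means = np.array([v[d == u].mean() for u in uniq])
    if dose_means.max() - dose_means.min() < FLAT_RANGE:
        level = float(np.clip(v.mean(), *E0_BOUNDS))
        rss = float(np.sum((v - v.mean()) ** 2))
        return HillFit(level, level, np.nan, np.nan, rss, d.size, True, False)

    lo_ec50, hi_ec50 = uniq.min() / 100.0, uniq.max() * 100.0
    bounds = (
        [E0_BOUNDS[0], EINF_BOUNDS[0], np.log10(lo_ec50), HILL_BOUNDS[0]],
        [E0_BOUNDS[1], EINF_BOUNDS[1], np.log10(hi_ec50), HILL_BOUNDS[1]],
    )
    e0_start = float(np.clip(dose_means[0], *E0_BOUNDS))
    einf_start = float(np.clip(dose_means[-1], *EINF_BOUNDS))
    # three log-spaced ec50 starts guard against local minima
    starts = np.log10(
        [np.sqrt(uniq.min() * uniq.max()), uniq.min(), uniq.max()]
    )
    best = None
    for s in starts:
        p0 = [e0_start, einf_start, float(s), 1.0]
        try:
            popt, _ = curve_fit(
                _hill, d, v, p0=p0, bounds=bounds, jac=_hill_jac, maxfev=200
            )
        except RuntimeError:
            continue
        rss = float(np.sum((_hill(d, *popt) - v) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return HillFit(e0_start, einf_start, np.nan, np.nan, np.inf,
                       d.size, False, False)
    (e0, einf, log_ec50, h), rss = best
    if einf > e0:  # rising response: ec50 not meaningful for a kill curve
        level = float(np.clip(v.mean(), *E0_BOUNDS))
        return HillFit(level, level, np.nan, np.nan, rss, d.size, True, False)
    return HillFit(float(e0), float(einf), float(10.0**log_ec50), float(h),
                   rss, d.size, True, True)


def absolute_ic50(fit: HillFit) -> Optional[float]:
    """Dose (µM) at which predicted viability equals 50%, or None.

    Closed form: solving ``einf + (e0-einf)/(1+(d/ec50)^h) = 0.5`` gives
    ``d = ec50 * ((e0 - 0.5)/(0.5 - einf))^(1/h)``. Returns None ("not
    reached") when the floor ``einf`` is at or above 0.5.
    """
    if not fit.converged:
        raise ValueError("absolute_ic50 requires a converged fit")
    if not fit.identifiable or fit.einf >= 0.5 or fit.e0 <= 0.5:
        return None
    return float(fit.ec50 * ((fit.e0 - 0.5) / (0.5 - fit.einf)) ** (1.0 / fit.h))


def make_sensitivity_call(
    drug: str, culture: str, fit: HillFit, max_dose: float
) -> SensitivityCall:
    """Derive the screen-entry call from a monotherapy fit and the top dose."""
    ic50 = absolute_ic50(fit) if fit.converged else None
    if ic50 is None:
        return SensitivityCall(drug, culture, None, False)
    return SensitivityCall(drug, culture, ic50, ic50 <= max_dose,
                           extrapolated=ic50 > max_dose)


def sensitivity_filter(
    calls: Iterable[SensitivityCall], min_fraction: float = 1.0
) -> set[str]:
    """Drugs retained for the combination screen.

    A drug is kept iff its absolute IC50 is reached within the tested range
    (``sensitive`` call) on at least ``min_fraction`` of its cultures
    (default: all of them).
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no sensitivity calls provided")
    per_drug: dict[str, list[bool]] = {}
    for c in calls:
        per_drug.setdefault(c.drug, []).append(c.sensitive)
    return {
        drug for drug, flags in per_drug.items()
        if np.mean(flags) >= min_fraction
    }


def filter_combinations(
    combinations: Iterable[tuple[str, str]], retained: set[str]
) -> list[tuple[str, str]]:
    """Combinations surviving the filter: both partners must be retained."""
    return [(a, b) for a, b in combinations if a in retained and b in retained]


def fit_monotherapies(table) -> "pd.DataFrame":
    """Fit every (drug, culture) group of a long-format viability table.

    ``table`` is a pandas DataFrame with columns {culture, drug, dose_um,
    replicate, viability} (doses in µM, viability as fraction of control).
    Returns one row per (drug, culture) with the HillFit fields and the
    sensitivity call against that group's top tested dose.
    """
    import pandas as pd  # deferred: the numeric core stays frame-free

    required = {"culture", "drug", "dose_um", "replicate", "viability"}
    if not required.issubset(table.columns):
        raise ValueError(f"missing columns {required - set(table.columns)}")
    rows = []
    for (drug, culture), grp in table.groupby(["drug", "culture"], sort=True):
        fit = fit_hill(grp["dose_um"].to_numpy(),
                       grp["viability"].to_numpy())
        call = make_sensitivity_call(drug, culture, fit,
                                     max_dose=float(grp["dose_um"].max()))
        rows.append({
            "drug": drug, "culture": culture, "e0": fit.e0, "einf": fit.einf,
            "ec50_um": fit.ec50, "hill_slope": fit.h, "rss": fit.rss,
            "n_points": fit.n_points, "converged": fit.converged,
            "identifiable": fit.identifiable, "ic50_abs_um": call.ic50_abs,
            "sensitive": call.sensitive, "extrapolated": call.extrapolated,
        })
    return pd.DataFrame(rows)
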