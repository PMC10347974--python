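"""Long-term (repeated-exposure) synergy scoring and classification.

Endpoint viability matrices from the 18-day spheroid assay are scored with
the same Loewe engine as the short-term screen. Because no external cut-off
exists for "longitudinal synergy", combinations are called against a
permutation null: well values are shuffled across plate positions
(monotherapy edges included, vehicle control fixed) and the shuffled matrix
is rescored from scratch — monotherapy edges refitted, expectation surface
rebuilt — so the null captures how large a summed score arises when the
dose structure is destroyed. A combination is synergistic when its observed
score exceeds the null's 95th percentile in at least one culture. Under an
exchangeable-noise null the observed matrix is one more permutation, which
makes the call exact at the nominal level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Optional

import numpy as np

from .grids import DoseMatrix
from .surfaces import (HillFit, fit_edges, loewe_surface, score_all_models)

__all__ = ["LongitudinalResult", "score_longitudinal", "classify_longitudinal"]


@dataclass
class LongitudinalResult:
    """Loewe synergy call for one combination on one culture at endpoint."""

    combination: str
    culture: str
    loewe_score_sum: float  # percentage points
    null_threshold: float = np.nan  # permutation-null 95th percentile
    synergistic: Optional[bool] = None
    hsa_only: bool = False  # unfittable monotherapy edge; HSA score reported
    n_fallback_wells: int = 0
    schedule: Optional[dict] = None  # exposure/imaging metadata, untouched


def score_longitudinal(matrix: DoseMatrix, fit_a: Optional[HillFit] = None,
                       fit_b: Optional[HillFit] = None,
                       combination: str = "",
                       schedule: Optional[dict] = None) -> LongitudinalResult:
    """Loewe score for an endpoint matrix, via the short-term engine.

    If a monotherapy edge cannot support a Hill fit, the HSA score is
    reported instead and flagged. ``schedule`` (exposure windows, imaging
    days) is carried through to the result unchanged.
    """
    results = score_all_models(matrix, fit_a, fit_b, combination=combination)
    if "loewe" in results:
        r = results["loewe"]
        return LongitudinalResult(r.combination, r.culture, r.score_sum,
                                  n_fallback_wells=r.n_fallback_wells,
                                  schedule=schedule)
    r = results["hsa"]
    return LongitudinalResult(r.combination, r.culture, r.score_sum,
                              hsa_only=True, schedule=schedule)


def _edges_fittable(matrix: DoseMatrix) -> bool:
    """Both monotherapy edges show a clear decreasing dose trend.

    A Hill fit is meaningful only when viability falls with dose; the gate
    (Spearman correlation of edge means vs dose rank <= -0.5) rejects
    trendless edges before any optimizer runs. The same gate is applied to
    observed and permuted matrices, so permutation calls stay exchangeable.
    """
    mean = matrix.replicate_mean()
    for edge in (mean[1:, 0], mean[0, 1:]):
        ok = ~np.isnan(edge)
        if ok.sum() < 4:
            return False
        ranks_d = np.arange(ok.sum(), dtype=float)  # doses already ascending
        ranks_v = np.argsort(np.argsort(edge[ok])).astype(float)
        denom = np.sqrt(((ranks_d - ranks_d.mean()) ** 2).sum()
                        * ((ranks_v - ranks_v.mean()) ** 2).sum())
        if denom == 0:
            return False
        rho = ((ranks_d - ranks_d.mean()) * (ranks_v - ranks_v.mean())
               ).sum() / denom
        if rho > -0.5:
            return False
    return True


def _rescore(matrix: DoseMatrix) -> tuple[float, bool]:
    """Summed Loewe score recomputed from scratch (HSA when unfittable).

    Returns (score, hsa_only). The dose-equivalence surface needs
    identifiable monotone edges; matrices failing the trend gate or the
    Hill fit are scored against the HSA expectation instead.
    """
    mean = matrix.replicate_mean()
    hsa_only = True
    expected = None
    if _edges_fittable(matrix):
        fit_a, fit_b = fit_edges(matrix)
        if fit_a.identifiable and fit_b.identifiable:
            expected, _ = loewe_surface(fit_a, fit_b, matrix.axis_a[1:],
                                        matrix.axis_b[1:])
            hsa_only = False
    if expected is None:
        va = np.minimum(mean[1:, 0], 1.0)
        vb = np.minimum(mean[0, 1:], 1.0)
        expected = np.minimum.outer(va, vb)
    dev = (expected - mean[1:, 1:]) * 100.0
    return float(np.nansum(dev)), hsa_only


def _null_scores(matrix: DoseMatrix, n_permutations: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Scores of position-shuffled copies of the replicate-mean matrix.

    The vehicle control at (0, 0) stays put; every other well — edges
    included — is exchanged, and each shuffled matrix goes through the full
    scoring path (edge refit, expectation surface, summed deviation).
    """
    mean = matrix.replicate_mean()
    flat = mean.ravel()
    movable = ~np.isnan(flat)
    movable[0] = False  # (0, 0) control
    idx = np.flatnonzero(movable)
    scores = np.empty(n_permutations)
    for b in range(n_permutations):
        shuffled = flat.copy()
        shuffled[idx] = flat[idx][rng.permutation(idx.size)]
        perm = replace(matrix,
                       viability=shuffled.reshape(mean.shape)[None, :, :])
        scores[b] = _rescore(perm)[0]
    return scores


def classify_longitudinal(
    matrices: Mapping[tuple[str, str], DoseMatrix],
    n_permutations: int = 1000,
    seed: int = 0,
    quantile: float = 0.95,
) -> tuple[dict[str, bool], list[LongitudinalResult]]:
    """Permutation-null synergy call per combination.

    ``matrices`` maps (combination, culture) to the endpoint DoseMatrix.
    Observed and null scores are both computed on the replicate-mean
    matrix through the identical rescoring path, so the comparison is
    exchangeable. Returns the per-combination flag (synergistic in >= 1
    culture) and the per-culture results with their null thresholds.
    Deterministic for a given seed; matrices are processed in sorted key
    order.
    """
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives a coarse null "
                      "threshold")
    rng = np.random.default_rng(seed)
    results: list[LongitudinalResult] = []
    flags: dict[str, bool] = {}
    for (combo, culture) in sorted(matrices):
        matrix = matrices[(combo, culture)]
        collapsed = replace(matrix,
                            viability=matrix.replicate_mean()[None, :, :])
        score, hsa_only = _rescore(collapsed)
        res = LongitudinalResult(combo, culture, score, hsa_only=hsa_only)
        null = _null_scores(matrix, n_permutations, rng)
        res.null_threshold = float(np.quantile(null, quantile))
        res.synergistic = bool(res.loewe_score_sum > res.null_threshold)
        results.append(res)
        flags[combo] = flags.get(combo, False) or res.synergistic
    return flags, results
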