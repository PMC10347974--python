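"""End-to-end screen analysis: matrices -> scores -> panels -> selection.

Runs the full short-term analysis on a collection of combination matrices:
per-matrix Hill fits and multi-model scoring, assembly of the
combination × culture × metric panels (signed sums for the primary
analysis, synergy-only sums for the validation), z-scaling, BIC-selected
Gaussian-mixture clustering, K-means validation and the consistent-synergy
selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .consolidate import (ClusterModel, MetricPanel, gmm_cluster,
                          kmeans_validate, select_consistent, zscale)
from .grids import DoseMatrix
from .surfaces import score_all_models

__all__ = ["ScreenAnalysis", "analyze_screen"]

PRIMARY_METRICS = ("loewe", "hsa", "bliss", "min_viability")
VALIDATION_METRICS = ("loewe", "hsa", "bliss", "chou_talalay", "min_viability")


@dataclass
class ScreenAnalysis:
    """Everything the consolidation stage produced for one screen."""

    panel: MetricPanel  # signed score sums + min viability, z-scaled
    synergy_only_panel: MetricPanel
    model: ClusterModel
    kmeans_labels: np.ndarray
    selected: set[str]
    scores: pd.DataFrame  # tidy per (combination, culture, model) record

    def assignments(self) -> pd.DataFrame:
        return pd.DataFrame({
            "combination": self.panel.combinations,
            "gmm_cluster": self.model.labels,
            "kmeans_cluster": self.kmeans_labels,
            "selected": [c in self.selected for c in self.panel.combinations],
        })


def analyze_screen(
    matrices: Mapping[tuple[str, str, str], DoseMatrix],
    seed: int = 0,
    k_range: Optional[range] = None,
    n_restarts: int = 10,
) -> ScreenAnalysis:
    """Run scoring and consolidation over (culture, drug_a, drug_b) matrices.

    Combinations and cultures are taken from the mapping keys; missing
    combination × culture cells stay missing in the panels.
    """
    combos = sorted({f"{a}+{b}" for (_, a, b) in matrices})
    cultures = sorted({c for (c, _, _) in matrices})
    ci = {c: i for i, c in enumerate(combos)}
    li = {c: i for i, c in enumerate(cultures)}

    primary = np.full((len(combos), len(cultures), len(PRIMARY_METRICS)),
                      np.nan)
    validation = np.full((len(combos), len(cultures), len(VALIDATION_METRICS)),
                         np.nan)
    records = []
    for (culture, da, db) in sorted(matrices):
        matrix = matrices[(culture, da, db)]
        combo = f"{da}+{db}"
        results = score_all_models(matrix, combination=combo)
        for model_name, res in results.items():
            records.append({
                "combination": combo, "culture": culture, "model": model_name,
                "score_sum": res.score_sum,
                "score_synergy_only": res.score_synergy_only,
                "score_antagonism_only": res.score_antagonism_only,
                "min_viability": res.min_viability,
                "n_wells": res.n_wells,
                "n_fallback_wells": res.n_fallback_wells,
            })
            if model_name in PRIMARY_METRICS:
                primary[ci[combo], li[culture],
                        PRIMARY_METRICS.index(model_name)] = res.score_sum
            if model_name in VALIDATION_METRICS:
                validation[ci[combo], li[culture],
                           VALIDATION_METRICS.index(model_name)] = \
                    res.score_synergy_only
        any_res = next(iter(results.values()))
        primary[ci[combo], li[culture],
                PRIMARY_METRICS.index("min_viability")] = any_res.min_viability
        validation[ci[combo], li[culture],
                   VALIDATION_METRICS.index("min_viability")] = \
            any_res.min_viability

    panel = zscale(MetricPanel(combos, cultures, list(PRIMARY_METRICS),
                               primary))
    syn_panel = zscale(MetricPanel(combos, cultures,
                                   list(VALIDATION_METRICS), validation))

    feats, _ = panel.features(list(PRIMARY_METRICS))
    model = gmm_cluster(feats, k_range=k_range, n_restarts=n_restarts,
                        seed=seed, metric_names=PRIMARY_METRICS)
    vfeats, _ = syn_panel.features(list(VALIDATION_METRICS))
    km_labels = kmeans_validate(vfeats, k=model.k, seed=seed,
                                n_restarts=n_restarts)
    selected = select_consistent(model, panel, km_labels,
                                 validation_panel=syn_panel)
    return ScreenAnalysis(
        panel=panel, synergy_only_panel=syn_panel, model=model,
        kmeans_labels=km_labels, selected=selected,
        scores=pd.DataFrame.from_records(records),
    )
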