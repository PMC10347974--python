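"""Z-scale consolidation of screen metrics and model-based clustering.

Synergy scores from different reference models and the minimum-viability
readout live on incommensurable scales, so each metric is standardized to
z-values over all combination × culture entries before clustering. Gaussian
mixture models (number of components and covariance family chosen by BIC)
partition the combinations; a K-means run on the synergy-only variant of the
metrics validates the partition, and the "consistently synergistic"
combinations are those assigned to the synergistic-and-tumoricidal cluster
in both analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

__all__ = [
    "MetricPanel",
    "ClusterModel",
    "zscale",
    "gmm_cluster",
    "kmeans_validate",
    "select_consistent",
    "replicate_concordance",
]

SYNERGY_METRICS = ("loewe", "hsa", "bliss")
VIABILITY_METRIC = "min_viability"
COVARIANCE_FAMILIES = ("diag", "full", "tied", "spherical")


@dataclass
class MetricPanel:
    """Combinations × cultures × metrics tensor of screen scores.

    ``values`` holds raw scores (NaN = missing); ``zvalues`` the per-metric
    standardization, populated by :func:`zscale`. Missing entries stay
    missing through every transformation.
    """

    combinations: list[str]
    cultures: list[str]
    metrics: list[str]
    values: np.ndarray  # (C, L, M)
    zvalues: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        expected = (len(self.combinations), len(self.cultures),
                    len(self.metrics))
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != {expected}")

    def summary(self, scaled: bool = True) -> np.ndarray:
        """Per-combination median over cultures (C × metrics)."""
        source = self.zvalues if scaled else self.values
        if source is None:
            raise ValueError("call zscale() before requesting z summaries")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmedian(source, axis=1)

    def features(self, metrics: Sequence[str], scaled: bool = True
                 ) -> tuple[np.ndarray, int]:
        """Clustering feature matrix (C × len(metrics)) of median z-values.

        Remaining missing entries are imputed with the per-metric median;
        the imputation count is returned so it can be reported, never
        silently absorbed.
        """
        idx = [self.metrics.index(m) for m in metrics]
        feats = self.summary(scaled=scaled)[:, idx]
        n_imputed = int(np.isnan(feats).sum())
        if n_imputed:
            med = np.nanmedian(feats, axis=0)
            feats = np.where(np.isnan(feats), med, feats)
        return feats, n_imputed


def zscale(panel: MetricPanel) -> MetricPanel:
    """Standardize each metric to mean 0, sample SD 1 (n−1 denominator).

    Statistics are taken over all non-missing combination × culture entries
    of that metric. A metric with zero spread or fewer than 2 values is an
    error (it cannot be made commensurable).
    """
    z = np.full_like(panel.values, np.nan, dtype=float)
    for m, name in enumerate(panel.metrics):
        x = panel.values[:, :, m]
        ok = ~np.isnan(x)
        if ok.sum() < 2:
            raise ValueError(f"metric {name!r} has fewer than 2 values")
        sd = x[ok].std(ddof=1)
        if sd == 0:
            raise ValueError(f"metric {name!r} has zero standard deviation")
        z[:, :, m] = (x - x[ok].mean()) / sd
    return MetricPanel(panel.combinations, panel.cultures, panel.metrics,
                       panel.values, zvalues=z)


@dataclass
class ClusterModel:
    """Selected Gaussian-mixture clustering of the combination panel."""

    k: int
    labels: np.ndarray  # 1-based assignments, length C
    means: np.ndarray
    covariance_type: str
    weights: np.ndarray
    bic: float
    seed: int
    bic_table: pd.DataFrame = field(repr=False, default=None)
    characterization: Optional[pd.DataFrame] = None  # cluster × metric medians

    def report(self) -> dict:
        """JSON-serializable model report: k, BIC table, characterization."""
        out = {
            "k": int(self.k),
            "covariance_type": self.covariance_type,
            "bic": float(self.bic),
            "seed": int(self.seed),
            "weights": [float(w) for w in self.weights],
            "bic_table": self.bic_table.to_dict(orient="records"),
        }
        if self.characterization is not None:
            out["characterization"] = {
                str(k): {m: float(v) for m, v in row.items()}
                for k, row in self.characterization.iterrows()
            }
        return out


def gmm_cluster(features: np.ndarray, k_range: Optional[Sequence[int]] = None,
                n_restarts: int = 10, seed: int = 0,
                covariance_families: Sequence[str] = COVARIANCE_FAMILIES,
                metric_names: Optional[Sequence[str]] = None) -> ClusterModel:
    """EM fits over k and covariance family; lowest BIC wins.

    Deterministic for a given seed. ``k_range`` defaults to 1..min(9, C−1).
    """
    X = np.asarray(features, dtype=float)
    if np.isnan(X).any():
        raise ValueError("features contain NaN; impute before clustering")
    n = X.shape[0]
    if k_range is None:
        k_range = range(1, min(10, n))
    k_range = list(k_range)
    if max(k_range) > n - 1:
        raise ValueError(f"max k {max(k_range)} needs at least "
                         f"{max(k_range) + 1} observations, have {n}")
    rows = []
    best = None
    for k in k_range:
        for fam in covariance_families:
            gm = GaussianMixture(n_components=k, covariance_type=fam,
                                 n_init=n_restarts, random_state=seed,
                                 reg_covar=1e-6)
            gm.fit(X)
            bic = gm.bic(X)
            # components supported by too few points are likelihood spikes
            # (covariance collapsing onto the observations), not clusters;
            # a full covariance needs at least d+1 points for full rank,
            # per-component diagonal/spherical variances need at least 2
            # (tied pools all observations)
            min_support = X.shape[1] + 1 if fam == "full" else 2
            counts = np.bincount(gm.predict(X), minlength=k)
            degenerate = bool((counts < min_support).any())
            rows.append({"k": k, "covariance": fam, "bic": bic,
                         "degenerate": degenerate})
            if degenerate:
                continue
            if best is None or bic < best[0]:
                best = (bic, k, fam, gm)
    if best is None:
        raise ValueError("no non-degenerate mixture model found")
    bic_val, k, fam, gm = best
    labels = gm.predict(X) + 1
    model = ClusterModel(
        k=k, labels=labels, means=gm.means_, covariance_type=fam,
        weights=gm.weights_, bic=float(bic_val), seed=seed,
        bic_table=pd.DataFrame(rows),
    )
    if metric_names is not None:
        model.characterization = characterize(labels, X, metric_names)
    return model


def characterize(labels: np.ndarray, features: np.ndarray,
                 metric_names: Sequence[str]) -> pd.DataFrame:
    """Per-cluster median of each clustering feature."""
    rows = {}
    for lab in np.unique(labels):
        rows[int(lab)] = np.median(features[labels == lab], axis=0)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(metric_names))


def kmeans_validate(features: np.ndarray, k: int, seed: int = 0,
                    n_restarts: int = 10) -> np.ndarray:
    """K-means partition (1-based labels) on the synergy-only metric panel."""
    X = np.asarray(features, dtype=float)
    if np.isnan(X).any():
        raise ValueError("features contain NaN; impute before clustering")
    if k > X.shape[0]:
        raise ValueError("more clusters than observations")
    if k == 1:
        return np.ones(X.shape[0], dtype=int)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(X) + 1


def _synergy_clusters(labels: np.ndarray, features: np.ndarray,
                      metric_names: Sequence[str],
                      synergy_metrics: Sequence[str],
                      viability_metric: str) -> list[int]:
    """Clusters read as "synergy with viability loss".

    A qualifying cluster sits above the screen average on the synergy
    metrics (pooled median z > 0) and below it on minimum viability
    (median z < 0). Mixture components are not clusters: when BIC resolves
    the synergetic region into several components, every component with
    this profile belongs to the synergy cluster, so all qualifying labels
    are returned. A single-cluster solution offers no contrast and yields
    no call.
    """
    uniq = np.unique(labels)
    if uniq.size < 2:
        return []
    syn_idx = [metric_names.index(m) for m in synergy_metrics
               if m in metric_names]
    via_idx = metric_names.index(viability_metric)
    out = []
    for lab in uniq:
        member = features[labels == lab]
        syn_med = float(np.median(member[:, syn_idx]))
        via_med = float(np.median(member[:, via_idx]))
        if via_med < 0 and syn_med > 0:
            out.append(int(lab))
    return out


def select_consistent(
    model: ClusterModel,
    panel: MetricPanel,
    validation_labels: np.ndarray,
    validation_panel: Optional[MetricPanel] = None,
    synergy_metrics: Sequence[str] = SYNERGY_METRICS,
    viability_metric: str = VIABILITY_METRIC,
) -> set[str]:
    """Combinations consistently called synergistic-and-tumoricidal.

    The synergy-with-viability-loss cluster is identified independently in
    the GMM partition (on ``panel``) and in the validation K-means
    partition (on ``validation_panel``, default the same panel); the
    returned set is the intersection of their memberships. Empty, with a
    warning, when either analysis shows no such cluster.
    """
    validation_panel = validation_panel or panel
    feats, _ = panel.features(list(panel.metrics))
    gmm_labs = _synergy_clusters(model.labels, feats, list(panel.metrics),
                                 synergy_metrics, viability_metric)
    vfeats, _ = validation_panel.features(list(validation_panel.metrics))
    val_syn = [m for m in validation_panel.metrics if m != viability_metric]
    km_labs = _synergy_clusters(validation_labels, vfeats,
                                list(validation_panel.metrics), val_syn,
                                viability_metric)
    if not gmm_labs or not km_labs:
        warnings.warn("no cluster combines synergy with viability loss; "
                      "returning an empty selection")
        return set()
    combos = np.asarray(panel.combinations)
    gmm_members = set(map(str, combos[np.isin(model.labels, gmm_labs)]))
    km_members = set(map(str, np.asarray(validation_panel.combinations)[
        np.isin(validation_labels, km_labs)]))
    return gmm_members & km_members


def replicate_concordance(scores_rep1: Sequence[float],
                          scores_rep2: Sequence[float],
                          method: str = "pearson") -> tuple[float, float]:
    """Correlation between paired replicate score vectors: (r, two-sided p)."""
    x = np.asarray(scores_rep1, dtype=float)
    y = np.asarray(scores_rep2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("replicate score vectors must be 1-D and paired")
    if x.size < 3:
        raise ValueError("need at least 3 paired scores")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)
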