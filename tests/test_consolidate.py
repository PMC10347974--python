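import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from synscreen.consolidate import (MetricPanel, gmm_cluster, kmeans_validate,
                                   replicate_concordance, select_consistent,
                                   zscale)
from synscreen.synthdata import make_blobs


def panel_from(values, metrics=None):
    values = np.asarray(values, dtype=float)
    C, L, M = values.shape
    return MetricPanel([f"x{i}" for i in range(C)],
                       [f"c{i}" for i in range(L)],
                       metrics or [f"m{i}" for i in range(M)], values)


class TestZscale:
    def test_two_point_sample_sd(self):
        # {0, 2} with the n-1 denominator standardizes to +/- 1/sqrt(2)
        p = zscale(panel_from(np.array([0.0, 2.0]).reshape(2, 1, 1)))
        z = p.zvalues[:, 0, 0]
        assert z[0] == pytest.approx(-0.7071, abs=1e-4)
        assert z[1] == pytest.approx(+0.7071, abs=1e-4)

    def test_mean_zero_unit_sd_per_metric(self, rng):
        p = zscale(panel_from(rng.normal(5, 3, (8, 5, 3))))
        for m in range(3):
            z = p.zvalues[:, :, m]
            assert z.mean() == pytest.approx(0.0, abs=1e-9)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_idempotent_on_standardized_input(self, rng):
        x = rng.normal(0, 1, (10, 4, 2))
        x = (x - x.mean((0, 1))) / x.std((0, 1), ddof=1)
        p = zscale(panel_from(x))
        assert np.allclose(p.zvalues, x, atol=1e-12)

    def test_missing_entries_stay_missing(self, rng):
        x = rng.normal(0, 1, (6, 3, 1))
        x[2, 1, 0] = np.nan
        p = zscale(panel_from(x))
        assert np.isnan(p.zvalues[2, 1, 0])
        assert np.isfinite(p.zvalues[~np.isnan(x)]).all()

    def test_zero_sd_metric_named_in_error(self):
        x = np.ones((4, 2, 1))
        with pytest.raises(ValueError, match="m0"):
            zscale(panel_from(x))

    def test_too_few_values_error(self):
        x = np.full((4, 1, 1), np.nan)
        x[0, 0, 0] = 1.0
        with pytest.raises(ValueError, match="fewer than 2"):
            zscale(panel_from(x))


class TestGmmCluster:
    def test_three_blobs_recovered_exactly(self):
        X, truth = make_blobs(3, 30, sep=8.0, seed=0)
        model = gmm_cluster(X, seed=0)
        assert model.k == 3
        assert adjusted_rand_score(truth, model.labels) == pytest.approx(1.0)
        # recovered means match the sample means of the true clusters (the
        # finite-n optimum) to well under the within-cluster spread
        for lab in range(3):
            target = X[truth == lab].mean(axis=0)
            d = np.linalg.norm(model.means - target, axis=1)
            assert d.min() < 0.2

    def test_identical_points_give_one_cluster(self):
        X = np.zeros((12, 3))
        model = gmm_cluster(X, seed=0)
        assert model.k == 1
        assert set(model.labels) == {1}

    def test_reproducible_under_seed(self):
        X, _ = make_blobs(3, 20, sep=3.0, seed=4)
        m1 = gmm_cluster(X, seed=11)
        m2 = gmm_cluster(X, seed=11)
        assert m1.k == m2.k
        assert np.array_equal(m1.labels, m2.labels)
        assert m1.bic == m2.bic

    def test_k_range_exceeding_observations_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            gmm_cluster(X, k_range=[6], seed=0)

    def test_nan_features_rejected(self):
        X = np.full((10, 2), np.nan)
        with pytest.raises(ValueError):
            gmm_cluster(X, seed=0)


class TestKmeansValidate:
    def test_blobs_ari_one(self):
        X, truth = make_blobs(3, 30, sep=8.0, seed=1)
        labels = kmeans_validate(X, k=3, seed=0)
        assert adjusted_rand_score(truth, labels) == pytest.approx(1.0)

    def test_k_one_single_label(self):
        X, _ = make_blobs(2, 10, sep=3.0, seed=2)
        assert set(kmeans_validate(X, k=1, seed=0)) == {1}


class TestSelectConsistent:
    @staticmethod
    def synthetic_panel(rng, n_syn=10, n_total=40, shift=3.0):
        """Panels with an injected synergy+tumoricidal block."""
        C, L = n_total, 6
        metrics = ["loewe", "hsa", "bliss", "min_viability"]
        x = rng.normal(0, 20, (C, L, 4))
        x[:, :, 3] = rng.normal(0.5, 0.1, (C, L))  # viability fractions
        x[:n_syn, :, :3] += shift * 20
        x[:n_syn, :, 3] -= 0.3
        return zscale(MetricPanel([f"x{i}" for i in range(C)],
                                  [f"c{i}" for i in range(L)], metrics, x))

    def test_injected_block_recovered(self, rng):
        panel = self.synthetic_panel(rng)
        feats, _ = panel.features(panel.metrics)
        model = gmm_cluster(feats, seed=0, metric_names=panel.metrics)
        km = kmeans_validate(feats, k=model.k, seed=0)
        selected = select_consistent(model, panel, km)
        truth = {f"x{i}" for i in range(10)}
        assert len(selected & truth) >= 9
        assert len(selected - truth) <= 2

    def test_selection_subset_of_gmm_members(self, rng):
        panel = self.synthetic_panel(rng)
        feats, _ = panel.features(panel.metrics)
        model = gmm_cluster(feats, seed=0)
        km = kmeans_validate(feats, k=model.k, seed=0)
        selected = select_consistent(model, panel, km)
        all_gmm_members = set()
        for lab in np.unique(model.labels):
            members = {panel.combinations[i]
                       for i in np.flatnonzero(model.labels == lab)}
            if members & selected:
                all_gmm_members |= members
        assert selected <= all_gmm_members

    def test_label_permutation_invariance(self, rng):
        # selection depends on cluster characterization, not label ids
        panel = self.synthetic_panel(rng)
        feats, _ = panel.features(panel.metrics)
        model = gmm_cluster(feats, seed=0)
        km = kmeans_validate(feats, k=model.k, seed=0)
        base = select_consistent(model, panel, km)
        perm = {lab: model.k + 1 - lab for lab in range(1, model.k + 1)}
        model.labels = np.array([perm[l] for l in model.labels])
        assert select_consistent(model, panel, km) == base

    def test_no_injected_synergy_gives_empty_set(self, rng):
        panel = self.synthetic_panel(rng, n_syn=0, shift=0.0)
        feats, _ = panel.features(panel.metrics)
        model = gmm_cluster(feats, seed=0)
        km = kmeans_validate(feats, k=max(model.k, 1), seed=0)
        if model.k == 1:
            with pytest.warns(UserWarning):
                assert select_consistent(model, panel, km) == set()
        else:
            assert len(select_consistent(model, panel, km)) <= 2


class TestReplicateConcordance:
    def test_identical_vectors(self):
        r, p = replicate_concordance([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert r == pytest.approx(1.0)
        assert p < 0.01

    def test_correlated_pairs_estimate_generating_rho(self, rng):
        rho, n = 0.8, 43
        cov = [[1, rho], [rho, 1]]
        estimates = []
        for _ in range(500):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            estimates.append(replicate_concordance(xy[:, 0], xy[:, 1])[0])
        assert 0.75 <= np.mean(estimates) <= 0.85

    def test_independent_pairs_near_zero(self, rng):
        # under independence r*sqrt(n-2)/sqrt(1-r^2) is t(n-2); the exact
        # null probability of |r| < 0.3 at n = 43 is the oracle
        n, r0 = 43, 0.3
        t0 = r0 * np.sqrt((n - 2) / (1 - r0**2))
        p_exact = 2 * stats.t.cdf(t0, df=n - 2) - 1  # ~0.949
        hits = 0
        n_sims = 400
        for _ in range(n_sims):
            r, _ = replicate_concordance(rng.normal(size=n),
                                         rng.normal(size=n))
            hits += abs(r) < r0
        assert hits / n_sims == pytest.approx(p_exact, abs=0.04)

    def test_spearman_option_and_validation(self):
        r, _ = replicate_concordance([1, 2, 3, 4], [2, 4, 6, 8.0],
                                     method="spearman")
        assert r == pytest.approx(1.0)
        with pytest.raises(ValueError):
            replicate_concordance([1, 2], [1, 2])
        with pytest.raises(ValueError):
            replicate_concordance([1, 2, 3], [1, 2, 3], method="kendall")
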