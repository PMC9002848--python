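import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from floraltime import match_candidates, select_k_and_cluster, zscore
from floraltime.cluster import ClusterModel, _kmeans, _pooled_within_ss

from .oracles import best_two_partition_ss

TPS = [10, 15, 19, 29]


def _frame(x):
    return pd.DataFrame(np.asarray(x, float),
                        index=[f"g{i}" for i in range(len(x))], columns=TPS)


def planted_two_group(seed, n_up=60, n_down=30, noise_sd=0.1):
    """Monotone up and monotone down trajectories plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    up = np.linspace(0.0, 2.0, 4)
    x = np.vstack([up + rng.normal(0, noise_sd, (n_up, 4)),
                   up[::-1] + rng.normal(0, noise_sd, (n_down, 4))])
    labels = np.array([0] * n_up + [1] * n_down)
    return _frame(x), labels


class TestZscore:
    def test_hand_evaluated_example(self):
        z = zscore(_frame([[1, 2, 3, 4]]))
        np.testing.assert_allclose(
            z.iloc[0], [-1.1619, -0.3873, 0.3873, 1.1619], atol=1e-4)

    def test_flat_profile_excluded(self):
        z = zscore(_frame([[5, 5, 5, 5], [1, 2, 3, 4]]))
        assert list(z.index) == ["g1"]

    def test_mean_zero_unit_sd(self):
        rng = np.random.default_rng(0)
        z = zscore(_frame(rng.normal(size=(50, 4))))
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
    def test_affine_invariance(self, a, b):
        x = np.array([[0.5, 1.7, 0.2, 3.0]])
        np.testing.assert_allclose(zscore(_frame(x)).to_numpy(),
                                   zscore(_frame(a * x + b)).to_numpy(),
                                   atol=1e-7)


class TestSelectK:
    def test_planted_two_groups_recovered(self):
        x, labels = planted_two_group(seed=0)
        z = zscore(x)
        model = select_k_and_cluster(z, seed=0)
        assert model.k == 2
        assert adjusted_rand_score(labels, model.assignments.to_numpy()) == 1.0

    def test_duplicating_genes_keeps_assignments(self):
        x, _ = planted_two_group(seed=1, n_up=20, n_down=15)
        z = zscore(x)
        m1 = select_k_and_cluster(z, seed=3, restarts=20, gap_refs=10)
        dup = pd.concat([z, z.set_axis([f"d{i}" for i in range(len(z))])])
        m2 = select_k_and_cluster(dup, seed=3, restarts=20, gap_refs=10)
        assert m2.k == m1.k
        # original genes keep cluster co-membership structure
        a1 = m1.assignments
        a2 = m2.assignments.loc[a1.index]
        assert adjusted_rand_score(a1.to_numpy(), a2.to_numpy()) == 1.0

    def test_kmeans_matches_exhaustive_partition_optimum(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            x = rng.normal(size=(8, 4))
            km = _kmeans(x, 2, seed=trial, n_init=50)
            ss = _pooled_within_ss(x, km.labels_)
            assert ss == pytest.approx(best_two_partition_ss(x), rel=1e-9)

    def test_too_few_genes_error(self):
        z = zscore(_frame(np.random.default_rng(5).normal(size=(6, 4))))
        with pytest.raises(ValueError, match="at least"):
            select_k_and_cluster(z, k_range=(2, 10))

    def test_objective_is_fixed_point(self):
        x, _ = planted_two_group(seed=6)
        z = zscore(x)
        model = select_k_and_cluster(z, seed=6, restarts=10, gap_refs=5)
        xv = z.to_numpy()
        labels = model.assignments.to_numpy()
        # reassigning each point to its nearest centroid changes nothing
        cen = model.centroids.to_numpy()
        d = ((xv[:, None, :] - cen[None, :, :]) ** 2).sum(-1)
        np.testing.assert_array_equal(np.argmin(d, axis=1), labels)

    def test_centroid_is_member_mean_with_near_zero_mean(self):
        x, _ = planted_two_group(seed=7)
        z = zscore(x)
        model = select_k_and_cluster(z, seed=7, restarts=10, gap_refs=5)
        for c in range(model.k):
            members = z[model.assignments == c]
            np.testing.assert_allclose(model.centroids.loc[c],
                                       members.mean(axis=0), atol=1e-12)
            assert abs(model.centroids.loc[c].mean()) < 1e-9


class TestMatchCandidates:
    def _model(self):
        up = zscore(_frame([np.linspace(0, 2, 4)])).iloc[0].to_numpy()
        centroids = pd.DataFrame([up, up[::-1]], columns=TPS,
                                 index=pd.RangeIndex(2, name="cluster"))
        assignments = pd.Series([0, 1], index=["f0", "f1"], name="cluster")
        return ClusterModel(k=2, assignments=assignments, centroids=centroids)

    def test_exact_centroid_match(self):
        model = self._model()
        pool = pd.DataFrame([model.centroids.loc[0]], index=["cand"])
        out = match_candidates(model, pool)
        assert out.iloc[0]["r"] == pytest.approx(1.0)
        assert bool(out.iloc[0]["is_candidate"])

    def test_negated_centroid_matches_other_cluster(self):
        model = self._model()
        # -centroid0 is exactly centroid1 here (antiphase pair); a profile
        # orthogonal-ish to both is not a candidate
        pool = pd.DataFrame([[1.0, -1.0, 1.0, -1.0]], columns=TPS, index=["x"])
        out = match_candidates(model, pool)
        assert not bool(out.iloc[0]["is_candidate"])
        assert out.iloc[0]["r"] < 0.99

    def test_planted_trackers_recovered(self):
        model = self._model()
        rng = np.random.default_rng(8)
        cen = model.centroids.to_numpy()
        trackers = cen[rng.integers(0, 2, 50)] + rng.normal(0, 0.01, (50, 4))
        unrelated = rng.normal(size=(500, 4))
        pool = _frame(np.vstack([trackers, unrelated]))
        pool.index = [f"t{i}" for i in range(50)] + [f"u{i}" for i in range(500)]
        out = match_candidates(model, pool).set_index("gene_id")
        called = set(out.index[out["is_candidate"]])
        tp = len([g for g in called if g.startswith("t")])
        recall = tp / 50
        precision = tp / max(len(called), 1)
        assert recall >= 0.9 and precision >= 0.9

    def test_pool_overlap_with_clustered_genes_rejected(self):
        model = self._model()
        pool = pd.DataFrame([model.centroids.loc[0]], index=["f0"])
        with pytest.raises(ValueError, match="overlap"):
            match_candidates(model, pool)

    def test_degenerate_centroid_rejected(self):
        model = self._model()
        model.centroids.loc[0] = 1.0
        pool = pd.DataFrame([[0.0, 1.0, 2.0, 3.0]], columns=TPS, index=["x"])
        with pytest.raises(ValueError, match="degenerate centroid"):
            match_candidates(model, pool)

    def test_sorted_by_r_descending(self):
        model = self._model()
        rng = np.random.default_rng(9)
        pool = _frame(rng.normal(size=(20, 4)))
        out = match_candidates(model, pool)
        assert (out["r"].diff().dropna() <= 1e-12).all()
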