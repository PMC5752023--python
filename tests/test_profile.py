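"""Median normalization, PCA vs an SVD oracle, factor extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from sakemet.binning import FeatureMatrix
from sakemet.profile import (
    Factor,
    common_factors,
    median_normalize,
    run_pca,
    top_loadings,
)


def fm(values, samples=None, batch="b"):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, columns=samples,
                      index=[f"f{i}" for i in range(values.shape[0])])
    meta = pd.DataFrame(
        {"batch": batch, "day": range(len(samples)), "replicate": 1}, index=samples
    )
    return FeatureMatrix(df, meta)


class TestMedianNormalize:
    def test_identical_samples_unchanged(self):
        m = fm([[1, 1], [5, 5], [10, 10]])
        out = median_normalize(m)
        np.testing.assert_allclose(out.values.values, m.values.values)

    def test_doubled_sample_halved(self):
        a = np.array([1.0, 5.0, 10.0])
        m = fm(np.column_stack([a, 2 * a]))
        out = median_normalize(m)
        np.testing.assert_allclose(out.values["s1"], a)

    def test_postcondition_common_medians_equal_reference(self):
        rng = np.random.default_rng(3)
        vals = rng.exponential(100, size=(200, 6)) * rng.uniform(0.5, 2.0, 6)
        vals[rng.random(vals.shape) < 0.3] = 0.0
        m = fm(vals)
        out = median_normalize(m)
        common = (out.values > 0).all(axis=1)
        med = out.values.loc[common].median(axis=0)
        np.testing.assert_allclose(med, med.iloc[0], rtol=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        vals = rng.exponential(10, size=(50, 4)) + 0.1
        m1 = fm(vals)
        scaled = vals.copy()
        scaled[:, 2] *= 7.3
        m2 = fm(scaled)
        np.testing.assert_allclose(
            median_normalize(m1).values.values,
            median_normalize(m2).values.values,
            rtol=1e-9,
        )

    def test_no_common_positive_feature_rejected(self):
        m = fm([[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="positive in all samples"):
            median_normalize(m)


def svd_oracle(values, k):
    """Reference PCA by direct SVD of the feature-centered matrix."""
    X = values.T  # samples x features
    Xc = X - X.mean(axis=0)
    U, s, Vt = linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T * (s[:k] / np.sqrt(X.shape[0] - 1))
    return scores.T, loadings, s


def align_signs(got, want):
    """Per-component sign alignment (PCA is sign-indeterminate)."""
    out = want.copy()
    for j in range(got.shape[1]):
        if np.dot(got[:, j], want[:, j]) < 0:
            out[:, j] = -want[:, j]
    return out


class TestRunPca:
    def test_matches_svd_oracle_on_random_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            vals = rng.exponential(size=(100, 20)) * rng.uniform(0.5, 2.0, size=(100, 1))
            res = run_pca(fm(vals), components=4)
            o_scores, o_loadings, _ = svd_oracle(vals, 4)
            np.testing.assert_allclose(
                res.loadings.values, align_signs(res.loadings.values, o_loadings), atol=1e-8
            )
            np.testing.assert_allclose(
                res.scores.T, align_signs(res.scores.T, o_scores.T), atol=1e-8
            )

    def test_single_varying_feature_owns_pc1(self):
        vals = np.ones((10, 5))
        vals[3] = [1, 2, 3, 4, 5]
        res = run_pca(fm(vals), components=2)
        assert np.argmax(np.abs(res.loadings["PC1"])) == 3
        assert res.loadings["PC1"].iloc[3] > 0  # sign convention
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction_from_full_components(self):
        rng = np.random.default_rng(6)
        vals = rng.exponential(size=(30, 8))
        res = run_pca(fm(vals), components=7)
        unit = res.loadings.values / (res.singular_values / np.sqrt(8 - 1))
        recon = res.scores.T @ unit.T  # samples x features
        centered = vals.T - vals.T.mean(axis=0)
        np.testing.assert_allclose(recon, centered, atol=1e-8)

    def test_duplicated_replicates_coincide(self):
        rng = np.random.default_rng(7)
        col = rng.exponential(10, size=50)
        other = rng.exponential(10, size=(50, 3))
        vals = np.column_stack([col, col, other])
        res = run_pca(fm(vals), components=2)
        np.testing.assert_allclose(res.scores[:, 0], res.scores[:, 1], atol=1e-9)

    def test_scores_centered_and_variance_monotone(self):
        rng = np.random.default_rng(8)
        res = run_pca(fm(rng.exponential(size=(40, 10))), components=5)
        np.testing.assert_allclose(res.scores.sum(axis=1), 0, atol=1e-8)
        ev = res.explained_variance_ratio
        assert np.all(np.diff(ev) <= 1e-12) and ev.sum() <= 1 + 1e-9

    def test_component_truncation_warns(self):
        vals = np.random.default_rng(9).exponential(size=(20, 3))
        with pytest.warns(UserWarning, match="truncated"):
            res = run_pca(fm(vals), components=10)
        assert res.n_components == 2

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            run_pca(fm(np.ones((5, 1))))


class TestTopLoadings:
    def make_result(self, pc1, ids):
        import sakemet.profile as profile

        loadings = pd.DataFrame({"PC1": pc1, "PC2": 0.0}, index=ids)
        return profile.PcaResult(
            scores=np.zeros((2, 2)),
            loadings=loadings,
            explained_variance_ratio=np.array([0.9, 0.1]),
            mean=np.zeros(len(ids)),
            sample_ids=["s0", "s1"],
            singular_values=np.array([1.0, 1.0]),
        )

    def test_ties_broken_by_feature_id(self):
        res = self.make_result([3.0, 3.0, 5.0, 1.0], ["b", "a", "d", "c"])
        # ids must parse as feature ids; use grid-style labels instead
        res.loadings.index = ["201-202|0-50", "200-201|0-50", "203-204|0-50", "202-203|0-50"]
        got = [f.feature_id for f in top_loadings(res, 0, 3)]
        assert got == ["203-204|0-50", "200-201|0-50", "201-202|0-50"]

    def test_ranks_run_from_one(self):
        res = self.make_result([1.0, 2.0], ["200-201|0-50", "201-202|0-50"])
        factors = top_loadings(res, 0, 2)
        assert [f.rank for f in factors] == [1, 2]
        assert factors[0].pc1 == 2.0

    def test_k_exceeding_features_rejected(self):
        res = self.make_result([1.0], ["200-201|0-50"])
        with pytest.raises(ValueError, match="feature count"):
            top_loadings(res, 0, 5)


def factor(fid, rank, batch="a"):
    return Factor.from_feature_id(fid, pc1=10.0 - rank, pc2=0.0, rank=rank, batch=batch)


class TestCommonFactors:
    def test_identical_lists_pair_fully(self):
        a = [factor("455-456|1250-1300", 1), factor("273-274|1350-1400", 2)]
        b = [factor("273-274|1350-1400", 1, "b"), factor("455-456|1250-1300", 2, "b")]
        pairs = common_factors(a, b)
        assert [p.feature_id for p in pairs] == ["455-456|1250-1300", "273-274|1350-1400"]

    def test_disjoint_lists_empty(self):
        a = [factor("455-456|1250-1300", 1)]
        b = [factor("273-274|1350-1400", 1, "b")]
        assert common_factors(a, b) == []

    def test_adjacent_scan_bins_merge_to_one_span(self):
        a = [factor("391-392|2600-2650", 1), factor("391-392|2650-2700", 2)]
        b = [factor("391-392|2600-2650", 1, "b"), factor("391-392|2650-2700", 2, "b")]
        pairs = common_factors(a, b, merge_adjacent=True)
        assert len(pairs) == 1
        assert pairs[0].feature_id == "391-392|2600-2700"

    def test_merge_requires_same_mz_bin(self):
        a = [factor("391-392|2600-2650", 1), factor("392-393|2650-2700", 2)]
        b = [factor("391-392|2600-2650", 1, "b")]
        pairs = common_factors(a, b, merge_adjacent=True)
        assert [p.feature_id for p in pairs] == ["391-392|2600-2650"]

    def test_preserves_batch_a_rank_order(self):
        a = [factor("273-274|1350-1400", 2), factor("455-456|1250-1300", 1)]
        b = [factor("273-274|1350-1400", 5, "b"), factor("455-456|1250-1300", 9, "b")]
        pairs = common_factors(a, b)
        assert [p.factor_a.rank for p in pairs] == [1, 2]


class TestReplicateGeometry:
    def test_replicate_pairs_are_mutual_nearest_neighbors(self, pipeline_result):
        """Technical replicates sit together in (PC1, PC2) score space."""
        for batch, res in pipeline_result.pca.items():
            meta = pipeline_result.normalized.meta.loc[res.sample_ids]
            pts = res.scores[:2].T
            for day in meta.day.unique():
                idx = np.flatnonzero(meta.day.values == day)
                d_rep = np.linalg.norm(pts[idx[0]] - pts[idx[1]])
                others = np.delete(np.arange(len(pts)), idx)
                d_other = min(
                    np.linalg.norm(pts[i] - pts[j]) for i in idx for j in others
                )
                assert d_rep < d_other
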