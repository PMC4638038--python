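"""PCA, component selection, signature subsetting and hierarchical clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from proteopanel import unsupervised as us


def frame(arr):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"P{i}" for i in range(arr.shape[0])],
        columns=[f"S{j}" for j in range(arr.shape[1])],
    )


class TestPCA:
    def test_constant_rows_have_no_variance(self):
        mat = frame(np.tile([[1.0], [5.0], [3.0]], (1, 6)))
        res = us.pca(mat)
        assert np.allclose(res.explained_variance_fraction, 0.0, atol=1e-20)

    def test_full_rank_reconstruction(self, rng):
        mat = frame(rng.normal(size=(50, 10)))
        res = us.pca(mat)
        X = mat.T.to_numpy()
        Xc = X - X.mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, Xc, atol=1e-10)
        assert res.explained_variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)
        # explained fractions non-increasing
        assert (np.diff(res.explained_variance_fraction) <= 1e-12).all()

    def test_loadings_orthonormal(self, rng):
        res = us.pca(frame(rng.normal(size=(30, 8))))
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_sign_convention_deterministic(self, rng):
        mat = frame(rng.normal(size=(20, 6)))
        res = us.pca(mat)
        for c in res.loadings.columns:
            col = res.loadings[c].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_invariance_to_sample_order_and_row_shift(self, rng):
        mat = frame(rng.normal(size=(20, 6)))
        base = us.pca(mat)
        shifted = mat.add(rng.normal(size=20), axis=0)  # per-protein constant
        perm = mat[np.random.default_rng(1).permutation(mat.columns)]
        res_shift = us.pca(shifted)
        assert np.allclose(
            res_shift.explained_variance_fraction, base.explained_variance_fraction, atol=1e-10
        )
        res_perm = us.pca(perm)
        assert np.allclose(
            sorted(res_perm.explained_variance_fraction),
            sorted(base.explained_variance_fraction),
            atol=1e-10,
        )

    def test_planted_fold_change_separates_subtypes(self, normalized):
        norm, truth = normalized
        res = us.pca(norm)
        labels = truth.subtype_labels.reindex(norm.columns)
        ci, cj = us.select_component_pair(res, labels)
        scores = res.scores[[ci, cj]].to_numpy()
        assert silhouette_score(scores, labels.to_numpy()) > 0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            us.pca(frame([[1.0], [2.0]]))


class TestSelectComponentPair:
    def test_single_informative_component(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(12, 5)) * 0.1
        labels = pd.Series(["A"] * 6 + ["B"] * 6, index=[f"S{j}" for j in range(12)])
        scores[:6, 2] += 10  # only PC3 separates
        res = us.PCAResult(
            scores=pd.DataFrame(scores, index=labels.index,
                                columns=[f"PC{k+1}" for k in range(5)]),
            loadings=pd.DataFrame(),
            explained_variance_fraction=np.ones(5) / 5,
        )
        pair = us.select_component_pair(res, labels)
        assert "PC3" in pair

    def test_matches_exhaustive_scan(self, rng):
        from scipy.stats import ttest_ind

        scores = rng.normal(size=(10, 6))
        labels = pd.Series(["A"] * 4 + ["B"] * 6, index=[f"S{j}" for j in range(10)])
        res = us.PCAResult(
            scores=pd.DataFrame(scores, index=labels.index,
                                columns=[f"PC{k+1}" for k in range(6)]),
            loadings=pd.DataFrame(),
            explained_variance_fraction=np.ones(6) / 6,
        )
        pair = us.select_component_pair(res, labels)
        t = [abs(ttest_ind(scores[:4, k], scores[4:, k]).statistic) for k in range(6)]
        best = np.argsort(t)[::-1][:2]
        assert set(pair) == {f"PC{k+1}" for k in best}

    def test_one_class_labels_rejected(self, rng):
        res = us.pca(frame(rng.normal(size=(10, 6))))
        labels = pd.Series(["A"] * 6, index=res.scores.index)
        with pytest.raises(ValueError):
            us.select_component_pair(res, labels)


class TestTopLoadings:
    def make_result(self, loadings):
        ids = [f"P{i}" for i in range(len(loadings))]
        return us.PCAResult(
            scores=pd.DataFrame(),
            loadings=pd.DataFrame({"PC1": loadings}, index=ids),
            explained_variance_fraction=np.array([1.0]),
        )

    def test_largest_absolute_loading_first(self):
        res = self.make_result([0.9, -0.1, 0.05])
        top = us.top_loadings(res, "PC1", 1)
        assert list(top.index) == ["P0"]
        assert top["sign"].iloc[0] == "+"

    def test_ties_broken_by_stable_id_order(self):
        res = self.make_result([0.5, -0.5, 0.5])
        top = us.top_loadings(res, "PC1", 2)
        assert list(top.index) == ["P0", "P1"]

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            us.top_loadings(self.make_result([0.1]), "PC1", 2)


class TestSignaturePCA:
    def test_full_signature_equals_pca(self, random_matrix):
        full = us.pca(random_matrix)
        sig = us.signature_pca(random_matrix, list(random_matrix.index))
        pd.testing.assert_frame_equal(sig.scores, full.scores)
        assert sig.n_signature_matched == 40

    def test_match_count_reported(self, random_matrix):
        ids = list(random_matrix.index[:6]) + ["MISSING1", "MISSING2", "M3", "M4"]
        res = us.signature_pca(random_matrix, ids)
        assert res.n_signature_matched == 6

    def test_too_few_matches(self, random_matrix):
        with pytest.raises(ValueError, match="need >= 3"):
            us.signature_pca(random_matrix, ["X", "Y", random_matrix.index[0]])

    def test_planted_signature_separates_subtypes(self, normalized):
        norm, truth = normalized
        sig_ids = sorted(truth.differential_ids & set(norm.index))
        res = us.signature_pca(norm, sig_ids)
        labels = truth.subtype_labels.reindex(norm.columns)
        pair = us.select_component_pair(res, labels)
        scores = res.scores[list(pair)].to_numpy()
        assert silhouette_score(scores, labels.to_numpy()) > 0


class TestHierarchicalCluster:
    def test_identical_samples_merge_first_at_zero(self, rng):
        data = rng.normal(size=(20, 4))
        data[:, 1] = data[:, 0]  # S1 duplicates S0
        dend = us.hierarchical_cluster(frame(data), axis="samples")
        first = dend.linkage_matrix[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_two_planted_pairs_top_split(self, rng):
        base1, base2 = rng.normal(size=20), rng.normal(size=20)
        data = np.column_stack(
            [base1, base1 + rng.normal(0, 0.01, 20),
             base2, base2 + rng.normal(0, 0.01, 20)]
        )
        dend = us.hierarchical_cluster(frame(data), axis="samples")
        cut = dend.cut(2)
        assert {frozenset(cut.index[cut == c]) for c in cut.unique()} == {
            frozenset({"S0", "S1"}),
            frozenset({"S2", "S3"}),
        }

    def test_merge_order_matches_brute_force_average_linkage(self, rng):
        """Small instance against an independent naive agglomeration."""
        data = rng.normal(size=(15, 5))
        dend = us.hierarchical_cluster(frame(data), axis="samples")
        # naive oracle: agglomerate by smallest average pairwise correlation distance
        X = data.T
        d = {}
        for i in range(5):
            for j in range(i + 1, 5):
                r = np.corrcoef(X[i], X[j])[0, 1]
                d[(i, j)] = 1 - r
        clusters = {i: [i] for i in range(5)}
        merges = []
        next_id = 5
        while len(clusters) > 1:
            best, bd = None, np.inf
            for a in clusters:
                for b in clusters:
                    if a < b:
                        dist = np.mean(
                            [d[tuple(sorted((x, y)))] for x in clusters[a] for y in clusters[b]]
                        )
                        if dist < bd:
                            bd, best = dist, (a, b)
            a, b = best
            merges.append((set(clusters[a] + clusters[b]), bd))
            clusters[next_id] = clusters.pop(a) + clusters.pop(b)
            next_id += 1
        for row, (members, height) in zip(dend.linkage_matrix, merges):
            assert row[2] == pytest.approx(height, abs=1e-10)
            assert int(row[3]) == len(members)

    def test_constant_row_rejected(self):
        data = np.ones((4, 3))
        with pytest.raises(ValueError, match="constant"):
            us.hierarchical_cluster(frame(data), axis="proteins")

    def test_newick_roundtrip_topology(self, rng):
        dend = us.hierarchical_cluster(frame(rng.normal(size=(10, 4))), axis="samples")
        nwk = dend.to_newick()
        assert nwk.endswith(";")
        for s in ("S0", "S1", "S2", "S3"):
            assert s in nwk


class TestSubtypeSplit:
    def labelled(self, rng, flip=0):
        data = rng.normal(size=(30, 8))
        data[:10, :4] += 3.0  # block structure in both subtypes
        data[10:20, 4:] += 3.0
        labels = pd.Series(["A"] * 4 + ["B"] * 4, index=[f"S{j}" for j in range(8)])
        if flip:
            labels.iloc[0], labels.iloc[-1] = "B", "A"
        return frame(data), labels

    def test_separated_data_true(self, rng):
        mat, labels = self.labelled(rng)
        dend = us.hierarchical_cluster(mat, axis="samples")
        assert us.subtype_split_correct(dend, labels)

    def test_permuted_label_false(self, rng):
        mat, labels = self.labelled(rng, flip=1)
        dend = us.hierarchical_cluster(mat, axis="samples")
        assert not us.subtype_split_correct(dend, labels)

    def test_random_labels_usually_false(self, rng):
        mat, labels = self.labelled(rng)
        dend = us.hierarchical_cluster(mat, axis="samples")
        wrong = 0
        for _ in range(20):
            perm = pd.Series(rng.permutation(labels.values), index=labels.index)
            if not us.subtype_split_correct(dend, perm):
                wrong += 1
        assert wrong >= 15
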