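"""PCA + promax rotation, component scores, clustering, ROC separation and
split-half stability."""

import numpy as np
import pandas as pd
import pytest

from gazedyn.latent import (
    align_sign,
    cluster_viewers,
    fit_pca_promax,
    project_scores,
    promax,
    reconstruct_features,
    roc_separation,
    split_half_stability,
    varimax,
)

# Pattern matrix produced by R's stats::promax (kappa = 4) on the loading
# fixture generated below; frozen as an independent oracle.
R_PROMAX_PATTERN = np.array([
    [0.8424137199, 0.0326130194, 0.0770029968],
    [0.6484513149, -0.018201056, -0.071330512],
    [0.9564639609, -0.0928446046, 0.0201802199],
    [0.7413512145, 0.0547796604, 0.0101916252],
    [-0.0747773184, 0.4994253454, 0.0334985312],
    [-0.0174076884, 0.8370611874, 0.0139463006],
    [0.1696193303, 0.6776610852, -0.0681224583],
    [-0.1324961465, 0.8074329096, 0.0806064296],
    [0.003880419, -0.1044608194, 0.385913405],
    [0.0783679871, 0.0322830494, 0.6823808351],
    [-0.0535194741, -0.0025527694, 0.5961005497],
    [0.0391205267, 0.0381481831, 0.8872791106],
])


def _loading_fixture():
    rng = np.random.default_rng(42)
    A = np.zeros((12, 3))
    A[:4, 0] = rng.uniform(0.6, 0.9, 4)
    A[4:8, 1] = rng.uniform(0.5, 0.8, 4)
    A[8:, 2] = rng.uniform(0.4, 0.9, 4)
    A += rng.normal(0, 0.1, (12, 3))
    return A


def _align_columns(B, ref):
    """Resolve column permutation/sign indeterminacy before comparison."""
    from itertools import permutations

    best = None
    for perm in permutations(range(B.shape[1])):
        Bp = B[:, perm] * np.sign(np.sum(B[:, perm] * ref, axis=0))
        err = np.abs(Bp - ref).max()
        if best is None or err < best:
            best = err
    return best


class TestRotations:
    def test_promax_matches_r_oracle(self):
        pattern, phi, _ = promax(_loading_fixture(), kappa=4)
        assert _align_columns(pattern, R_PROMAX_PATTERN) < 1e-9
        assert np.allclose(np.diag(phi), 1.0)

    def test_promax_kappa_one_is_varimax(self):
        A = _loading_fixture()
        v, _ = varimax(A)
        pattern, phi, _ = promax(A, kappa=1.0)
        assert _align_columns(pattern, v) < 1e-8
        assert np.allclose(phi, np.eye(3), atol=1e-8)

    def test_varimax_preserves_communalities(self):
        A = _loading_fixture()
        v, rot = varimax(A)
        assert np.allclose((v**2).sum(axis=1), (A**2).sum(axis=1))
        assert np.allclose(rot @ rot.T, np.eye(3), atol=1e-10)


def _factor_data(n=80, seed=0, noise=0.1):
    """One latent factor loading on the first 20 of 30 features."""
    rng = np.random.default_rng(seed)
    f = rng.normal(size=n)
    X = rng.normal(0, noise, (n, 30))
    X[:, :20] += np.outer(f, rng.uniform(0.7, 1.0, 20))
    cols = [f"fix_dur_mean" if i == 0 else f"feat{i}" for i in range(30)]
    return pd.DataFrame(X, columns=cols)


class TestPCA:
    def test_single_factor_retention_and_loadings(self):
        X = _factor_data()
        sol = fit_pca_promax(X)
        assert sol.n_components == 1
        assert (sol.loadings.iloc[:20, 0].abs() >= 0.2).all()

    def test_deterministic_same_seed(self):
        X = _factor_data(seed=3)
        a = fit_pca_promax(X, seed=1234)
        b = fit_pca_promax(X, seed=1234)
        pd.testing.assert_frame_equal(a.scores, b.scores)
        pd.testing.assert_frame_equal(a.loadings, b.loadings)

    def test_eigenvalues_sum_to_feature_count(self):
        X = _factor_data(seed=4)
        sol = fit_pca_promax(X)
        assert sol.eigenvalues.sum() == pytest.approx(X.shape[1], rel=1e-9)

    def test_scores_zero_mean_and_anchor_sign(self):
        rng = np.random.default_rng(5)
        X = _factor_data(seed=5, noise=0.3)
        sol = fit_pca_promax(X, n_components=2)
        assert np.allclose(sol.scores.mean(), 0.0, atol=1e-9)
        z = (X["fix_dur_mean"] - X["fix_dur_mean"].mean()) / X["fix_dur_mean"].std()
        assert np.corrcoef(sol.scores["PC1"], z)[0, 1] > 0

    def test_constant_columns_dropped_with_warning(self):
        X = _factor_data(seed=6)
        X["const_feat"] = 1.0
        with pytest.warns(UserWarning):
            sol = fit_pca_promax(X)
        assert "const_feat" not in sol.loadings.index

    def test_too_many_components_rejected(self):
        X = _factor_data(n=10, seed=7)
        with pytest.raises(ValueError):
            fit_pca_promax(X, n_components=25)


class TestProjection:
    def test_projection_identity_on_training_data(self):
        X = _factor_data(seed=8, noise=0.3)
        sol = fit_pca_promax(X, n_components=2)
        proj = project_scores(sol, X)
        assert np.allclose(proj.to_numpy(), sol.scores.to_numpy(), atol=1e-9)

    def test_missing_feature_rejected(self):
        X = _factor_data(seed=9)
        sol = fit_pca_promax(X)
        with pytest.raises(ValueError):
            project_scores(sol, X.drop(columns=["feat5"]))

    def test_category_subset_scores_correlate(self):
        """Two feature tables driven by the same per-subject latent style
        project to strongly correlated PC1 scores."""
        rng = np.random.default_rng(10)
        n = 90
        f = rng.normal(size=n)
        load = rng.uniform(0.7, 1.0, 30)

        def table(noise_seed):
            r2 = np.random.default_rng(noise_seed)
            X = r2.normal(0, 0.4, (n, 30)) + np.outer(f, load)
            cols = ["fix_dur_mean"] + [f"feat{i}" for i in range(1, 30)]
            return pd.DataFrame(X, columns=cols)

        ref = table(1)
        sol = fit_pca_promax(ref, n_components=1)
        p1 = project_scores(sol, table(2))["PC1"]
        p2 = project_scores(sol, table(3))["PC1"]
        assert np.corrcoef(p1, sol.scores["PC1"])[0, 1] > 0.9
        assert np.corrcoef(p1, p2)[0, 1] > 0.9


class TestReconstruction:
    def test_full_rank_identity_unrotated(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("abcdef"))
        sol = fit_pca_promax(X, n_components=6, rotation="none")
        recon, r = reconstruct_features(sol, sol.component_names, X)
        Z = (X - X.mean()) / X.std()
        assert np.allclose(recon.to_numpy(), Z.to_numpy(), atol=1e-6)
        assert np.allclose(r, 1.0)

    def test_dominant_component_reconstructs_best(self):
        X = _factor_data(seed=12, noise=0.3)
        sol = fit_pca_promax(X, n_components=3)
        _, r1 = reconstruct_features(sol, ["PC1"], X)
        _, r3 = reconstruct_features(sol, ["PC3"], X)
        assert r1.mean() > r3.mean()
        assert r1.shape == (len(X),)

    def test_empty_subset_rejected(self):
        X = _factor_data(seed=13)
        sol = fit_pca_promax(X)
        with pytest.raises(ValueError):
            reconstruct_features(sol, [], X)


def _two_blob_data(n_per=30, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n_per, 4))
    b = rng.normal(sep, 1, (n_per, 4))
    X = pd.DataFrame(np.vstack([a, b]), columns=list("wxyz"))
    truth = pd.Series(["dynamic"] * n_per + ["static"] * n_per, index=X.index)
    return X, truth


class TestClustering:
    def test_two_blobs_recovered(self):
        X, truth = _two_blob_data()
        sol = cluster_viewers(X, k=None, anchor=X["w"])
        assert sol.k == 2
        assert max(sol.silhouette_by_k, key=sol.silhouette_by_k.get) == 2
        assert (sol.labels == truth).mean() == 1.0

    def test_jaccard_with_hierarchical_agreement(self):
        X, _ = _two_blob_data(seed=1)
        sol = cluster_viewers(X, k=2, anchor=X["w"])
        # well-separated blobs: geometric metrics find the same partition
        # (correlation distance is blind to a uniform mean shift)
        assert sol.jaccard["hierarchical_euclidean"] == 1.0
        assert sol.jaccard["hierarchical_cityblock"] == 1.0
        assert all(0.0 <= v <= 1.0 for v in sol.jaccard.values())

    def test_k_exceeding_subjects_rejected(self):
        X, _ = _two_blob_data(n_per=3)
        with pytest.raises(ValueError):
            cluster_viewers(X, k_range=range(2, 10), k=2)

    def test_degenerate_data_rejected(self):
        X = pd.DataFrame(np.ones((20, 3)))
        with pytest.raises(ValueError):
            cluster_viewers(X, k=2)


class TestROC:
    def test_perfect_separation(self):
        scores = pd.Series(np.r_[np.zeros(20), np.ones(20) + 1])
        labels = pd.Series(["dynamic"] * 20 + ["static"] * 20)
        out = roc_separation(scores, labels, n_boot=200)
        assert out["accuracy_pct"] == 100.0
        assert out["auc_pct"] == 100.0

    def test_identical_distributions_auc_near_chance(self):
        rng = np.random.default_rng(14)
        scores = pd.Series(rng.normal(size=200))
        labels = pd.Series(["static", "dynamic"] * 100)
        out = roc_separation(scores, labels, n_boot=200)
        assert 40 < out["auc_pct"] < 60

    def test_label_inversion_symmetry(self):
        rng = np.random.default_rng(15)
        scores = pd.Series(np.r_[rng.normal(0, 1, 30), rng.normal(2, 1, 30)])
        labels = pd.Series(["dynamic"] * 30 + ["static"] * 30)
        flipped = labels.map({"static": "dynamic", "dynamic": "static"})
        a = roc_separation(scores, labels, n_boot=50)
        b = roc_separation(scores, flipped, n_boot=50)
        assert a["auc_pct"] == pytest.approx(100 - b["auc_pct"], abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_separation(
                pd.Series([1.0, 2.0]), pd.Series(["static", "static"])
            )


class TestSplitHalf:
    def test_identical_halves_perfect_stability(self):
        X = _factor_data(seed=16, noise=0.3)
        sol = fit_pca_promax(X, n_components=1)
        labels = cluster_viewers(sol.scores, k=2, anchor=X["fix_dur_mean"]).labels
        out = split_half_stability(X, X, X, sol, labels)
        assert out["r"]["all_vs_odd"] == pytest.approx(1.0, abs=1e-6)
        assert out["r"]["odd_vs_even"] == pytest.approx(1.0, abs=1e-6)
        assert out["label_agreement_pct"]["odd"] == 100.0

    def test_style_driven_halves_correlate(self):
        rng = np.random.default_rng(17)
        n = 80
        f = rng.normal(size=n)
        load = rng.uniform(0.7, 1.0, 30)
        cols = ["fix_dur_mean"] + [f"feat{i}" for i in range(1, 30)]

        def half(seed):
            r2 = np.random.default_rng(seed)
            return pd.DataFrame(
                np.outer(f, load) + r2.normal(0, 0.4, (n, 30)), columns=cols
            )

        all_, odd, even = half(1), half(2), half(3)
        sol = fit_pca_promax(all_, n_components=1)
        labels = cluster_viewers(sol.scores, k=2, anchor=all_["fix_dur_mean"]).labels
        out = split_half_stability(all_, odd, even, sol, labels)
        assert all(r > 0.9 for r in out["r"].values())

    def test_align_sign(self):
        s = pd.Series([1.0, 2.0, 3.0])
        assert (align_sign(-s, s) == s).all()
        assert (align_sign(s, s) == s).all()
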