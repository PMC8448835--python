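"""Latent structure of the feature table: PCA with oblique (promax)
rotation, component scores, viewing-style clustering, and stability
diagnostics.

Component retention follows two joint rules: eigenvalue above 1 (Kaiser)
and explained variance of at least 10%.  Retained loadings are promax-
rotated (kappa = 4); component scores use the regression method on the
rotated solution.  Component signs are arbitrary, so a fixed convention is
applied: the first component is aligned to correlate positively with mean
fixation duration (making "static = high PC1" reproducible), and every
other component is flipped so its largest-magnitude loading is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.metrics import roc_curve, silhouette_score


# ---------------------------------------------------------------------------
# Rotations


def varimax(loadings: np.ndarray, normalize: bool = True, eps: float = 1e-5,
            max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation (with Kaiser row normalisation by default).

    Returns (rotated loadings, rotation matrix).
    """
    x = np.array(loadings, dtype=float)
    p, nc = x.shape
    if nc < 2:
        return x, np.eye(nc)
    if normalize:
        sc = np.sqrt((x**2).sum(axis=1))
        sc[sc == 0] = 1.0
        x = x / sc[:, None]
    rot = np.eye(nc)
    d = 0.0
    for _ in range(max_iter):
        z = x @ rot
        b = x.T @ (z**3 - z @ np.diag((z**2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(b)
        rot = u @ vt
        d_past, d = d, s.sum()
        if d < d_past * (1 + eps):
            break
    z = x @ rot
    if normalize:
        z = z * sc[:, None]
    return z, rot


def promax(loadings: np.ndarray, kappa: float = 4.0):
    """Promax oblique rotation (Hendrickson & White).

    Varimax first, then an oblique least-squares fit to the element-wise
    power-``kappa`` target.  Returns (pattern, phi, rotation) where
    ``pattern`` is the oblique pattern matrix, ``phi`` the factor
    correlation matrix, and ``rotation`` maps unrotated loadings to the
    pattern (pattern = loadings @ rotation).
    """
    v, rotmat = varimax(loadings)
    if v.shape[1] < 2:
        return v.copy(), np.eye(v.shape[1]), rotmat
    target = v * np.abs(v) ** (kappa - 1.0)
    u, *_ = np.linalg.lstsq(v, target, rcond=None)
    d = np.diag(np.linalg.inv(u.T @ u))
    u = u @ np.diag(np.sqrt(d))
    pattern = v @ u
    rotation = rotmat @ u
    phi = np.linalg.inv(rotation.T @ rotation)
    # the varimax pre-rotation already orthonormalises, so phi has unit
    # diagonal by construction of the normalisation above
    return pattern, phi, rotation


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCASolution:
    """Rotated principal-component solution of a subjects x features table."""

    loadings: pd.DataFrame  # features x components (pattern matrix)
    scores: pd.DataFrame  # subjects x components
    explained_variance: np.ndarray  # % per retained component (unrotated)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    n_components: int
    rotation: str  # {"promax", "none"}
    phi: np.ndarray  # component correlation matrix
    feature_means: pd.Series
    feature_sds: pd.Series
    score_weights: pd.DataFrame  # features x components (regression method)
    seed: int = 1234
    dropped_features: list[str] = field(default_factory=list)

    @property
    def component_names(self) -> list[str]:
        return list(self.loadings.columns)

    @property
    def structure(self) -> pd.DataFrame:
        """Structure matrix: feature-component correlations (pattern @ phi).

        Under an oblique rotation the pattern and structure matrices
        differ; "how strongly a feature loads on a component" in the
        correlation sense is the structure entry.
        """
        return pd.DataFrame(
            self.loadings.to_numpy() @ self.phi,
            index=self.loadings.index,
            columns=self.loadings.columns,
        )


def _standardize(X: pd.DataFrame, means: pd.Series, sds: pd.Series) -> np.ndarray:
    return (X[means.index].to_numpy(dtype=float) - means.to_numpy()) / sds.to_numpy()


def fit_pca_promax(
    features: pd.DataFrame,
    n_components: int | None = None,
    rotation: str = "promax",
    kappa: float = 4.0,
    seed: int = 1234,
    eig_threshold: float = 1.0,
    var_threshold_pct: float = 10.0,
    anchor_feature: str = "fix_dur_mean",
) -> PCASolution:
    """PCA of a subjects x features table with promax rotation.

    Features are z-scored; constant columns are dropped with a warning.
    When ``n_components`` is None the retained count is the number of top
    components passing both the Kaiser rule (eigenvalue > ``eig_threshold``)
    and the ``var_threshold_pct`` explained-variance rule.
    """
    X = features.copy()
    sds = X.std(ddof=1)
    constant = sds[(sds == 0) | sds.isna()].index.tolist()
    if constant:
        warnings.warn(f"dropping constant features: {constant}", stacklevel=2)
        X = X.drop(columns=constant)
        sds = sds.drop(index=constant)
    if X.isna().any().any():
        raise ValueError("feature table contains missing values")
    means = X.mean()
    Z = _standardize(X, means, sds)
    n, p = Z.shape
    corr = (Z.T @ Z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.maximum(eigvals[order], 0.0)
    eigvecs = eigvecs[:, order]
    pct = eigvals / p * 100.0

    if n_components is None:
        keep = (eigvals > eig_threshold) & (pct >= var_threshold_pct)
        k = int(np.argmin(keep)) if not keep.all() else len(keep)
        if k == 0:
            raise ValueError("no component passes the retention rules")
    else:
        if n_components > np.linalg.matrix_rank(corr):
            raise ValueError("more components demanded than matrix rank")
        k = int(n_components)

    A = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    if rotation == "promax" and k >= 2:
        pattern, phi, _rot = promax(A, kappa=kappa)
    elif rotation in ("promax", "none"):
        pattern, phi = A.copy(), np.eye(k)
    else:
        raise ValueError(f"unknown rotation {rotation!r}")

    # order rotated components by their sum of squared pattern loadings
    # (rotation redistributes variance, so the unrotated order need not
    # survive; this is the conventional post-rotation ordering)
    ssl = (pattern**2).sum(axis=0)
    order_idx = np.argsort(ssl)[::-1]
    pattern = pattern[:, order_idx]
    phi = phi[np.ix_(order_idx, order_idx)]

    structure = pattern @ phi
    # regression-method weights; pinv guards rank-deficient correlation
    # matrices (fewer subjects than features)
    weights = np.linalg.pinv(corr, rcond=1e-8) @ structure
    scores = Z @ weights

    # deterministic sign convention
    feat_names = list(X.columns)
    for j in range(k):
        if j == 0 and anchor_feature in X.columns:
            r = np.corrcoef(scores[:, 0], Z[:, feat_names.index(anchor_feature)])[0, 1]
            flip = r < 0
        else:
            flip = pattern[np.argmax(np.abs(pattern[:, j])), j] < 0
        if flip:
            pattern[:, j] *= -1
            structure[:, j] *= -1
            weights[:, j] *= -1
            scores[:, j] *= -1
            phi[j, :] *= -1
            phi[:, j] *= -1

    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCASolution(
        loadings=pd.DataFrame(pattern, index=feat_names, columns=comp_names),
        scores=pd.DataFrame(scores, index=features.index, columns=comp_names),
        explained_variance=pct[:k],
        eigenvalues=eigvals,
        n_components=k,
        rotation=rotation if k >= 2 else "none",
        phi=phi,
        feature_means=means,
        feature_sds=sds,
        score_weights=pd.DataFrame(weights, index=feat_names, columns=comp_names),
        seed=seed,
    )


def project_scores(solution: PCASolution, new_features: pd.DataFrame) -> pd.DataFrame:
    """Project a new feature table into a reference component space.

    Standardisation uses the REFERENCE means/SDs, so scores are comparable
    with the training scores.  Raises on any missing feature column.
    """
    missing = set(solution.feature_means.index) - set(new_features.columns)
    if missing:
        raise ValueError(f"missing feature columns: {sorted(missing)}")
    Z = _standardize(new_features, solution.feature_means, solution.feature_sds)
    scores = Z @ solution.score_weights.to_numpy()
    return pd.DataFrame(
        scores, index=new_features.index, columns=solution.component_names
    )


def reconstruct_features(
    solution: PCASolution,
    component_subset: list[str],
    features: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Rank-limited reconstruction of the standardised feature table from a
    subset of component scores.

    Reconstruction regresses the standardised features on the selected
    scores (least squares), which reduces to the usual loadings-based
    reconstruction for unrotated components and returns the table exactly
    when all components of a full-rank solution are used.  Returns the
    reconstruction and the per-subject Pearson correlation between
    original and reconstructed feature vectors.
    """
    if not component_subset:
        raise ValueError("component subset must be non-empty")
    F = solution.scores[list(component_subset)].to_numpy()
    if features is None:
        raise ValueError("pass the feature table used to fit the solution")
    Z = _standardize(features, solution.feature_means, solution.feature_sds)
    B, *_ = np.linalg.lstsq(F, Z, rcond=None)
    recon = F @ B
    r = np.array(
        [np.corrcoef(Z[i], recon[i])[0, 1] for i in range(Z.shape[0])]
    )
    recon_df = pd.DataFrame(
        recon, index=features.index, columns=solution.feature_means.index
    )
    return recon_df, pd.Series(r, index=features.index, name="similarity_r")


# ---------------------------------------------------------------------------
# Clustering


@dataclass
class ClusterSolution:
    k: int
    labels: pd.Series  # subject -> {"static", "dynamic"} (k=2) or int
    silhouette_by_k: dict[int, float]
    jaccard: dict[str, float]  # "hierarchical_<metric>" -> similarity


def _pair_jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard similarity of two partitions on co-membership pairs."""
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(len(a), k=1)
    sa, sb = same_a[iu], same_b[iu]
    union = np.sum(sa | sb)
    return float(np.sum(sa & sb) / union) if union else 1.0


def cluster_viewers(
    data: pd.DataFrame,
    k_range=range(2, 7),
    seed: int = 1234,
    k: int | None = 2,
    anchor: pd.Series | None = None,
) -> ClusterSolution:
    """K-means viewing-style clustering with silhouette and reliability
    diagnostics.

    Silhouette scores are computed for every k in ``k_range``; the final
    partition uses ``k`` (default 2, or the silhouette argmax when None).
    Reliability compares the k-means partition against average-linkage
    hierarchical solutions under euclidean, manhattan and correlation
    distances via the pairwise co-membership Jaccard index.

    With k = 2 the cluster whose mean ``anchor`` value (default: the first
    data column) is higher is labelled "static".
    """
    X = data.to_numpy(dtype=float)
    n = len(X)
    if n < 2 * max(k_range):
        raise ValueError("too few subjects for the requested k range")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate data: all subjects identical")

    sil = {}
    kmeans_labels = {}
    for kk in k_range:
        km = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit(X)
        kmeans_labels[kk] = km.labels_
        sil[kk] = float(silhouette_score(X, km.labels_))
    chosen = int(k) if k is not None else max(sil, key=sil.get)
    if chosen not in kmeans_labels:
        km = KMeans(n_clusters=chosen, n_init=10, random_state=seed).fit(X)
        kmeans_labels[chosen] = km.labels_
    labels_int = kmeans_labels[chosen]

    jaccard = {}
    for metric in ("euclidean", "cityblock", "correlation"):
        if metric == "correlation" and X.shape[1] < 3:
            continue  # correlation distance undefined / degenerate
        d = pdist(X, metric=metric)
        if not np.all(np.isfinite(d)):
            continue
        zlink = linkage(d, method="average")
        hier = fcluster(zlink, t=chosen, criterion="maxclust")
        jaccard[f"hierarchical_{metric}"] = _pair_jaccard(labels_int, hier)

    if chosen == 2:
        anchor_vals = (
            anchor.reindex(data.index).to_numpy(dtype=float)
            if anchor is not None
            else X[:, 0]
        )
        mean0 = anchor_vals[labels_int == 0].mean()
        mean1 = anchor_vals[labels_int == 1].mean()
        static_cluster = 0 if mean0 >= mean1 else 1
        labels = pd.Series(
            np.where(labels_int == static_cluster, "static", "dynamic"),
            index=data.index,
            name="style",
        )
    else:
        labels = pd.Series(labels_int, index=data.index, name="cluster")
    return ClusterSolution(k=chosen, labels=labels, silhouette_by_k=sil, jaccard=jaccard)


# ---------------------------------------------------------------------------
# Separation and stability


def roc_separation(
    scores: pd.Series,
    labels: pd.Series,
    positive: str = "static",
    n_boot: int = 2000,
    seed: int = 1234,
) -> dict:
    """ROC analysis of a 1-D score against binary style labels.

    The cutoff maximises Youden's J; accuracy is evaluated at that cutoff;
    the 95% CI for accuracy comes from a seeded bootstrap over subjects.
    Returns accuracy/AUC in percent.
    """
    y = (labels == positive).to_numpy().astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    s = scores.to_numpy(dtype=float)
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    cutoff = float(thr[np.argmax(j)])
    acc = float(np.mean((s >= cutoff) == y))

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    n = len(y)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        yb, sb = y[idx], s[idx]
        if yb.min() == yb.max():
            boot[i] = np.nan
            continue
        fpr_b, tpr_b, thr_b = roc_curve(yb, sb)
        cut_b = thr_b[np.argmax(tpr_b - fpr_b)]
        boot[i] = np.mean((sb >= cut_b) == yb)
    lo, hi = np.nanpercentile(boot, [2.5, 97.5])
    return {
        "accuracy_pct": acc * 100.0,
        "auc_pct": auc * 100.0,
        "cutoff": cutoff,
        "ci95_pct": [float(lo) * 100.0, float(hi) * 100.0],
    }


def align_sign(scores: pd.Series, reference: pd.Series) -> pd.Series:
    """Flip a component score vector so it correlates positively with the
    reference (components are sign-indeterminate)."""
    joined = pd.concat([scores, reference], axis=1, join="inner")
    r = np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1]
    return -scores if r < 0 else scores


def split_half_stability(
    features_all: pd.DataFrame,
    features_odd: pd.DataFrame,
    features_even: pd.DataFrame,
    reference: PCASolution,
    reference_labels: pd.Series,
    seed: int = 1234,
    anchor_feature: str = "fix_dur_mean",
) -> dict:
    """Odd/even image-subset stability of the first component and of the
    style labels.

    A separate PCA (same retention count as the reference) is fitted in
    each subset; PC1 scores are sign-aligned to the reference and
    correlated (all-vs-odd, all-vs-even, odd-vs-even); each subset's
    k-means partition is compared with the reference labels.
    """
    out = {"r": {}, "label_agreement_pct": {}}
    ref_pc1 = reference.scores["PC1"]
    subset_scores = {}
    for name, feats in (("odd", features_odd), ("even", features_even)):
        sol = fit_pca_promax(
            feats,
            n_components=reference.n_components,
            rotation=reference.rotation,
            seed=seed,
            anchor_feature=anchor_feature,
        )
        pc1 = align_sign(sol.scores["PC1"], ref_pc1)
        subset_scores[name] = pc1
        out["r"][f"all_vs_{name}"] = float(np.corrcoef(ref_pc1, pc1)[0, 1])
        cl = cluster_viewers(
            sol.scores, seed=seed, k=2, anchor=feats.get(anchor_feature)
        )
        agree = (cl.labels == reference_labels).mean()
        out["label_agreement_pct"][name] = float(agree * 100.0)
    out["r"]["odd_vs_even"] = float(
        np.corrcoef(subset_scores["odd"], subset_scores["even"])[0, 1]
    )
    return out
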