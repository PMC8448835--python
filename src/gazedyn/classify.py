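"""Cross-condition viewing-style classification and between-subject
similarity structure.

A random forest is trained on blank-screen features to predict the style
labels discovered during image viewing (stratified 10-fold CV); the
chance level is established by a seeded permutation test.  Between-subject
similarity compares the z-scored feature vectors of every subject pair
within and across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold


@dataclass
class ClassificationReport:
    accuracy_pct: float
    permutation_p: float
    ci95_pct: list[float]
    per_fold_accuracy: np.ndarray
    feature_importance: pd.Series
    confusion: np.ndarray  # rows true, cols predicted, order (static, dynamic)
    null_accuracies: np.ndarray


def _cv_predict(X, y, n_folds, seed, n_estimators):
    """Out-of-fold predictions from a stratified CV of a random forest."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=int)
    fold_acc = []
    importances = np.zeros(X.shape[1])
    for train, test in skf.split(X, y):
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        ).fit(X[train], y[train])
        pred[test] = rf.predict(X[test])
        fold_acc.append(float(np.mean(pred[test] == y[test])))
        importances += rf.feature_importances_
    return pred, np.array(fold_acc), importances / n_folds


def rf_cross_classify(
    blank_features: pd.DataFrame,
    labels: pd.Series,
    n_folds: int = 10,
    seed: int = 1234,
    n_estimators: int = 500,
    n_permutations: int = 1000,
    null_n_estimators: int = 100,
    n_boot: int = 2000,
) -> ClassificationReport:
    """Random-forest cross-classification of image-derived style labels
    from blank-screen features.

    Accuracy is the mean over stratified folds; the permutation p-value
    shuffles labels ``n_permutations`` times and recomputes the CV
    accuracy (with a lighter forest for tractability); the 95% CI is a
    subject-level bootstrap over out-of-fold correctness.
    """
    common = blank_features.index.intersection(labels.index)
    if len(common) != len(blank_features) or len(common) != len(labels):
        raise ValueError("subjects must be aligned across conditions")
    y_str = labels.loc[blank_features.index]
    classes = sorted(y_str.unique())
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    y = (y_str == "dynamic").to_numpy().astype(int)
    X = blank_features.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))

    pred, fold_acc, imp = _cv_predict(X, y, n_folds, seed, n_estimators)
    correct = (pred == y).astype(float)
    accuracy = float(correct.mean())

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        y_perm = rng.permutation(y)
        p_pred, _, _ = _cv_predict(X, y_perm, n_folds, seed, null_n_estimators)
        null[i] = float(np.mean(p_pred == y_perm))
    perm_p = float((1 + np.sum(null >= accuracy)) / (1 + n_permutations))

    boot = np.empty(n_boot)
    n = len(y)
    for i in range(n_boot):
        boot[i] = correct[rng.integers(0, n, n)].mean()
    lo, hi = np.percentile(boot, [2.5, 97.5])

    # confusion with rows/cols ordered (static, dynamic)
    conf = np.zeros((2, 2), dtype=int)
    for t, p_ in zip(y, pred):
        conf[t, p_] += 1
    importance = pd.Series(imp, index=blank_features.columns)
    importance /= importance.sum()
    return ClassificationReport(
        accuracy_pct=accuracy * 100.0,
        permutation_p=perm_p,
        ci95_pct=[float(lo) * 100.0, float(hi) * 100.0],
        per_fold_accuracy=fold_acc,
        feature_importance=importance,
        confusion=conf,
        null_accuracies=null,
    )


@dataclass
class SimilarityStructure:
    matrix_image_viewing: pd.DataFrame
    matrix_blank: pd.DataFrame
    within_static_mean: dict[str, float]  # per condition
    within_dynamic_mean: dict[str, float]
    between_mean: dict[str, float]
    comparisons: pd.DataFrame  # t-tests, Bonferroni-corrected
    matrix_correlation: float


def _pair_sets(labels: pd.Series):
    lab = labels.to_numpy()
    n = len(lab)
    iu = np.triu_indices(n, k=1)
    same = lab[iu[0]] == lab[iu[1]]
    static_pair = same & (lab[iu[0]] == "static")
    dynamic_pair = same & (lab[iu[0]] == "dynamic")
    return iu, static_pair, dynamic_pair, ~same


def between_subject_similarity(
    features_image: pd.DataFrame,
    features_blank: pd.DataFrame,
    labels: pd.Series,
) -> SimilarityStructure:
    """Pairwise Pearson correlations between subjects' z-scored feature
    vectors, per condition, with within- vs between-cluster comparisons.

    The two conditions' matrices are themselves correlated over their
    upper off-diagonal triangles.  Group comparisons use two-sample
    t-tests with Bonferroni correction over the six tests.
    """
    if not features_image.index.equals(features_blank.index):
        raise ValueError("subject sets must be aligned across conditions")
    for style in ("static", "dynamic"):
        if (labels == style).sum() < 3:
            raise ValueError(f"need at least 3 subjects in cluster {style!r}")

    mats = {}
    for name, feats in (("image_viewing", features_image), ("blank_screen", features_blank)):
        X = feats.to_numpy(dtype=float)
        sd = X.std(axis=0, ddof=1)
        Z = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
        mats[name] = pd.DataFrame(
            np.corrcoef(Z), index=feats.index, columns=feats.index
        )

    lab = labels.loc[features_image.index]
    iu, sp, dp, bp = _pair_sets(lab)
    within_s, within_d, between = {}, {}, {}
    rows = []
    for name, mat in mats.items():
        vals = mat.to_numpy()[iu]
        within_s[name] = float(vals[sp].mean())
        within_d[name] = float(vals[dp].mean())
        between[name] = float(vals[bp].mean())
        for label_a, a, label_b, b in (
            ("within_static", vals[sp], "between", vals[bp]),
            ("within_dynamic", vals[dp], "between", vals[bp]),
            ("within_static", vals[sp], "within_dynamic", vals[dp]),
        ):
            t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append(
                {"condition": name, "comparison": f"{label_a} vs {label_b}",
                 "t": float(t), "p": float(p)}
            )
    comp = pd.DataFrame(rows)
    comp["p_bonferroni"] = np.minimum(comp["p"] * len(comp), 1.0)

    v1 = mats["image_viewing"].to_numpy()[iu]
    v2 = mats["blank_screen"].to_numpy()[iu]
    return SimilarityStructure(
        matrix_image_viewing=mats["image_viewing"],
        matrix_blank=mats["blank_screen"],
        within_static_mean=within_s,
        within_dynamic_mean=within_d,
        between_mean=between,
        comparisons=comp,
        matrix_correlation=float(np.corrcoef(v1, v2)[0, 1]),
    )


def cross_condition_label_stability(
    pc1_image: pd.Series,
    pc1_blank_projected: pd.Series,
    image_labels: pd.Series,
    seed: int = 1234,
) -> float:
    """Fraction of subjects keeping their style when each condition's PC1
    scores are clustered independently (k-means, k = 2).

    Blank-screen scores must already be projected with the image-viewing
    loadings so the two score axes are comparable; within each condition
    the higher-PC1 cluster is "static".
    """
    from sklearn.cluster import KMeans

    common = pc1_image.index.intersection(pc1_blank_projected.index)
    out = {"image": image_labels.loc[common]}
    s = pc1_blank_projected.loc[common].to_numpy(dtype=float).reshape(-1, 1)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(s)
    static_cluster = int(np.argmax(km.cluster_centers_.ravel()))
    out["blank"] = pd.Series(
        np.where(km.labels_ == static_cluster, "static", "dynamic"), index=common
    )
    return float((out["image"] == out["blank"]).mean() * 100.0)
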