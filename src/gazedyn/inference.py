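"""Inferential layer: nested OLS model comparison, split-half predictive
validation, crossed-random-intercept mixed models for fixation topography,
viewing-style characterisation, and the covariate (demographic/cognitive/
personality) model.

Nested OLS models are compared with sequential F tests (the likelihood-
ratio chain for Gaussian linear models); mixed models are fitted by
maximum likelihood (not REML) so their likelihood-ratio tests over fixed
effects are valid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# Nested OLS


@dataclass
class NestedComparison:
    model_names: list[str]
    F: float  # final adjacent comparison
    df1: int
    df2: int
    p: float
    adj_r2_by_model: dict[str, float]
    coefficients: pd.DataFrame  # full-model table: estimate, t, p
    comparisons: pd.DataFrame = field(default=None)  # all adjacent tests
    model_F: float = float("nan")  # omnibus F of the full model
    model_p: float = float("nan")


def _fit_ols(data: pd.DataFrame, response: str, predictors: list[str]):
    X = sm.add_constant(data[predictors]) if predictors else pd.DataFrame(
        {"const": np.ones(len(data))}, index=data.index
    )
    return sm.OLS(data[response], X).fit()


def fit_nested_ols(
    data: pd.DataFrame,
    response: str,
    predictor_sets: list[list[str]],
    model_names: list[str] | None = None,
) -> NestedComparison:
    """Fit a strictly nested sequence of OLS models and compare adjacent
    pairs with sequential F tests.

    Rows with missing values in the response or any predictor of the
    largest model are dropped listwise.  Raises on non-nested sets and on
    singular designs (naming the offending columns).
    """
    for smaller, larger in zip(predictor_sets, predictor_sets[1:]):
        if not set(smaller) < set(larger):
            raise ValueError(
                f"predictor sets must be strictly nested: {smaller} vs {larger}"
            )
    names = model_names or [f"M{i + 1}" for i in range(len(predictor_sets))]
    cols = [response] + list(predictor_sets[-1])
    sub = data[cols].dropna()
    if len(sub) < len(predictor_sets[-1]) + 2:
        raise ValueError("too few complete cases")
    X_full = sub[predictor_sets[-1]].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(sub)), X_full]))
    if rank < len(predictor_sets[-1]) + 1:
        corr = np.corrcoef(X_full, rowvar=False)
        bad = [
            (predictor_sets[-1][i], predictor_sets[-1][j])
            for i in range(len(corr))
            for j in range(i + 1, len(corr))
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"singular design; near-collinear columns: {bad}")

    fits = [_fit_ols(sub, response, preds) for preds in predictor_sets]
    rows = []
    for (name_r, fit_r), (name_f, fit_f) in zip(
        zip(names, fits), zip(names[1:], fits[1:])
    ):
        df1 = int(fit_r.df_resid - fit_f.df_resid)
        df2 = int(fit_f.df_resid)
        F = ((fit_r.ssr - fit_f.ssr) / df1) / (fit_f.ssr / df2)
        p = float(stats.f.sf(F, df1, df2))
        rows.append(
            {"comparison": f"{name_f} vs {name_r}", "F": F, "df1": df1, "df2": df2, "p": p}
        )
    comparisons = pd.DataFrame(rows)
    full = fits[-1]
    coef = pd.DataFrame(
        {"estimate": full.params, "t": full.tvalues, "p": full.pvalues}
    )
    if len(rows):
        last = comparisons.iloc[-1]
        F, df1, df2, p = last["F"], last["df1"], last["df2"], last["p"]
    else:  # single model: report its omnibus test
        F, df1, df2, p = full.fvalue, full.df_model, full.df_resid, full.f_pvalue
    return NestedComparison(
        model_names=names,
        F=float(F),
        df1=int(df1),
        df2=int(df2),
        p=float(p),
        adj_r2_by_model={n: float(f.rsquared_adj) for n, f in zip(names, fits)},
        coefficients=coef,
        comparisons=comparisons,
        model_F=float(full.fvalue),
        model_p=float(full.f_pvalue),
    )


# ---------------------------------------------------------------------------
# Split-half predictive validation


@dataclass
class ValidationResult:
    r_per_iteration: np.ndarray
    mean_r: float
    sd_r: float
    fraction_significant: float


def split_half_validate(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    n_iter: int = 1000,
    seed: int = 1234,
) -> ValidationResult:
    """Random half/half split-validation of an OLS model.

    Per iteration the complete-case sample is split in two, the model is
    fitted on one half and predicts the other; the Pearson correlation
    between actual and predicted responses is recorded, together with the
    fraction of iterations whose correlation is significant at p < .05.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    sub = data[[response] + predictors].dropna()
    n = len(sub)
    if n < 10:
        raise ValueError("need at least 10 complete cases")
    y = sub[response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(n), sub[predictors].to_numpy(dtype=float)])
    rng = np.random.default_rng(seed)
    rs = np.empty(n_iter)
    sig = np.zeros(n_iter, dtype=bool)
    half = n // 2
    for i in range(n_iter):
        perm = rng.permutation(n)
        train, test = perm[:half], perm[half:]
        beta, *_ = np.linalg.lstsq(X[train], y[train], rcond=None)
        pred = X[test] @ beta
        r, p = stats.pearsonr(y[test], pred)
        rs[i] = r
        sig[i] = p < 0.05
    return ValidationResult(
        r_per_iteration=rs,
        mean_r=float(rs.mean()),
        sd_r=float(rs.std(ddof=1)),
        fraction_significant=float(sig.mean()),
    )


# ---------------------------------------------------------------------------
# Mixed-effects topography models


@dataclass
class MixedComparison:
    chi2: float  # final adjacent LRT
    df: int
    p: float
    fixed_effects: pd.DataFrame  # full-model: estimate, t, p
    marginal_r2_by_model: dict[str, float]
    loglik_by_model: dict[str, float]
    comparisons: pd.DataFrame = field(default=None)


def _marginal_r2(fit, data: pd.DataFrame, response: str, predictors: list[str]) -> float:
    """Variance of the fixed-effect predictions over total response
    variance (fixed + random + residual), a marginal R^2."""
    params = fit.fe_params
    pred = np.full(len(data), params.get("Intercept", params.iloc[0]))
    for name in predictors:
        if name in params:
            pred = pred + params[name] * data[name].to_numpy(dtype=float)
    var_f = np.var(pred)
    var_rand = 0.0
    if fit.cov_re.size:
        var_rand += float(np.trace(fit.cov_re))
    if getattr(fit, "vcomp", None) is not None:
        var_rand += float(np.sum(fit.vcomp))
    var_res = float(fit.scale)
    return float(var_f / (var_f + var_rand + var_res))


class _OLSAsMixed:
    """Adapter presenting an OLS fit with the MixedLM result surface,
    used when the random-intercept variance degenerates to zero."""

    def __init__(self, fit):
        self.fe_params = fit.params
        self.llf = fit.llf
        self.tvalues = fit.tvalues
        self.pvalues = fit.pvalues
        self.cov_re = np.empty((0, 0))
        self.vcomp = np.zeros(0)
        self.scale = fit.scale


def _fit_mixed(data, response, predictors, crossed=True):
    fixed = " + ".join(predictors) if predictors else "1"
    formula = f"{response} ~ {fixed}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if crossed:
            model = sm.MixedLM.from_formula(
                formula,
                data=data,
                groups=np.ones(len(data)),
                re_formula="0",
                vc_formula={"subject": "0 + C(subject)", "image": "0 + C(image)"},
            )
        else:
            model = sm.MixedLM.from_formula(formula, data=data, groups=data["image"])
        for method in ("lbfgs", "powell", "cg"):
            try:
                fit = model.fit(reml=False, method=method, maxiter=200)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isfinite(fit.llf) and np.all(np.isfinite(fit.fe_params)):
                return fit
        # random-effect variance collapsed: the model reduces to OLS
        X = sm.add_constant(data[list(predictors)]) if predictors else pd.DataFrame(
            {"const": np.ones(len(data))}, index=data.index
        )
        return _OLSAsMixed(sm.OLS(data[response], X).fit())


def fit_mixed_topography(
    data: pd.DataFrame,
    response: str = "fdm",
    predictor_sets: list[list[str]] | None = None,
    model_names: list[str] | None = None,
) -> MixedComparison:
    """Nested mixed models of fixation topography over grid cells.

    ``data`` holds one row per (subject, image, cell) with columns fdm,
    sal, sem, ksd, subject, image.  Rows with missing KSD cells are
    dropped listwise.  Models carry crossed random intercepts for subjects
    and images and are fitted by ML; adjacent models are compared by
    likelihood-ratio chi-square tests.
    """
    predictor_sets = predictor_sets or [["sal"], ["sal", "sem"], ["sal", "sem", "ksd"]]
    names = model_names or [f"MM{i + 1}" for i in range(len(predictor_sets))]
    cols = [response, "subject", "image"] + list(predictor_sets[-1])
    sub = data[cols].dropna().copy()
    if sub["subject"].nunique() < 2 or sub["image"].nunique() < 2:
        raise ValueError("need at least two subjects and two images")

    fits = [_fit_mixed(sub, response, preds) for preds in predictor_sets]
    rows = []
    for (name_r, fit_r), (name_f, fit_f) in zip(
        zip(names, fits), zip(names[1:], fits[1:])
    ):
        df = len(fit_f.fe_params) - len(fit_r.fe_params)
        chi2 = max(2.0 * (fit_f.llf - fit_r.llf), 0.0)
        rows.append(
            {
                "comparison": f"{name_f} vs {name_r}",
                "chi2": chi2,
                "df": df,
                "p": float(stats.chi2.sf(chi2, df)),
            }
        )
    comparisons = pd.DataFrame(rows)
    full = fits[-1]
    fe = pd.DataFrame(
        {"estimate": full.fe_params, "t": full.tvalues[full.fe_params.index],
         "p": full.pvalues[full.fe_params.index]}
    )
    last = comparisons.iloc[-1]
    return MixedComparison(
        chi2=float(last["chi2"]),
        df=int(last["df"]),
        p=float(last["p"]),
        fixed_effects=fe,
        marginal_r2_by_model={
            n: _marginal_r2(f, sub, response, preds)
            for n, f, preds in zip(names, fits, predictor_sets)
        },
        loglik_by_model={n: float(f.llf) for n, f in zip(names, fits)},
        comparisons=comparisons,
    )


def per_subject_topography_winners(
    data: pd.DataFrame,
    response: str = "fdm",
    predictor_sets: list[list[str]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Within-subject variant: random intercept for images only, fitted
    per subject; the winning model is the largest one whose addition is
    significant in the sequential LRT chain."""
    predictor_sets = predictor_sets or [["sal"], ["sal", "sem"], ["sal", "sem", "ksd"]]
    rows = []
    for subject, sdf in data.groupby("subject"):
        sub = sdf.dropna(subset=[response] + list(predictor_sets[-1]))
        if sub["image"].nunique() < 2:
            continue
        fits = [
            _fit_mixed(sub, response, preds, crossed=False)
            for preds in predictor_sets
        ]
        winner = 0
        for i in range(1, len(fits)):
            df = len(fits[i].fe_params) - len(fits[i - 1].fe_params)
            delta = 2.0 * (fits[i].llf - fits[i - 1].llf)
            chi2 = max(delta, 0.0) if np.isfinite(delta) else 0.0
            if stats.chi2.sf(chi2, df) < alpha:
                winner = i
        rows.append({"subject": subject, "winner": f"MM{winner + 1}"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cluster characterisation


def characterize_clusters(
    features: pd.DataFrame,
    labels: pd.Series,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature Welch t-tests between static and dynamic viewers with
    pooled-SD Cohen's d and Benjamini-Hochberg FDR across all features.

    Returns one row per feature: t, p, q, d, direction, significant.
    Features constant in both groups are missing-coded.
    """
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError("labels must define exactly two groups")
    g_static = features.loc[labels == "static"]
    g_dynamic = features.loc[labels == "dynamic"]
    if len(g_static) < 2 or len(g_dynamic) < 2:
        raise ValueError("both groups need at least 2 subjects")
    rows = []
    for feat in features.columns:
        a = g_static[feat].dropna().to_numpy(dtype=float)
        b = g_dynamic[feat].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2 or (np.ptp(a) == 0 and np.ptp(b) == 0):
            rows.append(
                {"feature": feat, "t": np.nan, "p": np.nan, "d": np.nan,
                 "direction": "undefined"}
            )
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        pooled = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (len(a) + len(b) - 2)
        )
        d = (a.mean() - b.mean()) / pooled if pooled > 0 else np.nan
        rows.append(
            {
                "feature": feat,
                "t": float(t),
                "p": float(p),
                "d": float(d),
                "direction": "static_higher" if d > 0 else "dynamic_higher",
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    valid = out["p"].notna()
    q = np.full(len(out), np.nan)
    if valid.any():
        _, q_valid, _, _ = multipletests(out.loc[valid, "p"], method="fdr_bh")
        q[valid.to_numpy()] = q_valid
    out["q"] = q
    out["significant"] = out["q"] < fdr_alpha
    return out


def fit_covariate_model(
    pc1_scores: pd.Series,
    covariates: pd.DataFrame,
    n_iter: int = 1000,
    seed: int = 1234,
) -> tuple[NestedComparison, ValidationResult]:
    """Full OLS of PC1 scores on the demographic/cognitive/personality
    table (complete cases), plus its split-half validation.

    Depression/anxiety (DASS) and ROCF-copy scores are screening
    instruments, not predictors, and are never expected in the table.
    """
    preds = [c for c in covariates.columns if c != "subject_id"]
    data = covariates.copy()
    if "subject_id" in data.columns:
        data = data.set_index("subject_id")
    data = data.join(pc1_scores.rename("pc1"), how="inner")
    comparison = fit_nested_ols(data, "pc1", [preds], model_names=["full"])
    validation = split_half_validate(data, "pc1", preds, n_iter=n_iter, seed=seed)
    return comparison, validation
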