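"""Nested OLS comparisons, split-half validation, mixed-effects topography
models and cluster characterisation."""

import numpy as np
import pandas as pd
import pytest

from gazedyn.inference import (
    characterize_clusters,
    fit_covariate_model,
    fit_mixed_topography,
    fit_nested_ols,
    per_subject_topography_winners,
    split_half_validate,
)

SETS = [["sal"], ["sal", "sem"], ["sal", "sem", "shen"], ["sal", "sem", "shen", "ksd"]]


def _predictor_frame(n=114, seed=0, beta_ksd=0.0, sigma=1.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.normal(size=(n, 4)), columns=["sal", "sem", "shen", "ksd"]
    )
    df["pc1"] = beta_ksd * df["ksd"] + rng.normal(0, sigma, n)
    return df


class TestNestedOLS:
    def test_degrees_of_freedom_n114(self):
        """3 vs 4 predictors at n = 114 gives F degrees of freedom (1, 109)."""
        out = fit_nested_ols(_predictor_frame(), "pc1", SETS)
        assert (out.df1, out.df2) == (1, 109)

    def test_non_strictly_nested_rejected(self):
        with pytest.raises(ValueError):
            fit_nested_ols(_predictor_frame(), "pc1", [["sal"], ["sal"]])
        with pytest.raises(ValueError):
            fit_nested_ols(_predictor_frame(), "pc1", [["sal"], ["sem"]])

    def test_planted_coefficient_recovered(self):
        df = _predictor_frame(seed=1, beta_ksd=2.0, sigma=1e-6)
        out = fit_nested_ols(df, "pc1", SETS)
        assert out.coefficients.loc["ksd", "estimate"] == pytest.approx(2.0, abs=1e-4)
        assert out.p < 1e-10

    def test_singular_design_named(self):
        df = _predictor_frame(seed=2)
        df["sem"] = df["sal"] * 2.0
        with pytest.raises(ValueError, match="sal"):
            fit_nested_ols(df, "pc1", SETS)

    def test_sequential_f_agrees_with_lr_ordering(self):
        """F-based and likelihood-ratio-based comparisons order the models
        identically on the same data."""
        from scipy import stats

        df = _predictor_frame(seed=3, beta_ksd=0.5)
        out = fit_nested_ols(df, "pc1", SETS)
        # recompute LR chi2 from RSS ratios
        n = len(df)
        chi2 = []
        import statsmodels.api as sm

        rss = []
        for preds in SETS:
            X = sm.add_constant(df[preds])
            rss.append(sm.OLS(df["pc1"], X).fit().ssr)
        for r, f in zip(rss, rss[1:]):
            chi2.append(n * np.log(r / f))
        p_lr = [stats.chi2.sf(c, 1) for c in chi2]
        order_f = np.argsort(out.comparisons["p"].to_numpy())
        order_lr = np.argsort(p_lr)
        assert list(order_f) == list(order_lr)


class TestSplitHalfValidation:
    def test_planted_signal_predicts(self):
        rng = np.random.default_rng(4)
        df = _predictor_frame(seed=4, beta_ksd=1.0, sigma=1.0)  # R2 ~ 0.5
        out = split_half_validate(df, "pc1", ["sal", "sem", "shen", "ksd"], 200, 1)
        assert out.mean_r > 0.5

    def test_null_centred_at_zero(self):
        """Averaged over independent null datasets, the split-half r
        distribution is centred at zero (within one dataset the in-sample
        spurious fit biases it, so averaging across datasets is needed)."""
        means = []
        for seed in range(20):
            df = _predictor_frame(seed=50 + seed)
            out = split_half_validate(df, "pc1", ["sal", "sem", "shen", "ksd"], 40, 2)
            means.append(out.mean_r)
        grand = np.mean(means)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(grand) < max(3 * se, 0.05)

    def test_same_seed_identical(self):
        df = _predictor_frame(seed=6)
        a = split_half_validate(df, "pc1", ["sal"], 50, 9)
        b = split_half_validate(df, "pc1", ["sal"], 50, 9)
        assert np.array_equal(a.r_per_iteration, b.r_per_iteration)

    def test_bad_n_iter_rejected(self):
        with pytest.raises(ValueError):
            split_half_validate(_predictor_frame(), "pc1", ["sal"], 0, 1)


def _cell_data(n_subj=12, n_img=6, a=2.0, b=1.0, seed=0, re_sd=0.5, ksd_beta=0.0):
    rng = np.random.default_rng(seed)
    subj_re = rng.normal(0, re_sd, n_subj)
    img_re = rng.normal(0, re_sd, n_img)
    rows = []
    for s in range(n_subj):
        ksd_cells = rng.normal(0, 1, 100)  # per-subject spatial KSD
        for i in range(n_img):
            sal = rng.normal(0, 1, 100)
            sem = rng.normal(0, 1, 100)
            fdm = (
                a * sal + b * sem + ksd_beta * ksd_cells
                + subj_re[s] + img_re[i] + rng.normal(0, 1, 100)
            )
            rows.append(
                pd.DataFrame(
                    {"subject": f"S{s}", "image": f"I{i}", "fdm": fdm,
                     "sal": sal, "sem": sem, "ksd": ksd_cells}
                )
            )
    return pd.concat(rows, ignore_index=True)


class TestMixedTopography:
    def test_lrt_df_one_and_parameter_recovery(self):
        """2-SE intervals of the fixed effects cover the planted values at
        the nominal rate (coverage over replicate datasets; a single
        dataset misses ~5% of the time by construction)."""
        covered, total = 0, 0
        ksd_estimates = []
        for seed in range(6):
            data = _cell_data(n_subj=8, n_img=4, seed=seed)
            out = fit_mixed_topography(data)
            assert out.df == 1
            fe = out.fixed_effects
            for name, truth in (("sal", 2.0), ("sem", 1.0)):
                est = fe.loc[name, "estimate"]
                se = abs(est / fe.loc[name, "t"])
                covered += abs(est - truth) < 2 * se
                total += 1
            ksd_estimates.append(fe.loc["ksd", "estimate"])
        assert covered >= total - 2
        # ksd was never in the generating model
        assert abs(np.mean(ksd_estimates)) < 0.05

    def test_zero_variance_random_effects_reduce_to_ols(self):
        import statsmodels.api as sm

        data = _cell_data(n_subj=4, n_img=3, seed=2, re_sd=0.0)
        out = fit_mixed_topography(data)
        X = sm.add_constant(data[["sal", "sem", "ksd"]])
        ols = sm.OLS(data["fdm"], X).fit()
        assert out.fixed_effects.loc["sal", "estimate"] == pytest.approx(
            ols.params["sal"], abs=0.02
        )

    def test_per_subject_winner_tally(self):
        data = _cell_data(n_subj=6, n_img=4, seed=3, ksd_beta=1.0)
        winners = per_subject_topography_winners(data)
        assert len(winners) == 6
        assert (winners["winner"] == "MM3").mean() > 0.5

    def test_single_subject_rejected(self):
        data = _cell_data(n_subj=1, n_img=3, seed=4)
        with pytest.raises(ValueError):
            fit_mixed_topography(data)


class TestCharacterizeClusters:
    def _features(self, shift, n=50, seed=0, p=6):
        rng = np.random.default_rng(seed)
        a = pd.DataFrame(rng.normal(0, 1, (n, p)))
        b = pd.DataFrame(rng.normal(shift, 1, (n, p)))
        X = pd.concat([a, b], ignore_index=True)
        X.columns = [f"f{i}" for i in range(p)]
        labels = pd.Series(["dynamic"] * n + ["static"] * n)
        return X, labels

    def test_identical_groups_d_near_zero(self):
        X, labels = self._features(0.0, seed=1)
        out = characterize_clusters(X, labels)
        assert (out["d"].abs() < 0.5).all()
        assert not out["significant"].any()

    def test_one_sd_shift_gives_d_near_one(self):
        X, labels = self._features(1.0, seed=2)
        out = characterize_clusters(X, labels)
        assert np.allclose(out["d"], 1.0, atol=0.45)
        assert (out["direction"] == "static_higher").all()

    def test_bh_monotone_and_equal_p_case(self):
        X, labels = self._features(0.7, seed=3, p=10)
        out = characterize_clusters(X, labels)
        s = out.dropna().sort_values("p")
        assert s["q"].is_monotonic_increasing or (
            np.diff(s["q"]) > -1e-12
        ).all()
        assert (s["q"] >= s["p"] - 1e-12).all()

    def test_constant_feature_missing_coded(self):
        X, labels = self._features(0.5, seed=4)
        X["f0"] = 1.0
        out = characterize_clusters(X, labels)
        assert np.isnan(out.loc["f0", "d"])


class TestCovariateModel:
    def _covariates(self, n=100, seed=0, age_beta=1.0):
        rng = np.random.default_rng(seed)
        cov = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "age": rng.normal(23, 2.5, n),
                "sex": rng.integers(0, 2, n),
                "stroop": rng.normal(50, 8, n),
                "neo_openness": rng.normal(50, 10, n),
            }
        )
        pc1 = pd.Series(
            age_beta * (cov["age"] - 23).to_numpy() + rng.normal(0, 1, n),
            index=cov["subject_id"],
        )
        return cov, pc1

    def test_age_effect_detected(self):
        hits = 0
        for seed in range(10):
            cov, pc1 = self._covariates(seed=seed, age_beta=0.6)
            model, _ = fit_covariate_model(pc1, cov, n_iter=5, seed=seed)
            coefs = model.coefficients
            if coefs.loc["age", "p"] < 0.05 and (
                coefs.drop(index=["const", "age"])["p"] > 0.05
            ).mean() >= 0.5:
                hits += 1
        assert hits >= 9

    def test_noise_covariates_rarely_significant(self):
        sig = 0
        for seed in range(10):
            cov, pc1 = self._covariates(seed=100 + seed, age_beta=0.0)
            model, _ = fit_covariate_model(pc1, cov, n_iter=5, seed=seed)
            if model.model_p < 0.05:
                sig += 1
        assert sig <= 1

    def test_dass_rocf_absence_accepted(self):
        cov, pc1 = self._covariates(seed=7)
        assert "dass" not in cov.columns and "rocf_copy" not in cov.columns
        model, validation = fit_covariate_model(pc1, cov, n_iter=20, seed=3)
        assert np.isfinite(model.model_F)
        assert len(validation.r_per_iteration) == 20
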