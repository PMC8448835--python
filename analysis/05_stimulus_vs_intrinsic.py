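"""Does saliency/semantics or intrinsic dynamics predict the dominant
component?  Nested models M1 (SAL) .. M4 (+KSD) with sequential tests,
split-half predictive validation, and the cognitive-personality model.

Reads results/predictors.csv, scores_image.csv and covariates.csv
(run 01, 02 and 04 first).
"""

import importlib
import json

import pandas as pd

from gazedyn import inference

cfg_mod = importlib.import_module("00_config")


def main() -> None:
    out = cfg_mod.ensure_results()
    config, seed = cfg_mod.CONFIG, cfg_mod.SEED
    predictors = pd.read_csv(out / "predictors.csv", index_col=0)
    pc1 = pd.read_csv(out / "scores_image.csv", index_col=0)["PC1"]
    covariates = pd.read_csv(out / "covariates.csv")

    data = predictors.join(pc1.rename("pc1"), how="inner")
    sets = [["sal"], ["sal", "sem"], ["sal", "sem", "shen"],
            ["sal", "sem", "shen", "ksd"]]
    nested = inference.fit_nested_ols(data, "pc1", sets)
    validation = inference.split_half_validate(
        data, "pc1", sets[-1], n_iter=config.validation_iter, seed=seed
    )
    cov_model, cov_val = inference.fit_covariate_model(
        pc1, covariates, n_iter=config.validation_iter, seed=seed
    )

    nested.coefficients.to_csv(out / "m4_coefficients.csv")
    cov_model.coefficients.to_csv(out / "covariate_coefficients.csv")
    report = {
        "adj_r2": nested.adj_r2_by_model,
        "comparisons": nested.comparisons.to_dict(orient="records"),
        "m4_validation": {"mean_r": validation.mean_r, "sd_r": validation.sd_r,
                          "fraction_significant": validation.fraction_significant},
        "covariate_model": {"F": cov_model.model_F, "p": cov_model.model_p,
                            "adj_r2": cov_model.adj_r2_by_model["full"]},
        "covariate_validation": {"mean_r": cov_val.mean_r, "sd_r": cov_val.sd_r},
    }
    with open(out / "models_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)

    print("adjusted R2 by model:",
          {k: round(v, 3) for k, v in nested.adj_r2_by_model.items()})
    print(f"M4 vs M3: F[{nested.df1}, {nested.df2}] = {nested.F:.2f}, "
          f"p = {nested.p:.2g}")
    ksd_row = nested.coefficients.loc["ksd"]
    print(f"KSD in M4: t = {ksd_row['t']:.2f}, p = {ksd_row['p']:.2g}")
    print(f"split-half validation: mean r = {validation.mean_r:.2f} "
          f"(SD {validation.sd_r:.3f}), "
          f"{validation.fraction_significant * 100:.1f}% significant")
    sig = cov_model.coefficients.query("p < 0.05 and index != 'const'")
    print(f"cognitive-personality model: F = {cov_model.model_F:.2f}, "
          f"p = {cov_model.model_p:.3f}; significant terms: "
          f"{list(sig.index)}")


if __name__ == "__main__":
    main()
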