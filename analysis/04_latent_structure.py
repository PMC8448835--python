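"""Discover the latent structure of the feature table: PCA with promax
rotation, k-means viewing styles, ROC separation along PC1, per-feature
effect sizes, and the odd/even and category-projection control analyses.

Reads results/features_image.csv (run 02 first); re-simulates the cohort
only for the trial-subset controls.
"""

import importlib
import json

import numpy as np
import pandas as pd

from gazedyn import latent
from gazedyn.inference import characterize_clusters
from gazedyn.pipeline import simulate_stage, split_feature_tables

cfg_mod = importlib.import_module("00_config")


def main() -> None:
    out = cfg_mod.ensure_results()
    config, seed = cfg_mod.CONFIG, cfg_mod.SEED
    features = pd.read_csv(out / "features_image.csv", index_col=0)
    truth = pd.read_csv(out / "true_styles.csv", index_col=0)["true_style"]

    solution = latent.fit_pca_promax(features, seed=seed)
    clusters = latent.cluster_viewers(
        solution.scores, seed=seed, k=2, anchor=features["fix_dur_mean"]
    )
    roc = latent.roc_separation(solution.scores["PC1"], clusters.labels, seed=seed)
    effects = characterize_clusters(features, clusters.labels)

    solution.loadings.to_csv(out / "loadings_image.csv")
    solution.scores.to_csv(out / "scores_image.csv")
    pd.DataFrame({"style": clusters.labels, "true_style": truth}).to_csv(
        out / "labels.csv"
    )
    effects.to_csv(out / "effect_sizes.csv")

    agree = (clusters.labels == truth.loc[clusters.labels.index]).mean()
    print(f"retained components: {solution.n_components} "
          f"({np.round(solution.explained_variance, 1)} % variance)")
    print(f"style recovery vs planted labels: {max(agree, 1 - agree) * 100:.1f}%")
    print(f"ROC along PC1: accuracy {roc['accuracy_pct']:.1f}%, "
          f"AUC {roc['auc_pct']:.1f}%, cutoff {roc['cutoff']:.2f}")
    n_sig = int(effects["significant"].sum())
    print(f"features separating the styles after FDR: {n_sig}/{len(effects)}")

    # odd/even stability and category-specific projection controls
    profiles, scenes, _ = simulate_stage(config, seed)
    tables = split_feature_tables(profiles, scenes, config, seed)
    stability = latent.split_half_stability(
        tables["all"], tables["odd"], tables["even"], solution, clusters.labels,
        seed=seed,
    )
    cat_corr = {}
    for name, table in tables.items():
        if not name.startswith("category:"):
            continue
        proj = latent.project_scores(solution, table)["PC1"]
        joined = pd.concat([proj, solution.scores["PC1"]], axis=1, join="inner")
        cat_corr[name.split(":", 1)[1]] = float(
            np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1]
        )
    report = {"split_half": stability, "category_projection_r": cat_corr,
              "silhouette_by_k": clusters.silhouette_by_k,
              "jaccard": clusters.jaccard, "roc": roc}
    with open(out / "latent_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    print("odd/even PC1 correlations:",
          {k: round(v, 3) for k, v in stability["r"].items()})
    print("category-projection PC1 correlations:",
          {k: round(v, 3) for k, v in cat_corr.items()})


if __name__ == "__main__":
    main()
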