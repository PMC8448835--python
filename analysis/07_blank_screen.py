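"""Is the viewing style intrinsic?  Blank-screen analyses: the separate
PCA on the 53-feature table, random-forest cross-classification of the
image-derived style labels from blank-screen features, between-subject
similarity structure, and cross-condition label stability.

Reads results/features_*.csv and labels.csv (run 02 and 04 first).
"""

import importlib
import json

import numpy as np
import pandas as pd

from gazedyn import latent
from gazedyn.pipeline import classification_stage

cfg_mod = importlib.import_module("00_config")


def main() -> None:
    out = cfg_mod.ensure_results()
    config, seed = cfg_mod.CONFIG, cfg_mod.SEED
    fi = pd.read_csv(out / "features_image.csv", index_col=0)
    fb = pd.read_csv(out / "features_blank.csv", index_col=0)
    labels = pd.read_csv(out / "labels.csv", index_col=0)["style"]

    complete = fb.dropna()
    print(f"blank-screen sample: {len(complete)}/{len(fb)} subjects "
          f"(steady fixators excluded)")
    blank_solution = latent.fit_pca_promax(complete, n_components=3, seed=seed)
    blank_solution.loadings.to_csv(out / "loadings_blank.csv")
    print(f"blank PCA explained variance: "
          f"{np.round(blank_solution.explained_variance, 1)} %")

    image_solution = latent.fit_pca_promax(fi, seed=seed)
    report, similarity, stability = classification_stage(
        complete, fi, labels, image_solution, config, seed
    )
    similarity.matrix_image_viewing.to_csv(out / "similarity_image.csv")
    similarity.matrix_blank.to_csv(out / "similarity_blank.csv")
    summary = {
        "rf_accuracy_pct": report.accuracy_pct,
        "rf_permutation_p": report.permutation_p,
        "rf_ci95_pct": report.ci95_pct,
        "stability_pct": stability,
        "matrix_correlation": similarity.matrix_correlation,
        "within_static": similarity.within_static_mean,
        "within_dynamic": similarity.within_dynamic_mean,
        "between": similarity.between_mean,
    }
    with open(out / "blank_screen_report.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)

    print(f"RF cross-classification: {report.accuracy_pct:.1f}% "
          f"(permutation p = {report.permutation_p:.3g}, "
          f"95% CI [{report.ci95_pct[0]:.1f}, {report.ci95_pct[1]:.1f}])")
    print(f"style stability across conditions: {stability:.1f}%")
    print(f"between-subject similarity matrices correlate at "
          f"r = {similarity.matrix_correlation:.2f}")


if __name__ == "__main__":
    main()
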