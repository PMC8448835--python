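"""Preprocess every subject and extract the spatiotemporal feature
catalogue (58 features for image viewing, 53 for blank screen), plus the
per-subject predictors SAL, SEM, ShEn and KSD.

Writes the two feature tables, the predictor table, the true planted
styles and the feature-catalogue manifest under results/.
"""

import importlib

import pandas as pd
import yaml

from gazedyn.features import catalogue_manifest
from gazedyn.pipeline import (
    feature_table,
    features_stage,
    predictors_table,
    simulate_stage,
)

cfg_mod = importlib.import_module("00_config")


def main() -> None:
    out = cfg_mod.ensure_results()
    config, seed = cfg_mod.CONFIG, cfg_mod.SEED
    profiles, scenes, _ = simulate_stage(config, seed)
    records = features_stage(profiles, scenes, config, seed)

    fi = feature_table(records, "image_viewing")
    fb = feature_table(records, "blank_screen")
    predictors = predictors_table(records)
    truth = pd.Series(
        {sid: r.style_true for sid, r in records.items()}, name="true_style"
    )

    fi.to_csv(out / "features_image.csv")
    fb.to_csv(out / "features_blank.csv")
    predictors.to_csv(out / "predictors.csv")
    truth.to_csv(out / "true_styles.csv")
    with open(out / "catalogue.yaml", "w") as fh:
        yaml.safe_dump(catalogue_manifest(), fh, sort_keys=False)

    n_excluded = sum(not r.included for r in records.values())
    n_blank_missing = int(fb.isna().any(axis=1).sum())
    print(f"image-viewing features: {fi.shape[0]} subjects x {fi.shape[1]} features")
    print(f"blank-screen features:  {fb.shape[0]} subjects x {fb.shape[1]} features"
          f" ({n_blank_missing} with missing fixation features, excluded from PCA)")
    print(f"excluded for data loss: {n_excluded}")
    print(predictors.describe().loc[["mean", "std"]])


if __name__ == "__main__":
    main()
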