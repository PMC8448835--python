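"""Do intrinsic dynamics also shape WHERE fixations land?  Spatial KSD
maps on the 10 x 10 grid are compared with fixation density, saliency and
semantic maps through crossed-random-intercept mixed models MM1-MM3.

Self-contained: re-simulates the topography subject subset.
"""

import importlib
import json

from gazedyn.pipeline import features_stage, simulate_stage, topography_stage

cfg_mod = importlib.import_module("00_config")


def main() -> None:
    out = cfg_mod.ensure_results()
    config, seed = cfg_mod.CONFIG, cfg_mod.SEED
    profiles, scenes, _ = simulate_stage(config, seed)

    static_ids = [p.subject_id for p in profiles if p.style == "static"]
    dynamic_ids = [p.subject_id for p in profiles if p.style == "dynamic"]
    half = config.topography_n_subjects // 2
    subjects = static_ids[:half] + dynamic_ids[: config.topography_n_subjects - half]
    subset = [p for p in profiles if p.subject_id in set(subjects)]

    records = features_stage(
        subset, scenes, config, seed, topography_subjects=set(subjects)
    )
    images = [s.scene_id for s in scenes[: config.topography_n_images]]
    data, mixed, winners = topography_stage(records, scenes, config, subjects, images)

    data.to_csv(out / "topography_cells.csv", index=False)
    mixed.fixed_effects.to_csv(out / "mm3_fixed_effects.csv")
    report = {
        "chi2": mixed.chi2, "df": mixed.df, "p": mixed.p,
        "marginal_r2": mixed.marginal_r2_by_model,
        "comparisons": mixed.comparisons.to_dict(orient="records"),
        "per_subject_winners": winners["winner"].value_counts().to_dict(),
    }
    with open(out / "topography_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)

    n_cells = int(data[["subject", "image"]].drop_duplicates().shape[0]) * 100
    print(f"cell data: {len(data)} usable rows of {n_cells} "
          f"({len(subjects)} subjects x {len(images)} images x 100 cells)")
    print(f"MM3 vs MM2: chi2[{mixed.df}] = {mixed.chi2:.2f}, p = {mixed.p:.2g}")
    print("marginal R2:",
          {k: round(v, 3) for k, v in mixed.marginal_r2_by_model.items()})
    print("per-subject winning model:",
          winners["winner"].value_counts().to_dict())


if __name__ == "__main__":
    main()
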