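"""Simulate the synthetic study cohort and stimulus set.

Draws 60 static + 60 dynamic viewer profiles, fabricates the 185 scene
saliency/semantic maps, and writes the cohort table, the covariate table
and one example gaze log so later stages (and readers) can inspect what
the generator produces.
"""

import importlib

from gazedyn import simulate
from gazedyn.pipeline import simulate_stage

cfg_mod = importlib.import_module("00_config")


def main() -> None:
    out = cfg_mod.ensure_results()
    config, seed = cfg_mod.CONFIG, cfg_mod.SEED
    profiles, scenes, covariates = simulate_stage(config, seed)

    table = simulate.cohort_table(profiles)
    table.to_csv(out / "cohort.csv", index=False)
    covariates.to_csv(out / "covariates.csv", index=False)

    example = simulate.simulate_image_viewing(
        profiles[0], scenes[:2], config.session, seed=seed
    )
    example.to_tsv(out / "example_gaze.tsv")

    by_style = table.groupby("style")[
        ["fixation_duration_mean", "exploration_time_mean", "tail_exponent"]
    ].mean()
    print(f"cohort: {len(profiles)} viewers "
          f"({int((table['style'] == 'static').sum())} static)")
    print(by_style.round(2))
    print(f"scenes: {len(scenes)} across "
          f"{len({s.category for s in scenes})} categories")
    print(f"example gaze log: {len(example.samples)} samples, "
          f"{example.samples.trial_id.nunique()} trials "
          f"-> {out / 'example_gaze.tsv'}")


if __name__ == "__main__":
    main()
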