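"""End-to-end study pipeline: simulate -> preprocess -> features ->
step-law statistics -> latent structure -> inferential models ->
cross-condition classification.

Every stage is a plain function over explicit inputs so the numbered
analysis drivers, the test-suite and the acceptance script can run any
slice of the study; :func:`run_full_study` executes the whole sequence
under one seed and writes a results bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gazedyn import classify as classify_mod
from gazedyn import inference, latent, maps, simulate, steplaw
from gazedyn.config import SessionConfig
from gazedyn.features import catalogue_manifest, extract_features
from gazedyn.preprocess import (
    DetectionParams,
    compute_gaze_steps,
    detect_fixations,
    filter_validity,
    subject_inclusion,
    trial_durations,
)

KSD_THRESHOLDS_DEG = (0.2, 0.4, 0.8, 1.6, 3.2, 4.0, 4.9)


@dataclass(frozen=True)
class StudyConfig:
    """Everything the full study needs besides the seed."""

    session: SessionConfig = field(default_factory=SessionConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    n_static: int = 60
    n_dynamic: int = 60
    carry_over: float = 0.8
    steady_fixation_prob: float = 0.1
    n_min: int = 50  # minimum sample for any power-law fit
    ksd_thresholds_deg: tuple[float, ...] = KSD_THRESHOLDS_DEG
    threshold_curve_n_subjects: int = 12  # control analysis subsample
    grid_shape: tuple[int, int] = (10, 10)
    fdm_fwhm_deg: float = 2.0
    local_radius_deg: float = 1.0  # "local" window for SAL / SEM
    topography_n_subjects: int = 24
    topography_n_images: int = 8
    validation_iter: int = 1000
    rf_n_estimators: int = 500
    rf_null_n_estimators: int = 100
    rf_n_permutations: int = 200
    n_boot: int = 2000
    run_models: bool = True
    run_topography: bool = True
    run_classification: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["session"] = self.session.to_dict()
        d["detection"] = dataclasses.asdict(self.detection)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "session" in d:
            d["session"] = SessionConfig.from_dict(d["session"])
        if "detection" in d:
            d["detection"] = DetectionParams(**d["detection"])
        for key in ("ksd_thresholds_deg", "grid_shape"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown StudyConfig keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SubjectRecord:
    """Everything retained per subject after streaming preprocessing."""

    subject_id: str
    style_true: str
    included: bool
    features_image: pd.Series | None = None
    features_blank: pd.Series | None = None
    step_lengths_deg: np.ndarray | None = None  # pooled image-viewing steps
    sal: float = float("nan")
    sem: float = float("nan")
    shen: float = float("nan")
    ksd: float = float("nan")
    alpha: float = float("nan")
    fixations_by_scene: dict | None = None  # only for topography subjects
    ksd_grid: np.ndarray | None = None
    steps_xy: pd.DataFrame | None = None


def _child_seed(seed: int, *tokens) -> int:
    """Deterministic per-stage/per-subject seed below 2^31."""
    h = hashlib.sha256(("|".join(map(str, (seed, *tokens)))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _trial_table(recording) -> pd.DataFrame:
    dur = trial_durations(recording)
    start = recording.samples.groupby("trial_id")["timestamp"].min()
    return pd.DataFrame(
        {"trial_id": dur.index, "start": start.values, "duration": dur.values}
    )


def process_image_recording(
    recording,
    scenes,
    config: StudyConfig,
    local_sal: dict | None = None,
    local_sem: dict | None = None,
    keep_spatial: bool = False,
):
    """Preprocess one image-viewing recording into features + predictors.

    ``local_sal`` / ``local_sem`` are per-scene disc-mean maps (see
    :func:`gazedyn.maps.disc_mean_map`); when given, SAL and SEM are
    point-sampled from them at fixation centroids.
    """
    geometry = config.session
    samples, usable = filter_validity(recording)
    included = subject_inclusion(usable)
    trials = _trial_table(recording)
    fixations = detect_fixations(samples, config.detection, geometry)
    steps, flips = compute_gaze_steps(samples, geometry)
    features = extract_features(
        fixations, steps, flips, samples, trials, "image_viewing", geometry
    )

    out = {
        "included": included,
        "features": features,
        "step_lengths_deg": steps["length_deg"].to_numpy(),
    }

    # Shannon entropy of the per-image gaze heatmaps, averaged over images
    shens = [
        maps.visit_count_entropy(tdf["x"], tdf["y"], geometry)
        for _, tdf in samples.groupby("trial_id")
    ]
    out["shen"] = float(np.mean(shens)) if shens else float("nan")

    # power-law similarity of the pooled step-length distribution
    try:
        fit = steplaw.fit_power_law(out["step_lengths_deg"], n_min=config.n_min)
        out["ksd"], out["alpha"] = fit.ksd, fit.alpha
    except steplaw.DegenerateInputError:
        out["ksd"] = out["alpha"] = float("nan")

    # SAL / SEM: mean local map value at fixated locations
    if local_sal is not None and len(fixations):
        scene_of_trial = (
            recording.samples.groupby("trial_id")["scene_id"].first()
            if "scene_id" in recording.samples.columns
            else None
        )
        sal_vals, sem_vals = [], []
        for tid, fdf in fixations.groupby("trial_id"):
            sid = scene_of_trial.loc[tid] if scene_of_trial is not None else None
            if sid is None or sid not in local_sal:
                continue
            ix = np.clip(
                fdf["centroid_x"].to_numpy().astype(int), 0, geometry.map_width - 1
            )
            iy = np.clip(
                fdf["centroid_y"].to_numpy().astype(int), 0, geometry.map_height - 1
            )
            sal_vals.append(local_sal[sid][iy, ix].mean())
            sem_vals.append(local_sem[sid][iy, ix].mean())
        out["sal"] = float(np.mean(sal_vals)) if sal_vals else float("nan")
        out["sem"] = float(np.mean(sem_vals)) if sem_vals else float("nan")
    else:
        out["sal"] = out["sem"] = float("nan")

    if keep_spatial:
        out["fixations"] = fixations
        out["scene_of_trial"] = (
            recording.samples.groupby("trial_id")["scene_id"].first()
        )
        out["steps_xy"] = steps[["trial_id", "x0", "y0", "length_deg"]]
    return out


def process_blank_recording(recording, config: StudyConfig) -> pd.Series:
    geometry = config.session
    samples, _usable = filter_validity(recording)
    trials = _trial_table(recording)
    fixations = detect_fixations(samples, config.detection, geometry)
    steps, flips = compute_gaze_steps(samples, geometry)
    return extract_features(
        fixations, steps, flips, samples, trials, "blank_screen", geometry
    )


def split_feature_tables(
    profiles,
    scenes,
    config: StudyConfig,
    seed: int,
) -> dict[str, pd.DataFrame]:
    """Image-viewing feature tables for the whole session and for trial
    subsets: odd/even images and each scene category.

    Each subject is simulated and preprocessed once; features are then
    recomputed per trial subset, which is what the odd/even stability and
    category-projection control analyses consume.
    """
    geometry = config.session
    cat_of_scene = {s.scene_id: s.category for s in scenes}
    subsets: dict[str, dict] = {"all": {}, "odd": {}, "even": {}}
    for cat in sorted({s.category for s in scenes}):
        subsets[f"category:{cat}"] = {}
    for profile in profiles:
        sid = profile.subject_id
        rec = simulate.simulate_image_viewing(
            profile, scenes, geometry, _child_seed(seed, "img", sid)
        )
        samples, usable = filter_validity(rec)
        if not subject_inclusion(usable):
            continue
        trials = _trial_table(rec)
        fixations = detect_fixations(samples, config.detection, geometry)
        steps, flips = compute_gaze_steps(samples, geometry)
        scene_of_trial = rec.samples.groupby("trial_id")["scene_id"].first()

        def subset_features(trial_ids):
            tsub = trials[trials["trial_id"].isin(trial_ids)]
            return extract_features(
                fixations[fixations["trial_id"].isin(trial_ids)],
                steps[steps["trial_id"].isin(trial_ids)],
                flips[flips["trial_id"].isin(trial_ids)],
                samples[samples["trial_id"].isin(trial_ids)],
                tsub,
                "image_viewing",
                geometry,
            )

        all_ids = trials["trial_id"].to_numpy()
        subsets["all"][sid] = subset_features(all_ids)
        subsets["odd"][sid] = subset_features(all_ids[1::2])
        subsets["even"][sid] = subset_features(all_ids[::2])
        cats = scene_of_trial.map(cat_of_scene)
        for cat in sorted(set(cat_of_scene.values())):
            ids = cats.index[cats == cat]
            if len(ids):
                subsets[f"category:{cat}"][sid] = subset_features(ids)
    return {name: pd.DataFrame(d).T for name, d in subsets.items() if d}


# ---------------------------------------------------------------------------
# Stages


def simulate_stage(config: StudyConfig, seed: int):
    """Cohort, scenes and covariates for the study."""
    profiles = simulate.generate_cohort(
        config.n_static, config.n_dynamic, _child_seed(seed, "cohort")
    )
    scenes = simulate.generate_scene_maps(
        config.session.n_images, config.session, _child_seed(seed, "scenes")
    )
    covariates = simulate.generate_covariates(profiles, _child_seed(seed, "covariates"))
    return profiles, scenes, covariates


def features_stage(
    profiles,
    scenes,
    config: StudyConfig,
    seed: int,
    topography_subjects: set[str] | None = None,
) -> dict[str, SubjectRecord]:
    """Simulate and preprocess every subject (both conditions), streaming
    so raw samples are never all in memory at once."""
    geometry = config.session
    local_sal = {
        s.scene_id: maps.disc_mean_map(
            maps.PixelMap(s.saliency_map, "saliency"), config.local_radius_deg, geometry
        ).values.astype(np.float32)
        for s in scenes
    }
    local_sem = {
        s.scene_id: maps.disc_mean_map(
            maps.PixelMap(s.semantic_map, "semantic"), config.local_radius_deg, geometry
        ).values.astype(np.float32)
        for s in scenes
    }
    topography_subjects = topography_subjects or set()
    records: dict[str, SubjectRecord] = {}
    for profile in profiles:
        sid = profile.subject_id
        rec_img = simulate.simulate_image_viewing(
            profile, scenes, geometry, _child_seed(seed, "img", sid)
        )
        keep_spatial = sid in topography_subjects
        proc = process_image_recording(
            rec_img, scenes, config, local_sal, local_sem, keep_spatial=keep_spatial
        )
        rec_blank = simulate.simulate_blank_screen(
            profile,
            geometry,
            _child_seed(seed, "blank", sid),
            carry_over=config.carry_over,
            steady_fixation_prob=config.steady_fixation_prob,
        )
        features_blank = process_blank_recording(rec_blank, config)
        record = SubjectRecord(
            subject_id=sid,
            style_true=profile.style,
            included=proc["included"],
            features_image=proc["features"],
            features_blank=features_blank,
            step_lengths_deg=proc["step_lengths_deg"],
            sal=proc["sal"],
            sem=proc["sem"],
            shen=proc["shen"],
            ksd=proc["ksd"],
            alpha=proc["alpha"],
        )
        if keep_spatial:
            record.fixations_by_scene = {
                "fixations": proc["fixations"],
                "scene_of_trial": proc["scene_of_trial"],
            }
            record.steps_xy = proc["steps_xy"]
        records[sid] = record
    return records


def feature_table(records: dict[str, SubjectRecord], condition: str) -> pd.DataFrame:
    attr = "features_image" if condition == "image_viewing" else "features_blank"
    rows = {
        sid: getattr(r, attr)
        for sid, r in records.items()
        if r.included and getattr(r, attr) is not None
    }
    return pd.DataFrame(rows).T


def predictors_table(records: dict[str, SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            sid: {"sal": r.sal, "sem": r.sem, "shen": r.shen, "ksd": r.ksd,
                  "alpha": r.alpha}
            for sid, r in records.items()
            if r.included
        }
    ).T


def latent_stage(features_image: pd.DataFrame, seed: int):
    """Image-viewing PCA, style clustering and ROC separation."""
    solution = latent.fit_pca_promax(features_image.dropna(axis=0), seed=seed)
    clusters = latent.cluster_viewers(
        solution.scores,
        seed=seed,
        k=2,
        anchor=features_image["fix_dur_mean"],
    )
    roc = latent.roc_separation(
        solution.scores["PC1"], clusters.labels, seed=seed
    )
    return solution, clusters, roc


def blank_latent_stage(features_blank: pd.DataFrame, seed: int):
    """Blank-screen PCA on subjects with complete (non-missing) features.

    Viewers who held a steady central fixation lack dispersion-defined
    fixation features and are excluded here, mirroring the exclusion of
    steady-fixating observers from blank-screen analyses.
    """
    complete = features_blank.dropna(axis=0)
    solution = latent.fit_pca_promax(complete, n_components=3, seed=seed)
    return solution, complete


def models_stage(
    pc1: pd.Series,
    predictors: pd.DataFrame,
    covariates: pd.DataFrame,
    config: StudyConfig,
    seed: int,
):
    """Nested spatiotemporal-features models M1-M4 (+ validation) and the
    cognitive-personality covariate model."""
    data = predictors.join(pc1.rename("pc1"), how="inner")
    nested = inference.fit_nested_ols(
        data,
        "pc1",
        [["sal"], ["sal", "sem"], ["sal", "sem", "shen"], ["sal", "sem", "shen", "ksd"]],
    )
    validation = inference.split_half_validate(
        data,
        "pc1",
        ["sal", "sem", "shen", "ksd"],
        n_iter=config.validation_iter,
        seed=_child_seed(seed, "m4_validation"),
    )
    cov_model, cov_validation = inference.fit_covariate_model(
        pc1, covariates, n_iter=config.validation_iter,
        seed=_child_seed(seed, "cov_validation"),
    )
    return nested, validation, cov_model, cov_validation


def threshold_robustness_stage(
    records: dict[str, SubjectRecord],
    subjects: list[str],
    config: StudyConfig,
) -> pd.DataFrame:
    """KSD recomputed after removing steps below each length threshold,
    for a subsample of subjects (control analysis)."""
    rows = []
    for sid in subjects:
        curve = steplaw.ksd_threshold_curve(
            records[sid].step_lengths_deg,
            list(config.ksd_thresholds_deg),
            n_min=config.n_min,
        )
        curve.insert(0, "subject", sid)
        rows.append(curve)
    return pd.concat(rows, ignore_index=True)


def topography_stage(
    records: dict[str, SubjectRecord],
    scenes,
    config: StudyConfig,
    subjects: list[str],
    images: list[str],
):
    """Spatial KSD maps, subsampled FDM/saliency/semantic maps and the
    crossed-random-intercept mixed models MM1-MM3."""
    geometry = config.session
    scene_by_id = {s.scene_id: s for s in scenes}
    n_rows, n_cols = config.grid_shape

    sal_cells = {
        sid: maps.subsample_map(
            maps.PixelMap(scene_by_id[sid].saliency_map.astype(float), "saliency"),
            config.grid_shape,
        ).values.ravel()
        for sid in images
    }
    sem_cells = {
        sid: maps.subsample_map(
            maps.PixelMap(scene_by_id[sid].semantic_map.astype(float), "semantic"),
            config.grid_shape,
        ).values.ravel()
        for sid in images
    }

    rows = []
    for subj in subjects:
        rec = records[subj]
        if rec.steps_xy is None or rec.fixations_by_scene is None:
            continue
        ksd_map = steplaw.spatial_ksd_map(
            rec.steps_xy, geometry, config.grid_shape, n_min=config.n_min
        )
        rec.ksd_grid = ksd_map.grid
        ksd_cells = ksd_map.grid.ravel()
        fixations = rec.fixations_by_scene["fixations"]
        scene_of_trial = rec.fixations_by_scene["scene_of_trial"]
        for image_id in images:
            trials = scene_of_trial.index[scene_of_trial == image_id]
            fdf = fixations[fixations["trial_id"].isin(trials)]
            if len(fdf) == 0:
                continue
            fdm = maps.subsample_map(
                maps.fixation_density_map(fdf, geometry, config.fdm_fwhm_deg),
                config.grid_shape,
            ).values.ravel()
            rows.append(
                pd.DataFrame(
                    {
                        "subject": subj,
                        "image": image_id,
                        "cell": np.arange(n_rows * n_cols),
                        "fdm": fdm,
                        "sal": sal_cells[image_id],
                        "sem": sem_cells[image_id],
                        "ksd": ksd_cells,
                    }
                )
            )
    data = pd.concat(rows, ignore_index=True)
    mixed = inference.fit_mixed_topography(data)
    winners = inference.per_subject_topography_winners(data)
    return data, mixed, winners


def classification_stage(
    features_blank: pd.DataFrame,
    features_image: pd.DataFrame,
    labels: pd.Series,
    image_solution: latent.PCASolution,
    config: StudyConfig,
    seed: int,
):
    """Blank-screen -> image-style RF cross-classification, between-subject
    similarity, and cross-condition label stability.

    Subjects with missing blank-screen features (steady fixators) are
    excluded, mirroring their exclusion from the blank-screen PCA.
    """
    features_blank = features_blank.dropna(axis=0)
    common = features_blank.index.intersection(labels.index)
    blank = features_blank.loc[common]
    report = classify_mod.rf_cross_classify(
        blank,
        labels.loc[common],
        seed=_child_seed(seed, "rf"),
        n_estimators=config.rf_n_estimators,
        n_permutations=config.rf_n_permutations,
        null_n_estimators=config.rf_null_n_estimators,
        n_boot=config.n_boot,
    )
    similarity = classify_mod.between_subject_similarity(
        features_image.loc[common, blank.columns], blank, labels.loc[common]
    )
    # project blank features onto the image-viewing PC1 loading pattern over
    # the shared (blank-measurable) features; blank features are z-scored
    # within-condition so scale shifts between conditions do not dominate
    shared = [f for f in image_solution.feature_means.index if f in blank.columns]
    zb = blank[shared]
    zb = (zb - zb.mean()) / zb.std().replace(0.0, 1.0)
    pc1_blank = pd.Series(
        zb.to_numpy(dtype=float)
        @ image_solution.loadings.loc[shared, "PC1"].to_numpy(),
        index=common,
    )
    stability = classify_mod.cross_condition_label_stability(
        image_solution.scores.loc[common, "PC1"],
        pc1_blank,
        labels.loc[common],
        seed=_child_seed(seed, "stability"),
    )
    return report, similarity, stability


# ---------------------------------------------------------------------------
# Bundle


@dataclass
class StudyResultBundle:
    config: StudyConfig
    seed: int
    features_image: pd.DataFrame
    features_blank: pd.DataFrame
    true_styles: pd.Series
    predictors: pd.DataFrame
    solution_image: latent.PCASolution
    solution_blank: latent.PCASolution | None
    clusters: latent.ClusterSolution
    roc: dict
    effect_sizes: pd.DataFrame
    nested: inference.NestedComparison | None = None
    validation: inference.ValidationResult | None = None
    covariate_model: inference.NestedComparison | None = None
    covariate_validation: inference.ValidationResult | None = None
    threshold_curves: pd.DataFrame | None = None
    mixed: inference.MixedComparison | None = None
    topography_winners: pd.DataFrame | None = None
    classification: classify_mod.ClassificationReport | None = None
    similarity: classify_mod.SimilarityStructure | None = None
    stability_pct: float | None = None

    @property
    def recovery_accuracy(self) -> float:
        """Fraction of subjects whose discovered style matches the planted
        one (label permutation resolved by majority)."""
        truth = self.true_styles.loc[self.clusters.labels.index]
        agree = float((self.clusters.labels == truth).mean())
        return max(agree, 1.0 - agree)

    def provenance(self) -> dict:
        cfg_yaml = yaml.safe_dump(self.config.to_dict(), sort_keys=True)
        return {
            "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
            "seed": self.seed,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.features_image.to_csv(out / "features_image.csv")
        self.features_blank.to_csv(out / "features_blank.csv")
        self.predictors.to_csv(out / "predictors.csv")
        self.solution_image.loadings.to_csv(out / "loadings_image.csv")
        self.solution_image.scores.to_csv(out / "scores_image.csv")
        if self.solution_blank is not None:
            self.solution_blank.loadings.to_csv(out / "loadings_blank.csv")
            self.solution_blank.scores.to_csv(out / "scores_blank.csv")
        pd.DataFrame(
            {"style": self.clusters.labels, "true_style": self.true_styles}
        ).to_csv(out / "labels.csv")
        self.effect_sizes.to_csv(out / "effect_sizes.csv")
        with open(out / "catalogue.yaml", "w") as fh:
            yaml.safe_dump(catalogue_manifest(), fh, sort_keys=False)
        report = {
            "explained_variance_pct": [float(v) for v in
                                       self.solution_image.explained_variance],
            "silhouette_by_k": self.clusters.silhouette_by_k,
            "jaccard": self.clusters.jaccard,
            "roc": self.roc,
            "recovery_accuracy": self.recovery_accuracy,
            "provenance": self.provenance(),
        }
        if self.nested is not None:
            report["nested_models"] = {
                "adj_r2": self.nested.adj_r2_by_model,
                "final_F": self.nested.F,
                "final_df": [self.nested.df1, self.nested.df2],
                "final_p": self.nested.p,
                "coefficients": self.nested.coefficients.to_dict(),
            }
            report["m4_validation"] = {
                "mean_r": self.validation.mean_r,
                "sd_r": self.validation.sd_r,
                "fraction_significant": self.validation.fraction_significant,
            }
        if self.mixed is not None:
            report["mixed_models"] = {
                "chi2": self.mixed.chi2,
                "df": self.mixed.df,
                "p": self.mixed.p,
                "marginal_r2": self.mixed.marginal_r2_by_model,
                "fixed_effects": self.mixed.fixed_effects.to_dict(),
            }
            report["topography_winner_mm3_pct"] = float(
                (self.topography_winners["winner"] == "MM3").mean() * 100.0
            )
        if self.classification is not None:
            report["classification"] = {
                "accuracy_pct": self.classification.accuracy_pct,
                "permutation_p": self.classification.permutation_p,
                "ci95_pct": self.classification.ci95_pct,
            }
            report["similarity"] = {
                "matrix_correlation": self.similarity.matrix_correlation,
                "within_static": self.similarity.within_static_mean,
                "within_dynamic": self.similarity.within_dynamic_mean,
                "between": self.similarity.between_mean,
            }
            report["stability_pct"] = self.stability_pct
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)


def run_full_study(
    config: StudyConfig | str | Path | None = None,
    seed: int = 1234,
    outdir=None,
) -> StudyResultBundle:
    """Execute the whole study on synthetic data under one seed."""
    if config is None:
        config = StudyConfig()
    elif not isinstance(config, StudyConfig):
        config = StudyConfig.from_yaml(config)

    profiles, scenes, covariates = simulate_stage(config, seed)
    topo_subjects: list[str] = []
    if config.run_topography:
        # deterministic balanced subset for the topography stage
        static_ids = [p.subject_id for p in profiles if p.style == "static"]
        dynamic_ids = [p.subject_id for p in profiles if p.style == "dynamic"]
        half = config.topography_n_subjects // 2
        topo_subjects = static_ids[:half] + dynamic_ids[: config.topography_n_subjects - half]
    records = features_stage(
        profiles, scenes, config, seed, topography_subjects=set(topo_subjects)
    )

    features_image = feature_table(records, "image_viewing")
    features_blank = feature_table(records, "blank_screen")
    true_styles = pd.Series(
        {sid: r.style_true for sid, r in records.items()}, name="true_style"
    )
    predictors = predictors_table(records)

    solution, clusters, roc = latent_stage(features_image, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        solution_blank = None
        if features_blank.dropna(axis=0).shape[0] >= 10:
            solution_blank, _ = blank_latent_stage(features_blank, seed)
    effect_sizes = inference.characterize_clusters(
        features_image.loc[clusters.labels.index], clusters.labels
    )

    bundle = StudyResultBundle(
        config=config,
        seed=seed,
        features_image=features_image,
        features_blank=features_blank,
        true_styles=true_styles,
        predictors=predictors,
        solution_image=solution,
        solution_blank=solution_blank,
        clusters=clusters,
        roc=roc,
        effect_sizes=effect_sizes,
    )

    if config.run_models:
        nested, validation, cov_model, cov_val = models_stage(
            solution.scores["PC1"], predictors, covariates, config, seed
        )
        bundle.nested = nested
        bundle.validation = validation
        bundle.covariate_model = cov_model
        bundle.covariate_validation = cov_val
        bundle.threshold_curves = threshold_robustness_stage(
            records,
            list(features_image.index[: config.threshold_curve_n_subjects]),
            config,
        )

    if config.run_topography and topo_subjects:
        images = [s.scene_id for s in scenes[: config.topography_n_images]]
        _data, mixed, winners = topography_stage(
            records, scenes, config, topo_subjects, images
        )
        bundle.mixed = mixed
        bundle.topography_winners = winners

    if config.run_classification:
        report, similarity, stability = classification_stage(
            features_blank, features_image, clusters.labels, solution, config, seed
        )
        bundle.classification = report
        bundle.similarity = similarity
        bundle.stability_pct = stability

    if outdir is not None:
        bundle.write(outdir)
    return bundle
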