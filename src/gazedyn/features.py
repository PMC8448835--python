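"""Per-subject spatiotemporal feature catalogue.

58 named features for image viewing (53 for blank-screen viewing, which
drops the exploration-time family), organised in four families:

* fixations (14): count, rate, duration statistics, and the temporal course
  of both across the four quarters of each trial's exploration time;
* pupil diameter (8): per-eye and binocular means/SDs, pupil during
  fixations, and the mean within-trial range;
* gaze steps (31): count, length statistics (deg), direction flips and flip
  rates, their quarter-wise temporal course, sample-to-sample velocity, and
  the proportion of steps larger than 1 deg;
* exploration time (5): statistics of the self-paced trial durations.

Per-trial statistics are averaged across trials.  Quarter features use
per-trial quarters: half-open intervals [q*T/4, (q+1)*T/4) of each trial's
own exploration time T.  A subject with no detectable fixations (or a
single one, leaving dispersion undefined) carries NaN in the affected
fixation features; downstream stages treat NaN as missing-coded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from gazedyn.preprocess import flip_event_table

_QUARTERS = ("q1", "q2", "q3", "q4")

FIXATION_FEATURES = (
    ["fix_count", "fix_rate", "fix_dur_mean", "fix_dur_sd", "fix_dur_max", "fix_dur_median"]
    + [f"fix_dur_mean_{q}" for q in _QUARTERS]
    + [f"fix_count_{q}" for q in _QUARTERS]
)

PUPIL_FEATURES = [
    "pupil_mean_left",
    "pupil_sd_left",
    "pupil_mean_right",
    "pupil_sd_right",
    "pupil_mean",
    "pupil_sd",
    "pupil_fix_mean",
    "pupil_range",
]

STEP_FEATURES = (
    [
        "step_count",
        "step_len_mean",
        "step_len_sd",
        "step_len_max",
        "step_len_median",
        "step_len_cv",
        "step_len_skew",
        "x_flips",
        "y_flips",
        "x_flip_rate",
        "y_flip_rate",
    ]
    + [f"step_len_mean_{q}" for q in _QUARTERS]
    + [f"step_count_{q}" for q in _QUARTERS]
    + [f"x_flips_{q}" for q in _QUARTERS]
    + [f"y_flips_{q}" for q in _QUARTERS]
    + ["step_vel_mean", "step_vel_sd", "step_vel_max", "prop_steps_gt_1deg"]
)

EXPLORATION_FEATURES = [
    "explor_mean",
    "explor_sd",
    "explor_max",
    "explor_min",
    "explor_total",
]

IMAGE_FEATURES: list[str] = (
    FIXATION_FEATURES + PUPIL_FEATURES + STEP_FEATURES + EXPLORATION_FEATURES
)
BLANK_FEATURES: list[str] = FIXATION_FEATURES + PUPIL_FEATURES + STEP_FEATURES

assert len(IMAGE_FEATURES) == 58
assert len(BLANK_FEATURES) == 53

_FAMILY = {
    **{f: "fixations" for f in FIXATION_FEATURES},
    **{f: "pupil" for f in PUPIL_FEATURES},
    **{f: "gaze_steps" for f in STEP_FEATURES},
    **{f: "exploration_time" for f in EXPLORATION_FEATURES},
}


def feature_names(condition: str) -> list[str]:
    if condition == "image_viewing":
        return list(IMAGE_FEATURES)
    if condition == "blank_screen":
        return list(BLANK_FEATURES)
    raise ValueError(f"unknown condition {condition!r}")


def catalogue_manifest() -> dict:
    """Machine-readable catalogue: family, unit and brief formula per
    feature, for the YAML manifest written alongside feature tables."""
    units = {}
    for f in IMAGE_FEATURES:
        if f.startswith(("fix_dur", "explor")):
            units[f] = "ms"
        elif f.startswith("pupil"):
            units[f] = "mm"
        elif f.startswith("step_len"):
            units[f] = "deg" if "cv" not in f and "skew" not in f else "dimensionless"
        elif f.startswith("step_vel"):
            units[f] = "deg/s"
        elif "rate" in f:
            units[f] = "per_s"
        else:
            units[f] = "count"
    return {
        f: {"family": _FAMILY[f], "unit": units[f], "per_trial_average": True}
        for f in IMAGE_FEATURES
    }


def _nanmean(values) -> float:
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    return float(arr.mean()) if len(arr) else float("nan")


def _quarter_of(ts, start, duration):
    """Quarter index 0..3 of timestamps within a trial (half-open bins;
    the trial's final instant falls in the last quarter)."""
    frac = (np.asarray(ts) - start) / np.maximum(np.asarray(duration), 1e-9)
    return np.clip(np.floor(frac * 4).astype(int), 0, 3)


def extract_features(
    fixations: pd.DataFrame,
    steps: pd.DataFrame,
    flips: pd.DataFrame,
    samples: pd.DataFrame,
    trials: pd.DataFrame,
    condition: str,
    geometry,
) -> pd.Series:
    """Compute the feature catalogue for one subject and condition.

    Parameters mirror the preprocessing outputs: ``fixations``, ``steps``
    and ``flips`` from the detector / step extractor, ``samples`` the
    validity-filtered samples, and ``trials`` a table with columns
    trial_id, start, duration (ms).
    """
    if condition not in ("image_viewing", "blank_screen"):
        raise ValueError(f"unknown condition {condition!r}")
    if len(trials) == 0:
        raise ValueError("zero trials")

    trials = trials.set_index("trial_id")
    dur_s = trials["duration"] / 1000.0
    out: dict[str, float] = {}

    # -- fixations ----------------------------------------------------------
    if len(fixations):
        g = fixations.groupby("trial_id")["duration"]
        per_trial_count = g.count().reindex(trials.index, fill_value=0)
        out["fix_count"] = float(per_trial_count.mean())
        out["fix_rate"] = float((per_trial_count / dur_s).mean())
        out["fix_dur_mean"] = _nanmean(g.mean())
        out["fix_dur_sd"] = _nanmean(g.std())
        out["fix_dur_max"] = _nanmean(g.max())
        out["fix_dur_median"] = _nanmean(g.median())
        fq = _quarter_of(
            fixations["onset"].to_numpy(),
            trials.loc[fixations["trial_id"], "start"].to_numpy(),
            trials.loc[fixations["trial_id"], "duration"].to_numpy(),
        )
        qg = fixations.groupby([fixations["trial_id"], fq])["duration"]
        qmeans = qg.mean().unstack(fill_value=np.nan)
        qcounts = qg.count().unstack(fill_value=0).reindex(trials.index, fill_value=0)
        for q in range(4):
            out[f"fix_dur_mean_q{q + 1}"] = (
                _nanmean(qmeans[q]) if q in qmeans.columns else float("nan")
            )
            out[f"fix_count_q{q + 1}"] = (
                float(qcounts[q].mean()) if q in qcounts.columns else 0.0
            )
    else:
        for f in FIXATION_FEATURES:
            out[f] = float("nan")
        out["fix_count"] = 0.0
        out["fix_rate"] = 0.0
        for q in range(4):
            out[f"fix_count_q{q + 1}"] = 0.0

    # -- pupil --------------------------------------------------------------
    sp = samples.groupby("trial_id")
    out["pupil_mean_left"] = _nanmean(sp["pupil_left"].mean())
    out["pupil_sd_left"] = _nanmean(sp["pupil_left"].std())
    out["pupil_mean_right"] = _nanmean(sp["pupil_right"].mean())
    out["pupil_sd_right"] = _nanmean(sp["pupil_right"].std())
    out["pupil_mean"] = _nanmean(sp["pupil"].mean())
    out["pupil_sd"] = _nanmean(sp["pupil"].std())
    out["pupil_fix_mean"] = (
        _nanmean(fixations.groupby("trial_id")["mean_pupil"].mean())
        if len(fixations)
        else float("nan")
    )
    out["pupil_range"] = _nanmean(sp["pupil"].max() - sp["pupil"].min())

    # -- gaze steps ---------------------------------------------------------
    if len(steps):
        sg = steps.groupby("trial_id")["length_deg"]
        per_trial = sg.agg(["count", "mean", "std", "max", "median", "skew"])
        per_trial = per_trial.reindex(trials.index)
        out["step_count"] = float(per_trial["count"].fillna(0).mean())
        out["step_len_mean"] = _nanmean(per_trial["mean"])
        out["step_len_sd"] = _nanmean(per_trial["std"])
        out["step_len_max"] = _nanmean(per_trial["max"])
        out["step_len_median"] = _nanmean(per_trial["median"])
        out["step_len_cv"] = _nanmean(per_trial["std"] / per_trial["mean"])
        out["step_len_skew"] = _nanmean(per_trial["skew"])

        fl = flips.set_index("trial_id").reindex(trials.index, fill_value=0)
        out["x_flips"] = float(fl["x_flips"].mean())
        out["y_flips"] = float(fl["y_flips"].mean())
        out["x_flip_rate"] = float((fl["x_flips"] / dur_s).mean())
        out["y_flip_rate"] = float((fl["y_flips"] / dur_s).mean())

        sq = _quarter_of(
            steps["timestamp"].to_numpy(),
            trials.loc[steps["trial_id"], "start"].to_numpy(),
            trials.loc[steps["trial_id"], "duration"].to_numpy(),
        )
        qg = steps.groupby([steps["trial_id"], sq])["length_deg"]
        qmeans = qg.mean().unstack()
        qcounts = qg.count().unstack(fill_value=0).reindex(trials.index, fill_value=0)
        for q in range(4):
            out[f"step_len_mean_q{q + 1}"] = (
                _nanmean(qmeans[q]) if q in qmeans.columns else float("nan")
            )
            out[f"step_count_q{q + 1}"] = (
                float(qcounts[q].mean()) if q in qcounts.columns else 0.0
            )

        # quarter-wise direction flips (within trial segments)
        ev = flip_event_table(steps)
        n_trials = len(trials)
        for q in range(4):
            out[f"x_flips_q{q + 1}"] = 0.0
            out[f"y_flips_q{q + 1}"] = 0.0
        if len(ev):
            evq = _quarter_of(
                ev["timestamp"].to_numpy(),
                trials.loc[ev["trial_id"], "start"].to_numpy(),
                trials.loc[ev["trial_id"], "duration"].to_numpy(),
            )
            qcount = ev.groupby([ev["axis"], evq]).size()
            for axis in ("x", "y"):
                for q in range(4):
                    out[f"{axis}_flips_q{q + 1}"] = (
                        float(qcount.get((axis, q), 0)) / n_trials
                    )

        vel = steps["length_deg"] / (geometry.dt_ms / 1000.0)
        vg = vel.groupby(steps["trial_id"])
        out["step_vel_mean"] = _nanmean(vg.mean())
        out["step_vel_sd"] = _nanmean(vg.std())
        out["step_vel_max"] = _nanmean(vg.max())
        out["prop_steps_gt_1deg"] = _nanmean(
            (steps["length_deg"] > 1.0).groupby(steps["trial_id"]).mean()
        )
    else:
        for f in STEP_FEATURES:
            out[f] = 0.0
        for f in ("step_len_skew", "step_len_cv"):
            out[f] = float("nan")

    # -- exploration time ---------------------------------------------------
    if condition == "image_viewing":
        d = trials["duration"]
        out["explor_mean"] = float(d.mean())
        out["explor_sd"] = float(d.std()) if len(d) > 1 else float("nan")
        out["explor_max"] = float(d.max())
        out["explor_min"] = float(d.min())
        out["explor_total"] = float(d.sum())

    names = feature_names(condition)
    return pd.Series({k: out[k] for k in names}, name="value")[names]
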