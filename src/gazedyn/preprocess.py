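"""Raw gaze preprocessing: validity filtering, velocity-threshold fixation
detection, and gaze-step extraction.

The fixation detector follows the adaptive velocity-threshold family used
throughout the eye-movement literature: per-trial sample velocities from a
moving-window central difference, robust (median-based) velocity dispersion
estimates per axis, and an elliptic criterion with multiplier lambda
marking saccadic samples.  Maximal runs of non-saccadic samples at least
``min_fixation_duration`` long become fixations.  Gaps left by invalid
samples split fixations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DetectionParams:
    """Velocity-threshold detector settings (lambda = 15 by default)."""

    lam: float = 15.0
    min_fixation_duration: float = 50.0  # ms
    velocity_window: int = 5  # samples, must be odd

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.min_fixation_duration < 0:
            raise ValueError("min_fixation_duration must be >= 0")
        if self.velocity_window < 3 or self.velocity_window % 2 == 0:
            raise ValueError("velocity_window must be an odd integer >= 3")


def filter_validity(recording) -> tuple[pd.DataFrame, pd.Series]:
    """Keep only samples where both eyes carry validity code 0.

    Gaze position and pupil are binocular averages of the two (valid) eyes;
    the per-eye pupil columns are retained for the pupil feature family.

    Returns ``(samples, usable_fraction)`` where ``usable_fraction`` is the
    per-trial fraction of retained samples.  An all-invalid recording
    returns an empty frame (not an exception); an empty recording raises.
    """
    df = recording.samples
    if len(df) == 0:
        raise ValueError("recording contains no samples")
    ok = (df["validity_left"].to_numpy() == 0) & (df["validity_right"].to_numpy() == 0)
    usable = (
        pd.Series(ok, index=df.index).groupby(df["trial_id"]).mean().rename("usable")
    )
    kept = df.loc[ok]
    out = pd.DataFrame(
        {
            "timestamp": kept["timestamp"].to_numpy(),
            "x": (kept["x_left"].to_numpy() + kept["x_right"].to_numpy()) / 2.0,
            "y": (kept["y_left"].to_numpy() + kept["y_right"].to_numpy()) / 2.0,
            "pupil": (kept["pupil_left"].to_numpy() + kept["pupil_right"].to_numpy())
            / 2.0,
            "pupil_left": kept["pupil_left"].to_numpy(),
            "pupil_right": kept["pupil_right"].to_numpy(),
            "trial_id": kept["trial_id"].to_numpy(),
        }
    )
    return out, usable


def subject_inclusion(usable_fractions: pd.Series) -> bool:
    """Inclusion rule: exclude a subject when more than 25% of trials have
    less than 50% usable samples.  Both boundaries count as acceptable:
    a trial at exactly 50% usable is usable, and an affected-trial fraction
    of exactly 25% still includes the subject.
    """
    if len(usable_fractions) == 0:
        raise ValueError("need at least one trial")
    bad = (usable_fractions < 0.5).mean()
    return bool(bad <= 0.25)


def trial_durations(recording) -> pd.Series:
    """Per-trial exploration time (ms): last minus first raw timestamp plus
    one sampling interval."""
    ts = recording.samples.groupby("trial_id")["timestamp"]
    dt = np.median(np.diff(recording.samples["timestamp"].to_numpy()[:200]))
    return (ts.max() - ts.min() + dt).rename("duration")


def _segments(times: np.ndarray, dt: float, gap_factor: float = 1.5):
    """Split sample indices into contiguous runs (gaps > gap_factor * dt)."""
    if len(times) == 0:
        return
    breaks = np.flatnonzero(np.diff(times) > gap_factor * dt)
    start = 0
    for b in breaks:
        yield start, b + 1
        start = b + 1
    yield start, len(times)



def _robust_sigma(v: np.ndarray) -> float:
    """Median-based velocity dispersion: sqrt(median(v^2) - median(v)^2)."""
    s2 = np.median(v**2) - np.median(v) ** 2
    return float(np.sqrt(max(s2, 1e-12)))


def detect_fixations(
    samples: pd.DataFrame,
    params: DetectionParams,
    geometry,
) -> pd.DataFrame:
    """Velocity-threshold fixation detection over valid samples.

    ``samples`` is the output of :func:`filter_validity` (possibly many
    trials).  Velocities are computed per contiguous segment within a trial;
    the dispersion estimate pools all samples of the trial.  A sample is
    saccadic when (vx / (lam * sx))^2 + (vy / (lam * sy))^2 > 1.

    Returns a fixation table: trial_id, onset, offset, duration,
    centroid_x, centroid_y, mean_pupil, n_samples.
    """
    dt_ms = geometry.dt_ms
    dt_s = dt_ms / 1000.0
    w = params.velocity_window
    k = w // 2
    cols = [
        "trial_id",
        "onset",
        "offset",
        "duration",
        "centroid_x",
        "centroid_y",
        "mean_pupil",
        "n_samples",
    ]
    if len(samples) == 0:
        return pd.DataFrame(columns=cols)

    t = samples["timestamp"].to_numpy()
    x = samples["x"].to_numpy()
    y = samples["y"].to_numpy()
    p = samples["pupil"].to_numpy()
    trial = samples["trial_id"].to_numpy()
    n = len(t)

    new_seg = np.ones(n, dtype=bool)
    if n > 1:
        new_seg[1:] = (trial[1:] != trial[:-1]) | (np.diff(t) > 1.5 * dt_ms)
    seg = np.cumsum(new_seg) - 1

    # moving-window central-difference velocity, valid only where the whole
    # window lies inside one segment; edges reuse the nearest interior value
    def _velocity(coord):
        # sum of the k samples ahead minus the k samples behind
        v = np.full(n, np.nan)
        csum = np.concatenate(([0.0], np.cumsum(coord)))
        if n > 2 * k:
            ahead = csum[1 + 2 * k :] - csum[1 + k : n + 1 - k]
            behind = csum[k : n - k] - csum[: n - 2 * k]
            interior = (ahead - behind) / (k * (k + 1) * dt_s)
            ok = seg[2 * k :] == seg[: n - 2 * k]
            v[k : n - k][ok] = interior[ok]
        ser = pd.Series(v).groupby(seg)
        return ser.ffill().groupby(seg).bfill().to_numpy()

    vx = _velocity(x)
    vy = _velocity(y)
    # samples with no defined velocity (segments shorter than the window)
    # are treated as stationary
    vx = np.nan_to_num(vx)
    vy = np.nan_to_num(vy)

    vdf = pd.DataFrame({"vx": vx, "vy": vy, "trial": trial})
    med = vdf.groupby("trial").median()
    med2 = (vdf[["vx", "vy"]] ** 2).groupby(trial).median()
    sx = np.sqrt(np.maximum(med2["vx"] - med["vx"] ** 2, 1e-12))
    sy = np.sqrt(np.maximum(med2["vy"] - med["vy"] ** 2, 1e-12))
    sx_full = sx.loc[trial].to_numpy()
    sy_full = sy.loc[trial].to_numpy()
    saccadic = (vx / (params.lam * sx_full)) ** 2 + (
        vy / (params.lam * sy_full)
    ) ** 2 > 1.0

    # trials shorter than the velocity window yield no fixations
    trial_len = pd.Series(np.ones(n)).groupby(trial).transform("size").to_numpy()
    eligible = (~saccadic) & (trial_len >= w)

    # maximal eligible runs within segments
    run_break = np.ones(n, dtype=bool)
    run_break[1:] = new_seg[1:] | (eligible[1:] != eligible[:-1])
    run_id = np.cumsum(run_break) - 1
    starts = np.flatnonzero(run_break)
    stops = np.append(starts[1:], n)
    keep_run = eligible[starts]
    starts, stops = starts[keep_run], stops[keep_run]

    length = stops - starts
    onset = t[starts]
    offset = t[stops - 1]
    dur = offset - onset
    ok = (length >= 2) & (dur >= params.min_fixation_duration)
    starts, stops = starts[ok], stops[ok]
    if len(starts) == 0:
        return pd.DataFrame(columns=cols)

    csx = np.concatenate(([0.0], np.cumsum(x)))
    csy = np.concatenate(([0.0], np.cumsum(y)))
    csp = np.concatenate(([0.0], np.cumsum(p)))
    length = stops - starts
    return pd.DataFrame(
        {
            "trial_id": trial[starts],
            "onset": t[starts],
            "offset": t[stops - 1],
            "duration": t[stops - 1] - t[starts],
            "centroid_x": (csx[stops] - csx[starts]) / length,
            "centroid_y": (csy[stops] - csy[starts]) / length,
            "mean_pupil": (csp[stops] - csp[starts]) / length,
            "n_samples": length,
        }
    )



def compute_gaze_steps(
    samples: pd.DataFrame,
    geometry,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gaze steps: Euclidean displacement between consecutive valid samples.

    Steps never cross trial boundaries or dropout gaps.  Returns
    ``(steps, flips)``:

    * ``steps`` -- one row per step with trial_id, timestamp (of the first
      sample of the pair), origin x0/y0, dx, dy, length_px, length_deg;
    * ``flips`` -- per-trial counts of direction flips on each axis (a flip
      is a sign change between consecutive nonzero deltas).
    """
    dt_ms = geometry.dt_ms
    step_cols = [
        "trial_id",
        "segment",
        "timestamp",
        "x0",
        "y0",
        "dx",
        "dy",
        "length_px",
        "length_deg",
    ]
    trial_index = pd.Index(np.unique(samples["trial_id"].to_numpy()), name="trial_id")
    empty_flips = pd.DataFrame(
        {"trial_id": trial_index, "x_flips": 0, "y_flips": 0}
    ).reset_index(drop=True)
    if len(samples) < 2:
        return pd.DataFrame(columns=step_cols), empty_flips

    t = samples["timestamp"].to_numpy()
    x = samples["x"].to_numpy()
    y = samples["y"].to_numpy()
    trial = samples["trial_id"].to_numpy()
    n = len(t)
    new_seg = np.ones(n, dtype=bool)
    new_seg[1:] = (trial[1:] != trial[:-1]) | (np.diff(t) > 1.5 * dt_ms)
    seg = np.cumsum(new_seg) - 1

    pair = seg[1:] == seg[:-1]  # consecutive samples in the same segment
    i = np.flatnonzero(pair)
    dx = x[i + 1] - x[i]
    dy = y[i + 1] - y[i]
    steps = pd.DataFrame(
        {
            "trial_id": trial[i],
            "segment": seg[i],
            "timestamp": t[i],
            "x0": x[i],
            "y0": y[i],
            "dx": dx,
            "dy": dy,
            "length_px": np.hypot(dx, dy),
            "length_deg": geometry.px_to_deg(dx, dy),
        }
    )
    ev = flip_event_table(steps)
    if len(ev):
        counts = (
            ev.groupby(["trial_id", "axis"]).size().unstack(fill_value=0)
            .reindex(trial_index, fill_value=0)
        )
        flips = pd.DataFrame(
            {
                "trial_id": trial_index,
                "x_flips": counts.get("x", pd.Series(0, index=trial_index)),
                "y_flips": counts.get("y", pd.Series(0, index=trial_index)),
            }
        ).reset_index(drop=True)
    else:
        flips = empty_flips
    return steps, flips


def flip_event_table(steps: pd.DataFrame) -> pd.DataFrame:
    """Direction-flip events over a step table.

    A flip on an axis is a sign change between consecutive nonzero deltas
    of the same trial segment; its timestamp is that of the later step.
    Returns a table with columns trial_id, axis ('x' or 'y'), timestamp.
    """
    out = []
    trial = steps["trial_id"].to_numpy()
    segment = steps["segment"].to_numpy()
    ts = steps["timestamp"].to_numpy()
    for axis, col in (("x", "dx"), ("y", "dy")):
        d = steps[col].to_numpy()
        nz = d != 0
        dnz = d[nz]
        if len(dnz) < 2:
            continue
        tr, sg, tz = trial[nz], segment[nz], ts[nz]
        change = (np.sign(dnz[1:]) != np.sign(dnz[:-1])) & (sg[1:] == sg[:-1])
        out.append(
            pd.DataFrame(
                {"trial_id": tr[1:][change], "axis": axis, "timestamp": tz[1:][change]}
            )
        )
    if not out:
        return pd.DataFrame(columns=["trial_id", "axis", "timestamp"])
    return pd.concat(out, ignore_index=True)


def count_flips(deltas: np.ndarray) -> int:
    """Sign changes between consecutive nonzero deltas on one axis."""
    nz = deltas[deltas != 0]
    if len(nz) < 2:
        return 0
    return int(np.sum(np.sign(nz[1:]) != np.sign(nz[:-1])))


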