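"""Synthetic fixation--saccade gaze simulator.

Generates raw binocular gaze logs with the statistical structure the
downstream analyses assume: alternating fixation epochs (gamma-distributed
durations) and one-sample saccades whose amplitudes follow a two-component
mixture -- a truncated Pareto tail with a per-viewer exponent, and a
lognormal "preferred amplitude" component with a characteristic scale.
Viewers come in two styles:

* ``static``  -- long fixations, long self-paced exploration, step lengths
  dominated by the scale-free Pareto component (low KSD);
* ``dynamic`` -- short frequent fixations, shorter exploration, a balanced
  mixture of scale-free and characteristic-scale saccades (higher KSD),
  larger pupil, stronger attraction toward salient scene regions.

Scene saliency and semantic maps are fabricated as correlated mixtures of
Gaussian blobs; they stand in for model-derived maps and are consumed, not
produced, by the analysis pipeline.

All generators are pure functions of their arguments and a seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gazedyn.config import SessionConfig

# Pareto tail support starts well above fixational jitter (~0.05 deg) so the
# scale-free regime is identifiable by an xmin scan.
SACCADE_XMIN_DEG = 0.3
#: Lognormal "characteristic scale" saccade component (deg).
SHORT_COMPONENT_MEDIAN_DEG = 3.0
SHORT_COMPONENT_SIGMA = 0.5
#: Within-fixation positional jitter, per axis (deg).
FIXATION_JITTER_DEG = 0.05
#: Floor on a fixation epoch (ms); below this the oculomotor system cannot
#: programme the next saccade.
MIN_FIXATION_MS = 80.0

GAZE_COLUMNS = [
    "timestamp",
    "x_left",
    "y_left",
    "x_right",
    "y_right",
    "pupil_left",
    "pupil_right",
    "validity_left",
    "validity_right",
    "trial_id",
]


@dataclass(frozen=True)
class ViewerProfile:
    """Generative parameters of one simulated observer."""

    subject_id: str
    style: str  # {"static", "dynamic"}
    fixation_duration_mean: float  # ms
    fixation_duration_shape: float  # gamma shape (dimensionless)
    tail_exponent: float  # power-law exponent of saccade amplitudes, > 1
    long_step_mixture_weight: float  # P(saccade drawn from the Pareto tail)
    pupil_baseline: float  # mm
    pupil_fixation_coupling: float  # mm/s of diameter change within a fixation
    dropout_rate: float  # per-sample, per-eye invalidation probability
    exploration_time_mean: float  # ms, self-paced trial duration
    saliency_bias: float  # P(saccade aimed at a salient scene location)

    def __post_init__(self) -> None:
        if self.style not in ("static", "dynamic"):
            raise ValueError(f"unknown style {self.style!r}")
        if self.tail_exponent <= 1:
            raise ValueError("tail_exponent must exceed 1")
        if self.fixation_duration_mean <= 0:
            raise ValueError("fixation_duration_mean must be positive")
        for name in ("long_step_mixture_weight", "dropout_rate", "saliency_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def fixation_rate(self) -> float:
        """Implied fixations per second (one saccade sample per fixation)."""
        return 1000.0 / (self.fixation_duration_mean + 1000.0 / 120.0)


#: Style-conditional sampling distributions for profile parameters:
#: (mean, sd, lo, hi) of a clipped normal.
STYLE_PARAMS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "static": {
        "fixation_duration_mean": (420.0, 45.0, 330.0, 560.0),
        "fixation_duration_shape": (6.0, 0.5, 2.5, 9.0),
        "tail_exponent": (2.0, 0.08, 1.7, 2.3),
        "long_step_mixture_weight": (0.85, 0.05, 0.70, 0.97),
        "pupil_baseline": (3.3, 0.15, 2.8, 3.8),
        "pupil_fixation_coupling": (-0.35, 0.05, -0.55, -0.15),
        "dropout_rate": (0.02, 0.005, 0.0, 0.06),
        "exploration_time_mean": (6500.0, 700.0, 5200.0, 9500.0),
        "saliency_bias": (0.20, 0.05, 0.05, 0.40),
    },
    "dynamic": {
        "fixation_duration_mean": (230.0, 25.0, 170.0, 300.0),
        "fixation_duration_shape": (5.0, 0.5, 2.5, 9.0),
        "tail_exponent": (2.35, 0.12, 2.0, 2.8),
        "long_step_mixture_weight": (0.45, 0.07, 0.25, 0.65),
        "pupil_baseline": (3.9, 0.15, 3.4, 4.4),
        "pupil_fixation_coupling": (-0.20, 0.05, -0.45, -0.05),
        "dropout_rate": (0.02, 0.005, 0.0, 0.06),
        "exploration_time_mean": (3800.0, 500.0, 2400.0, 5100.0),
        "saliency_bias": (0.45, 0.07, 0.25, 0.65),
    },
}


def _clipped_normal(rng, mean, sd, lo, hi, size=None):
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def generate_cohort(n_static: int, n_dynamic: int, seed: int) -> list[ViewerProfile]:
    """Draw a cohort of viewer profiles from the style-specific distributions.

    Clipping bounds guarantee that every static profile has strictly longer
    mean fixation duration and exploration time than every dynamic one.
    """
    if n_static < 0 or n_dynamic < 0 or n_static + n_dynamic < 2:
        raise ValueError("need at least two profiles and nonnegative counts")
    rng = np.random.default_rng(seed)
    profiles: list[ViewerProfile] = []
    styles = ["static"] * n_static + ["dynamic"] * n_dynamic
    for i, style in enumerate(styles):
        params = {
            name: float(_clipped_normal(rng, *spec))
            for name, spec in STYLE_PARAMS[style].items()
        }
        profiles.append(
            ViewerProfile(subject_id=f"S{i + 1:03d}", style=style, **params)
        )
    return profiles


def cohort_table(profiles: list[ViewerProfile]) -> pd.DataFrame:
    """Cohort as a tidy table (one row per viewer), suitable for CSV."""
    return pd.DataFrame([dataclasses.asdict(p) for p in profiles])


# ---------------------------------------------------------------------------
# Scenes


@dataclass
class SyntheticScene:
    """Fabricated scene with correlated saliency and semantic maps.

    Both maps are nonnegative and normalised to unit mass.
    """

    scene_id: str
    category: str
    saliency_map: np.ndarray  # height x width, sums to 1
    semantic_map: np.ndarray  # height x width, sums to 1
    _target_pool: np.ndarray | None = field(default=None, repr=False)

    def target_pool(self, size: int = 1024) -> np.ndarray:
        """Pool of pixel indices presampled from the combined saliency +
        semantic map (inverse-CDF, seeded by the scene id), cached so that
        saccade targeting never rebuilds the pixel CDF."""
        if self._target_pool is None:
            combined = (self.saliency_map + self.semantic_map).ravel()
            cdf = np.cumsum(combined.astype(np.float64))
            cdf /= cdf[-1]
            pool_seed = int.from_bytes(
                self.scene_id.encode()[-4:].rjust(4, b"\0"), "big"
            )
            pool_rng = np.random.default_rng(pool_seed)
            self._target_pool = np.searchsorted(
                cdf, pool_rng.random(size)
            ).astype(np.int64)
        return self._target_pool


def _blob_mixture(rng, height, width, n_lo=2, n_hi=8) -> np.ndarray:
    """Unnormalised mixture of Gaussian blobs on the pixel grid (float32)."""
    n_blobs = int(rng.integers(n_lo, n_hi + 1))
    yy = np.arange(height, dtype=np.float32)
    xx = np.arange(width, dtype=np.float32)
    out = np.zeros((height, width), dtype=np.float32)
    for _ in range(n_blobs):
        cy = rng.uniform(0.1 * height, 0.9 * height)
        cx = rng.uniform(0.1 * width, 0.9 * width)
        sy = rng.uniform(0.04, 0.12) * height
        sx = rng.uniform(0.04, 0.12) * width
        w = rng.uniform(0.5, 1.5)
        ey = np.exp(-0.5 * ((yy - cy) / sy) ** 2)
        ex = np.exp(-0.5 * ((xx - cx) / sx) ** 2)
        out += w * np.outer(ey, ex)  # separable Gaussian
    return out


def generate_scene_maps(
    n_scenes: int,
    config: SessionConfig,
    seed: int,
    map_correlation: float = 0.5,
) -> list[SyntheticScene]:
    """Fabricate ``n_scenes`` scenes, balanced over the category list (+-1).

    The semantic map mixes a fraction ``map_correlation`` of the saliency
    field with independent blobs, so the two maps are correlated but not
    identical.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    rng = np.random.default_rng(seed)
    scenes = []
    cats = config.image_categories
    for i in range(n_scenes):
        sal = _blob_mixture(rng, config.map_height, config.map_width)
        own = _blob_mixture(rng, config.map_height, config.map_width)
        sal_n = sal / sal.sum()
        sem_raw = map_correlation * sal_n + (1 - map_correlation) * (own / own.sum())
        scenes.append(
            SyntheticScene(
                scene_id=f"img{i + 1:03d}",
                category=cats[i % len(cats)],
                saliency_map=sal_n.astype(np.float32),
                semantic_map=(sem_raw / sem_raw.sum()).astype(np.float32),
            )
        )
    return scenes


def save_scene_maps(scenes: list[SyntheticScene], directory) -> None:
    """Write each scene's maps as row-major float CSV (height x width)."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = []
    for s in scenes:
        np.savetxt(directory / f"{s.scene_id}_saliency.csv", s.saliency_map,
                   delimiter=",")
        np.savetxt(directory / f"{s.scene_id}_semantic.csv", s.semantic_map,
                   delimiter=",")
        index.append({"scene_id": s.scene_id, "category": s.category})
    pd.DataFrame(index).to_csv(directory / "scenes.csv", index=False)


def load_scene_maps(directory) -> list[SyntheticScene]:
    """Inverse of :func:`save_scene_maps`."""
    from pathlib import Path

    directory = Path(directory)
    index = pd.read_csv(directory / "scenes.csv")
    scenes = []
    for _, row in index.iterrows():
        sal = np.loadtxt(directory / f"{row.scene_id}_saliency.csv", delimiter=",")
        sem = np.loadtxt(directory / f"{row.scene_id}_semantic.csv", delimiter=",")
        scenes.append(
            SyntheticScene(
                scene_id=row.scene_id,
                category=row.category,
                saliency_map=sal.astype(np.float32),
                semantic_map=sem.astype(np.float32),
            )
        )
    return scenes


# ---------------------------------------------------------------------------
# Recordings


@dataclass
class RawGazeRecording:
    """Time-ordered binocular samples for one subject and condition."""

    subject_id: str
    condition: str  # {"image_viewing", "blank_screen"}
    samples: pd.DataFrame  # GAZE_COLUMNS (+ scene_id for image viewing)

    def to_tsv(self, path) -> None:
        self.samples.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, subject_id: str, condition: str) -> "RawGazeRecording":
        df = pd.read_csv(path, sep="\t")
        missing = set(GAZE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"gaze TSV missing columns: {sorted(missing)}")
        return cls(subject_id=subject_id, condition=condition, samples=df)


def _draw_amplitude(rng, profile: ViewerProfile, cap_deg: float) -> float:
    """Saccade amplitude (deg) from the mixture, truncated at ``cap_deg``."""
    if rng.random() < profile.long_step_mixture_weight:
        a = profile.tail_exponent
        xm = SACCADE_XMIN_DEG
        cap = max(cap_deg, xm * 1.01)
        # inverse-CDF draw from a Pareto truncated at cap
        u = rng.random()
        frac = 1.0 - (xm / cap) ** (a - 1.0)
        return xm * (1.0 - u * frac) ** (-1.0 / (a - 1.0))
    amp = math.exp(
        math.log(SHORT_COMPONENT_MEDIAN_DEG)
        + SHORT_COMPONENT_SIGMA * rng.standard_normal()
    )
    return min(amp, cap_deg)


def _simulate_trial_anchors(
    rng,
    profile: ViewerProfile,
    config: SessionConfig,
    duration_ms: float,
    scene: SyntheticScene | None,
):
    """Fixation anchors and per-fixation sample counts for one trial.

    Returns (anchor_x, anchor_y, n_samples_per_fixation).
    """
    dt = config.dt_ms
    n_total = max(int(round(duration_ms / dt)), 1)
    w, h = config.map_width, config.map_height
    ppx, ppy = config.px_per_deg_x, config.px_per_deg_y

    scale = profile.fixation_duration_mean / profile.fixation_duration_shape

    ax, ay, counts = [], [], []
    # first fixation lands near the centre (central fixation bias)
    x = np.clip(w / 2 + rng.normal(0, ppx), 1.0, w - 1.0)
    y = np.clip(h / 2 + rng.normal(0, ppy), 1.0, h - 1.0)
    remaining = n_total
    pool = scene.target_pool() if scene is not None else None
    while remaining > 0:
        dur = max(rng.gamma(profile.fixation_duration_shape, scale), MIN_FIXATION_MS)
        n_fix = min(max(int(round(dur / dt)), 1), remaining)
        ax.append(x)
        ay.append(y)
        counts.append(n_fix)
        remaining -= n_fix
        if remaining <= 0:
            break
        # saccade: amplitude from the mixture, direction toward a salient
        # target with probability saliency_bias, otherwise isotropic
        cap = math.hypot(max(x, w - x) / ppx, max(y, h - y) / ppy)
        amp = _draw_amplitude(rng, profile, cap)
        if pool is not None and rng.random() < profile.saliency_bias:
            pix = int(pool[int(rng.integers(len(pool)))])
            ty, tx = divmod(pix, w)
            dxp, dyp = tx - x, ty - y
            norm = math.hypot(dxp / ppx, dyp / ppy)
            if norm < 1e-9:
                dxp, dyp, norm = 1.0, 0.0, 1.0 / ppx
            # move toward the target but never past the screen edge
            reach = min(amp / norm, 1.0)
            nx, ny = x + dxp * reach, y + dyp * reach
            nx = min(max(nx, 1.0), w - 1.0)
            ny = min(max(ny, 1.0), h - 1.0)
        else:
            # isotropic: rejection-sample a direction keeping the endpoint
            # on screen, preserving the drawn amplitude where possible
            for _ in range(40):
                theta = rng.uniform(0.0, 2.0 * math.pi)
                nx = x + amp * math.cos(theta) * ppx
                ny = y + amp * math.sin(theta) * ppy
                if 1.0 <= nx <= w - 1.0 and 1.0 <= ny <= h - 1.0:
                    break
            else:
                nx = min(max(nx, 1.0), w - 1.0)
                ny = min(max(ny, 1.0), h - 1.0)
        x, y = nx, ny
    return np.array(ax), np.array(ay), np.array(counts, dtype=int)


def _expand_trial(
    rng,
    profile: ViewerProfile,
    config: SessionConfig,
    t0: float,
    trial_id: int,
    anchors,
    carry_pupil: float | None = None,
) -> dict[str, np.ndarray]:
    """Expand fixation anchors into per-sample arrays for one trial."""
    ax, ay, counts = anchors
    n = int(counts.sum())
    dt = config.dt_ms
    jit_x = config.deg_to_px_x(FIXATION_JITTER_DEG)
    jit_y = config.deg_to_px_y(FIXATION_JITTER_DEG)

    fix_idx = np.repeat(np.arange(len(counts)), counts)
    x = ax[fix_idx] + rng.normal(0, jit_x, n)
    y = ay[fix_idx] + rng.normal(0, jit_y, n)
    np.clip(x, 0.0, config.map_width - 1e-6, out=x)
    np.clip(y, 0.0, config.map_height - 1e-6, out=y)

    # elapsed time within the current fixation, for the pupil decline
    starts = np.repeat(np.cumsum(counts) - counts, counts)
    within = (np.arange(n) - starts) * dt / 1000.0  # s
    base = carry_pupil if carry_pupil is not None else profile.pupil_baseline
    pupil = base + profile.pupil_fixation_coupling * within
    pupil = pupil + rng.normal(0, 0.03, n)

    eye_noise = 0.3  # px, independent per-eye measurement noise
    out = {
        "timestamp": t0 + np.arange(n) * dt,
        "x_left": x + rng.normal(0, eye_noise, n),
        "y_left": y + rng.normal(0, eye_noise, n),
        "x_right": x + rng.normal(0, eye_noise, n),
        "y_right": y + rng.normal(0, eye_noise, n),
        "pupil_left": pupil + rng.normal(0, 0.02, n),
        "pupil_right": pupil + rng.normal(0, 0.02, n),
        "validity_left": np.where(rng.random(n) < profile.dropout_rate, 4, 0),
        "validity_right": np.where(rng.random(n) < profile.dropout_rate, 4, 0),
        "trial_id": np.full(n, trial_id),
    }
    return out


def _truncnorm(rng, mean, sd, lo, hi):
    """Normal draw restricted to [lo, hi] (rejection with clip fallback)."""
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v
    return float(np.clip(v, lo, hi))


def simulate_image_viewing(
    profile: ViewerProfile,
    scenes: list[SyntheticScene],
    config: SessionConfig,
    seed: int,
) -> RawGazeRecording:
    """Simulate one subject's self-paced image-viewing session.

    One trial per scene; trial durations are truncated normals centred on
    the viewer's exploration-time mean, bounded by the session's
    [trial_min, trial_max] window.
    """
    if not scenes:
        raise ValueError("need at least one scene")
    rng = np.random.default_rng(seed)
    chunks = []
    t0 = 0.0
    sd = 0.18 * profile.exploration_time_mean
    for trial_id, scene in enumerate(scenes):
        duration = _truncnorm(
            rng, profile.exploration_time_mean, sd, config.trial_min, config.trial_max
        )
        anchors = _simulate_trial_anchors(rng, profile, config, duration, scene)
        chunk = _expand_trial(rng, profile, config, t0, trial_id, anchors)
        chunk["scene_id"] = np.full(len(chunk["timestamp"]), scene.scene_id)
        chunks.append(chunk)
        t0 = chunk["timestamp"][-1] + config.dt_ms + config.iti
    samples = pd.DataFrame(
        {col: np.concatenate([c[col] for c in chunks]) for col in chunks[0]}
    )
    return RawGazeRecording(profile.subject_id, "image_viewing", samples)


def neutral_profile_params() -> dict[str, float]:
    """Midpoint of the two style-default means, used as the carry-over
    attractor for blank-screen viewing."""
    out = {}
    for name in STYLE_PARAMS["static"]:
        out[name] = 0.5 * (
            STYLE_PARAMS["static"][name][0] + STYLE_PARAMS["dynamic"][name][0]
        )
    return out


def simulate_blank_screen(
    profile: ViewerProfile,
    config: SessionConfig,
    seed: int,
    carry_over: float = 0.8,
    steady_fixation_prob: float = 0.1,
) -> RawGazeRecording:
    """Simulate 30 s (default) of blank-screen viewing.

    Style parameters are attenuated toward the population midpoint by
    ``1 - carry_over``; at ``carry_over = 0`` every viewer behaves like the
    neutral profile and blank-screen statistics carry no style information.
    With probability ``steady_fixation_prob`` the viewer simply holds a
    central fixation for the entire period, emulating observers who do not
    spontaneously explore an empty screen.
    """
    if config.blank_duration <= 0:
        raise ValueError("blank_duration must be positive")
    if not 0.0 <= carry_over <= 1.0:
        raise ValueError("carry_over must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    duration_ms = config.blank_duration * 1000.0

    neutral = neutral_profile_params()
    blend = {
        name: carry_over * getattr(profile, name) + (1 - carry_over) * neutral[name]
        for name in neutral
    }
    blend["saliency_bias"] = 0.0  # nothing to look at
    blend["dropout_rate"] = min(max(blend["dropout_rate"], 0.0), 1.0)
    eff = ViewerProfile(subject_id=profile.subject_id, style=profile.style, **blend)

    if rng.random() < steady_fixation_prob:
        # a single unbroken central fixation for the whole period: its
        # dispersion statistics are undefined downstream, which is what
        # excludes steady fixators from blank-screen feature analyses
        n = max(int(round(duration_ms / config.dt_ms)), 1)
        anchors = (
            np.array([config.map_width / 2.0]),
            np.array([config.map_height / 2.0]),
            np.array([n]),
        )
        eff = dataclasses.replace(eff, dropout_rate=0.0)
    else:
        anchors = _simulate_trial_anchors(rng, eff, config, duration_ms, scene=None)
    chunk = _expand_trial(rng, eff, config, 0.0, 0, anchors)
    return RawGazeRecording(profile.subject_id, "blank_screen", pd.DataFrame(chunk))


# ---------------------------------------------------------------------------
# Covariates


def generate_covariates(
    profiles: list[ViewerProfile],
    seed: int,
    age_effect: float = 1.2,
    stroop_effect: float = -4.0,
) -> pd.DataFrame:
    """Fabricate a per-subject demographic / cognitive / personality table.

    Age and Stroop interference carry a real association with viewing style
    (static viewers older and less impulsive, scaled by the effect
    arguments); the remaining scores are style-independent noise.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in profiles:
        s = 1.0 if p.style == "static" else -1.0
        age = float(np.clip(np.round(23.5 + age_effect * s + rng.normal(0, 2.2)), 19, 34))
        rows.append(
            {
                "subject_id": p.subject_id,
                "age": age,
                "sex": int(rng.random() < 0.5),
                "education": float(np.clip(np.round(rng.normal(16, 1.5)), 12, 21)),
                "digit_span_fwd": float(np.clip(np.round(rng.normal(6, 1)), 3, 9)),
                "digit_span_bwd": float(np.clip(np.round(rng.normal(5, 1)), 2, 8)),
                "stroop": 50.0 + stroop_effect * s + rng.normal(0, 8.0),
                "rocf_recall": float(np.clip(rng.normal(22, 4), 8, 36)),
                "bis_bas": rng.normal(50, 10),
                "neo_extraversion": rng.normal(50, 10),
                "neo_agreeableness": rng.normal(50, 10),
                "neo_conscientiousness": rng.normal(50, 10),
                "neo_neuroticism": rng.normal(50, 10),
                "neo_openness": rng.normal(50, 10),
            }
        )
    return pd.DataFrame(rows)
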