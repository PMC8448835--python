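import numpy as np
import pandas as pd
import pytest

from gazedyn import simulate
from gazedyn.config import SessionConfig
from gazedyn.preprocess import (
    DetectionParams,
    compute_gaze_steps,
    detect_fixations,
    filter_validity,
)


@pytest.fixture(scope="session")
def geometry() -> SessionConfig:
    return SessionConfig()


@pytest.fixture(scope="session")
def small_scenes(geometry):
    return simulate.generate_scene_maps(6, geometry, seed=11)


@pytest.fixture(scope="session")
def cohort():
    return simulate.generate_cohort(3, 3, seed=1234)


@pytest.fixture(scope="session")
def one_subject(geometry, small_scenes, cohort):
    """A fully preprocessed static viewer over six scenes (shared across
    tests to keep the suite fast)."""
    profile = cohort[0]
    rec = simulate.simulate_image_viewing(profile, small_scenes, geometry, seed=77)
    samples, usable = filter_validity(rec)
    fixations = detect_fixations(samples, DetectionParams(), geometry)
    steps, flips = compute_gaze_steps(samples, geometry)
    return {
        "profile": profile,
        "recording": rec,
        "samples": samples,
        "usable": usable,
        "fixations": fixations,
        "steps": steps,
        "flips": flips,
    }


def make_recording(samples_df: pd.DataFrame, subject="Sx", condition="image_viewing"):
    return simulate.RawGazeRecording(subject, condition, samples_df)


def synthetic_trace(
    positions: np.ndarray,
    dt: float = 1000.0 / 120.0,
    trial_id: int = 0,
    pupil: float = 3.5,
) -> pd.DataFrame:
    """Valid-sample frame (filter_validity output format) from an (n, 2)
    array of gaze positions."""
    n = len(positions)
    return pd.DataFrame(
        {
            "timestamp": np.arange(n) * dt,
            "x": positions[:, 0],
            "y": positions[:, 1],
            "pupil": np.full(n, pupil),
            "pupil_left": np.full(n, pupil),
            "pupil_right": np.full(n, pupil),
            "trial_id": np.full(n, trial_id),
        }
    )
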