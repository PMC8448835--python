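"""Shared settings for the analysis drivers: the study configuration, the
seed, and where results go.  Import, don't run."""

from pathlib import Path

from gazedyn.pipeline import StudyConfig

SEED = 1234  # fixed for every seed-based analysis
RESULTS = Path(__file__).resolve().parent.parent / "results"
CONFIG = StudyConfig()


def ensure_results() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
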