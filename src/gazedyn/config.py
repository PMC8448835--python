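"""Session geometry and acquisition parameters.

The default configuration mirrors a tabletop eye-tracking setup: a 120 Hz
binocular tracker, stimuli subtending 27.1 deg x 20.5 deg rendered on a
512 x 683 (height x width) pixel map, self-paced image trials between 2 and
10 s with a 1.5 s inter-trial interval, and a 30 s blank-screen baseline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

#: Level-1 scene taxonomy crossed with human presence.
DEFAULT_CATEGORIES: tuple[str, ...] = (
    "indoor_humans",
    "indoor_no_humans",
    "outdoor_natural_humans",
    "outdoor_natural_no_humans",
    "outdoor_manmade_humans",
    "outdoor_manmade_no_humans",
)


@dataclass(frozen=True)
class SessionConfig:
    """Acquisition geometry and trial-structure parameters.

    Coordinates use the map-pixel frame: origin at the top-left corner,
    x increasing rightward, y increasing downward.  Degrees of visual angle
    convert to pixels axis-wise through the stimulus extent
    (``map_width / image_deg_width`` horizontally, similarly vertically).
    """

    sampling_rate: float = 120.0  # Hz
    n_images: int = 185
    trial_min: float = 2000.0  # ms
    trial_max: float = 10000.0  # ms
    iti: float = 1500.0  # ms
    blank_duration: float = 30.0  # s
    image_categories: tuple[str, ...] = DEFAULT_CATEGORIES
    map_height: int = 512  # px
    map_width: int = 683  # px
    image_deg_width: float = 27.1  # deg
    image_deg_height: float = 20.5  # deg
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.trial_min > self.trial_max:
            raise ValueError("trial_min must not exceed trial_max")
        if self.map_height <= 0 or self.map_width <= 0:
            raise ValueError("map dimensions must be positive")

    # -- geometry -----------------------------------------------------------

    @property
    def dt_ms(self) -> float:
        """Inter-sample interval in milliseconds (8.333 ms at 120 Hz)."""
        return 1000.0 / self.sampling_rate

    @property
    def px_per_deg_x(self) -> float:
        return self.map_width / self.image_deg_width

    @property
    def px_per_deg_y(self) -> float:
        return self.map_height / self.image_deg_height

    def px_to_deg(self, dx_px, dy_px):
        """Convert axis-wise pixel displacements to a Euclidean angle (deg)."""
        return np.hypot(
            np.asarray(dx_px) / self.px_per_deg_x,
            np.asarray(dy_px) / self.px_per_deg_y,
        )

    def deg_to_px_x(self, deg: float) -> float:
        return deg * self.px_per_deg_x

    def deg_to_px_y(self, deg: float) -> float:
        return deg * self.px_per_deg_y

    @property
    def max_amplitude_deg(self) -> float:
        """Image diagonal in degrees; upper bound for any on-screen saccade."""
        return float(np.hypot(self.image_deg_width, self.image_deg_height))

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_categories"] = list(self.image_categories)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        if "image_categories" in d:
            d["image_categories"] = tuple(d["image_categories"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SessionConfig keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def grid_edges(size: int, n_cells: int) -> np.ndarray:
    """Integer cell boundaries splitting ``size`` pixels into ``n_cells``
    nearly equal runs (remainder pixels land in the later cells)."""
    if n_cells > size:
        raise ValueError("grid larger than map")
    return np.floor(np.arange(n_cells + 1) * size / n_cells).astype(int)


def cell_index(coord: np.ndarray, size: int, n_cells: int) -> np.ndarray:
    """Cell index of pixel coordinates under :func:`grid_edges` boundaries.

    Bounds are half-open with the last cell closed, so ``coord == size``
    still maps to the final cell.
    """
    edges = grid_edges(size, n_cells)
    idx = np.searchsorted(edges, np.asarray(coord), side="right") - 1
    return np.clip(idx, 0, n_cells - 1)
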