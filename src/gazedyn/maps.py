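"""Attention maps: gaze heatmaps, Shannon entropy, fixation density maps,
saliency/semantic sampling at fixations, and grid subsampling.

All maps live on the image-pixel grid (height x width) and, once
normalised, sum to one.  Smoothing uses an isotropic-in-degrees Gaussian
whose full width at half maximum defaults to 2 deg (roughly the foveal
window); in pixels the kernel is anisotropic because the horizontal and
vertical pixels-per-degree differ slightly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from gazedyn.config import grid_edges

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PixelMap:
    """Nonnegative real-valued map over image space."""

    values: np.ndarray
    kind: str  # {gaze_heatmap, fdm, saliency, semantic, ksd_grid}
    smoothed: bool = False
    fwhm_deg: float | None = None

    @property
    def normalized(self) -> bool:
        return bool(abs(float(self.values.sum()) - 1.0) < 1e-6)

    def normalize(self) -> "PixelMap":
        total = float(self.values.sum())
        if total <= 0:
            raise ValueError("cannot normalise an empty map")
        return PixelMap(self.values / total, self.kind, self.smoothed, self.fwhm_deg)


def _clip_coords(xs, ys, geometry):
    """Clip pixel coordinates to the map; returns integer pixel indices."""
    ix = np.clip(np.floor(xs).astype(int), 0, geometry.map_width - 1)
    iy = np.clip(np.floor(ys).astype(int), 0, geometry.map_height - 1)
    return ix, iy


def gaze_heatmap(samples, geometry) -> PixelMap:
    """Per-pixel visit counts of gaze samples, normalised to unit mass.

    Samples outside the image are clipped to the nearest edge pixel.
    """
    if len(samples) == 0:
        raise ValueError("no valid samples")
    ix, iy = _clip_coords(
        np.asarray(samples["x"]), np.asarray(samples["y"]), geometry
    )
    values = np.zeros((geometry.map_height, geometry.map_width))
    np.add.at(values, (iy, ix), 1.0)
    return PixelMap(values / values.sum(), kind="gaze_heatmap")


def shannon_entropy(pixel_map: PixelMap) -> float:
    """Shannon entropy (bits) of a normalised map: -sum p log2 p over p>0."""
    if not pixel_map.normalized:
        raise ValueError("map must be normalised to unit mass")
    p = pixel_map.values[pixel_map.values > 0]
    return float(-np.sum(p * np.log2(p)))


def visit_count_entropy(xs, ys, geometry) -> float:
    """Entropy of the gaze heatmap computed from sparse visit counts.

    Equivalent to ``shannon_entropy(gaze_heatmap(...))`` without building
    the dense pixel map; used where many per-trial heatmaps are needed.
    """
    ix, iy = _clip_coords(np.asarray(xs), np.asarray(ys), geometry)
    flat = iy.astype(np.int64) * geometry.map_width + ix
    _, counts = np.unique(flat, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def smooth_map(pixel_map: PixelMap, fwhm_deg: float, geometry) -> PixelMap:
    """Gaussian smoothing (zero-padded) with renormalisation.

    Mass is conserved exactly by renormalising after the zero-padded
    convolution; the output is nonnegative everywhere.
    """
    sigma_y = fwhm_deg * FWHM_TO_SIGMA * geometry.px_per_deg_y
    sigma_x = fwhm_deg * FWHM_TO_SIGMA * geometry.px_per_deg_x
    sm = ndimage.gaussian_filter(
        pixel_map.values.astype(float), sigma=(sigma_y, sigma_x), mode="constant"
    )
    sm = np.maximum(sm, 0.0)
    if pixel_map.normalized:
        sm /= sm.sum()
    return PixelMap(sm, pixel_map.kind, smoothed=True, fwhm_deg=fwhm_deg)


def fixation_density_map(
    fixations,
    geometry,
    fwhm_deg: float = 2.0,
) -> PixelMap:
    """FDM: unit mass per fixation centroid, smoothed with a Gaussian of
    FWHM ``fwhm_deg`` (default 2 deg) and renormalised to unit mass."""
    if len(fixations) == 0:
        raise ValueError("no fixations")
    ix, iy = _clip_coords(
        np.asarray(fixations["centroid_x"]),
        np.asarray(fixations["centroid_y"]),
        geometry,
    )
    values = np.zeros((geometry.map_height, geometry.map_width))
    np.add.at(values, (iy, ix), 1.0)
    raw = PixelMap(values / values.sum(), kind="fdm")
    return smooth_map(raw, fwhm_deg, geometry)


def _disc_kernel(radius_deg: float, geometry) -> np.ndarray:
    """Binary disc of radius ``radius_deg`` on the pixel grid (elliptic in
    pixels), normalised to unit sum."""
    ry = max(int(np.ceil(radius_deg * geometry.px_per_deg_y)), 1)
    rx = max(int(np.ceil(radius_deg * geometry.px_per_deg_x)), 1)
    yy = np.arange(-ry, ry + 1)[:, None] / geometry.px_per_deg_y
    xx = np.arange(-rx, rx + 1)[None, :] / geometry.px_per_deg_x
    disc = (yy**2 + xx**2) <= radius_deg**2
    k = disc.astype(float)
    return k / k.sum()


def _disc_denominator(shape: tuple[int, int], kernel: np.ndarray) -> np.ndarray:
    from scipy.signal import fftconvolve

    return np.maximum(fftconvolve(np.ones(shape), kernel, mode="same"), 1e-12)


def disc_mean_map(pixel_map: PixelMap, radius_deg: float, geometry) -> PixelMap:
    """Map of local disc means: value at p = mean of the input within a
    disc of ``radius_deg`` around p (edge discs renormalised to the
    in-bounds area)."""
    from scipy.signal import fftconvolve

    k = _disc_kernel(radius_deg, geometry)
    num = fftconvolve(pixel_map.values.astype(float), k, mode="same")
    den = _disc_denominator(pixel_map.values.shape, k)
    return PixelMap(
        np.maximum(num, 0.0) / den,
        pixel_map.kind,
        pixel_map.smoothed,
        pixel_map.fwhm_deg,
    )


def sample_map_at_fixations(
    pixel_map: PixelMap,
    fixations,
    geometry,
    mode: str = "disc",
    radius_deg: float = 1.0,
) -> float:
    """Mean local map value over fixations.

    ``mode="disc"`` (default) averages the map within a 1 deg-radius disc
    around each fixation centroid; ``mode="point"`` reads the single pixel
    under the centroid.  Fixations off the map are clipped to the edge.
    """
    if len(fixations) == 0:
        raise ValueError("no fixations")
    if mode == "disc":
        local = disc_mean_map(pixel_map, radius_deg, geometry)
        values = local.values
    elif mode == "point":
        values = pixel_map.values
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ix, iy = _clip_coords(
        np.asarray(fixations["centroid_x"]),
        np.asarray(fixations["centroid_y"]),
        geometry,
    )
    return float(values[iy, ix].mean())


def subsample_map(pixel_map: PixelMap, grid_shape: tuple[int, int] = (10, 10)) -> PixelMap:
    """Reduce a map to a coarse grid; each cell is the mean of the pixels
    it covers (cell bounds shared with the spatial-KSD grid).  Normalised
    inputs are renormalised so the coarse map again sums to one."""
    h, w = pixel_map.values.shape
    n_rows, n_cols = grid_shape
    if n_rows > h or n_cols > w:
        raise ValueError("grid larger than map")
    re = grid_edges(h, n_rows)
    ce = grid_edges(w, n_cols)
    out = np.empty((n_rows, n_cols))
    for r in range(n_rows):
        block = pixel_map.values[re[r] : re[r + 1]]
        for c in range(n_cols):
            out[r, c] = block[:, ce[c] : ce[c + 1]].mean()
    was_normalized = pixel_map.normalized
    pm = PixelMap(out, pixel_map.kind, pixel_map.smoothed, pixel_map.fwhm_deg)
    return pm.normalize() if was_normalized else pm
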