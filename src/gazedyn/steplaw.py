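"""Power-law fitting of gaze-step lengths and the Kolmogorov--Smirnov
distance (KSD).

A subject's step lengths x >= xmin are modelled as a continuous power law
p(x) ~ x^(-alpha).  The exponent is the maximum-likelihood estimate
alpha = 1 + n / sum(ln(x_i / xmin)); the lower cutoff xmin is chosen by
scanning candidate cutoffs and minimising the KS distance between the tail
empirical CDF and the fitted law (the standard Clauset-style recipe), with
an option to fix xmin instead.  KSD is that supremum distance:

    ksd = sup_{x >= xmin} | ECDF_tail(x) - (1 - (x / xmin)^(1 - alpha)) |

Lower KSD means the empirical distribution is closer to a power law.
Zero-length steps are excluded from fitting (the law has support x > 0)
but are retained upstream in step counts and features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gazedyn.config import cell_index

#: Minimum tail observations for a fit; anything smaller is missing-coded.
DEFAULT_N_MIN = 50


class DegenerateInputError(ValueError):
    """Raised when a sample cannot support a power-law fit."""


@dataclass(frozen=True)
class PowerLawFit:
    alpha: float  # exponent, > 1
    xmin: float  # lower cutoff, same units as the data
    ksd: float  # KS distance in [0, 1]
    n_tail: int  # observations >= xmin


def _tail_ksd(sorted_tail: np.ndarray, alpha: float, xmin: float) -> float:
    """Exact sup-distance between the tail ECDF and the fitted CDF."""
    n = len(sorted_tail)
    cdf = 1.0 - (sorted_tail / xmin) ** (1.0 - alpha)
    hi = np.arange(1, n + 1) / n
    lo = np.arange(0, n) / n
    return float(np.max(np.maximum(np.abs(hi - cdf), np.abs(cdf - lo))))


def _mle_alpha(tail: np.ndarray, xmin: float) -> float:
    return 1.0 + len(tail) / float(np.sum(np.log(tail / xmin)))


def fit_power_law(
    lengths,
    xmin: float | str | None = None,
    n_min: int = DEFAULT_N_MIN,
    n_candidates: int = 100,
    tail_fraction: float = 0.005,
) -> PowerLawFit:
    """Fit a continuous power law to positive step lengths.

    ``xmin=None`` scans candidate cutoffs (at most ``n_candidates``,
    quantile-spaced over the unique values) and keeps the one minimising
    the tail KS distance; ``xmin="min"`` fixes the cutoff at the smallest
    positive observation; a float fixes it explicitly.

    The scan only admits cutoffs keeping at least ``n_min`` observations
    and at least ``tail_fraction`` of the positive sample in the tail, so
    large samples cannot be "fitted" on a vanishing sliver of extreme
    values.
    """
    x = np.asarray(lengths, dtype=float)
    x = x[x > 0]
    if len(x) < n_min:
        raise DegenerateInputError(
            f"need at least {n_min} positive values, got {len(x)}"
        )
    x = np.sort(x)
    if x[0] == x[-1]:
        raise DegenerateInputError("all values identical")
    min_tail = max(n_min, int(np.ceil(tail_fraction * len(x))))

    if isinstance(xmin, str):
        if xmin != "min":
            raise ValueError(f"unknown xmin policy {xmin!r}")
        candidates = np.array([x[0]])
    elif xmin is not None:
        candidates = np.array([float(xmin)])
    else:
        uniq = np.unique(x)
        # candidates must leave a substantial tail
        uniq = uniq[uniq <= x[-min_tail]]
        if len(uniq) == 0:
            raise DegenerateInputError("no candidate xmin leaves enough tail")
        if len(uniq) > n_candidates:
            idx = np.unique(
                np.linspace(0, len(uniq) - 1, n_candidates).round().astype(int)
            )
            uniq = uniq[idx]
        candidates = uniq

    best: PowerLawFit | None = None
    for xm in candidates:
        tail = x[x >= xm]
        if len(tail) < max(n_min, 2) or tail[0] == tail[-1]:
            continue
        alpha = _mle_alpha(tail, xm)
        if not np.isfinite(alpha) or alpha <= 1.0:
            continue
        d = _tail_ksd(tail, alpha, xm)
        if best is None or d < best.ksd:
            best = PowerLawFit(alpha=alpha, xmin=float(xm), ksd=d, n_tail=len(tail))
    if best is None:
        raise DegenerateInputError("no admissible power-law fit")
    return best


def compute_ksd(lengths, fit: PowerLawFit) -> float:
    """KS distance of ``lengths`` (restricted to the fit's tail) from the
    fitted power law; equals an exhaustive ECDF-gap scan."""
    x = np.asarray(lengths, dtype=float)
    tail = np.sort(x[x >= fit.xmin])
    if len(tail) == 0:
        raise DegenerateInputError("no observations above xmin")
    return _tail_ksd(tail, fit.alpha, fit.xmin)


def ksd_threshold_curve(
    lengths,
    thresholds: list[float],
    n_min: int = DEFAULT_N_MIN,
) -> pd.DataFrame:
    """KSD after removing steps below each length threshold (same units as
    ``lengths``, conventionally degrees).

    For each threshold the power law is refit on the surviving steps.
    Thresholds whose surviving sample is too small are missing-coded.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("empty threshold list")
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    x = np.asarray(lengths, dtype=float)
    rows = []
    for thr in thresholds:
        sub = x[x >= thr]
        try:
            fit = fit_power_law(sub, n_min=n_min)
            rows.append(
                {"threshold": thr, "ksd": fit.ksd, "alpha": fit.alpha, "n": fit.n_tail}
            )
        except DegenerateInputError:
            rows.append(
                {"threshold": thr, "ksd": np.nan, "alpha": np.nan, "n": len(sub)}
            )
    return pd.DataFrame(rows)


@dataclass
class SpatialKSDMap:
    """Grid of per-cell KSD values (NaN where a cell has too few steps)."""

    grid: np.ndarray  # n_rows x n_cols of KSD values
    n_per_cell: np.ndarray  # counts of steps per cell
    alpha: np.ndarray  # per-cell fitted exponents (NaN where missing)


def spatial_ksd_map(
    steps: pd.DataFrame,
    geometry,
    grid_shape: tuple[int, int] = (10, 10),
    n_min: int = DEFAULT_N_MIN,
) -> SpatialKSDMap:
    """Per-cell power-law fits over a coarse grid of image space.

    Each gaze step is assigned to the grid cell containing its originating
    sample (half-open cell bounds, last row/column closed).  Cells with at
    least ``n_min`` steps get a KSD from their own power-law fit; the rest
    are missing-coded.  Pass a per-image subset of ``steps`` for
    per-(subject, image) maps, or all steps for pooled per-subject maps.
    """
    if geometry is None:
        raise ValueError("geometry required")
    n_rows, n_cols = grid_shape
    rows_idx = cell_index(steps["y0"].to_numpy(), geometry.map_height, n_rows)
    cols_idx = cell_index(steps["x0"].to_numpy(), geometry.map_width, n_cols)
    lengths = steps["length_deg"].to_numpy()

    grid = np.full(grid_shape, np.nan)
    alpha = np.full(grid_shape, np.nan)
    counts = np.zeros(grid_shape, dtype=int)
    flat = rows_idx * n_cols + cols_idx
    order = np.argsort(flat, kind="stable")
    flat_sorted = flat[order]
    lengths_sorted = lengths[order]
    bounds = np.searchsorted(flat_sorted, np.arange(n_rows * n_cols + 1))
    for cell in range(n_rows * n_cols):
        a, b = bounds[cell], bounds[cell + 1]
        r, c = divmod(cell, n_cols)
        counts[r, c] = b - a
        if b - a >= n_min:
            try:
                fit = fit_power_law(lengths_sorted[a:b], n_min=n_min)
            except DegenerateInputError:
                continue
            grid[r, c] = fit.ksd
            alpha[r, c] = fit.alpha
    return SpatialKSDMap(grid=grid, n_per_cell=counts, alpha=alpha)
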