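"""Whole-breast segmentation by dynamic-programming boundary tracing.

Step 1 of the measurement pipeline. On each 2D slice of the pre-contrast
fat-suppressed T1 volume two boundaries are traced as one-row-per-column
paths: the chest wall (posterior limit of breast tissue) and the skin line
(anterior tissue/air surface). Each path minimises

    sum_c cost[path(c), c]
    + lambda_smooth * sum_c |path(c) - path(c-1)|
    + lambda_prior  * sum_c |path(c) - prior(c)|

globally, via dynamic programming over columns with the per-column step
bounded by ``smoothness_limit``. The prior term ties each slice to the paths
traced on the previous slice, exploiting the continuity of both boundaries
across adjacent slices. The breast mask is the band between the two paths,
split at the sternum midline into left and right breasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

#: defaults for the path objective; the cost map is normalised to [0, 1], so
#: lambda_smooth is small (descending a steep breast edge must cost less than
#: cutting across air) and the directional bias is well below one edge depth.
DEFAULT_SMOOTHNESS_LIMIT = 12
DEFAULT_LAMBDA_SMOOTH = 0.05
DEFAULT_LAMBDA_PRIOR = 0.02
_DIRECTION_BIAS = 0.1
_BAND_PENALTY = 2.0
_POSTERIOR_BAND_FRACTION = 0.35
#: the skin search is excluded from this many rows above the traced chest wall
#: so it cannot ride the chest-wall gradient halo
_SKIN_CHEST_MARGIN = 2
_MIN_COLUMN_THICKNESS = _SKIN_CHEST_MARGIN + 2  # thinner columns are background


@dataclass
class Volume:
    """A 3D scalar volume with voxel spacing, axes (slice, row, column);
    rows run posterior to anterior."""

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.intensities.ndim}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("volume intensities must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")


@dataclass
class BreastSegmentation:
    mask: np.ndarray
    left_mask: np.ndarray
    right_mask: np.ndarray
    midline_col: int
    chest_rows: np.ndarray  # (n_slices, n_cols) traced chest-wall row per column
    skin_rows: np.ndarray


def compute_cost_map(slice_image: np.ndarray) -> np.ndarray:
    """Boundary cost for one slice: low where the intensity gradient is strong.

    The slice is lightly smoothed, the Sobel gradient magnitude g is taken,
    and costs are the saturating transform ``1 - g/(g + g0)`` with ``g0`` a
    robust noise-gradient scale (twice the median of g). Saturation puts every
    genuine tissue edge — skin/air, muscle and fat/gland alike — near zero
    cost while noise texture stays expensive, so path selection between edges
    is driven by the directional bias and continuity terms rather than by
    edge contrast. Costs lie in (0, 1]; a constant slice yields a uniform
    cost map.
    """
    img = np.asarray(slice_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("cost map expects a 2D slice")
    smoothed = ndimage.gaussian_filter(img, 1.0)
    g = np.hypot(ndimage.sobel(smoothed, axis=0), ndimage.sobel(smoothed, axis=1))
    gmax = g.max()
    if gmax == 0:
        return np.ones_like(img)
    g0 = max(2.0 * float(np.median(g)), 0.01 * gmax)
    return 1.0 - g / (g + g0)


def trace_boundary_dp(
    cost_map: np.ndarray,
    prior_path: np.ndarray | None = None,
    smoothness_limit: int = DEFAULT_SMOOTHNESS_LIMIT,
    lambda_smooth: float = DEFAULT_LAMBDA_SMOOTH,
    lambda_prior: float = DEFAULT_LAMBDA_PRIOR,
) -> np.ndarray:
    """Globally optimal one-row-per-column path through a cost map.

    Ties are broken toward the smallest row index, both in the per-column
    transition and in the final column, making the result deterministic.
    """
    cost = np.asarray(cost_map, dtype=float)
    if cost.ndim != 2 or cost.size == 0:
        raise ValueError("cost map must be a non-empty 2D array")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost map must be finite")
    n_rows, n_cols = cost.shape
    rows = np.arange(n_rows)

    if prior_path is not None:
        prior_path = np.asarray(prior_path)
        if prior_path.shape != (n_cols,):
            raise ValueError("prior path length must equal the number of columns")

    def node_cost(c):
        nc = cost[:, c].copy()
        if prior_path is not None and lambda_prior:
            nc += lambda_prior * np.abs(rows - prior_path[c])
        return nc

    parents = np.zeros((n_cols, n_rows), dtype=np.intp)
    dp = node_cost(0)
    offsets = range(-smoothness_limit, smoothness_limit + 1)
    for c in range(1, n_cols):
        best = np.full(n_rows, np.inf)
        best_parent = np.zeros(n_rows, dtype=np.intp)
        for d in offsets:  # ascending parent row => strict '<' keeps smallest
            lo, hi = max(0, -d), min(n_rows, n_rows - d)
            if lo >= hi:
                continue
            cand = dp[lo + d : hi + d] + lambda_smooth * abs(d)
            seg = slice(lo, hi)
            better = cand < best[seg]
            best[seg] = np.where(better, cand, best[seg])
            best_parent[seg] = np.where(better, rows[lo + d : hi + d], best_parent[seg])
        dp = best + node_cost(c)
        parents[c] = best_parent

    path = np.empty(n_cols, dtype=np.intp)
    path[-1] = int(np.argmin(dp))  # argmin returns the first (smallest) row
    for c in range(n_cols - 1, 0, -1):
        path[c - 1] = parents[c, path[c]]
    return path


def path_total_cost(cost_map, path, prior_path=None,
                    lambda_smooth=DEFAULT_LAMBDA_SMOOTH,
                    lambda_prior=DEFAULT_LAMBDA_PRIOR) -> float:
    """Objective value of a given path; used for auditing and testing."""
    cost_map = np.asarray(cost_map, dtype=float)
    path = np.asarray(path)
    cols = np.arange(cost_map.shape[1])
    total = float(cost_map[path, cols].sum())
    total += lambda_smooth * float(np.abs(np.diff(path)).sum())
    if prior_path is not None:
        total += lambda_prior * float(np.abs(path - np.asarray(prior_path)).sum())
    return total


def _foreground(vol: np.ndarray):
    """Tissue/air foreground with a separability guard; returns None when the
    volume has no breast-like foreground.

    Otsu runs on log-compressed intensities: the air/tissue gap dominates
    there, so the threshold separates air from all tissue classes rather than
    fat from brighter tissue.
    """
    if np.ptp(vol) == 0:
        return None
    # structure test: smoothing annihilates pure noise but not anatomy, so a
    # breast-like volume keeps a dynamic range well above the noise floor
    smoothed = ndimage.gaussian_filter(vol, 2.0)
    sigma_hf = 1.4826 * float(np.median(np.abs(vol - smoothed)))
    if np.ptp(smoothed) <= 8.0 * sigma_hf:
        return None
    # Otsu on lightly smoothed, log-compressed intensities: the air/tissue gap
    # dominates the log histogram and smoothing suppresses speckle at high noise
    work = np.log1p(np.clip(ndimage.gaussian_filter(vol, 1.0), 0.0, None))
    thr = threshold_otsu(work)
    fg = work > thr
    if not fg.any() or fg.all():
        return None
    return fg


def segment_whole_breast(
    volume,
    smoothness_limit: int = DEFAULT_SMOOTHNESS_LIMIT,
    lambda_smooth: float = DEFAULT_LAMBDA_SMOOTH,
    lambda_prior: float = DEFAULT_LAMBDA_PRIOR,
) -> BreastSegmentation:
    """Segment the whole breast on a pre-contrast volume.

    Slices are processed sequentially, each seeded by the previous slice's
    chest-wall and skin paths. The chest-wall search is restricted to the
    posterior part of the automatically extracted volume of interest and
    biased posterior; the skin search runs anterior of the traced chest wall
    and is biased anterior. The resulting band mask is split at the sternum
    midline (the minimum-foreground column near the volume centre).
    """
    vol = volume.intensities if isinstance(volume, Volume) else np.asarray(volume, float)
    if vol.ndim != 3:
        raise ValueError("expected a 3D volume")
    nz, ny, nx = vol.shape
    empty = np.zeros(vol.shape, dtype=bool)

    fg = _foreground(vol)
    if fg is None:
        warnings.warn("no breast-like foreground found; returning empty mask")
        return BreastSegmentation(empty, empty.copy(), empty.copy(), nx // 2,
                                  np.zeros((nz, nx), int), np.zeros((nz, nx), int))

    # smoothing before Otsu dilates the tissue blob by about one voxel; one
    # erosion restores an unbiased surface for the volume trim, while the
    # un-eroded outline keeps the stronger edge for path tracing
    fg_trim = ndimage.binary_erosion(fg)

    fg_rows = np.flatnonzero(fg.any(axis=(0, 2)))
    r0, r1 = int(fg_rows[0]), int(fg_rows[-1])
    chest_band_max = min(ny - 1, r0 + max(2, int(_POSTERIOR_BAND_FRACTION * (r1 - r0))))

    rows = np.arange(ny, dtype=float)
    posterior_bias = _DIRECTION_BIAS * rows / max(ny - 1, 1)

    mask = np.zeros(vol.shape, dtype=bool)
    chest_rows = np.zeros((nz, nx), dtype=int)
    skin_rows = np.zeros((nz, nx), dtype=int)

    # middle-out sweep: seed the continuity prior on the slice with the most
    # foreground (where both boundaries are fully developed), then propagate
    # towards either end so each slice is seeded by its neighbour's paths
    z_seed = int(np.argmax(fg.sum(axis=(1, 2))))
    order = list(range(z_seed, nz)) + list(range(z_seed - 1, -1, -1))
    chest_prior = skin_prior = None

    for z in order:
        if z == z_seed - 1:  # second sweep restarts from the seed slice
            chest_prior, skin_prior = chest_rows[z_seed], skin_rows[z_seed]

        chest_cost = compute_cost_map(vol[z]) + posterior_bias[:, None]
        chest_cost[chest_band_max + 1 :, :] += _BAND_PENALTY
        chest = trace_boundary_dp(chest_cost, chest_prior, smoothness_limit,
                                  lambda_smooth, lambda_prior)

        # the skin line is the outer tissue/air surface: trace it on the
        # gradient of the foreground outline, where it is the only edge
        skin_cost = compute_cost_map(fg[z].astype(float)) + posterior_bias[:, None]
        below = rows[:, None] <= (chest[None, :] + _SKIN_CHEST_MARGIN)
        skin_cost = np.where(below, skin_cost + _BAND_PENALTY, skin_cost)
        skin = trace_boundary_dp(skin_cost, skin_prior, smoothness_limit,
                                 lambda_smooth, lambda_prior)
        skin = np.maximum(skin, chest)  # never posterior of the chest wall

        # band between the paths, trimmed to tissue: the DP paths set the
        # extents, the foreground removes residual air (inter-breast valley)
        band = (rows[:, None] >= chest[None, :]) & (rows[:, None] <= skin[None, :] + 1)
        band[:, (skin - chest) <= _MIN_COLUMN_THICKNESS] = False
        mask[z] = band & fg_trim[z]

        chest_rows[z], skin_rows[z] = chest, skin
        chest_prior, skin_prior = chest, skin

    midline = _midline_column(mask)
    left = mask.copy()
    left[:, :, midline:] = False
    right = mask.copy()
    right[:, :, :midline] = False
    return BreastSegmentation(mask, left, right, midline, chest_rows, skin_rows)


def _midline_column(mask: np.ndarray) -> int:
    """Sternum midline: the minimum-foreground column in the central third."""
    nx = mask.shape[2]
    counts = mask.sum(axis=(0, 1))
    lo, hi = nx // 3, nx - nx // 3
    if hi <= lo:
        return nx // 2
    return int(lo + np.argmin(counts[lo:hi]))
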