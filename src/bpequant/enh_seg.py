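"""Enhanced-FGT segmentation on subtraction images.

Step 3 of the measurement pipeline. For each post-contrast phase the
subtraction volume (post minus pre, no clipping) is thresholded at ``k`` times
the estimated noise level: FGT voxels whose subtraction value exceeds
``k * sigma`` are labelled enhanced. Sigma is estimated robustly
(1.4826 * MAD) from a reference region that should not enhance — by default
the fatty breast voxels outside the FGT mask — so genuine enhancement does
not inflate the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

DEFAULT_K = 3.0
PHASE_TIMES_S = (60.0, 180.0, 300.0)
_MAD_TO_SIGMA = 1.4826  # consistency constant for Gaussian data


@dataclass
class SubtractionVolume:
    """Voxelwise post - pre difference for one phase (60/180/300 s)."""

    data: np.ndarray
    phase_index: int  # 0, 1, 2
    phase_time: float  # seconds

    def __post_init__(self):
        if self.phase_time not in PHASE_TIMES_S:
            raise ValueError(f"phase time must be one of {PHASE_TIMES_S}")


def subtract_volumes(post: np.ndarray, pre: np.ndarray, phase_index: int = 0) -> SubtractionVolume:
    """Voxelwise subtraction, no clipping. Grids must match exactly."""
    post = np.asarray(post, dtype=float)
    pre = np.asarray(pre, dtype=float)
    if post.shape != pre.shape:
        raise ValueError(f"grid mismatch: {post.shape} vs {pre.shape}")
    if not 0 <= phase_index <= 2:
        raise ValueError("phase_index must be 0, 1 or 2")
    return SubtractionVolume(post - pre, phase_index, PHASE_TIMES_S[phase_index])


def estimate_noise_sigma(subtraction, reference_region: np.ndarray) -> float:
    """Robust spread of subtraction values in a non-enhancing reference region.

    Uses 1.4826 * median absolute deviation, which tolerates a moderate
    fraction of contaminating enhanced voxels.
    """
    data = subtraction.data if isinstance(subtraction, SubtractionVolume) else np.asarray(subtraction)
    reference_region = np.asarray(reference_region, dtype=bool)
    if data.shape != reference_region.shape:
        raise ValueError("reference region grid mismatch")
    vals = data[reference_region]
    if vals.size == 0:
        raise ValueError("reference region is empty")
    return float(_MAD_TO_SIGMA * np.median(np.abs(vals - np.median(vals))))


def segment_enhanced_fgt(subtraction, fgt_mask: np.ndarray, sigma: float, k: float = DEFAULT_K) -> np.ndarray:
    """Enhanced-FGT mask: FGT voxels with subtraction value above k * sigma.

    Always a subset of ``fgt_mask``; monotone in ``k`` (a larger multiplier
    never grows the mask).
    """
    data = subtraction.data if isinstance(subtraction, SubtractionVolume) else np.asarray(subtraction)
    fgt_mask = np.asarray(fgt_mask, dtype=bool)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not fgt_mask.any():
        raise ValueError("FGT mask is empty")
    if data.shape != fgt_mask.shape:
        raise ValueError("subtraction/FGT grid mismatch")
    return fgt_mask & (data > k * sigma)


def reference_region(breast_mask: np.ndarray, fgt_mask: np.ndarray) -> np.ndarray:
    """Non-enhancing reference: fatty breast voxels (breast minus FGT), falling
    back to the whole breast when the difference is empty."""
    breast_mask = np.asarray(breast_mask, dtype=bool)
    fgt_mask = np.asarray(fgt_mask, dtype=bool)
    region = breast_mask & ~fgt_mask
    if not region.any():
        warnings.warn("no fat voxels outside FGT; using whole breast as noise reference")
        return breast_mask
    return region
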