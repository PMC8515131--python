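"""Quantitative FGT and BPE metrics from the segmentation masks.

Three quantities per subject, all dimensionless:

* ``FGT``    = V_fibroglandular / V_breast  (volume fraction),
* ``BPE_V``  = V_enhanced_FGT / V_FGT       (per post-contrast phase),
* ``BPE_I``  = mean over enhanced voxels of I_subtraction / I_original
  (per phase),

where voxel volumes are identical within a series, so volume ratios reduce to
voxel-count ratios. To avoid lesion effects, the reported measurement per
subject is the mean of the two breasts for controls and the contralateral
breast for subjects with a lesion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from bpequant.breast_seg import segment_whole_breast
from bpequant.enh_seg import (
    estimate_noise_sigma,
    reference_region,
    segment_enhanced_fgt,
    subtract_volumes,
)
from bpequant.fgt_seg import segment_fgt

#: BPE_I denominator guard: voxels whose pre-contrast intensity falls below
#: this fraction of the volume's robust intensity scale are excluded.
MIN_ORIGINAL_FRACTION = 0.01


@dataclass
class QuantResult:
    """FGT fraction plus per-phase BPE_V and BPE_I for one breast (or the
    subject-level selection). NaN entries mark undefined values (no FGT, or
    no enhanced voxels at that phase); ``flags`` records why."""

    fgt: float
    bpe_v: tuple[float, float, float]
    bpe_i: tuple[float, float, float]
    side: str = "combined"  # left | right | combined
    flags: list = field(default_factory=list)

    def is_complete(self) -> bool:
        return not (
            math.isnan(self.fgt)
            or any(math.isnan(v) for v in self.bpe_v)
            or any(math.isnan(v) for v in self.bpe_i)
        )


def compute_fgt_fraction(fgt_mask, breast_mask, spacing=(1.0, 1.0, 1.0)) -> float:
    """FGT volume fraction of the breast. With one voxel volume throughout,
    the ratio of volumes equals the ratio of voxel counts."""
    fgt_mask = np.asarray(fgt_mask, dtype=bool)
    breast_mask = np.asarray(breast_mask, dtype=bool)
    n_breast = int(breast_mask.sum())
    if n_breast == 0:
        raise ValueError("breast mask is empty")
    if np.any(fgt_mask & ~breast_mask):
        raise ValueError("FGT mask must be a subset of the breast mask")
    return float(fgt_mask.sum()) / n_breast


def compute_bpe_v(enhanced_mask, fgt_mask) -> float:
    """Enhanced-FGT volume fraction of the FGT; NaN when FGT is empty."""
    enhanced_mask = np.asarray(enhanced_mask, dtype=bool)
    fgt_mask = np.asarray(fgt_mask, dtype=bool)
    n_fgt = int(fgt_mask.sum())
    if n_fgt == 0:
        return math.nan
    if np.any(enhanced_mask & ~fgt_mask):
        raise ValueError("enhanced mask must be a subset of the FGT mask")
    return float(enhanced_mask.sum()) / n_fgt


def compute_bpe_i(subtraction, pre_volume, enhanced_mask) -> float:
    """Mean subtraction/original intensity ratio over enhanced voxels.

    NaN when the enhanced mask is empty. Voxels whose pre-contrast intensity
    is below 1% of the volume's robust scale (median absolute intensity) are
    excluded from the mean to guard the division; exclusions are warned about.
    """
    data = getattr(subtraction, "data", subtraction)
    data = np.asarray(data, dtype=float)
    pre = np.asarray(pre_volume, dtype=float)
    enhanced_mask = np.asarray(enhanced_mask, dtype=bool)
    if not enhanced_mask.any():
        return math.nan
    sub_vals = data[enhanced_mask]
    pre_vals = pre[enhanced_mask]
    floor = MIN_ORIGINAL_FRACTION * float(np.median(np.abs(pre)))
    keep = pre_vals > floor
    n_excluded = int((~keep).sum())
    if n_excluded:
        warnings.warn(f"BPE_I: excluded {n_excluded} voxels with near-zero original intensity")
    if not keep.any():
        return math.nan
    return float(np.mean(sub_vals[keep] / pre_vals[keep]))


def select_measurement(record, left: QuantResult, right: QuantResult) -> QuantResult:
    """Subject-level measurement: mean of both breasts for controls, the
    contralateral breast verbatim for the benign and cancer groups."""
    if record.group == "control":
        mean3 = lambda a, b: tuple((x + y) / 2.0 for x, y in zip(a, b))
        return QuantResult(
            fgt=(left.fgt + right.fgt) / 2.0,
            bpe_v=mean3(left.bpe_v, right.bpe_v),
            bpe_i=mean3(left.bpe_i, right.bpe_i),
            side="combined",
            flags=sorted(set(left.flags) | set(right.flags)),
        )
    if record.lesion_side not in ("left", "right"):
        raise ValueError(
            f"subject {record.subject_id}: group {record.group!r} requires a lesion side"
        )
    chosen = right if record.lesion_side == "left" else left
    return replace(chosen, flags=list(chosen.flags))


def _quantify_masks(pre, subtractions, breast_mask, fgt_mask, enhanced_masks, side) -> QuantResult:
    flags = []
    if not breast_mask.any():
        return QuantResult(math.nan, (math.nan,) * 3, (math.nan,) * 3, side, ["empty_breast"])
    fgt = compute_fgt_fraction(fgt_mask, breast_mask)
    if not fgt_mask.any():
        flags.append("empty_fgt")
    bpe_v, bpe_i = [], []
    for sub, enh in zip(subtractions, enhanced_masks):
        bpe_v.append(compute_bpe_v(enh, fgt_mask))
        val = compute_bpe_i(sub, pre, enh) if enh.any() else math.nan
        if not enh.any():
            flags.append("no_enhancement")
        bpe_i.append(val)
    return QuantResult(fgt, tuple(bpe_v), tuple(bpe_i), side, flags)


def quantify_subject(series, k: float = 3.0, fcm_seed: int = 0):
    """Run the full three-step measurement on one subject's series.

    Returns ``(per_side, masks)`` where per_side maps 'left'/'right'/'combined'
    to QuantResults and masks holds the segmentations (breast segmentation
    object, FGT mask, list of per-phase enhanced masks).
    """
    seg = segment_whole_breast(series.pre)
    if not seg.mask.any():
        nanq = QuantResult(math.nan, (math.nan,) * 3, (math.nan,) * 3, "combined", ["empty_breast"])
        return {"left": nanq, "right": nanq, "combined": nanq}, (seg, seg.mask, [])

    fgt_mask = segment_fgt(series.pre, seg.mask, seed=fcm_seed)
    ref = reference_region(seg.mask, fgt_mask)

    subtractions, enhanced_masks = [], []
    for phase_idx, post in enumerate(series.posts):
        sub = subtract_volumes(post, series.pre, phase_idx)
        sigma = estimate_noise_sigma(sub, ref)
        if fgt_mask.any():
            enh = segment_enhanced_fgt(sub, fgt_mask, sigma, k)
        else:
            enh = np.zeros_like(fgt_mask)
        subtractions.append(sub)
        enhanced_masks.append(enh)

    per_side = {}
    for side, bmask in (("left", seg.left_mask), ("right", seg.right_mask), ("combined", seg.mask)):
        f = fgt_mask & bmask
        e = [m & bmask for m in enhanced_masks]
        per_side[side] = _quantify_masks(series.pre, subtractions, bmask, f, e, side)
    return per_side, (seg, fgt_mask, enhanced_masks)
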