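"""Digital DCE-MRI breast phantoms with ground truth.

No raw scans ship with this package, so every downstream stage is exercised on
3D phantoms that emulate what the measurement pipeline actually relies on:

* prone bilateral breast geometry — two hemiellipsoids resting on a flat
  chest-wall slab, wrapped in a one-voxel skin shell, surrounded by air;
* fat-suppressed T1 intensity ordering (air < fat < skin < muscle < gland);
* an FGT core of prescribed volume fraction inside each breast;
* phase-wise contrast enhancement of a prescribed fraction of FGT voxels at a
  prescribed subtraction/original intensity ratio, at 60/180/300 s;
* additive Gaussian voxel noise (Rician optional).

Ground-truth masks are returned alongside the image series, and
:func:`true_metrics` recomputes the three target quantities (FGT fraction,
BPE_V, BPE_I) directly from those masks — the oracle the measured pipeline is
judged against.

:func:`make_cohort` generates whole case-control cohorts with the group sizes,
menopause split and menstrual-week strata of the study population, drawing each
subject's true fractions from logit-normal distributions whose medians are the
published group medians and whose spread is derived from the published AUCs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.special import expit, logit, ndtri

from bpequant.stats import SubjectRecord

PHASE_TIMES_S = (60.0, 180.0, 300.0)

# Fat-suppressed T1 tissue intensities (arbitrary units). Ordering is what
# matters: fat is suppressed, gland is bright, skin sits between.
INTENSITY = {
    "air": 5.0,
    "fat": 60.0,
    "skin": 90.0,
    "muscle": 130.0,
    "gland": 220.0,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Construction parameters for one subject's phantom.

    ``enhanced_fraction_true`` and ``enhancement_ratio_true`` are per
    post-contrast phase (60/180/300 s); they are the ground truth for BPE_V
    and BPE_I respectively. ``breast_radius`` is the lateral semi-axis of each
    hemiellipsoidal breast in mm; the superior-inferior and anterior semi-axes
    are 1.7x and 2.0x that radius.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    breast_radius: float = 20.0
    chest_wall_depth: float = 12.0
    fgt_fraction_true: float = 0.164
    enhanced_fraction_true: tuple[float, float, float] = (0.305, 0.481, 0.543)
    enhancement_ratio_true: tuple[float, float, float] = (0.265, 0.323, 0.359)
    noise_sigma: float = 5.0
    seed: int = 0
    kinetics: str = "monotone"
    noise_model: str = "gaussian"

    def validate(self) -> None:
        if any(int(n) <= 0 for n in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError(f"grid_shape must be three positive ints, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        if not 0.0 <= self.fgt_fraction_true <= 1.0:
            raise ValueError(f"fgt_fraction_true outside [0,1]: {self.fgt_fraction_true}")
        for name in ("enhanced_fraction_true",):
            vals = getattr(self, name)
            if len(vals) != 3 or any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValueError(f"{name} must be three fractions in [0,1], got {vals}")
        if len(self.enhancement_ratio_true) != 3 or any(v < 0 for v in self.enhancement_ratio_true):
            raise ValueError("enhancement_ratio_true must be three non-negative ratios")
        if self.kinetics == "monotone":
            e = self.enhanced_fraction_true
            if not (e[0] <= e[1] <= e[2]):
                raise ValueError(f"monotone kinetics requires non-decreasing enhanced fractions, got {e}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


@dataclass
class MRISeries:
    """One subject's series: a pre-contrast volume and three timed post-contrast
    volumes on a common grid. Axis convention: (slice, row, column), rows run
    posterior (chest) to anterior (nipple)."""

    pre: np.ndarray
    posts: list[np.ndarray]
    phase_times: tuple[float, float, float] = PHASE_TIMES_S
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass
class GroundTruth:
    breast_mask: np.ndarray
    fgt_mask: np.ndarray
    enhanced_masks: list[np.ndarray]
    true_fgt: float = 0.0
    true_bpe_v: tuple[float, float, float] = (0.0, 0.0, 0.0)
    true_bpe_i: tuple[float, float, float] = (0.0, 0.0, 0.0)


def _ellipsoid_rho(shape, spacing, center_mm, semi_axes_mm):
    """Normalised ellipsoidal radius for every voxel (<=1 inside)."""
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    a, b, c = semi_axes_mm
    cz, cy, cx = center_mm
    return np.sqrt(((zz - cz) / a) ** 2 + ((yy - cy) / b) ** 2 + ((xx - cx) / c) ** 2)


def _build_geometry(spec: PhantomSpec):
    """Tissue-class label volume plus the truth masks for breast and skin."""
    nz, ny, nx = spec.grid_shape
    sz, sy, sx = spec.voxel_spacing
    cw_row = max(1, int(round(spec.chest_wall_depth / sy)))

    r = spec.breast_radius
    semi = (1.7 * r, 2.0 * r, r)
    cy = cw_row * sy  # breasts rest on the chest-wall plane
    centers = [((nz / 2) * sz, cy, 0.27 * nx * sx), ((nz / 2) * sz, cy, 0.73 * nx * sx)]

    rows = np.arange(ny)[None, :, None]
    anterior = np.broadcast_to(rows >= cw_row, spec.grid_shape)

    breast = np.zeros(spec.grid_shape, dtype=bool)
    rho_by_side = []
    for center in centers:
        rho = _ellipsoid_rho(spec.grid_shape, spec.voxel_spacing, center, semi)
        breast |= (rho <= 1.0) & anterior
        rho_by_side.append(rho)

    # one-voxel outer shell, excluding the base face on the chest wall
    eroded = ndimage.binary_erosion(breast)
    skin = breast & ~eroded & np.broadcast_to(rows > cw_row, spec.grid_shape)

    chest = np.broadcast_to(rows < cw_row, spec.grid_shape) & ~breast
    return breast, skin, chest, cw_row, rho_by_side, centers, semi


def _select_fgt(spec: PhantomSpec, breast, skin, cw_row, centers, semi):
    """Pick FGT voxels per breast as a compact anterior core of exact count."""
    sz, sy, sx = spec.voxel_spacing
    fgt = np.zeros(spec.grid_shape, dtype=bool)
    nx = spec.grid_shape[2]
    mid = nx // 2
    for side, (cz, cy, cx) in enumerate(centers):
        side_cols = slice(0, mid) if side == 0 else slice(mid, nx)
        side_mask = np.zeros_like(breast)
        side_mask[:, :, side_cols] = True
        side_breast = breast & side_mask
        n_side = int(side_breast.sum())
        n_target = int(round(spec.fgt_fraction_true * n_side))
        if n_target == 0:
            continue
        # core centred anterior of the chest wall so the gland never abuts it
        core_center = (cz, cy + 0.45 * semi[1], cx)
        rho = _ellipsoid_rho(spec.grid_shape, spec.voxel_spacing, core_center, semi)
        key = np.where(skin, rho + 1e6, rho)  # interior voxels first
        idx = np.flatnonzero(side_breast)
        order = idx[np.argsort(key.ravel()[idx], kind="stable")]
        fgt.ravel()[order[:n_target]] = True
    return fgt


def make_phantom(spec: PhantomSpec) -> tuple[MRISeries, GroundTruth]:
    """Generate one subject's DCE series and its ground truth.

    Deterministic given ``spec.seed``. With ``noise_sigma = 0`` the volumes are
    piecewise constant by tissue class, post-contrast volumes differ from the
    pre-contrast one only on enhanced voxels (scaled so that
    subtraction/original equals ``enhancement_ratio_true`` exactly).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    breast, skin, chest, cw_row, _, centers, semi = _build_geometry(spec)
    fgt = _select_fgt(spec, breast, skin, cw_row, centers, semi)

    # nested per-phase enhancement: a seeded permutation of FGT voxels, the
    # first round(e_p * N) of which enhance at phase p
    fgt_idx = np.flatnonzero(fgt)
    perm = rng.permutation(fgt_idx.size)
    enhanced_masks = []
    for e_p in spec.enhanced_fraction_true:
        n_e = int(round(e_p * fgt_idx.size))
        m = np.zeros(spec.grid_shape, dtype=bool)
        m.ravel()[fgt_idx[perm[:n_e]]] = True
        enhanced_masks.append(m)

    clean = np.full(spec.grid_shape, INTENSITY["air"], dtype=np.float64)
    clean[chest] = INTENSITY["muscle"]
    clean[breast] = INTENSITY["fat"]
    clean[skin] = INTENSITY["skin"]
    clean[fgt] = INTENSITY["gland"]

    def _noisy(vol):
        if spec.noise_sigma == 0:
            return vol.copy()
        if spec.noise_model == "rician":
            n1 = rng.normal(0.0, spec.noise_sigma, vol.shape)
            n2 = rng.normal(0.0, spec.noise_sigma, vol.shape)
            return np.hypot(vol + n1, n2)
        return vol + rng.normal(0.0, spec.noise_sigma, vol.shape)

    pre = _noisy(clean)
    posts = []
    for m, ratio in zip(enhanced_masks, spec.enhancement_ratio_true):
        post_clean = clean.copy()
        post_clean[m] *= 1.0 + ratio
        posts.append(_noisy(post_clean))

    n_breast = int(breast.sum())
    n_fgt = int(fgt.sum())
    true_fgt = n_fgt / n_breast if n_breast else 0.0
    if n_fgt:
        true_bpe_v = tuple(m.sum() / n_fgt for m in enhanced_masks)
    else:
        true_bpe_v = (math.nan,) * 3
    true_bpe_i = tuple(
        r if m.any() else math.nan
        for m, r in zip(enhanced_masks, spec.enhancement_ratio_true)
    )

    series = MRISeries(pre=pre, posts=posts, spacing=tuple(spec.voxel_spacing))
    gt = GroundTruth(
        breast_mask=breast,
        fgt_mask=fgt,
        enhanced_masks=enhanced_masks,
        true_fgt=true_fgt,
        true_bpe_v=true_bpe_v,
        true_bpe_i=true_bpe_i,
    )
    return series, gt


def true_metrics(gt: GroundTruth, spacing=(1.0, 1.0, 1.0)):
    """Recompute FGT / BPE_V / BPE_I directly from the truth masks.

    Voxel volume is identical everywhere, so the volume ratios reduce to voxel
    counts; BPE_I truth is carried on the GroundTruth (enhancement is applied
    at a single known ratio per phase). Serves as the oracle for the measured
    pipeline.
    """
    from bpequant.metrics import QuantResult

    n_breast = int(gt.breast_mask.sum())
    if n_breast == 0:
        raise ValueError("empty breast mask")
    for m in gt.enhanced_masks:
        if np.any(m & ~gt.fgt_mask):
            raise ValueError("enhanced mask not nested in FGT mask")
    if np.any(gt.fgt_mask & ~gt.breast_mask):
        raise ValueError("FGT mask not nested in breast mask")

    n_fgt = int(gt.fgt_mask.sum())
    fgt = n_fgt / n_breast
    if n_fgt:
        bpe_v = tuple(float(m.sum()) / n_fgt for m in gt.enhanced_masks)
    else:
        bpe_v = (math.nan,) * 3
    return QuantResult(fgt=fgt, bpe_v=bpe_v, bpe_i=tuple(gt.true_bpe_i), side="combined")


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

GROUPS = ("control", "benign", "cancer")

# Published group medians (fractions) per stratum, and the cancer-vs-control
# AUC of each stratum's most discriminative phase, from which the logit-scale
# spread of the generating distributions is derived.
GROUP_MEDIANS = {
    "fgt": {
        "pre": {"control": 0.173, "benign": 0.170, "cancer": 0.164},
        "post": {"control": 0.082, "benign": 0.094, "cancer": 0.094},
    },
    "bpe_v": {
        "pre": {
            "control": (0.195, 0.322, 0.402),
            "benign": (0.246, 0.389, 0.482),
            "cancer": (0.305, 0.481, 0.543),
        },
        "post": {
            "control": (0.1375, 0.217, 0.252),
            "benign": (0.1285, 0.256, 0.305),
            "cancer": (0.175, 0.260, 0.2985),
        },
    },
    "bpe_i": {
        "pre": {
            "control": (0.247, 0.299, 0.323),
            "benign": (0.264, 0.320, 0.348),
            "cancer": (0.265, 0.323, 0.359),
        },
        "post": {
            "control": (0.231, 0.247, 0.2625),
            "benign": (0.227, 0.2495, 0.2655),
            "cancer": (0.2555, 0.2725, 0.291),
        },
    },
}

# (best phase index, cancer-vs-control AUC at that phase) per metric/stratum
REFERENCE_AUC = {
    "fgt": {"pre": (None, 0.524), "post": (None, 0.598)},
    "bpe_v": {"pre": (1, 0.715), "post": (0, 0.684)},
    "bpe_i": {"pre": (2, 0.648), "post": (1, 0.618)},
}

AGE_RANGES = {
    "pre": {"control": (25, 54), "cancer": (25, 51), "benign": (27, 51)},
    "post": {"control": (47, 79), "cancer": (47, 79), "benign": (48, 75)},
}


def logit_normal_sigma(median_cancer: float, median_other: float, auc: float) -> float:
    """Logit-scale spread implied by two group medians and their AUC.

    For two logit-normals with common spread sigma, the pair-probability AUC is
    Phi(|delta| / (sigma * sqrt(2))) with delta the gap between logit medians;
    invert for sigma. AUC at or below 0.5 carries no spread information and
    falls back to sigma = 0.5.
    """
    delta = abs(logit(median_cancer) - logit(median_other))
    z = ndtri(auc)
    if z <= 0 or delta == 0:
        return 0.5
    return float(delta / (math.sqrt(2.0) * z))


def _metric_sigma(metric: str, stratum: str) -> float:
    phase, auc = REFERENCE_AUC[metric][stratum]
    med = GROUP_MEDIANS[metric][stratum]
    if phase is None:
        return logit_normal_sigma(med["cancer"], med["control"], auc)
    return logit_normal_sigma(med["cancer"][phase], med["control"][phase], auc)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort structure and generating distributions.

    Defaults reproduce the study population: three groups of 132 subjects
    each, split 62 premenopausal / 70 postmenopausal, premenopausal subjects
    stratified by menstrual week with counts 13/16/15/18. Per-subject true
    fractions are logit-normal around the published group medians; with
    ``sampling='stratified'`` they are placed at evenly spaced quantiles so
    cohort medians equal the construction medians exactly.
    """

    group_sizes: dict = field(
        default_factory=lambda: {"control": 132, "benign": 132, "cancer": 132}
    )
    premenopausal_per_group: int = 62
    week_counts: tuple[int, int, int, int] = (13, 16, 15, 18)
    medians: dict = field(default_factory=lambda: GROUP_MEDIANS)
    sigma_overrides: dict = field(default_factory=dict)
    sampling: str = "iid"
    phantom_template: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError("group sizes must be >= 0")
            if n and self.premenopausal_per_group > n:
                raise ValueError("premenopausal count exceeds group size")
        if self.group_sizes and any(self.group_sizes.values()):
            if sum(self.week_counts) != self.premenopausal_per_group:
                raise ValueError(
                    f"menstrual-week strata {self.week_counts} must sum to the "
                    f"premenopausal count {self.premenopausal_per_group}"
                )
        if self.sampling not in ("iid", "stratified"):
            raise ValueError(f"unknown sampling {self.sampling!r}")
        for metric, strata in self.medians.items():
            for stratum, groups in strata.items():
                for g, v in groups.items():
                    vals = v if isinstance(v, tuple) else (v,)
                    if any(not 0.0 < x < 1.0 for x in vals):
                        raise ValueError(
                            f"median for {metric}/{stratum}/{g} outside (0,1): {v}"
                        )

    def sigma(self, metric: str, stratum: str) -> float:
        key = (metric, stratum)
        if key in self.sigma_overrides:
            return float(self.sigma_overrides[key])
        return _metric_sigma(metric, stratum)


def _scores(rng, n: int, sampling: str) -> np.ndarray:
    """Standard-normal scores for n subjects: iid draws, or evenly spaced
    quantiles in seeded random order (stratified)."""
    if n == 0:
        return np.empty(0)
    if sampling == "stratified":
        q = ndtri((np.arange(n) + 0.5) / n)
        return q[rng.permutation(n)]
    return rng.normal(size=n)


def _phase_values(median_tuple, sigma, z) -> tuple[float, float, float]:
    """One latent score per subject shifted by the per-phase median offsets:
    keeps per-phase medians exact and preserves monotone kinetics."""
    return tuple(float(expit(logit(m) + sigma * z)) for m in median_tuple)


def recovery_cohort_specs(
    n: int,
    stratum: str = "pre",
    group: str = "cancer",
    grid_shape: tuple[int, int, int] = (96, 96, 96),
    breast_radius: float = 20.0,
    chest_wall_depth: float = 12.0,
    noise_sigma: float = 5.0,
    seed: int = 0,
) -> list[PhantomSpec]:
    """Phantom specs for a recovery experiment on one group/stratum.

    True fractions are logit-normal around the published group medians with
    the AUC-derived spread, sampled at evenly spaced quantiles (stratified),
    so the cohort median of each true metric equals the published median by
    construction and any deviation of the measured median is attributable to
    the measurement pipeline.
    """
    rng = np.random.default_rng(seed)
    z_fgt = _scores(rng, n, "stratified")
    z_v = _scores(rng, n, "stratified")
    z_i = _scores(rng, n, "stratified")
    s_fgt = _metric_sigma("fgt", stratum)
    s_v = _metric_sigma("bpe_v", stratum)
    s_i = _metric_sigma("bpe_i", stratum)
    med_fgt = GROUP_MEDIANS["fgt"][stratum][group]
    med_v = GROUP_MEDIANS["bpe_v"][stratum][group]
    med_i = GROUP_MEDIANS["bpe_i"][stratum][group]
    specs = []
    for j in range(n):
        specs.append(
            PhantomSpec(
                grid_shape=grid_shape,
                breast_radius=breast_radius,
                chest_wall_depth=chest_wall_depth,
                noise_sigma=noise_sigma,
                fgt_fraction_true=float(expit(logit(med_fgt) + s_fgt * z_fgt[j])),
                enhanced_fraction_true=_phase_values(med_v, s_v, z_v[j]),
                enhancement_ratio_true=_phase_values(med_i, s_i, z_i[j]),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def make_cohort(cohort: CohortSpec) -> list[SubjectRecord]:
    """Generate the full cohort of subject records, each carrying the
    PhantomSpec that realises that subject's true metric values."""
    cohort.validate()
    rng = np.random.default_rng(cohort.seed)
    records: list[SubjectRecord] = []
    sid = 0

    for group in GROUPS:
        n_group = int(cohort.group_sizes.get(group, 0))
        if n_group == 0:
            continue
        n_pre = int(cohort.premenopausal_per_group)
        n_post = n_group - n_pre
        for stratum, n_sub in (("pre", n_pre), ("post", n_post)):
            if n_sub == 0:
                continue
            z_fgt = _scores(rng, n_sub, cohort.sampling)
            z_v = _scores(rng, n_sub, cohort.sampling)
            z_i = _scores(rng, n_sub, cohort.sampling)
            s_fgt = cohort.sigma("fgt", stratum)
            s_v = cohort.sigma("bpe_v", stratum)
            s_i = cohort.sigma("bpe_i", stratum)
            med = {m: cohort.medians[m][stratum][group] for m in ("fgt", "bpe_v", "bpe_i")}

            if stratum == "pre":
                weeks = np.repeat(np.arange(1, 5), cohort.week_counts)
            else:
                weeks = np.full(n_sub, -1)

            lo, hi = AGE_RANGES[stratum][group]
            ages = rng.integers(lo, hi + 1, size=n_sub)

            for j in range(n_sub):
                fgt_true = float(expit(logit(med["fgt"]) + s_fgt * z_fgt[j]))
                bpe_v_true = _phase_values(med["bpe_v"], s_v, z_v[j])
                bpe_i_true = _phase_values(med["bpe_i"], s_i, z_i[j])
                spec = replace(
                    cohort.phantom_template,
                    fgt_fraction_true=fgt_true,
                    enhanced_fraction_true=bpe_v_true,
                    enhancement_ratio_true=bpe_i_true,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                lesion_side = None
                if group != "control":
                    lesion_side = "left" if rng.integers(0, 2) == 0 else "right"
                records.append(
                    SubjectRecord(
                        subject_id=f"S{sid:04d}",
                        group=group,
                        age=int(ages[j]),
                        menopause=stratum,
                        menstrual_week=int(weeks[j]) if stratum == "pre" else None,
                        lesion_side=lesion_side,
                        phantom=spec,
                    )
                )
                sid += 1
    return records
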