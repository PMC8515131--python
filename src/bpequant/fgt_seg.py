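"""Fibroglandular-tissue segmentation by fuzzy c-means clustering.

Step 2 of the measurement pipeline. Voxel intensities inside the breast mask
are clustered with fuzzy c-means (FCM); the number of clusters is selected
automatically by minimising the Xie-Beni validity index over a small range.
On fat-suppressed T1 images the gland is bright and fat is dark, so clusters
whose centroid lies above the midpoint of the extreme centroids are labelled
FGT.

FCM minimises  J = sum_k sum_i u_ik^m (v_k - c_i)^2  subject to the
memberships of each sample summing to one, by alternating the closed-form
membership and centroid updates. Initialisation places centroids at evenly
spaced intensity quantiles, which makes runs deterministic and independent of
sample order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_FUZZIFIER = 2.0
DEFAULT_TOL = 1e-5
DEFAULT_MAX_ITER = 300
DEFAULT_C_RANGE = (2, 5)
_SELECTION_SAMPLE_CAP = 30000


@dataclass
class FcmResult:
    centroids: np.ndarray  # (c,) sorted ascending
    memberships: np.ndarray  # (n, c), rows sum to 1
    objective: float
    iterations: int
    objective_history: list = field(default_factory=list)

    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.memberships, axis=1)


def _memberships(values: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    d2 = (values[:, None] - centroids[None, :]) ** 2
    zero = d2 <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        w = d2 ** (-1.0 / (m - 1.0))
        u = w / w.sum(axis=1, keepdims=True)
    hit = zero.any(axis=1)
    if hit.any():  # samples coinciding with a centroid get crisp membership
        u[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
    return u


def fuzzy_cmeans(
    values,
    c: int,
    m: float = DEFAULT_FUZZIFIER,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | None = None,
) -> FcmResult:
    """Fuzzy c-means on a 1D sample.

    ``seed`` is accepted for interface stability but unused: quantile
    initialisation is deterministic. Raises when ``c`` exceeds the number of
    distinct values or inputs are non-finite.
    """
    values = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if c < 2:
        raise ValueError("c must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if np.unique(values).size < c:
        raise ValueError(f"need at least {c} distinct values for c={c} clusters")

    centroids = np.quantile(values, (np.arange(c) + 0.5) / c)
    centroids = np.asarray(centroids, dtype=float)

    history: list[float] = []
    prev_j = np.inf
    u = _memberships(values, centroids, m)
    for it in range(1, max_iter + 1):
        um = u**m
        centroids = (um * values[:, None]).sum(axis=0) / um.sum(axis=0)
        u = _memberships(values, centroids, m)
        j = float(((values[:, None] - centroids[None, :]) ** 2 * u**m).sum())
        history.append(j)
        # relative decrease keeps the stopping rule scale-invariant, so
        # rescaling intensities rescales centroids exactly
        if abs(prev_j - j) < tol * max(j, np.finfo(float).tiny):
            break
        prev_j = j

    order = np.argsort(centroids)
    return FcmResult(
        centroids=centroids[order],
        memberships=u[:, order],
        objective=history[-1],
        iterations=len(history),
        objective_history=history,
    )


def xie_beni(values, result: FcmResult, m: float = DEFAULT_FUZZIFIER) -> float:
    """Xie-Beni validity index: compactness (the FCM objective) over n times
    the squared minimum centroid separation. Smaller is better."""
    values = np.asarray(values, dtype=float).ravel()
    c = result.centroids
    sep = np.min(np.abs(c[:, None] - c[None, :])[~np.eye(c.size, dtype=bool)])
    if sep == 0:
        return np.inf
    return result.objective / (values.size * sep**2)


def select_cluster_number(
    values,
    c_min: int = DEFAULT_C_RANGE[0],
    c_max: int = DEFAULT_C_RANGE[1],
    m: float = DEFAULT_FUZZIFIER,
) -> int:
    """Pick the cluster count in [c_min, c_max] minimising the Xie-Beni index.

    Near-constant samples (or samples with too few distinct values) fall back
    to ``c_min`` with a degeneracy warning.
    """
    if c_min < 2 or c_max < c_min:
        raise ValueError("need 2 <= c_min <= c_max")
    values = np.asarray(values, dtype=float).ravel()
    distinct = np.unique(values).size
    scale = max(abs(values.max()), abs(values.min()), 1.0)
    if distinct < c_min or np.ptp(values) < 1e-9 * scale:
        warnings.warn("degenerate intensity sample; falling back to c_min clusters")
        return c_min

    best_c, best_score = c_min, np.inf
    for c in range(c_min, min(c_max, distinct) + 1):
        res = fuzzy_cmeans(values, c, m=m)
        score = xie_beni(values, res, m=m)
        if score < best_score:
            best_c, best_score = c, score
    return best_c


def segment_fgt(
    volume,
    breast_mask: np.ndarray,
    c_min: int = DEFAULT_C_RANGE[0],
    c_max: int = DEFAULT_C_RANGE[1],
    m: float = DEFAULT_FUZZIFIER,
    seed: int = 0,
    min_relative_contrast: float = 0.5,
) -> np.ndarray:
    """Segment FGT within the breast mask; the result is always a subset of
    ``breast_mask``.

    Cluster-number selection runs on a seeded subsample (cap 30k voxels) for
    speed; the final FCM runs on all breast-mask intensities. Voxels are
    hard-assigned to their maximum-membership cluster, and clusters with
    centroid above the midpoint of the extreme centroids are labelled FGT.
    On fat-suppressed T1 the gland/fat contrast is large; when the centroid
    spread is below ``min_relative_contrast`` of the brightest centroid the
    breast is considered gland-free (fat and skin only) and the mask is empty.
    """
    vol = getattr(volume, "intensities", volume)
    vol = np.asarray(vol, dtype=float)
    breast_mask = np.asarray(breast_mask, dtype=bool)
    if not breast_mask.any():
        raise ValueError("breast mask is empty")
    values = vol[breast_mask]

    sample = values
    if values.size > _SELECTION_SAMPLE_CAP:
        rng = np.random.default_rng(seed)
        sample = rng.choice(values, _SELECTION_SAMPLE_CAP, replace=False)
    c_star = select_cluster_number(sample, c_min, c_max, m=m)

    if np.unique(values).size < c_star:
        warnings.warn("degenerate breast intensities; returning empty FGT mask")
        return np.zeros_like(breast_mask)
    res = fuzzy_cmeans(values, c_star, m=m)
    spread = res.centroids[-1] - res.centroids[0]
    if res.centroids[-1] > 0 and spread < min_relative_contrast * res.centroids[-1]:
        warnings.warn("no gland/fat contrast within the breast; returning empty FGT mask")
        return np.zeros_like(breast_mask)
    labels = res.hard_labels()
    midpoint = 0.5 * (res.centroids[0] + res.centroids[-1])
    fgt_clusters = np.flatnonzero(res.centroids > midpoint)

    fgt = np.zeros_like(breast_mask)
    fgt[breast_mask] = np.isin(labels, fgt_clusters)
    return fgt
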