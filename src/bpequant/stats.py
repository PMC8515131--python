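"""Matched case-control statistics: cohort matching, Mann-Whitney U tests and
nonparametric ROC/AUC per metric, menopause stratum and phase.

The discrimination question is whether FGT, BPE_V or BPE_I separates the
cancer group from controls (and from the benign-lesion group). Groups are
compared with the two-sided Mann-Whitney U test; discriminative performance is
the empirical AUC — the probability that a random cancer-group value exceeds a
random comparator value, ties half-weighted — which equals U/(n1*n2).

`CaseControlModel` packages the full analysis as a fitted-model object: build
it from a per-subject DataFrame, call :meth:`~CaseControlModel.fit`, and read
the per-comparison table off the results.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats as sps

if TYPE_CHECKING:  # pragma: no cover
    from bpequant.metrics import QuantResult
    from bpequant.phantom import PhantomSpec

MAX_AGE_GAP_YEARS = 5.0
PHASE_NAMES = ("early", "mid", "late")


@dataclass
class SubjectRecord:
    """One subject: demographics, group membership and (once measured) the
    quantitative result. ``menstrual_week`` is set only for premenopausal
    subjects; ``lesion_side`` only for the benign and cancer groups."""

    subject_id: str
    group: str  # control | benign | cancer
    age: float
    menopause: str  # pre | post
    menstrual_week: Optional[int] = None
    lesion_side: Optional[str] = None  # left | right
    quant: Optional["QuantResult"] = None
    phantom: Optional["PhantomSpec"] = None


@dataclass
class ComparisonResult:
    """One row of the comparison tables: a metric at a phase within a
    menopause stratum, cancer group versus one comparator group."""

    metric: str
    stratum: str
    phase: Optional[str]
    contrast: str  # e.g. "cancer_vs_control"
    cancer_median: float  # percent
    other_median: float  # percent
    n_cancer: int
    n_other: int
    u_statistic: float
    p_value: float
    auc: float


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two independent samples.

    Returns ``(U, p)`` with U the statistic of the first sample. The p-value
    is exact (full enumeration) when n1+n2 <= 12 and the pooled sample is
    tie-free, otherwise the tie-corrected normal approximation with continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def empirical_auc(positive_values, other_values) -> float:
    """Pair-counting AUC: P(positive > other) + 0.5 * P(tie).

    Computed via midranks, which is algebraically the U/(n1*n2) identity.
    """
    pos = np.asarray(positive_values, dtype=float)
    neg = np.asarray(other_values, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def binormal_mean_separation(auc: float) -> float:
    """Mean gap between two unit-variance normal samples that yields the given
    pair-probability AUC: delta = sqrt(2) * Phi^-1(AUC)."""
    if not 0.0 < auc < 1.0:
        raise ValueError("AUC must be in (0, 1)")
    return float(np.sqrt(2.0) * sps.norm.ppf(auc))


def match_cohorts(cases, candidates):
    """Greedy 1:1 matching of cases to candidates.

    A candidate is eligible for a case when menopause status agrees, the
    menstrual week agrees for premenopausal pairs, and the age gap is at most
    five years. Cases are processed in ascending age order (ties broken by
    subject_id); each takes its nearest-age eligible candidate (ties again by
    subject_id) and removes it from the pool.

    Returns ``(pairs, unmatched)`` where pairs is a list of
    ``(case, candidate)`` tuples and unmatched the leftover cases.
    """
    pool = list(candidates)
    pairs = []
    unmatched = []
    for case in sorted(cases, key=lambda r: (r.age, r.subject_id)):
        eligible = [
            c
            for c in pool
            if c.menopause == case.menopause
            and (case.menopause != "pre" or c.menstrual_week == case.menstrual_week)
            and abs(c.age - case.age) <= MAX_AGE_GAP_YEARS
        ]
        if not eligible:
            unmatched.append(case)
            continue
        best = min(eligible, key=lambda c: (abs(c.age - case.age), c.subject_id))
        pool.remove(best)
        pairs.append((case, best))
    return pairs, unmatched


def _metric_value(record: SubjectRecord, metric: str, phase_idx: Optional[int]) -> float:
    q = record.quant
    if q is None:
        return np.nan
    if metric == "fgt":
        return q.fgt
    vals = getattr(q, metric)
    return vals[phase_idx]


def compare_groups(records, metric, stratum, phase=None):
    """Compare cancer against control and against benign for one metric.

    ``phase`` is an index 0/1/2 (early/mid/late) for BPE metrics and None for
    FGT. Records with missing (NaN) values are dropped listwise. Returns one
    :class:`ComparisonResult` per contrast.
    """
    in_stratum = [r for r in records if r.menopause == stratum]
    by_group = {}
    for g in ("cancer", "control", "benign"):
        vals = np.array(
            [_metric_value(r, metric, phase) for r in in_stratum if r.group == g]
        )
        by_group[g] = vals[~np.isnan(vals)]
    if by_group["cancer"].size < 2:
        raise ValueError(f"stratum {stratum!r} has fewer than 2 cancer records")

    out = []
    for other in ("control", "benign"):
        if by_group[other].size < 2:
            raise ValueError(f"stratum {stratum!r} has fewer than 2 {other} records")
        u, p = mann_whitney_u(by_group["cancer"], by_group[other])
        auc = empirical_auc(by_group["cancer"], by_group[other])
        out.append(
            ComparisonResult(
                metric=metric,
                stratum=stratum,
                phase=None if phase is None else PHASE_NAMES[phase],
                contrast=f"cancer_vs_{other}",
                cancer_median=float(np.median(by_group["cancer"])) * 100.0,
                other_median=float(np.median(by_group[other])) * 100.0,
                n_cancer=int(by_group["cancer"].size),
                n_other=int(by_group[other].size),
                u_statistic=u,
                p_value=p,
                auc=auc,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

_LONG_COLUMNS = [
    "metric",
    "stratum",
    "phase",
    "contrast",
    "cancer_pct",
    "comparator_pct",
    "n_cancer",
    "n_comparator",
    "U",
    "P",
    "AUC",
]


class CaseControlModel:
    """Case-control discrimination analysis over a measured cohort.

    Parameters
    ----------
    records : list of SubjectRecord
        Subjects with their quantitative results attached.
    metrics : sequence of str
        Which metrics to analyse (default all three).
    strata : sequence of str
        Menopause strata (default pre and post).
    """

    def __init__(self, records, metrics=("fgt", "bpe_v", "bpe_i"), strata=("pre", "post")):
        self.records = list(records)
        self.metrics = tuple(metrics)
        self.strata = tuple(strata)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CaseControlModel":
        """Build from a per-subject table with columns subject_id, group, age,
        menopause, menstrual_week, lesion_side, fgt, and bpe_v_/bpe_i_ columns
        suffixed early/mid/late (fractions, not percent)."""
        from bpequant.metrics import QuantResult

        records = []
        for row in df.itertuples(index=False):
            d = row._asdict()
            quant = QuantResult(
                fgt=float(d["fgt"]),
                bpe_v=tuple(float(d[f"bpe_v_{p}"]) for p in PHASE_NAMES),
                bpe_i=tuple(float(d[f"bpe_i_{p}"]) for p in PHASE_NAMES),
                side=str(d.get("side", "combined")),
            )
            week = d.get("menstrual_week")
            records.append(
                SubjectRecord(
                    subject_id=str(d["subject_id"]),
                    group=str(d["group"]),
                    age=float(d["age"]),
                    menopause=str(d["menopause"]),
                    menstrual_week=None if pd.isna(week) else int(week),
                    lesion_side=d.get("lesion_side"),
                    quant=quant,
                )
            )
        return cls(records, **kwargs)

    def fit(self) -> "CaseControlResults":
        rows = []
        for metric, stratum in itertools.product(self.metrics, self.strata):
            phases = (None,) if metric == "fgt" else (0, 1, 2)
            for phase in phases:
                rows.extend(compare_groups(self.records, metric, stratum, phase))
        return CaseControlResults(self, rows)


class CaseControlResults:
    """Fitted comparison table with tabular and pretty-printed views."""

    def __init__(self, model: CaseControlModel, comparisons):
        self.model = model
        self.comparisons = list(comparisons)

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            (
                c.metric,
                c.stratum,
                c.phase if c.phase is not None else "",
                c.contrast,
                c.cancer_median,
                c.other_median,
                c.n_cancer,
                c.n_other,
                c.u_statistic,
                c.p_value,
                c.auc,
            )
            for c in self.comparisons
        ]
        return pd.DataFrame(rows, columns=_LONG_COLUMNS)

    def max_auc(self, metric: str, stratum: str, contrast: str = "cancer_vs_control"):
        """The most discriminative phase of a metric within a stratum."""
        rows = [
            c
            for c in self.comparisons
            if c.metric == metric and c.stratum == stratum and c.contrast == contrast
        ]
        best = max(rows, key=lambda c: c.auc)
        return best.phase, best.auc

    def summary(self) -> str:
        df = self.table.copy()
        for col in ("cancer_pct", "comparator_pct"):
            df[col] = df[col].map(lambda v: f"{v:.2f}")
        df["P"] = df["P"].map(lambda v: f"{v:.3f}")
        df["AUC"] = df["AUC"].map(lambda v: f"{v:.3f}")
        header = "Case-control discrimination (Mann-Whitney U, empirical AUC)\n"
        return header + df.to_string(index=False)

    def __repr__(self):
        return f"<CaseControlResults: {len(self.comparisons)} comparisons>"
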