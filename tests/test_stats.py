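"""Matching, Mann-Whitney U, empirical AUC and the case-control model."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from bpequant.metrics import QuantResult
from bpequant.stats import (
    CaseControlModel,
    SubjectRecord,
    binormal_mean_separation,
    compare_groups,
    empirical_auc,
    mann_whitney_u,
    match_cohorts,
)


def brute_force_auc(pos, neg):
    """Oracle: count pairs directly."""
    wins = sum(1.0 for p in pos for n in neg if p > n)
    ties = sum(0.5 for p in pos for n in neg if p == n)
    return (wins + ties) / (len(pos) * len(neg))


def enumeration_p_value(x, y):
    """Oracle: exact two-sided Mann-Whitney p by enumerating all labelings."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(first):
        rest = [v for i, v in enumerate(pooled) if i not in set(first)]
        vals = [pooled[i] for i in first]
        return sum(1.0 for a in vals for b in rest if a > b)

    u_obs = sum(1.0 for a in x for b in y if a > b)
    us = [u_stat(c) for c in itertools.combinations(range(len(pooled)), n1)]
    mean_u = n1 * (len(pooled) - n1) / 2.0
    extreme = sum(1 for u in us if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12)
    return extreme / len(us)


def _rec(sid, group, value, stratum="pre", week=2, age=45):
    q = QuantResult(fgt=value, bpe_v=(value,) * 3, bpe_i=(value,) * 3)
    return SubjectRecord(sid, group, age, stratum,
                         menstrual_week=week if stratum == "pre" else None,
                         lesion_side=None if group == "control" else "left",
                         quant=q)


class TestMatchCohorts:
    def test_nearest_age_candidate_wins(self):
        case = SubjectRecord("a", "cancer", 41, "pre", 2, "left")
        c1 = SubjectRecord("b", "control", 43, "pre", 2)
        c2 = SubjectRecord("c", "control", 48, "pre", 2)
        pairs, unmatched = match_cohorts([case], [c1, c2])
        assert pairs == [(case, c1)] and not unmatched

    def test_age_gap_over_five_years_unmatched(self):
        case = SubjectRecord("a", "cancer", 41, "pre", 2, "left")
        cand = SubjectRecord("b", "control", 49, "pre", 2)
        pairs, unmatched = match_cohorts([case], [cand])
        assert not pairs and unmatched == [case]

    def test_menopause_status_must_agree(self):
        case = SubjectRecord("a", "cancer", 50, "post", None, "left")
        cand = SubjectRecord("b", "control", 50, "pre", 2)
        pairs, unmatched = match_cohorts([case], [cand])
        assert not pairs and unmatched == [case]

    def test_menstrual_week_must_agree_for_premenopausal(self):
        case = SubjectRecord("a", "cancer", 41, "pre", 1, "left")
        cand = SubjectRecord("b", "control", 41, "pre", 3)
        pairs, unmatched = match_cohorts([case], [cand])
        assert not pairs and unmatched == [case]

    def test_each_candidate_used_once_and_order_invariant(self):
        cases = [SubjectRecord(f"x{i}", "cancer", 40 + i, "post", None, "left") for i in range(3)]
        cands = [SubjectRecord(f"y{i}", "control", 40 + i, "post", None) for i in range(3)]
        pairs1, _ = match_cohorts(cases, cands)
        pairs2, _ = match_cohorts(cases[::-1], cands[::-1])
        key = lambda ps: sorted((a.subject_id, b.subject_id) for a, b in ps)
        assert key(pairs1) == key(pairs2)
        assert len({b.subject_id for _, b in pairs1}) == 3


class TestMannWhitneyU:
    def test_exact_small_sample(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)
        assert p == pytest.approx(enumeration_p_value([1, 2], [3, 4]))

    def test_complete_tie_gives_p_one(self):
        _, p = mann_whitney_u([5.0], [5.0])
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 5, 2)
        pooled = rng.permutation(np.arange(20.0))[: n1 + n2]  # tie-free
        x, y = pooled[:n1], pooled[n1:]
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(enumeration_p_value(x, y), abs=1e-12)

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(12345)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            _, p = mann_whitney_u(x, y)
            rejections += p < 0.05
        assert 0.04 <= rejections / reps <= 0.06

    def test_exact_and_normal_approximation_agree_at_n6(self):
        rng = np.random.default_rng(7)
        pooled = rng.permutation(np.arange(50.0))[:12]
        x, y = pooled[:6], pooled[6:]
        _, p_exact = mann_whitney_u(x, y)
        p_norm = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert abs(p_exact - p_norm) < 0.02

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestEmpiricalAuc:
    def test_examples(self):
        assert empirical_auc([10, 11], [1, 2]) == 1.0
        assert empirical_auc([2, 4], [1, 3]) == 0.75
        assert empirical_auc([1, 2, 3], [1, 2, 3]) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        # 50 pairs per seed, integer-valued so ties occur
        for _ in range(50):
            pos = rng.integers(0, 8, rng.integers(1, 8)).astype(float)
            neg = rng.integers(0, 8, rng.integers(1, 8)).astype(float)
            assert empirical_auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_u_identity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, rng.integers(2, 10)).astype(float)
        y = rng.integers(0, 6, rng.integers(2, 10)).astype(float)
        u, _ = mann_whitney_u(x, y)
        assert empirical_auc(x, y) == pytest.approx(u / (len(x) * len(y)), abs=1e-12)

    def test_complement_symmetry_tie_free(self):
        rng = np.random.default_rng(3)
        pooled = rng.permutation(np.arange(30.0))
        x, y = pooled[:12], pooled[12:20]
        assert empirical_auc(x, y) + empirical_auc(y, x) == pytest.approx(1.0)

    def test_binormal_separation_roundtrip(self):
        rng = np.random.default_rng(9)
        delta = binormal_mean_separation(0.715)
        x = rng.normal(delta, 1.0, 4000)
        y = rng.normal(0.0, 1.0, 4000)
        assert empirical_auc(x, y) == pytest.approx(0.715, abs=0.02)


class TestCompareGroups:
    def _records(self):
        rng = np.random.default_rng(0)
        recs = []
        for g, shift in (("control", 0.0), ("benign", 0.05), ("cancer", 0.15)):
            for i in range(20):
                recs.append(_rec(f"{g}{i}", g, 0.3 + shift + 0.05 * rng.normal()))
        return recs

    def test_auc_field_matches_empirical_auc_exactly(self):
        recs = self._records()
        res = compare_groups(recs, "bpe_v", "pre", phase=1)
        cancer = [r.quant.bpe_v[1] for r in recs if r.group == "cancer"]
        control = [r.quant.bpe_v[1] for r in recs if r.group == "control"]
        cvc = [c for c in res if c.contrast == "cancer_vs_control"][0]
        assert cvc.auc == empirical_auc(cancer, control)
        assert cvc.phase == "mid"

    def test_identical_groups_are_null(self):
        recs = []
        for g in ("control", "benign", "cancer"):
            for i in range(15):
                recs.append(_rec(f"{g}{i}", g, 0.2 + 0.01 * i))
        for c in compare_groups(recs, "fgt", "pre"):
            assert c.auc == pytest.approx(0.5)
            assert c.p_value > 0.9

    def test_missing_values_dropped_listwise(self):
        recs = self._records()
        recs[0].quant = QuantResult(fgt=math.nan, bpe_v=(math.nan,) * 3, bpe_i=(math.nan,) * 3)
        res = compare_groups(recs, "fgt", "pre")
        assert res[0].n_other == 19  # one control dropped


class TestCaseControlModel:
    def test_fit_produces_full_comparison_table(self):
        rng = np.random.default_rng(1)
        recs = []
        for stratum in ("pre", "post"):
            for g, shift in (("control", 0.0), ("benign", 0.02), ("cancer", 0.1)):
                for i in range(10):
                    recs.append(_rec(f"{stratum}{g}{i}", g, 0.25 + shift + 0.03 * rng.normal(),
                                     stratum=stratum))
        results = CaseControlModel(recs).fit()
        # (1 fgt + 3 bpe_v + 3 bpe_i phases) x 2 strata x 2 contrasts
        assert len(results.comparisons) == 28
        table = results.table
        assert set(table["contrast"]) == {"cancer_vs_control", "cancer_vs_benign"}
        assert "AUC" in table.columns and table["AUC"].between(0, 1).all()
        phase, auc = results.max_auc("bpe_v", "pre")
        assert phase in ("early", "mid", "late") and 0 <= auc <= 1
        assert "Mann-Whitney" in results.summary()

    def test_from_dataframe_roundtrip(self):
        rng = np.random.default_rng(2)
        recs = []
        for g in ("control", "benign", "cancer"):
            for i in range(8):
                recs.append(_rec(f"{g}{i}", g, 0.2 + 0.1 * rng.uniform()))
        rows = []
        for r in recs:
            row = {"subject_id": r.subject_id, "group": r.group, "age": r.age,
                   "menopause": r.menopause, "menstrual_week": r.menstrual_week,
                   "lesion_side": r.lesion_side, "fgt": r.quant.fgt}
            for j, p in enumerate(("early", "mid", "late")):
                row[f"bpe_v_{p}"] = r.quant.bpe_v[j]
                row[f"bpe_i_{p}"] = r.quant.bpe_i[j]
            rows.append(row)
        import pandas as pd

        model = CaseControlModel.from_dataframe(pd.DataFrame(rows), strata=("pre",))
        direct = CaseControlModel(recs, strata=("pre",))
        t1, t2 = model.fit().table, direct.fit().table
        pd.testing.assert_frame_equal(t1, t2)
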