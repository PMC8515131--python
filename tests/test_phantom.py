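"""Phantom generator: determinism, mask nesting, truth recovery, cohorts."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.special import expit, logit

from bpequant.phantom import (
    CohortSpec,
    PhantomSpec,
    make_cohort,
    make_phantom,
    recovery_cohort_specs,
    true_metrics,
)


class TestMakePhantom:
    def test_seeded_determinism(self, small_spec):
        s1, g1 = make_phantom(small_spec)
        s2, g2 = make_phantom(small_spec)
        np.testing.assert_array_equal(s1.pre, s2.pre)
        for a, b in zip(s1.posts, s2.posts):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(g1.fgt_mask, g2.fgt_mask)
        for a, b in zip(g1.enhanced_masks, g2.enhanced_masks):
            np.testing.assert_array_equal(a, b)

    def test_zero_fgt_fraction_gives_empty_gland(self, small_spec):
        spec = replace(small_spec, fgt_fraction_true=0.0,
                       enhanced_fraction_true=(0.0, 0.0, 0.0))
        _, gt = make_phantom(spec)
        assert not gt.fgt_mask.any()
        assert gt.true_fgt == 0.0

    def test_fgt_voxel_ratio_matches_construction_target(self, small_phantom):
        _, gt = small_phantom
        ratio = gt.fgt_mask.sum() / gt.breast_mask.sum()
        assert abs(ratio - 0.164) < 0.01

    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_mask_nesting(self, seed):
        spec = PhantomSpec(grid_shape=(48, 48, 48), breast_radius=10.0,
                           chest_wall_depth=6.0, seed=seed)
        _, gt = make_phantom(spec)
        assert not (gt.fgt_mask & ~gt.breast_mask).any()
        for m in gt.enhanced_masks:
            assert not (m & ~gt.fgt_mask).any()

    def test_monotone_kinetics_gives_monotone_bpe_v(self, small_phantom):
        _, gt = small_phantom
        v = gt.true_bpe_v
        assert v[0] <= v[1] <= v[2]

    def test_noiseless_volumes_are_piecewise_constant(self, noiseless_phantom):
        _, (series, gt) = noiseless_phantom
        assert np.unique(series.pre).size <= 5  # one intensity per tissue class
        sub = series.posts[0] - series.pre
        assert np.all(sub[~gt.enhanced_masks[0]] == 0)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(grid_shape=(0, 64, 64)),
            dict(fgt_fraction_true=1.2),
            dict(enhanced_fraction_true=(0.5, 0.4, 0.3)),  # violates monotone kinetics
            dict(noise_sigma=-1.0),
        ],
    )
    def test_invalid_specs_raise(self, bad):
        with pytest.raises(ValueError):
            make_phantom(PhantomSpec(**bad))


class TestTrueMetrics:
    def test_identity_cases(self, small_phantom):
        _, gt = small_phantom
        q = true_metrics(gt)
        assert q.fgt == gt.fgt_mask.sum() / gt.breast_mask.sum()
        # enhanced == fgt at every phase => BPE_V = 1
        gt2 = replace_masks(gt, enhanced=[gt.fgt_mask.copy()] * 3)
        assert true_metrics(gt2).bpe_v == (1.0, 1.0, 1.0)
        # fgt == breast => FGT = 1
        gt3 = replace_masks(gt, fgt=gt.breast_mask.copy(),
                            enhanced=[gt.breast_mask.copy()] * 3)
        assert true_metrics(gt3).fgt == 1.0

    def test_voxel_counting_oracle_for_enhanced_fractions(self):
        spec = PhantomSpec(grid_shape=(64, 64, 64), breast_radius=13.0,
                           chest_wall_depth=8.0,
                           enhanced_fraction_true=(0.2, 0.4, 0.5), seed=5)
        _, gt = make_phantom(spec)
        q = true_metrics(gt)
        # independent count: enhanced voxels / FGT voxels, phase by phase
        n_fgt = gt.fgt_mask.sum()
        for measured, mask, target in zip(q.bpe_v, gt.enhanced_masks, (0.2, 0.4, 0.5)):
            assert measured == mask.sum() / n_fgt
            assert abs(measured - target) < 0.01

    def test_empty_breast_raises(self, small_phantom):
        _, gt = small_phantom
        bad = replace_masks(gt, breast=np.zeros_like(gt.breast_mask),
                            fgt=np.zeros_like(gt.fgt_mask),
                            enhanced=[np.zeros_like(m) for m in gt.enhanced_masks])
        with pytest.raises(ValueError):
            true_metrics(bad)


def replace_masks(gt, breast=None, fgt=None, enhanced=None):
    from bpequant.phantom import GroundTruth

    return GroundTruth(
        breast_mask=gt.breast_mask if breast is None else breast,
        fgt_mask=gt.fgt_mask if fgt is None else fgt,
        enhanced_masks=gt.enhanced_masks if enhanced is None else enhanced,
        true_fgt=gt.true_fgt,
        true_bpe_v=gt.true_bpe_v,
        true_bpe_i=gt.true_bpe_i,
    )


class TestMakeCohort:
    def test_study_population_structure(self):
        records = make_cohort(CohortSpec(seed=1))
        assert len(records) == 396
        for group in ("control", "benign", "cancer"):
            in_group = [r for r in records if r.group == group]
            assert len(in_group) == 132
            pre = [r for r in in_group if r.menopause == "pre"]
            assert len(pre) == 62
            weeks = [sum(1 for r in pre if r.menstrual_week == w) for w in (1, 2, 3, 4)]
            assert weeks == [13, 16, 15, 18]

    def test_metadata_consistency(self):
        for r in make_cohort(CohortSpec(seed=2)):
            assert (r.menstrual_week is not None) == (r.menopause == "pre")
            assert (r.lesion_side is not None) == (r.group != "control")
            assert r.phantom is not None

    def test_empty_cohort(self):
        spec = CohortSpec(group_sizes={g: 0 for g in ("control", "benign", "cancer")},
                          premenopausal_per_group=0, week_counts=(0, 0, 0, 0))
        assert make_cohort(spec) == []

    def test_reproducible_given_seed(self):
        a = make_cohort(CohortSpec(seed=9))
        b = make_cohort(CohortSpec(seed=9))
        assert [(r.subject_id, r.age, r.menstrual_week, r.lesion_side) for r in a] == [
            (r.subject_id, r.age, r.menstrual_week, r.lesion_side) for r in b
        ]
        assert all(x.phantom == y.phantom for x, y in zip(a, b))

    def test_inconsistent_strata_raise(self):
        with pytest.raises(ValueError):
            CohortSpec(week_counts=(13, 16, 15, 17)).validate()


class TestRecoveryCohort:
    def test_stratified_medians_hit_construction_targets(self):
        specs = recovery_cohort_specs(n=40, seed=3)
        med_fgt = np.median([s.fgt_fraction_true for s in specs])
        med_v_mid = np.median([s.enhanced_fraction_true[1] for s in specs])
        assert abs(med_fgt - 0.164) < 1e-3
        assert abs(med_v_mid - 0.481) < 1e-3

    def test_subject_kinetics_monotone(self):
        for s in recovery_cohort_specs(n=10, seed=4):
            e = s.enhanced_fraction_true
            assert e[0] <= e[1] <= e[2]
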