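import numpy as np
import pytest
from dataclasses import replace

from provseg.cohort import (
    DegradationSpec,
    PhantomSpec,
    degrade_contour,
    generate_cohort,
    generate_phantom_pair,
    make_fold_splits,
    mirror_case,
)
from provseg.metrics import dice
from provseg.types import LEFT, RIGHT


def principal_axis_angle_deg(mask, label):
    """Angle between a structure's principal axis and the axial plane."""
    pts = np.argwhere(mask.labels == label) * np.array(mask.spacing)
    pts = pts - pts.mean(axis=0)
    _, vecs = np.linalg.eigh(pts.T @ pts / len(pts))
    pa = vecs[:, -1]
    return np.degrees(np.arcsin(abs(pa[0]) / np.linalg.norm(pa)))


class TestGeneratePhantomPair:
    def test_fixed_seed_determinism(self, tiny_phantom_spec):
        a = generate_phantom_pair(tiny_phantom_spec, "a")
        b = generate_phantom_pair(tiny_phantom_spec, "a")
        assert np.array_equal(a.mr_volume.values, b.mr_volume.values)
        assert np.array_equal(a.ct_volume.values, b.ct_volume.values)
        assert np.array_equal(a.gt_mask_mr.labels, b.gt_mask_mr.labels)
        assert np.array_equal(a.degraded_mask_ct.labels, b.degraded_mask_ct.labels)
        assert np.array_equal(a.true_affine.matrix, b.true_affine.matrix)

    def test_default_inclination_near_20_degrees(self):
        rec = generate_phantom_pair(PhantomSpec(seed=4), "c")
        for lab in (LEFT, RIGHT):
            angle = principal_axis_angle_deg(rec.gt_mask_ct, lab)
            assert abs(angle - 20.0) < 3.0
            # in the tilted contouring frame the axis lies in-plane
            assert principal_axis_angle_deg(rec.gt_mask_mr, lab) < 3.0

    def test_zero_jitter_zero_tilt_gives_identity_frames(self, tiny_phantom_spec):
        spec = replace(tiny_phantom_spec, affine_jitter=(0.0, 0.0), inclination_deg=0.0)
        rec = generate_phantom_pair(spec, "c")
        assert rec.true_affine.is_identity()
        assert np.array_equal(rec.gt_mask_mr.labels, rec.gt_mask_ct.labels)

    def test_structure_overlaps_across_frames_through_true_affine(self, tiny_case):
        # mapping the MR ground truth through tilt reversal + true affine must
        # land on the CT-frame structure
        from provseg.preprocess import propagate_contour

        prop = propagate_contour(
            tiny_case.gt_mask_mr, tiny_case.tilt_angle_deg, tiny_case.true_affine,
            smooth_sd_mm=1.0, target=tiny_case.gt_mask_ct.grid,
        )
        for lab in (LEFT, RIGHT):
            assert dice(prop.side(lab), tiny_case.gt_mask_ct.side(lab)) > 0.6

    def test_mr_contrast_to_noise_exceeds_ct(self, tiny_case, tiny_phantom_spec):
        for vol, mask, sd in (
            (tiny_case.mr_volume, tiny_case.gt_mask_mr, tiny_phantom_spec.noise_sd_mr),
            (tiny_case.ct_volume, tiny_case.gt_mask_ct, tiny_phantom_spec.noise_sd_ct),
        ):
            fg = vol.values[mask.labels != 0].mean()
            bg = vol.values[mask.labels == 0].mean()
            vol._cnr = (fg - bg) / sd
        assert tiny_case.mr_volume._cnr > 2.0 * tiny_case.ct_volume._cnr

    def test_low_mr_contrast_rejected(self, tiny_phantom_spec):
        spec = replace(tiny_phantom_spec, contrast_mr=5.0, noise_sd_mr=10.0)
        with pytest.raises(ValueError, match="contrast-to-noise"):
            generate_phantom_pair(spec, "c")

    def test_oversized_structure_rejected_with_margin_diagnostic(self, tiny_phantom_spec):
        spec = replace(tiny_phantom_spec, structure_length_mm=60.0)
        with pytest.raises(ValueError, match="margin"):
            generate_phantom_pair(spec, "c")

    def test_mask_invariants(self, tiny_case):
        tiny_case.validate()  # one component per label, sides split by midplane


class TestDegradeContour:
    def test_zero_noise_is_identity(self, tiny_case):
        deg = DegradationSpec(0.0, 0.0, 0.0, 0.0, seed=0)
        out = degrade_contour(tiny_case.gt_mask_ct, deg)
        assert np.array_equal(out.labels, tiny_case.gt_mask_ct.labels)
        for lab in (LEFT, RIGHT):
            assert dice(out.side(lab), tiny_case.gt_mask_ct.side(lab)) == 1.0

    def test_mean_dice_decreases_when_noise_doubles(self, tiny_case):
        def mean_dice(boundary_sd, n=20):
            vals = []
            for s in range(n):
                deg = DegradationSpec(boundary_noise_sd_mm=boundary_sd, global_shift_sd_mm=0.0,
                                      per_slice_jitter_sd_mm=0.0, dropout_prob_slice=0.0, seed=s)
                out = degrade_contour(tiny_case.gt_mask_ct, deg)
                for lab in (LEFT, RIGHT):
                    vals.append(dice(out.side(lab), tiny_case.gt_mask_ct.side(lab)))
            return np.mean(vals)

        assert mean_dice(2.0) < mean_dice(1.0) < mean_dice(0.5)

    def test_each_scale_monotonically_degrades(self, tiny_case):
        base = dict(boundary_noise_sd_mm=0.5, global_shift_sd_mm=0.5,
                    per_slice_jitter_sd_mm=0.5, dropout_prob_slice=0.1)

        def mean_dice(**kw):
            params = {**base, **kw}
            vals = []
            for s in range(15):
                out = degrade_contour(tiny_case.gt_mask_ct, DegradationSpec(seed=s, **params))
                for lab in (LEFT, RIGHT):
                    vals.append(dice(out.side(lab), tiny_case.gt_mask_ct.side(lab)))
            return np.mean(vals)

        ref = mean_dice()
        assert mean_dice(global_shift_sd_mm=2.5) < ref
        assert mean_dice(per_slice_jitter_sd_mm=2.5) < ref
        assert mean_dice(dropout_prob_slice=0.9) < ref

    def test_emptied_label_raises(self, tiny_case):
        deg = DegradationSpec(boundary_noise_sd_mm=0.0, global_shift_sd_mm=60.0,
                              per_slice_jitter_sd_mm=0.0, dropout_prob_slice=0.0, seed=0)
        with pytest.raises(ValueError, match="emptied foreground label"):
            degrade_contour(tiny_case.gt_mask_ct, deg)

    def test_geometry_preserved(self, tiny_case):
        out = degrade_contour(tiny_case.gt_mask_ct, DegradationSpec(seed=3))
        assert out.grid == tiny_case.gt_mask_ct.grid


class TestFoldSplits:
    def test_reference_cohort_arithmetic(self):
        rng = np.random.default_rng(0)
        ids = [f"case_{i:03d}" for i in range(45)]
        splits = make_fold_splits(ids, 5, rng)
        assert len(splits) == 5
        for s in splits:
            assert (len(s.train_ids), len(s.validation_ids), len(s.test_ids)) == (27, 9, 9)
        tests = [cid for s in splits for cid in s.test_ids]
        assert len(tests) == 45 and set(tests) == set(ids)

    def test_small_cohort_keeps_3_1_1_arithmetic(self):
        splits = make_fold_splits([f"c{i}" for i in range(10)], 5, np.random.default_rng(0))
        for s in splits:
            assert (len(s.train_ids), len(s.validation_ids), len(s.test_ids)) == (6, 2, 2)

    def test_indivisible_cohort_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            make_fold_splits([f"c{i}" for i in range(7)], 5, np.random.default_rng(0))

    def test_within_fold_disjoint(self):
        for s in make_fold_splits([f"c{i}" for i in range(20)], 5, np.random.default_rng(2)):
            all_ids = list(s.train_ids) + list(s.validation_ids) + list(s.test_ids)
            assert len(all_ids) == len(set(all_ids)) == 20


class TestGenerateCohort:
    def test_cohort_determinism_and_splits(self, tiny_phantom_spec):
        deg = DegradationSpec(seed=0)
        rec1, splits1 = generate_cohort(6, tiny_phantom_spec, deg, 3, seed=9)
        rec2, splits2 = generate_cohort(6, tiny_phantom_spec, deg, 3, seed=9)
        assert [r.case_id for r in rec1] == [r.case_id for r in rec2]
        for a, b in zip(rec1, rec2):
            assert np.array_equal(a.ct_volume.values, b.ct_volume.values)
            assert np.array_equal(a.degraded_mask_ct.labels, b.degraded_mask_ct.labels)
        assert splits1 == splits2
        for s in splits1:
            assert (len(s.train_ids), len(s.validation_ids), len(s.test_ids)) == (2, 2, 2)

    def test_case_seeds_differ(self, tiny_phantom_spec):
        recs, _ = generate_cohort(3, tiny_phantom_spec, DegradationSpec(seed=0), 3, seed=1)
        assert not np.array_equal(recs[0].ct_volume.values, recs[1].ct_volume.values)


def test_mirror_case_is_valid_and_involutive(tiny_case):
    mirrored = mirror_case(tiny_case)
    mirrored.validate()
    back = mirror_case(mirrored)
    assert np.array_equal(back.gt_mask_mr.labels, tiny_case.gt_mask_mr.labels)
    assert np.array_equal(back.ct_volume.values, tiny_case.ct_volume.values)
    # labels swapped: left voxel count of the mirror equals original right count
    assert mirrored.gt_mask_mr.side(LEFT).sum() == tiny_case.gt_mask_mr.side(RIGHT).sum()
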