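"""Masking, crop geometry, slice filtering, frequencies and splits."""

import numpy as np
import pytest

from rildseg import preprocess as pp
from rildseg.imaging_io import CTVolume, LabelMap, LungMask, OUTSIDE
from conftest import random_label_volume


def _mask(arr, spacing=(1.0, 1.0, 1.0)):
    return LungMask(np.asarray(arr, dtype=np.uint8), spacing)


class TestMaskLungs:
    def test_identity_under_full_mask(self, one_case):
        full = _mask(np.ones(one_case.volume.shape), one_case.volume.spacing)
        out = pp.mask_lungs(one_case.volume, full)
        assert np.array_equal(out.voxels, one_case.volume.voxels)

    def test_fill_count_equals_outside_voxels(self, rng):
        vox = rng.normal(-500, 100, (4, 6, 8)).astype(np.float32)
        checker = (np.indices(vox.shape).sum(axis=0) % 2).astype(np.uint8)
        out = pp.mask_lungs(CTVolume(vox, (1, 1, 1)), _mask(checker))
        outside = checker == 0
        assert np.all(out.voxels[outside] == pp.FILL_HU)
        assert np.array_equal(out.voxels[~outside], vox[~outside])
        assert int((out.voxels == pp.FILL_HU).sum()) == int(outside.sum())

    def test_empty_mask_rejected(self, one_case):
        empty = _mask(np.zeros(one_case.volume.shape), one_case.volume.spacing)
        with pytest.raises(ValueError, match="empty"):
            pp.mask_lungs(one_case.volume, empty)


class TestComputeCrop:
    def _box_mask(self, h, w, grid=(1, 512, 512)):
        m = np.zeros(grid, dtype=np.uint8)
        m[:, :h, :w] = 1
        return _mask(m)

    def test_fitting_box_keeps_native_resolution(self):
        geo = pp.compute_crop(self._box_mask(200, 300), target=(288, 384))
        assert geo.scale == 1.0
        assert (geo.pad_y, geo.pad_x) == ((288 - 200) // 2, (384 - 300) // 2)

    def test_oversized_box_gets_single_isotropic_scale(self):
        geo = pp.compute_crop(self._box_mask(576, 768, grid=(1, 800, 800)), target=(288, 384))
        assert geo.scale == pytest.approx(0.5)
        assert (geo.scaled_h, geo.scaled_w) == (288, 384)

    def test_exact_fit_boundary(self):
        geo = pp.compute_crop(self._box_mask(288, 384), target=(288, 384))
        assert geo.scale == 1.0 and geo.pad_y == 0 and geo.pad_x == 0

    def test_minimal_downscaling(self):
        # only one axis overflows: s set by that axis alone
        geo = pp.compute_crop(self._box_mask(400, 100, grid=(1, 512, 512)), target=(288, 384))
        assert geo.scale == pytest.approx(288 / 400)


class TestFilterSlices:
    def test_hand_counted_toy(self):
        lab = np.zeros((3, 10, 10), dtype=np.int16)
        mask = np.zeros_like(lab)
        mask[:, :10, :10] = 1  # 100 lung voxels per slice
        lab[mask > 0] = 1
        lab[1, 0, 0] = 2            # 1% exactly -> retained (>= tau)
        lab[2, 0, :5] = 3           # 5%
        retained, frac = pp.filter_slices(
            LabelMap(lab, (1, 1, 1)), _mask(mask)
        )
        assert retained == [1, 2]
        assert frac[1] == pytest.approx(0.01)

    def test_all_normal_volume_keeps_nothing(self, small_cohort):
        case = small_cohort[0][0]
        normal = LabelMap(
            np.where(case.lung_mask.bool, 1, OUTSIDE), case.labels.spacing
        )
        retained, _ = pp.filter_slices(normal, case.lung_mask)
        assert retained == []

    def test_tau_zero_retains_every_lung_slice(self, one_case):
        retained, _ = pp.filter_slices(one_case.labels, one_case.lung_mask, tau=0.0)
        lungy = np.flatnonzero(one_case.lung_mask.voxels.any(axis=(1, 2)))
        assert retained == lungy.tolist()

    def test_matches_bruteforce_counter(self, rng):
        for _ in range(100):
            labels, mask = random_label_volume(rng)
            retained, frac = pp.filter_slices(
                LabelMap(labels, (1, 1, 1)), _mask(mask), tau=0.01
            )
            expected = []
            for z in range(labels.shape[0]):
                lung = path = 0
                for y in range(labels.shape[1]):
                    for x in range(labels.shape[2]):
                        if mask[z, y, x]:
                            lung += 1
                            if labels[z, y, x] >= 2:
                                path += 1
                if lung and path / lung >= 0.01:
                    expected.append(z)
            assert retained == expected

    def test_bad_threshold_rejected(self, one_case):
        with pytest.raises(ValueError):
            pp.filter_slices(one_case.labels, one_case.lung_mask, tau=1.5)


class TestMakeSamples:
    def test_shapes_range_and_provenance(self, one_case):
        plan = pp.plan_case(one_case, target=(288, 384))
        samples = pp.make_samples(one_case, plan)
        assert len(samples) == len(plan.retained)
        for s in samples[:3]:
            assert s.image.shape == (288, 384) and s.labels.shape == (288, 384)
            assert 0.0 <= s.image.min() and s.image.max() <= 1.0
            assert s.slice_index in plan.retained

    def test_label_histogram_conserved_at_unit_scale(self, one_case):
        plan = pp.plan_case(one_case, target=(64, 96))
        assert plan.crop.scale == 1.0
        s = pp.make_samples(one_case, plan)[0]
        geo = plan.crop
        src = one_case.labels.voxels[s.slice_index, geo.y0:geo.y1, geo.x0:geo.x1]
        assert np.array_equal(
            np.bincount(src.ravel(), minlength=6)[1:],
            np.bincount(s.labels.ravel(), minlength=6)[1:],
        )

    def test_plan_case_mismatch_rejected(self, small_cohort):
        cases, _ = small_cohort
        plan = pp.plan_case(cases[0], target=(64, 96))
        with pytest.raises(ValueError):
            pp.make_samples(cases[1], plan)


class TestGeometryRoundTrip:
    def test_unit_scale_exact_inverse(self, one_case):
        plan = pp.plan_case(one_case, target=(64, 96))
        geo = plan.crop
        z = plan.retained[0]
        pred = geo.apply_labels(one_case.labels.voxels[z])
        back = geo.map_back(pred, one_case.labels.shape[1:])
        inb = np.zeros(one_case.labels.shape[1:], dtype=bool)
        inb[geo.y0:geo.y1, geo.x0:geo.x1] = True
        assert np.array_equal(back[inb], one_case.labels.voxels[z][inb])

    def test_downscaled_coverage_is_total(self):
        mask = np.zeros((1, 100, 100), dtype=np.uint8)
        mask[0, 5:95, 2:98] = 1
        geo = pp.compute_crop(_mask(mask), target=(48, 64))
        assert geo.scale < 1.0
        pred = np.full((48, 64), 3, dtype=np.int16)
        back = geo.map_back(pred, (100, 100))
        assert np.all(back[5:95, 2:98] == 3)  # one label per source voxel


class TestClassFrequencies:
    def test_all_normal_single_case(self, small_cohort):
        case = small_cohort[0][0]
        normal_case = type(case)(
            case.patient_id, case.timepoint, case.volume, case.lung_mask,
            LabelMap(np.where(case.lung_mask.bool, 1, OUTSIDE), case.labels.spacing),
        )
        f = pp.class_frequencies([normal_case], "all")
        assert np.allclose(f.fractions, [1, 0, 0, 0, 0])

    def test_counts_conserve_lung_voxels(self, small_cohort):
        cases, _ = small_cohort
        f = pp.class_frequencies(cases, "all")
        total = sum(int(c.lung_mask.voxels.sum()) for c in cases)
        assert int(f.counts.sum()) == total

    def test_filtering_enriches_pathology(self, small_cohort):
        cases, _ = small_cohort
        f_all = pp.class_frequencies(cases, "all")
        f_filt = pp.class_frequencies(cases, "filtered")
        assert f_filt.fractions[1:].sum() > f_all.fractions[1:].sum()

    def test_empty_slice_set_rejected(self, small_cohort):
        case = small_cohort[0][0]
        normal_case = type(case)(
            case.patient_id, case.timepoint, case.volume, case.lung_mask,
            LabelMap(np.where(case.lung_mask.bool, 1, OUTSIDE), case.labels.spacing),
        )
        with pytest.raises(ValueError):
            pp.class_frequencies([normal_case], "filtered")


class TestSplits:
    def test_five_folds_of_two(self):
        ids = [f"P{i}" for i in range(10)]
        split = pp.split_patients(ids, K=5, seed=1)
        sizes = [len(split.fold_patients(k)) for k in range(5)]
        assert sizes == [2] * 5
        assert sorted(sum((split.fold_patients(k) for k in range(5)), [])) == sorted(ids)

    def test_split_is_per_patient_not_per_scan(self, small_cohort):
        cases, _ = small_cohort
        scan_ids = [c.patient_id for c in cases]  # repeated across timepoints
        split = pp.split_patients(scan_ids, K=2, seed=0)
        assert sorted(split.assignment) == sorted(set(scan_ids))
        folds = {split.assignment[c.patient_id] for c in cases if c.patient_id == "P000"}
        assert len(folds) == 1

    def test_determinism_and_seed_sensitivity(self):
        ids = [f"P{i}" for i in range(11)]
        a = pp.split_patients(ids, K=5, seed=3)
        b = pp.split_patients(ids, K=5, seed=3)
        c = pp.split_patients(ids, K=5, seed=4)
        assert a.assignment == b.assignment
        assert a.assignment != c.assignment
        sizes = sorted(len(a.fold_patients(k)) for k in range(5))
        assert sizes[-1] - sizes[0] <= 1

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            pp.split_patients(["a", "b"], K=5)

    def test_fixed_split_proportions(self):
        ids = [f"P{i}" for i in range(46)]
        dev, test = pp.fixed_split(ids, test_fraction=6 / 46, seed=0)
        assert len(test) == 6 and len(dev) == 40
        assert not set(dev) & set(test)
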