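"""Multilevel Otsu, local classification, watershed, class selection."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from hma.errors import DegenerateRegionError, ParameterError
from hma.partition import (
    class_select,
    classify_values,
    local_otsu_classify,
    multilevel_otsu,
    watershed_split,
)
from hma.roi import RoiMask
from .oracles import exhaustive_otsu3


def roi_from_mask(mask):
    regions, m = ndi.label(mask, structure=np.ones((3, 3)))
    return RoiMask(mask=mask.astype(bool), regions=regions, m=int(m))


def four_spike_values(rng, n=400):
    return rng.choice([0.05, 0.35, 0.65, 0.95], size=n)


class TestMultilevelOtsu:
    def test_four_spikes_separated(self):
        rng = np.random.default_rng(0)
        vals = np.repeat([0.05, 0.35, 0.65, 0.95], 100)
        t1, t2, t3 = multilevel_otsu(vals, k=3)
        assert 0.05 <= t1 < 0.35
        assert 0.35 <= t2 < 0.65
        assert 0.65 <= t3 < 0.95
        cls = classify_values(vals, (t1, t2, t3))
        for level, expected in zip([0.05, 0.35, 0.65, 0.95], [1, 2, 3, 4]):
            assert np.all(cls[vals == level] == expected)

    @pytest.mark.parametrize("instance", range(10))
    def test_matches_exhaustive_oracle(self, instance):
        rng = np.random.default_rng(100 + instance)
        if instance % 2 == 0:
            vals = rng.uniform(0, 1, 500)
        else:
            vals = np.clip(
                np.concatenate(
                    [rng.normal(0.25, 0.05, 250), rng.normal(0.7, 0.1, 250)]
                ),
                0,
                1,
            )
        assert multilevel_otsu(vals, k=3) == exhaustive_otsu3(vals)

    def test_k1_separates_bimodal_like_classic_otsu(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0.25, 0.02, 300), rng.normal(0.8, 0.02, 300)])
        vals = np.clip(vals, 0, 1)
        (t,) = multilevel_otsu(vals, k=1)
        t_ref = threshold_otsu(vals)
        # both thresholds land in the empty gap between the modes
        assert (vals <= t).sum() == (vals <= t_ref).sum() == 300

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateRegionError):
            multilevel_otsu([0.5] * 10, k=3)
        with pytest.raises(DegenerateRegionError):
            multilevel_otsu([0.1, 0.5, 0.9], k=3)  # only k distinct
        with pytest.raises(ParameterError):
            multilevel_otsu([0.1, 0.2, 0.3, 0.4], k=4)


class TestLocalOtsuClassify:
    def test_four_spike_region_classes_exact(self):
        rng = np.random.default_rng(1)
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:18, 2:18] = True
        ref = np.zeros((20, 20))
        ref[mask] = four_spike_values(rng, mask.sum())
        cm = local_otsu_classify(ref, roi_from_mask(mask))
        for level, expected in zip([0.05, 0.35, 0.65, 0.95], [1, 2, 3, 4]):
            sel = mask & (ref == level)
            assert np.all(cm.labels[sel] == expected)
        assert np.all(cm.labels[~mask] == 0)

    def test_regions_thresholded_independently(self):
        """Two regions with shifted histograms get different thresholds;
        a global threshold set would misclass one of them."""
        rng = np.random.default_rng(2)
        ref = np.zeros((20, 42))
        mask = np.zeros((20, 42), dtype=bool)
        mask[2:18, 2:18] = True
        mask[2:18, 24:40] = True
        left = np.s_[2:18, 2:18]
        right = np.s_[2:18, 24:40]
        ref[left] = rng.choice([0.05, 0.15, 0.25, 0.35], size=(16, 16))
        ref[right] = rng.choice([0.55, 0.65, 0.75, 0.85], size=(16, 16))
        cm = local_otsu_classify(ref, roi_from_mask(mask))
        t_left = cm.thresholds_per_region[1]
        t_right = cm.thresholds_per_region[2]
        assert t_left != t_right
        assert max(t_left) < min(0.55, *t_right)
        # each region uses all four classes locally
        assert set(np.unique(cm.labels[left])) == {1, 2, 3, 4}
        assert set(np.unique(cm.labels[right])) == {1, 2, 3, 4}

    def test_locality_shift_one_region_only(self):
        rng = np.random.default_rng(5)
        ref = rng.uniform(0.2, 0.6, (20, 42))
        mask = np.zeros((20, 42), dtype=bool)
        mask[2:18, 2:18] = True
        mask[2:18, 24:40] = True
        roi = roi_from_mask(mask)
        cm1 = local_otsu_classify(ref, roi)
        ref2 = ref.copy()
        ref2[2:18, 24:40] += 0.3  # shift only region 2
        cm2 = local_otsu_classify(ref2, roi)
        np.testing.assert_array_equal(
            cm1.labels[2:18, 2:18], cm2.labels[2:18, 2:18]
        )
        assert cm1.thresholds_per_region[1] == cm2.thresholds_per_region[1]
        assert cm1.thresholds_per_region[2] != cm2.thresholds_per_region[2]

    def test_degenerate_region_maps_to_dark_class(self):
        ref = np.full((16, 16), 0.5)
        mask = np.zeros((16, 16), dtype=bool)
        mask[4:12, 4:12] = True
        cm = local_otsu_classify(ref, roi_from_mask(mask))
        assert np.all(cm.labels[mask] == 1)

    def test_empty_roi_all_zero(self):
        cm = local_otsu_classify(np.zeros((16, 16)), roi_from_mask(np.zeros((16, 16), bool)))
        assert cm.labels.sum() == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            local_otsu_classify(np.zeros((8, 8)), roi_from_mask(np.zeros((9, 9), bool)))

    def test_partition_property(self, scene_factory):
        """The four class masks are pairwise disjoint and union to the ROI."""
        from hma.roi import max_roi_from_image
        from hma.blur import build_reference_stack

        scene = scene_factory(1)
        roi = max_roi_from_image(scene.image.pixels)
        stack = build_reference_stack(scene.image.pixels)
        cm = local_otsu_classify(stack.get("gauss20"), roi)
        union = np.zeros(roi.mask.shape, dtype=bool)
        total = 0
        for c in (1, 2, 3, 4):
            sel = class_select(cm, {c})
            assert not (sel & union).any()
            union |= sel
            total += sel.sum()
        np.testing.assert_array_equal(union, roi.mask)
        assert total == roi.mask.sum()


class TestClassSelect:
    def test_complement_within_roi(self):
        rng = np.random.default_rng(7)
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:18, 2:18] = True
        ref = np.zeros((20, 20))
        ref[mask] = four_spike_values(rng, mask.sum())
        cm = local_otsu_classify(ref, roi_from_mask(mask))
        all_classes = class_select(cm, {1, 2, 3, 4})
        np.testing.assert_array_equal(all_classes, mask)
        np.testing.assert_array_equal(
            class_select(cm, {3, 4}), mask & ~class_select(cm, {1, 2})
        )
        assert not class_select(cm, set()).any()

    def test_invalid_ids_rejected(self):
        from hma.partition import ClassMap

        cm = ClassMap(labels=np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(ParameterError):
            class_select(cm, {0, 5})


class TestWatershedSplit:
    def test_empty_mask(self):
        lm = watershed_split(np.zeros((32, 32), dtype=bool))
        assert lm.n_labels == 0

    def test_single_disk_single_label(self, disk_image):
        _, mask = disk_image
        lm = watershed_split(mask)
        assert lm.n_labels == 1
        np.testing.assert_array_equal(lm.labels > 0, mask)

    def test_dumbbell_splits_in_two(self, dumbbell_mask):
        lm = watershed_split(dumbbell_mask, min_seed_distance=10)
        assert lm.n_labels == 2
        np.testing.assert_array_equal(lm.labels > 0, dumbbell_mask)

    def test_labels_partition_mask_exactly(self, scene_factory):
        scene = scene_factory(2)
        mask = scene.gt_labels > 0
        lm = watershed_split(mask)
        assert (lm.labels > 0).sum() == mask.sum()
        assert not (lm.labels > 0)[~mask].any()
        areas = np.bincount(lm.labels.ravel())[1:]
        assert areas.sum() == mask.sum()
        assert lm.n_labels == len(areas)
        # every label support is 8-connected
        for i in range(1, lm.n_labels + 1):
            assert ndi.label(lm.labels == i, structure=np.ones((3, 3)))[1] == 1
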