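import math

import numpy as np
import pytest

from thoraseg.augmentation import (
    NoduleROI,
    augment_training_set,
    build_roi_bank,
    equivalent_diameter_mm,
    extract_nodule,
    insert_nodule,
    sample_insertion_site,
)
from thoraseg.ct_io import CTVolume, MaskSet
from thoraseg.errors import ConfigurationError, ExtractionError, PlacementError
from thoraseg.phantom import PhantomSpec, generate_case


def _sphere(shape, center, r):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    return (sum(((g - c) ** 2 for g, c in zip(grids, center))) <= r**2).astype(np.uint8)


@pytest.fixture(scope="module")
def donor():
    return generate_case(PhantomSpec(seed=21, n_nodules=2, peripheral_fraction=0.0))


@pytest.fixture(scope="module")
def recipient():
    return generate_case(PhantomSpec(seed=22, n_nodules=0))


class TestExtractNodule:
    def test_bounding_box_with_zero_margin(self):
        vox = np.zeros((9, 9, 9), dtype=np.int16)
        mask = _sphere((9, 9, 9), (4, 4, 4), 2.2)  # 5-voxel-wide sphere
        vol = CTVolume(voxels=vox, spacing=(1, 1, 1), id="d")
        roi = extract_nodule(vol, mask, margin_mm=0.0)
        idx = np.argwhere(mask)
        expected_shape = tuple(idx.max(0) - idx.min(0) + 1)
        assert roi.patch.shape == expected_shape
        assert roi.mask.sum() == mask.sum()

    def test_equivalent_diameter_closed_form(self):
        mask = _sphere((15, 15, 15), (7, 7, 7), 4)
        v = int(mask.sum())
        vol = CTVolume(voxels=np.zeros((15, 15, 15)), spacing=(1, 1, 1))
        roi = extract_nodule(vol, mask)
        assert roi.diameter_mm == pytest.approx((6 * v / math.pi) ** (1 / 3))
        assert equivalent_diameter_mm(v, (1, 1, 1)) == roi.diameter_mm

    def test_error_paths(self):
        vol = CTVolume(voxels=np.zeros((6, 6, 6)), spacing=(1, 1, 1))
        with pytest.raises(ExtractionError):
            extract_nodule(vol, np.zeros((6, 6, 6)))
        two = np.zeros((6, 6, 6))
        two[1, 1, 1] = two[4, 4, 4] = 1
        with pytest.raises(ExtractionError):
            extract_nodule(vol, two)
        with pytest.raises(ExtractionError):
            NoduleROI(patch=np.zeros((3, 3)), mask=two[:3, :3, 0] * 0)


class TestSampleInsertionSite:
    def test_single_voxel_roi_lands_inside_lung(self, recipient):
        roi = NoduleROI(patch=np.array([[[50]]]), mask=np.array([[[1]]]))
        site = sample_insertion_site(recipient.truth.lung, roi, rng_seed=3)
        assert recipient.truth.lung[site] == 1

    def test_interior_mode_footprint_subset_of_lung(self, donor, recipient):
        roi = extract_nodule(donor.volume, donor.truth.nodules[0])
        lung = recipient.truth.lung.astype(bool)
        site = sample_insertion_site(lung, roi, rng_seed=5)
        _, masks, _ = insert_nodule(recipient.volume, recipient.truth, roi, site)
        pasted = masks.nodules[-1].astype(bool)
        assert not (pasted & ~lung).any()

    def test_seeded_determinism(self, donor, recipient):
        roi = extract_nodule(donor.volume, donor.truth.nodules[0])
        s1 = sample_insertion_site(recipient.truth.lung, roi, rng_seed=9)
        s2 = sample_insertion_site(recipient.truth.lung, roi, rng_seed=9)
        assert s1 == s2

    def test_infeasible_placement_raises(self):
        lung = np.zeros((3, 8, 8), dtype=np.uint8)
        lung[1, 4, 4] = 1
        big = NoduleROI(patch=np.zeros((3, 7, 7)), mask=np.ones((3, 7, 7)))
        with pytest.raises(PlacementError):
            sample_insertion_site(lung, big, rng_seed=0, max_tries=50)


class TestInsertNodule:
    def test_locality_bit_identical_outside_footprint(self, donor, recipient):
        roi = extract_nodule(donor.volume, donor.truth.nodules[0])
        site = sample_insertion_site(recipient.truth.lung, roi, rng_seed=7)
        new_vol, masks, _ = insert_nodule(recipient.volume, recipient.truth, roi, site)
        pasted = masks.nodules[-1].astype(bool)
        diff = new_vol.voxels != recipient.volume.voxels
        assert not (diff & ~pasted).any()

    def test_set_arithmetic_lung_unchanged_nodule_added(self, donor, recipient):
        roi = extract_nodule(donor.volume, donor.truth.nodules[0])
        site = sample_insertion_site(recipient.truth.lung, roi, rng_seed=7)
        k = int(roi.mask.sum())
        _, masks, _ = insert_nodule(recipient.volume, recipient.truth, roi, site)
        # interior site: lung already covers the footprint, so union is a no-op
        assert masks.lung.sum() == recipient.truth.lung.sum()
        assert len(masks.nodules) == len(recipient.truth.nodules) + 1
        assert masks.nodules[-1].sum() == k

    def test_blend_max_with_darker_roi_leaves_volume_unchanged(self, recipient):
        roi = NoduleROI(
            patch=np.full((1, 3, 3), -1024, dtype=np.int16), mask=np.ones((1, 3, 3), dtype=np.uint8)
        )
        site = sample_insertion_site(recipient.truth.lung, roi, rng_seed=4)
        new_vol, masks, _ = insert_nodule(
            recipient.volume, recipient.truth, roi, site, blend="max"
        )
        np.testing.assert_array_equal(new_vol.voxels, recipient.volume.voxels)
        assert len(masks.nodules) == len(recipient.truth.nodules) + 1

    def test_pasted_nodule_brighter_than_replaced_lung(self, donor, recipient):
        roi = extract_nodule(donor.volume, donor.truth.nodules[0])
        site = sample_insertion_site(recipient.truth.lung, roi, rng_seed=7)
        new_vol, masks, _ = insert_nodule(recipient.volume, recipient.truth, roi, site)
        pasted = masks.nodules[-1].astype(bool)
        assert new_vol.voxels[pasted].mean() > recipient.volume.voxels[pasted].mean()

    def test_footprint_outside_grid(self, donor, recipient):
        roi = extract_nodule(donor.volume, donor.truth.nodules[0])
        with pytest.raises(PlacementError):
            insert_nodule(recipient.volume, recipient.truth, roi, (0, 0, 0))


@pytest.fixture(scope="module")
def bank(donor):
    return build_roi_bank([donor])


@pytest.fixture(scope="module")
def cases():
    return [generate_case(PhantomSpec(seed=s, n_nodules=0)) for s in (31, 32, 33, 34)]


class TestAugmentTrainingSet:
    def test_rate_zero_is_identity(self, cases, bank):
        out, manifest = augment_training_set(cases, bank, rate=0.0, seed=1)
        assert manifest == []
        for a, b in zip(out, cases):
            assert a is b

    def test_rate_one_augments_every_case(self, cases, bank):
        out, manifest = augment_training_set(cases, bank, rate=1.0, seed=1)
        assert len(manifest) == len(cases)
        for case in out:
            assert len(case.truth.nodules) == 1

    def test_manifest_deterministic_for_fixed_seed(self, cases, bank):
        m1 = augment_training_set(cases, bank, rate=0.5, seed=42)[1]
        m2 = augment_training_set(cases, bank, rate=0.5, seed=42)[1]
        assert [r.to_dict() for r in m1] == [r.to_dict() for r in m2]

    def test_coherent_truth_but_incoherent_defective_label(self, bank):
        cases = [generate_case(PhantomSpec(seed=40, n_nodules=0, protocol="nodules_excluded"))]
        out, manifest = augment_training_set(
            cases, bank, rate=1.0, seed=3, update_defective_lung=False
        )
        case = out[0]
        pasted = case.truth.nodules[-1].astype(bool)
        assert not (pasted & ~case.truth.lung.astype(bool)).any()  # truth stays coherent
        assert (pasted & ~case.original_masks.lung.astype(bool)).any()  # label excludes it
        assert len(manifest) == 1

    def test_empty_bank_and_bad_rate(self, cases):
        with pytest.raises(ConfigurationError):
            augment_training_set(cases, [], rate=0.5)
        with pytest.raises(ConfigurationError):
            augment_training_set(cases, [NoduleROI(np.zeros((1, 1, 1)), np.ones((1, 1, 1)))], rate=1.5)
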