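"""Hot-spot detection, adaptive segmentation, review, and compartment
classification on analytic phantoms."""

import numpy as np
import pytest

import psmascore as ps
from psmascore import Compartment, HotspotParams

from conftest import SHAPE, SPACING, make_lesion_spec


def _uniform_ref(blood=1.5, liver=5.0):
    return ps.ReferenceUptake(liver_suv_mean=liver, blood_pool_suv_mean=blood)


class TestDetect:
    def test_flat_pet_at_blood_pool_level_yields_no_seeds(self):
        pet = ps.VoxelGrid(np.full((10, 10, 10), 1.5), (2, 2, 2))
        assert ps.detect_hotspots(pet, _uniform_ref()) == []

    def test_three_disjoint_spheres_three_seeds(self):
        values = np.ones((30, 30, 30))
        centers = [(5, 5, 5), (15, 15, 15), (25, 25, 8)]
        xx, yy, zz = np.meshgrid(*[np.arange(30)] * 3, indexing="ij")
        for c in centers:
            ball = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2 <= 9
            values[ball] = 8.0
        pet = ps.VoxelGrid(values, (2, 2, 2))
        seeds = ps.detect_hotspots(pet, _uniform_ref(), HotspotParams(detect_rel=2.0))
        assert len(seeds) == 3
        # each seed is interior to exactly one sphere
        hit = {min(range(3), key=lambda i: sum((s - c) ** 2 for s, c in zip(seed, centers[i])))
               for seed in seeds}
        assert hit == {0, 1, 2}

    def test_subthreshold_sphere_not_detected(self):
        values = np.ones((12, 12, 12))
        values[5:8, 5:8, 5:8] = 2.5  # threshold = 2 * 1.5 = 3.0
        pet = ps.VoxelGrid(values, (2, 2, 2))
        assert ps.detect_hotspots(pet, _uniform_ref(), HotspotParams(detect_rel=2.0)) == []

    def test_full_recall_on_noise_free_phantom(self, four_lesion_phantom):
        _, pet, masks, truth, ref = four_lesion_phantom
        seeds = ps.detect_hotspots(pet, ref, exclude=masks.liver | masks.blood_pool)
        for gt in truth:
            assert any(gt.mask[s] for s in seeds), f"{gt.lesion_id} missed"


class TestSegment:
    def test_sphere_volume_within_15pct_of_analytic(self):
        spec = ps.PhantomSpec(
            grid_shape=SHAPE, voxel_spacing_mm=SPACING,
            lesions=(make_lesion_spec(Compartment.OSSEOUS, radius_mm=10.0),),
        )
        pet, masks, truth = ps.generate_phantom(spec)
        ref = ps.compute_reference_uptake(pet, masks)
        params = HotspotParams(seg_fraction=0.4)
        seeds = ps.detect_hotspots(pet, ref, params, exclude=masks.liver | masks.blood_pool)
        lesion = ps.segment_hotspot(pet, seeds[0], ref, params)
        # adaptive threshold = max(0.4 * 8, 1.5) = 3.2 SUV
        assert lesion.volume_ml == pytest.approx(4.18879, rel=0.15)
        assert lesion.suv_mean == pytest.approx(8.0)

    def test_single_hot_voxel_volume(self):
        values = np.ones((8, 8, 8))
        values[4, 4, 4] = 10.0
        pet = ps.VoxelGrid(values, (2, 2, 2))
        lesion = ps.segment_hotspot(
            pet, (4, 4, 4), _uniform_ref(), HotspotParams(min_volume_ml=0.0)
        )
        assert lesion.volume_ml == pytest.approx(0.008)

    def test_core_only_when_rim_below_adaptive_threshold(self):
        values = np.ones((20, 20, 20))
        xx, yy, zz = np.meshgrid(*[np.arange(20)] * 3, indexing="ij")
        d2 = (xx - 10) ** 2 + (yy - 10) ** 2 + (zz - 10) ** 2
        rim = d2 <= 36
        core = d2 <= 9
        values[rim] = 3.0
        values[core] = 10.0
        pet = ps.VoxelGrid(values, (2, 2, 2))
        # threshold = max(0.4 * 10, 1.5) = 4.0 -> rim voxels excluded
        lesion = ps.segment_hotspot(pet, (10, 10, 10), _uniform_ref(), HotspotParams())
        # brute-force oracle: exactly the voxels >= 4.0 connected to the seed
        assert lesion.voxel_count == int(core.sum())
        assert lesion.suv_mean == pytest.approx(10.0)

    def test_seed_below_threshold_rejected(self):
        pet = ps.VoxelGrid(np.ones((6, 6, 6)), (2, 2, 2))
        with pytest.raises(ValueError, match="below the detection threshold"):
            ps.segment_hotspot(pet, (3, 3, 3), _uniform_ref())

    def test_tiny_lesion_discarded_by_min_volume(self):
        values = np.ones((8, 8, 8))
        values[4, 4, 4] = 10.0
        pet = ps.VoxelGrid(values, (2, 2, 2))
        assert ps.segment_hotspot(
            pet, (4, 4, 4), _uniform_ref(), HotspotParams(min_volume_ml=0.1)
        ) is None

    @pytest.mark.parametrize("f_lo,f_hi", [(0.3, 0.5), (0.5, 0.8)])
    def test_raising_fraction_never_enlarges_mask(self, four_lesion_phantom, f_lo, f_hi):
        _, pet, masks, _, ref = four_lesion_phantom
        exclude = masks.liver | masks.blood_pool
        seeds = ps.detect_hotspots(pet, ref, exclude=exclude)
        for seed in seeds:
            lo = ps.segment_hotspot(pet, seed, ref, HotspotParams(seg_fraction=f_lo))
            hi = ps.segment_hotspot(pet, seed, ref, HotspotParams(seg_fraction=f_hi))
            if hi is None:
                continue
            assert not (hi.mask & ~lo.mask).any()  # hi subset of lo

    def test_distinct_lesion_masks_are_disjoint(self, four_lesion_phantom):
        _, pet, masks, _, ref = four_lesion_phantom
        lesions = ps.quantify_pet(pet, masks, ref)
        total = np.zeros(pet.shape, int)
        for les in lesions:
            total += les.mask
        assert total.max() <= 1

    def test_noise_free_end_to_end_recovery(self, four_lesion_phantom):
        _, pet, masks, truth, ref = four_lesion_phantom
        lesions = ps.quantify_pet(pet, masks, ref)
        assert len(lesions) == len(truth)
        for gt in truth:
            match = [l for l in lesions if (l.mask & gt.mask).sum() > 0]
            assert len(match) == 1
            assert match[0].suv_mean == pytest.approx(gt.suv_mean)
            assert match[0].volume_ml == pytest.approx(gt.volume_ml, rel=0.15)


class TestReviewAndClassify:
    def test_empty_decision_map_accepts_everything(self, four_lesion_phantom):
        _, pet, masks, _, ref = four_lesion_phantom
        lesions = ps.quantify_pet(pet, masks, ref)
        assert all(l.accepted for l in lesions)

    def test_reject_all_empties_the_scores(self, four_lesion_phantom):
        _, pet, masks, _, ref = four_lesion_phantom
        lesions = ps.quantify_pet(pet, masks, ref)
        ps.apply_review(lesions, {l.lesion_id: "reject" for l in lesions})
        scores = ps.compartment_scores(lesions, ref)
        assert scores.as_dict() == {
            "prostate_bed": None, "nodal": None, "osseous": None, "composite": 0.0
        }

    def test_rejecting_one_lesion_subtracts_its_score(self, four_lesion_phantom):
        _, pet, masks, _, ref = four_lesion_phantom
        lesions = ps.quantify_pet(pet, masks, ref)
        full = ps.compartment_scores(lesions, ref).composite
        target = lesions[0]
        own_score = ps.lesion_psma_score(target, ref)
        ps.apply_review(lesions, {target.lesion_id: "reject"})
        reduced = ps.compartment_scores(lesions, ref).composite
        assert full - reduced == pytest.approx(own_score)

    def test_unknown_lesion_id_rejected(self, four_lesion_phantom):
        _, pet, masks, _, ref = four_lesion_phantom
        lesions = ps.quantify_pet(pet, masks, ref)
        with pytest.raises(ValueError, match="unknown lesion ids"):
            ps.apply_review(lesions, {"nope": "reject"})

    def test_phantom_lesions_classified_into_their_compartments(self, four_lesion_phantom):
        _, pet, masks, truth, ref = four_lesion_phantom
        lesions = ps.quantify_pet(pet, masks, ref)
        for gt in truth:
            match = [l for l in lesions if (l.mask & gt.mask).sum() > 0][0]
            assert match.compartment == gt.compartment

    def test_nodal_split_at_bifurcation_plane(self, four_lesion_phantom):
        _, pet, masks, truth, _ = four_lesion_phantom
        by_comp = {gt.compartment: gt for gt in truth}
        hi = by_comp[Compartment.NONREGIONAL_NODE].centroid_mm(pet)[2]
        lo = by_comp[Compartment.REGIONAL_NODE].centroid_mm(pet)[2]
        assert lo <= masks.bifurcation_z_mm < hi

    def test_overlap_tie_prefers_osseous(self):
        shape = (6, 6, 6)
        les_mask = np.zeros(shape, bool)
        les_mask[2:4, 2:4, 2:4] = True
        skeleton = np.zeros(shape, bool)
        skeleton[2:4, 2:4, 2] = True  # half of the lesion
        nodal = np.zeros(shape, bool)
        nodal[2:4, 2:4, 3] = True  # the other half
        masks = ps.OrganMaskSet(
            liver=np.zeros(shape, bool), blood_pool=np.zeros(shape, bool),
            prostate_bed=np.zeros(shape, bool), skeleton=skeleton, nodal_region=nodal,
        )
        grid = ps.VoxelGrid(np.ones(shape), (2, 2, 2))
        lesion = ps.Lesion("T", les_mask, 0.064, 1.0, 1.0)
        assert ps.classify_compartment(lesion, masks, grid) == Compartment.OSSEOUS

    def test_no_overlap_leaves_lesion_unclassified_with_warning(self):
        shape = (6, 6, 6)
        empty = np.zeros(shape, bool)
        masks = ps.OrganMaskSet(empty, empty, empty, empty, empty)
        grid = ps.VoxelGrid(np.ones(shape), (2, 2, 2))
        les_mask = np.zeros(shape, bool)
        les_mask[1, 1, 1] = True
        lesion = ps.Lesion("T", les_mask, 0.008, 1.0, 1.0)
        with pytest.warns(UserWarning, match="unclassified"):
            assert ps.classify_compartment(lesion, masks, grid) is None
        assert ps.compartment_scores([lesion], _uniform_ref()).composite == 0.0
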