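"""Immersion partition, plane assignment and threshold masks."""

import warnings

import numpy as np
import pytest

from gatedpet import phantom, segmentation as seg


def _random_image(rng, two_gates=True):
    shape = (
        2 if two_gates else int(rng.integers(4, 6)),
        int(rng.integers(3, 9)),
        int(rng.integers(3, 9)),
        int(rng.integers(3, 9)),
    )
    img = rng.integers(0, 10, size=shape).astype(float)
    if img.max() <= 0:
        img.flat[0] = 1.0
    return img


class TestImmersionPartition:
    def test_single_maximum_single_region(self):
        g = np.zeros((4, 9, 9, 9))
        x = np.arange(9) - 4.0
        blob = np.exp(-(x[:, None, None] ** 2 + x[None, :, None] ** 2 + x[None, None, :] ** 2) / 8.0)
        g[:] = blob
        part = seg.immersion_partition(g, smoothing_fwhm_mm=0.0, flood_floor_frac=0.2)
        assert len(part.regions) == 1
        supra = g >= 0.2 * g.max()
        assert np.array_equal(part.labels > 0, supra)

    def test_two_maxima_split_at_central_minimum(self):
        profile = np.array([1.0, 5.0, 1.0, 6.0, 1.0]).reshape(1, 5, 1, 1)
        part = seg.immersion_partition(profile, smoothing_fwhm_mm=0.0, flood_floor_frac=0.0)
        lab = part.labels[0, :, 0, 0]
        assert len(part.regions) == 2
        assert lab[0] == lab[1] and lab[3] == lab[4]
        # the central minimum attaches to its steepest (brighter) neighbour
        assert lab[2] == lab[3]
        assert lab[1] != lab[3]

    @pytest.mark.parametrize("floor", [0.0, 0.1, 0.3])
    def test_matches_level_by_level_oracle(self, rng, floor):
        for _ in range(30):
            img = _random_image(rng, two_gates=bool(rng.integers(0, 2)))
            got = seg.immersion_partition(img, smoothing_fwhm_mm=0.0,
                                          flood_floor_frac=floor)
            want = seg.flood_level_by_level(img, floor)
            assert np.array_equal(got.labels, want)

    def test_invariant_to_monotone_rescaling(self, rng):
        img = _random_image(rng)
        a = seg.immersion_partition(img, smoothing_fwhm_mm=0.0, flood_floor_frac=0.0)
        b = seg.immersion_partition(2.0 * img + 1.0, smoothing_fwhm_mm=0.0,
                                    flood_floor_frac=0.0)
        assert np.array_equal(a.labels, b.labels)

    def test_partition_exhaustive_and_disjoint_above_floor(self, rng):
        img = _random_image(rng)
        part = seg.immersion_partition(img, smoothing_fwhm_mm=0.0, flood_floor_frac=0.2)
        floor = 0.2 * img.max()
        assert np.array_equal(part.labels > 0, img >= floor)
        # labels partition the supra-floor set: voxel counts add up
        total = sum(r.n_voxels for r in part.regions.values())
        assert total == int((img >= floor).sum())

    def test_each_region_seeded_at_its_maximum(self, rng):
        img = _random_image(rng)
        part = seg.immersion_partition(img, smoothing_fwhm_mm=0.0, flood_floor_frac=0.0)
        for rid, reg in part.regions.items():
            assert part.labels[reg.seed] == rid
            assert img[reg.seed] == reg.max_intensity

    def test_all_zero_image_raises(self):
        with pytest.raises(ValueError, match="no maxima"):
            seg.immersion_partition(np.zeros((2, 3, 3, 3)), smoothing_fwhm_mm=0.0)


def _phantom_partition(run):
    part = seg.immersion_partition(run.gated.intensities, smoothing_fwhm_mm=0.0,
                                   flood_floor_frac=0.10)
    return seg.assign_regions(part, phantom.default_planes(run.config))


class TestAssignRegions:
    def test_phantom_chambers_get_their_labels(self, small_run):
        part = small_run.analysis.partition
        for chamber, masks in (("LV", small_run.truth.lv_masks),
                               ("RV", small_run.truth.rv_masks)):
            for rid, reg in part.regions.items():
                if masks[reg.seed[0]][reg.seed[1:]]:
                    assert reg.chamber == chamber, (rid, chamber)

    def test_hot_spot_region_is_extra_ventricular(self, small_run):
        assert small_run.config.hot_spot
        assert len(small_run.analysis.partition.chamber_ids("EXTRA")) >= 1

    def test_barycentre_on_septal_plane_counts_as_lv(self):
        img = np.ones((4, 3, 3, 3)) * 0.1
        img[:, 1, 1, 1] = 1.0  # single region, barycentre ~ centre
        part = seg.immersion_partition(img, smoothing_fwhm_mm=0.0,
                                       flood_floor_frac=0.5)
        bary = part.regions[1].barycentre[1:]
        planes = seg.CardiacPlanes(
            septal=seg.Plane(point=tuple(bary), normal=(1, 0, 0)),
            valve=seg.Plane(point=(1, 1, 2.5), normal=(0, 0, -1)),
            infundibular=seg.Plane(point=(1, 1, 2.5), normal=(0, 0, -1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assigned = seg.assign_regions(part, planes)
        assert assigned.regions[1].chamber == "LV"

    def test_region_above_valve_plane_is_extra(self):
        img = np.ones((4, 3, 3, 3)) * 0.1
        img[:, 1, 1, 1] = 1.0
        part = seg.immersion_partition(img, smoothing_fwhm_mm=0.0, flood_floor_frac=0.5)
        planes = seg.CardiacPlanes(
            septal=seg.Plane(point=(0, 0, 0), normal=(1, 0, 0)),
            valve=seg.Plane(point=(1, 1, 0.25), normal=(0, 0, -1)),  # ventricles below
            infundibular=seg.Plane(point=(1, 1, 0.25), normal=(0, 0, -1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assigned = seg.assign_regions(part, planes)
        assert assigned.regions[1].chamber == "EXTRA"


class TestReassignRegion:
    def test_reassignment_moves_voxels_and_logs(self, small_run):
        part = small_run.analysis.partition
        extra = part.chamber_ids("EXTRA")
        assert extra
        rid = extra[0]
        before = part.chamber_label_mask("RV").sum()
        moved = seg.reassign_region(part, rid, "RV")
        assert moved.chamber_label_mask("RV").sum() == before + part.regions[rid].n_voxels
        assert moved.history[-1] == {"region_id": rid, "from": "EXTRA", "to": "RV"}
        assert np.array_equal(moved.labels, part.labels)  # geometry untouched

    def test_reassign_twice_is_involution(self, small_run):
        part = small_run.analysis.partition
        rid = part.chamber_ids("EXTRA")[0]
        back = seg.reassign_region(seg.reassign_region(part, rid, "RV"), rid, "EXTRA")
        assert {r: reg.chamber for r, reg in back.regions.items()} == {
            r: reg.chamber for r, reg in part.regions.items()
        }

    def test_unknown_region_raises(self, small_run):
        with pytest.raises(KeyError):
            seg.reassign_region(small_run.analysis.partition, 10**6, "LV")
        with pytest.raises(ValueError):
            seg.reassign_region(small_run.analysis.partition, 1, "AORTA")


class TestThresholdMask:
    def test_masks_are_nested_in_threshold(self, rng):
        for _ in range(10):
            img = _random_image(rng, two_gates=False) + 0.5
            part = seg.immersion_partition(img, smoothing_fwhm_mm=0.0,
                                           flood_floor_frac=0.0)
            for reg in part.regions.values():
                reg.chamber = "LV"
            series = seg.GatedImageSeries(img, voxel_size_mm=1.0, cycle_ms=1000.0)
            prev = None
            for theta in (0.40, 0.35, 0.30, 0.25, 0.20):
                mask = seg.threshold_mask(series, part, "LV", theta).mask
                if prev is not None:
                    assert np.all(prev <= mask)  # higher threshold is a subset
                prev = mask

    def test_tiny_threshold_recovers_full_region_set(self, small_run):
        part = small_run.analysis.partition
        mask = seg.threshold_mask(small_run.gated, part, "LV", 1e-9)
        assert np.array_equal(mask.mask, part.chamber_label_mask("LV"))

    def test_chamber_without_regions_raises(self, small_run):
        part = small_run.analysis.partition
        stripped = part
        for rid in part.chamber_ids("LV"):
            stripped = seg.reassign_region(stripped, rid, "EXTRA")
        with pytest.raises(ValueError, match="no assigned regions"):
            seg.threshold_mask(small_run.gated, stripped, "LV", 0.3)

    def test_lv_mask_dice_against_truth(self, full_noiseless_run):
        """30% LV mask at end-diastole overlaps the true occupancy (PSF 6 mm)."""
        run = full_noiseless_run
        got = run.analysis.lv_mask.mask[0]
        want = run.truth.lv_masks[0]
        dice = 2 * np.logical_and(got, want).sum() / (got.sum() + want.sum())
        assert dice >= 0.85
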