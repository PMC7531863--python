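import numpy as np
import pytest
from scipy import ndimage as ndi

from nucleoseg import (
    AlgorithmParams,
    IslandSpec,
    PhantomSpec,
    clean_regions,
    generate,
    segment_slice,
    segment_volume,
    select_nucleus,
    superpixels,
)
from nucleoseg.io import LABEL_NUCLEUS

from oracles import canonical_labels, flood_fill_labels


class TestSuperpixels:
    def test_empty_edge_mask_is_one_region(self):
        labels = superpixels(np.zeros((16, 16), dtype=bool))
        assert labels.max() == 1 and (labels == 1).all()

    def test_crossing_bands_make_four_quadrants(self):
        edges = np.zeros((21, 21), dtype=bool)
        edges[10, :] = True
        edges[:, 10] = True
        labels = superpixels(edges)
        assert labels.max() == 4
        corners = {labels[0, 0], labels[0, -1], labels[-1, 0], labels[-1, -1]}
        assert len(corners) == 4

    def test_matches_flood_fill_oracle_up_to_renumbering(self, rng):
        for _ in range(5):
            edges = rng.random((64, 64)) < 0.2
            got = canonical_labels(superpixels(edges))
            want = canonical_labels(flood_fill_labels(~edges))
            np.testing.assert_array_equal(got, want)


class TestCleanRegions:
    def test_border_region_dropped(self):
        regions = np.zeros((32, 32), dtype=int)
        regions[0:10, 0:10] = 1
        assert clean_regions(regions) == []

    def test_hole_filled_in_interior_region(self):
        regions = np.zeros((40, 40), dtype=int)
        regions[10:30, 10:30] = 1
        regions[20, 20] = 0
        out = clean_regions(regions, smoothing_radius=0)
        assert len(out) == 1
        assert out[0][20, 20]

    def test_small_region_dropped_by_area(self):
        regions = np.zeros((64, 64), dtype=int)
        regions[10:30, 10:30] = 1  # 400 px
        regions[40:42, 40:42] = 2  # 4 px < 0.01 * 4096
        out = clean_regions(regions, min_region_fraction=0.01, smoothing_radius=0)
        assert len(out) == 1
        assert out[0][15, 15] and not out[0][40, 40]

    def test_output_never_touches_border(self, rng):
        regions = superpixels(rng.random((64, 64)) < 0.1)
        for mask in clean_regions(regions):
            assert not mask[0].any() and not mask[-1].any()
            assert not mask[:, 0].any() and not mask[:, -1].any()


def _disk(shape, cy, cx, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


class TestSelectNucleus:
    def test_single_candidate_at_central_slice(self):
        cand = _disk((64, 64), 32, 32, 10)
        np.testing.assert_array_equal(select_nucleus([cand], None, (64, 64)), cand)

    def test_central_pick_prefers_large_central_region(self):
        central = _disk((64, 64), 32, 32, 12)
        corner = _disk((64, 64), 8, 8, 6)
        np.testing.assert_array_equal(
            select_nucleus([corner, central], None, (64, 64)), central
        )

    def test_island_without_overlap_discarded(self):
        ref = _disk((64, 64), 32, 32, 12)
        good = _disk((64, 64), 30, 30, 10)
        island = _disk((64, 64), 8, 55, 5)
        out = select_nucleus([good, island], ref, (64, 64))
        np.testing.assert_array_equal(out, good)

    def test_two_overlapping_lobes_unioned(self):
        ref = _disk((64, 64), 32, 32, 20)
        lobe_a = _disk((64, 64), 30, 22, 7)
        lobe_b = _disk((64, 64), 30, 44, 7)
        out = select_nucleus([lobe_a, lobe_b], ref, (64, 64))
        np.testing.assert_array_equal(out, lobe_a | lobe_b)

    def test_no_overlap_returns_empty(self):
        ref = _disk((64, 64), 10, 10, 5)
        cand = _disk((64, 64), 50, 50, 5)
        assert not select_nucleus([cand], ref, (64, 64)).any()

    def test_empty_reference_rejects_everything(self):
        cand = _disk((64, 64), 32, 32, 10)
        assert not select_nucleus([cand], np.zeros((64, 64), bool), (64, 64)).any()


class TestSegmentVolume:
    def test_single_slice_stack_equals_slice_segmentation(self, noise_free_phantom, params):
        stack, _ = noise_free_phantom
        central = stack.voxels[16][None]
        vol = segment_volume(central, params.replace(central_slice=0))
        single = segment_slice(stack.voxels[16], params)
        np.testing.assert_array_equal(vol[0], single.nucleus_mask)

    def test_masks_never_touch_border(self, default_masks):
        assert not default_masks[:, 0, :].any()
        assert not default_masks[:, -1, :].any()
        assert not default_masks[:, :, 0].any()
        assert not default_masks[:, :, -1].any()

    def test_deterministic_rerun(self, default_phantom, default_masks, params):
        stack, _ = default_phantom
        again = segment_volume(stack, params)
        np.testing.assert_array_equal(again, default_masks)

    def test_mirrored_stack_gives_mirrored_masks(self, noise_free_phantom, noise_free_masks, params):
        stack, _ = noise_free_phantom
        n = stack.n_slices
        mirrored = segment_volume(
            stack.voxels[::-1].copy(),
            params.replace(central_slice=n - 1 - n // 2),
        )
        np.testing.assert_array_equal(mirrored, noise_free_masks[::-1])

    def test_empty_stack_rejected(self, params):
        with pytest.raises(ValueError):
            segment_volume(np.zeros((0, 8, 8), dtype=np.uint8), params)

    def test_floating_island_absent_from_every_mask(self, params):
        spec = PhantomSpec(seed=7, island=IslandSpec())
        stack, _ = generate(spec)
        masks = segment_volume(stack, params)
        lo, hi = spec.island.slices
        for z in range(lo, hi + 1):
            assert not masks[z].any()
        # sanity: slice-independent segmentation *would* find the blob,
        # so its absence is the propagation rule at work
        independent = segment_slice(stack.voxels[(lo + hi) // 2], params)
        assert independent.nucleus_mask.sum() > 0

    def test_disjoint_lobes_both_retained(self, params):
        spec = PhantomSpec(seed=7, lobe_slices=(20, 24))
        stack, truth = generate(spec)
        masks = segment_volume(stack, params)
        for z in range(20, 25):
            ncomp = ndi.label(masks[z])[1]
            assert ncomp == 2
            truth_lobes, nlobes = ndi.label(truth[z] == LABEL_NUCLEUS)
            assert nlobes == 2
            for lobe in range(1, nlobes + 1):
                assert (masks[z] & (truth_lobes == lobe)).sum() > 0
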