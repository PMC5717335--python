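"""Segmentation chain: Otsu oracle, ROI, components vs flood fill, morphology."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from kinquant.io import ImageStack
from kinquant.segmentation import (
    ROI,
    EmptyForegroundError,
    SegmentationParams,
    build_annulus,
    crop_dapi_roi,
    expand_mask,
    otsu_threshold,
    segment_kinetochores,
)
from kinquant.simulate import SimImageParams, simulate_cell_stack
from tests._oracles import brute_force_otsu, flood_fill_segment, lattice_disk_count


def wrap_stack(aca, dapi=None, voxel_size=(0.2, 0.08, 0.08)):
    if dapi is None:
        dapi = np.zeros_like(aca)
    return ImageStack(
        data=np.stack([dapi, aca]).astype(np.float64),
        channel_names=["DAPI", "ACA"],
        voxel_size=voxel_size,
    )


def full_roi(shape):
    return ROI(bounds=tuple((0, n) for n in shape))


class TestOtsu:
    def test_bimodal_two_values(self):
        vals = np.concatenate([np.full(100, 10.0), np.full(100, 200.0)])
        t = otsu_threshold(vals)
        assert 10 <= t < 200
        assert t == pytest.approx(brute_force_otsu(vals))

    def test_three_value_sample_vs_brute_force(self):
        vals = np.concatenate([np.full(8, 1.0), np.full(8, 3.0), np.full(4, 10.0)])
        assert otsu_threshold(vals) == pytest.approx(brute_force_otsu(vals))

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(np.full(50, 7.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_bimodal_vs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.concatenate([rng.normal(20, 3, 300), rng.normal(120, 10, 80)])
        assert otsu_threshold(vals) == pytest.approx(brute_force_otsu(vals))

    def test_foreground_separates_modes(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(10, 1, 500), rng.normal(100, 5, 100)])
        t = otsu_threshold(vals)
        assert (vals > t).sum() == pytest.approx(100, abs=5)


class TestCropDapiRoi:
    def test_ellipsoid_bounding_box(self, seg_params):
        p = SimImageParams(
            grid_dims=(20, 64, 64),
            n_pairs=0,
            shot_noise=False,
            read_noise_sd=0.0,
            background_level=10.0,
            nuclear_semiaxes_um=(1.0, 1.5, 1.5),
            seed=0,
        )
        stack, _ = simulate_cell_stack(p)
        roi = crop_dapi_roi(stack, seg_params)
        # analytic box of the ellipsoid, in voxels, ± padding ± smoothing blur
        cz, cy, cx = (c / v for c, v in zip(p.nuclear_center_um, p.voxel_size))
        az, ay, ax = (a / v for a, v in zip(p.nuclear_semiaxes_um, p.voxel_size))
        for (lo, hi), c, a, n in zip(roi.bounds, (cz, cy, cx), (az, ay, ax), p.grid_dims):
            assert lo == pytest.approx(max(0, c - a - seg_params.roi_padding_px), abs=3)
            assert hi == pytest.approx(min(n, c + a + seg_params.roi_padding_px), abs=3)

    def test_empty_dapi_errors(self, seg_params):
        stack = wrap_stack(np.zeros((6, 16, 16)))
        with pytest.raises(EmptyForegroundError, match="no nucleus"):
            crop_dapi_roi(stack, seg_params)

    def test_roi_clipped_to_grid(self, seg_params):
        dapi = np.zeros((6, 16, 16))
        dapi[:, :4, :4] = 100.0  # nucleus touching the edge
        roi = crop_dapi_roi(wrap_stack(np.zeros_like(dapi), dapi), seg_params)
        for (lo, hi), n in zip(roi.bounds, dapi.shape):
            assert 0 <= lo < hi <= n


class TestSegmentKinetochores:
    def test_two_separated_spots(self, seg_params):
        aca = np.full((16, 48, 48), 10.0)
        centers = [(8.0, 12.0, 12.0), (8.0, 36.0, 36.0)]
        from kinquant.simulate import render_spot

        for c in centers:
            render_spot(aca, c, 5e4, (2.0, 2.0, 2.0))
        stack = wrap_stack(aca)
        regions = segment_kinetochores(stack, full_roi(aca.shape), seg_params)
        assert len(regions) == 2
        found = sorted(r.centroid for r in regions)
        for got, want in zip(found, sorted(centers)):
            assert np.linalg.norm(np.subtract(got, want)) < 1.0

    def test_min_size_filter_69_discarded_70_kept(self):
        # two flat 1-z-slice blobs of exactly 69 and 70 voxels on zero background
        aca = np.zeros((5, 40, 40))
        blob69 = [(y, x) for y in range(40) for x in range(20) if (y - 8) ** 2 + (x - 8) ** 2 <= 22]
        blob70 = [(y, x) for y in range(40) for x in range(20, 40) if (y - 28) ** 2 + (x - 30) ** 2 <= 25]
        blob69, blob70 = blob69[:69], blob70[:70]
        assert len(blob69) == 69 and len(blob70) == 70
        for y, x in blob69:
            aca[2, y, x] = 100.0
        for y, x in blob70:
            aca[2, y, x] = 100.0
        params = SegmentationParams(min_object_voxels=70)
        regions = segment_kinetochores(wrap_stack(aca), full_roi(aca.shape), params)
        assert len(regions) == 1
        assert regions[0].voxel_count == 70

    def test_all_background_empty_list(self, seg_params):
        aca = np.full((8, 24, 24), 100.0)  # flat background, nothing to segment
        regions = segment_kinetochores(wrap_stack(aca), full_roi(aca.shape), seg_params)
        assert regions == []

    def test_only_small_noise_objects_empty_list(self, rng):
        aca = np.full((8, 24, 24), 10.0)
        for _ in range(20):  # scatter bright single voxels
            z, y, x = rng.integers(0, 8), rng.integers(0, 24), rng.integers(0, 24)
            aca[z, y, x] = 500.0
        regions = segment_kinetochores(
            wrap_stack(aca), full_roi(aca.shape), SegmentationParams(min_object_voxels=70)
        )
        assert regions == []

    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("seed", range(4))
    def test_flood_fill_oracle_equivalence(self, connectivity, seed):
        """Threshold → components → size filter must be voxel-identical to the
        brute-force flood-fill oracle on small random blobby stacks."""
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(12, 33, size=3))
        aca = gaussian_filter(rng.random(shape), sigma=2) * 1000
        params = SegmentationParams(min_object_voxels=25, connectivity=connectivity)
        regions = segment_kinetochores(wrap_stack(aca), full_roi(shape), params)
        thr = brute_force_otsu(aca)
        expected = flood_fill_segment(aca > thr, 25, connectivity)
        got = np.zeros(shape, dtype=int)
        for r in regions:
            got[r.core_mask] = r.label
        np.testing.assert_array_equal(got, expected)

    def test_min_size_monotonicity(self, rng):
        shape = (16, 32, 32)
        aca = gaussian_filter(rng.random(shape), sigma=2) * 1000
        counts = []
        for mov in (10, 30, 60, 120):
            params = SegmentationParams(min_object_voxels=mov)
            counts.append(len(segment_kinetochores(wrap_stack(aca), full_roi(shape), params)))
        assert counts == sorted(counts, reverse=True)

    def test_recall_precision_on_synthetic(self):
        """Recall and precision >= 0.95 against ground truth at high SNR
        (40 pairs, several seeds)."""
        params = SegmentationParams()
        total_gt = total_matched = total_regions = matched_regions = 0
        for seed in range(4):
            p = SimImageParams(
                grid_dims=(26, 200, 200),
                n_pairs=40,
                sigma_xy_um=0.15,
                sigma_z_um=0.40,
                amplitude_mean={"ACA": 5e4, "target": 5e4},
                nuclear_semiaxes_um=(2.0, 6.5, 6.5),
                background_level=100.0,
                seed=seed,
            )
            stack, spots = simulate_cell_stack(p)
            roi = crop_dapi_roi(stack, params)
            regions = segment_kinetochores(stack, roi, params)
            centroids = np.array([r.centroid for r in regions]) if regions else np.zeros((0, 3))
            region_hit = np.zeros(len(regions), dtype=bool)
            for s in spots:
                if len(regions) == 0:
                    continue
                d = np.linalg.norm(centroids - np.array(s.center), axis=1)
                j = int(np.argmin(d))
                # a spot counts as found if a region centroid is within the pair separation
                if d[j] < 13:
                    total_matched += 1
                    region_hit[j] = True
            total_gt += len(spots)
            total_regions += len(regions)
            matched_regions += int(region_hit.sum())
        assert total_matched / total_gt >= 0.95, "recall"
        assert matched_regions / total_regions >= 0.95, "precision"


class TestExpandMask:
    def test_radius_zero_identity(self, rng):
        core = rng.random((4, 12, 12)) > 0.8
        np.testing.assert_array_equal(expand_mask(core, 0), core)

    @pytest.mark.parametrize("radius", [1, 2, 3, 4])
    def test_single_voxel_disk_counts(self, radius):
        core = np.zeros((3, 21, 21), dtype=bool)
        core[1, 10, 10] = True
        expanded = expand_mask(core, radius)
        assert expanded.sum() == lattice_disk_count(radius)
        assert expanded[0].sum() == 0 and expanded[2].sum() == 0  # in-plane only

    def test_single_voxel_radius_4_is_49(self):
        core = np.zeros((1, 15, 15), dtype=bool)
        core[0, 7, 7] = True
        assert expand_mask(core, 4).sum() == 49

    def test_default_radius_is_0_32_um(self, seg_params):
        assert seg_params.expand_radius_px * 0.08 == pytest.approx(0.32)

    def test_nesting(self, rng):
        core = rng.random((3, 24, 24)) > 0.9
        e1 = expand_mask(core, 1)
        e3 = expand_mask(core, 3)
        assert np.all(e3[e1])  # e1 ⊆ e3
        assert np.all(e1[core])

    def test_3d_dilation_crosses_z(self):
        core = np.zeros((5, 11, 11), dtype=bool)
        core[2, 5, 5] = True
        e = expand_mask(core, 2, dilate_3d=True)
        assert e[1].sum() > 0 and e[3].sum() > 0


class TestBuildAnnulus:
    def test_single_voxel_gap1_width2_is_24(self):
        base = np.zeros((1, 15, 15), dtype=bool)
        base[0, 7, 7] = True
        ann = build_annulus(base, base, gap_px=1, width_px=2)
        # disk r<=3 (29) minus disk r<=1 (5) = 24
        assert ann.sum() == lattice_disk_count(3) - lattice_disk_count(1) == 24

    def test_defaults(self, seg_params):
        assert seg_params.annulus_gap_px == 1
        assert seg_params.annulus_width_px == 2

    def test_neighbouring_regions_excluded(self, seg_params):
        aca = np.zeros((3, 30, 60))
        aca[1, 10:20, 10:20] = 100.0
        aca[1, 10:20, 32:42] = 100.0
        regions = segment_kinetochores(wrap_stack(aca), full_roi(aca.shape), seg_params)
        assert len(regions) == 2
        union_expanded = np.zeros(aca.shape, dtype=bool)
        for r in regions:
            union_expanded |= r.expanded_mask
        for r in regions:
            assert not np.any(r.annulus_mask & union_expanded)
            assert r.annulus_mask.any()

    def test_annulus_disjoint_from_own_mask(self, seg_params, small_params):
        stack, _ = simulate_cell_stack(small_params)
        roi = crop_dapi_roi(stack, seg_params)
        for r in segment_kinetochores(stack, roi, seg_params):
            assert not np.any(r.annulus_mask & r.expanded_mask)

    def test_fully_crowded_region_flagged(self):
        # one object filling the whole (tiny) ROI: annulus empty after clipping
        aca = np.zeros((3, 12, 12))
        aca[:, :, :] = 0.0
        aca[1] = 100.0
        params = SegmentationParams(min_object_voxels=10, expand_radius_px=4)
        regions = segment_kinetochores(wrap_stack(aca), full_roi(aca.shape), params)
        assert len(regions) == 1
        assert regions[0].flagged and "annulus" in regions[0].flag_reason

    def test_annulus_around_core_switch(self, seg_params):
        aca = np.zeros((3, 40, 40))
        aca[1, 15:25, 15:25] = 100.0
        params_core = replace(seg_params, annulus_around_core=True)
        r_exp = segment_kinetochores(wrap_stack(aca), full_roi(aca.shape), seg_params)[0]
        r_core = segment_kinetochores(wrap_stack(aca), full_roi(aca.shape), params_core)[0]
        # core-based annulus sits closer in; both exclude the expanded mask
        assert r_core.annulus_mask.sum() < r_exp.annulus_mask.sum() or not np.array_equal(
            r_core.annulus_mask, r_exp.annulus_mask
        )


class TestSegmentationParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            SegmentationParams(min_object_voxels=0)
        with pytest.raises(ValueError):
            SegmentationParams(connectivity=8)
        with pytest.raises(ValueError):
            SegmentationParams(expand_radius_px=-1)
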