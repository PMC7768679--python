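"""Bubble masks, occluded reconstruction, and ProportionPlane aggregation."""

import numpy as np
import pytest

import facetract as ft
from facetract.bubbles import generate_mask, proportion_plane
from facetract.pca_recon import reconstruct_modality


class TestGenerateMask:
    def test_saturating_diameter_covers_image(self):
        mask = generate_mask(20, 30, n_bubbles=1, diameter=80, seed=0)
        assert mask.mask.all()

    def test_seed_determinism(self):
        a = generate_mask(50, 60, seed=5)
        b = generate_mask(50, 60, seed=5)
        np.testing.assert_array_equal(a.mask, b.mask)
        assert a.centers == b.centers

    def test_single_disc_pixel_count_brute_force(self):
        mask = generate_mask(120, 160, n_bubbles=1, diameter=12, seed=3)
        (r0, c0), = mask.centers
        rr, cc = np.mgrid[0:120, 0:160]
        expected = (rr - r0) ** 2 + (cc - c0) ** 2 <= 6.0**2
        np.testing.assert_array_equal(mask.mask, expected)

    def test_every_visible_pixel_near_some_center(self):
        mask = generate_mask(40, 50, n_bubbles=5, diameter=8, seed=7)
        rr, cc = np.nonzero(mask.mask)
        centers = np.array(mask.centers)
        d2 = (rr[:, None] - centers[:, 0]) ** 2 + (cc[:, None] - centers[:, 1]) ** 2
        assert np.all(d2.min(axis=1) <= 4.0**2)

    def test_monotone_expected_coverage_in_bubble_count(self):
        cov = {
            n: np.mean(
                [
                    generate_mask(60, 80, n_bubbles=n, diameter=10, seed=s).mask.mean()
                    for s in range(20)
                ]
            )
            for n in (5, 20, 46)
        }
        assert cov[5] < cov[20] < cov[46]

    @pytest.mark.parametrize("kwargs", [dict(height=0, width=5), dict(n_bubbles=0), dict(diameter=0)])
    def test_invalid_arguments(self, kwargs):
        full = dict(height=10, width=10, n_bubbles=1, diameter=4, seed=0)
        full.update(kwargs)
        with pytest.raises(ValueError):
            generate_mask(**full)


class TestOccludeAndReconstruct:
    def test_all_true_mask_equals_unoccluded_cross_modal(self, model10, hybrid10):
        lo = hybrid10.layout("video")
        full = np.ones((lo.height, lo.width), dtype=bool)
        occluded = ft.occlude_and_reconstruct(model10, hybrid10, full, "video")
        plain = reconstruct_modality(model10, hybrid10, "mr").metrics
        assert occluded.loading_correlation == pytest.approx(
            plain.loading_correlation, abs=1e-10
        )
        assert occluded.loading_sse == pytest.approx(plain.loading_sse, rel=1e-10)

    def test_all_false_mask_gives_zero_loadings(self, model10, hybrid10):
        lo = hybrid10.layout("video")
        none = np.zeros((lo.height, lo.width), dtype=bool)
        res = ft.occlude_and_reconstruct(model10, hybrid10, none, "video")
        assert np.isnan(res.loading_correlation)
        assert res.loading_sse == pytest.approx((model10.loadings**2).sum())

    def test_informative_mask_beats_matched_uninformative_mask(self):
        # keeping the shared-cause region visible must reconstruct better
        # than keeping an equal-area background region
        bundle = ft.make_bundle(
            n_frames=12, k_shared=1, k_priv_a=0, k_priv_b=0, noise_sd=1.0, seed=5
        )
        sel_v = ft.select_reference(bundle.seq_a, seed=0)
        sel_m = ft.select_reference(bundle.seq_b, seed=1)
        h = ft.build_hybrid(
            (list(bundle.seq_a), sel_v.fields), (list(bundle.seq_b), sel_m.fields)
        )
        model = ft.fit_pca(h)
        gt = bundle.shared_mask("a")
        elsewhere = np.roll(gt, shift=(-55, 60), axis=(0, 1))
        sse_inf = ft.occlude_and_reconstruct(model, h, gt, "video").loading_sse
        sse_bg = ft.occlude_and_reconstruct(model, h, elsewhere, "video").loading_sse
        assert sse_inf < sse_bg

    def test_geometry_mismatch_raises(self, model10, hybrid10):
        with pytest.raises(ValueError, match="geometry"):
            ft.occlude_and_reconstruct(
                model10, hybrid10, np.ones((10, 10), bool), "video"
            )


class TestProportionPlane:
    def test_uniform_masks_give_top_frac_everywhere_covered(self):
        mask = generate_mask(20, 20, n_bubbles=2, diameter=6, seed=1)
        planes = proportion_plane([mask] * 10, np.arange(10.0), top_frac=0.1)
        covered = mask.mask
        np.testing.assert_allclose(planes.plane[covered], 0.1)
        assert np.isnan(planes.plane[~covered]).all()

    def test_disjoint_discs_isolate_best_iteration(self):
        masks = []
        for i in range(10):
            m = np.zeros((10, 100), dtype=bool)
            m[:, i * 10 : i * 10 + 5] = True
            masks.append(m)
        res = proportion_plane(masks, np.arange(1.0, 11.0), top_frac=0.1)
        np.testing.assert_allclose(res.plane[masks[0]], 1.0)
        for m in masks[1:]:
            np.testing.assert_allclose(res.plane[m], 0.0)

    def test_ties_break_by_iteration_index(self):
        masks = [np.zeros((4, 4), bool) for _ in range(10)]
        for i, m in enumerate(masks):
            m[i % 4, 0] = True
        res = proportion_plane(masks, np.zeros(10), top_frac=0.1)
        # all SSEs tie; the earliest iteration wins the single top slot
        assert res.correct_plane[0, 0] == 1
        assert res.correct_plane[1:, 0].sum() == 0

    def test_plane_bounded_and_correct_le_total(self, model10, hybrid10):
        bub = ft.run_bubbles(model10, hybrid10, "video", n_iter=30, seed=2)
        plane = bub.plane
        finite = np.isfinite(plane.plane)
        assert plane.plane[finite].min() >= 0.0
        assert plane.plane[finite].max() <= 1.0
        assert np.all(plane.correct_plane <= plane.total_plane)

    def test_uninformative_pixels_average_top_frac(self, model10, hybrid10):
        # at pixels carrying no signal, landing in the top decile is
        # independent of visibility, so the expected plane value is 0.1
        bub = ft.run_bubbles(model10, hybrid10, "video", n_iter=300, seed=4)
        plane = bub.plane.plane
        corner = plane[:20, :20]  # static background, far from any region
        vals = corner[np.isfinite(corner)]
        assert abs(vals.mean() - 0.1) < 0.04

    def test_per_frame_planes_consistent_with_whole_sequence(
        self, model10, hybrid10
    ):
        bub = ft.run_bubbles(
            model10, hybrid10, "video", n_iter=200, per_frame=True, seed=6
        )
        per = np.nanmean([p.plane for p in bub.per_frame_planes], axis=0)
        whole = bub.plane.plane
        finite = np.isfinite(whole) & np.isfinite(per)
        assert np.abs(per[finite] - whole[finite]).mean() < 0.1

    def test_length_mismatch_and_short_runs_rejected(self):
        masks = [np.ones((4, 4), bool)] * 10
        with pytest.raises(ValueError, match="aligned"):
            proportion_plane(masks, np.zeros(9))
        with pytest.raises(ValueError, match="at least 10"):
            proportion_plane(masks[:5], np.zeros(5))
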