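"""Uncentered PCA, cross-modal reconstruction, and fidelity metrics."""

import numpy as np
import pytest

import facetract as ft
from facetract.pca_recon import fit_pca, loading_correlation, loading_sse


def pearson_by_hand(x, y):
    # textbook formula, independent of any library correlation routine
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


class TestFitPCA:
    def test_rank_one_data_yields_single_component(self):
        rng = np.random.default_rng(0)
        pattern = rng.normal(size=50)
        scales = rng.uniform(1, 3, size=6)
        data = np.outer(pattern, scales)
        model = fit_pca(data)
        assert model.n_components == 1
        np.testing.assert_allclose(
            model.components @ model.loadings, data, atol=1e-10
        )

    def test_matches_full_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(50, 6))
        model = fit_pca(data)
        u, s, vt = np.linalg.svd(data, full_matrices=False)
        assert model.n_components == 6
        for k in range(6):
            sign = np.sign(model.components[:, k] @ u[:, k])
            np.testing.assert_allclose(
                model.components[:, k], sign * u[:, k], atol=1e-8
            )
            np.testing.assert_allclose(
                model.loadings[k], sign * s[k] * vt[k], atol=1e-8
            )

    def test_full_projection_reconstructs_training_data(self):
        rng = np.random.default_rng(2)
        data = rng.uniform(0, 255, size=(100, 8))
        model = fit_pca(data)
        recon = model.components @ project_all(model, data)
        np.testing.assert_allclose(recon, data, rtol=1e-8, atol=1e-8)

    def test_components_orthonormal(self, model10):
        gram = model10.components.T @ model10.components
        np.testing.assert_allclose(
            gram, np.eye(model10.n_components), atol=1e-8
        )

    def test_centered_mode_reconstructs_with_mean(self):
        rng = np.random.default_rng(3)
        data = rng.normal(5.0, 1.0, size=(30, 5))
        model = fit_pca(data, centered=True)
        assert model.mean_vector is not None
        recon = model.components @ ft.project(model, data)
        np.testing.assert_allclose(
            recon + model.mean_vector[:, None], data, atol=1e-8
        )

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            fit_pca(np.zeros((10, 1)))


def project_all(model, data):
    return ft.project(model, data)


class TestProject:
    def test_zero_column_gives_zero_loadings(self, model10):
        out = ft.project(model10, np.zeros(model10.components.shape[0]))
        np.testing.assert_array_equal(out, 0.0)

    def test_training_column_reproduces_loadings(self, model10, hybrid10):
        j = 4
        out = ft.project(model10, hybrid10.data[:, j])
        np.testing.assert_allclose(out, model10.loadings[:, j], atol=1e-8)

    def test_component_projects_to_unit_vector(self, model10):
        k = 2
        out = ft.project(model10, model10.components[:, k])
        expected = np.zeros(model10.n_components)
        expected[k] = 1.0
        np.testing.assert_allclose(out, expected, atol=1e-8)

    def test_dimension_mismatch_raises(self, model10):
        with pytest.raises(ValueError, match="dimension"):
            ft.project(model10, np.zeros(17))


class TestReconstructModality:
    def test_loading_additivity_identity(self, random_hybrid):
        # video-zeroed plus MR-zeroed reconstructed loadings equal the
        # original loadings exactly in the uncentered decomposition
        model = fit_pca(random_hybrid)
        rv = ft.reconstruct_modality(model, random_hybrid, "video")
        rm = ft.reconstruct_modality(model, random_hybrid, "mr")
        np.testing.assert_allclose(
            rv.recon_loadings + rm.recon_loadings,
            model.loadings,
            atol=1e-8,
        )

    def test_duplicated_blocks_reconstruct_half_loadings(self):
        rng = np.random.default_rng(4)
        frames = [rng.uniform(0, 255, (2, 3, 3)) for _ in range(5)]
        fields = [
            ft.WarpField(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
            for _ in range(5)
        ]
        h = ft.build_hybrid((frames, fields), (frames, fields))
        model = fit_pca(h)
        res = ft.reconstruct_modality(model, h, "mr")
        np.testing.assert_allclose(
            res.recon_loadings, 0.5 * model.loadings, atol=1e-8
        )
        assert res.metrics.loading_correlation == pytest.approx(1.0)

    def test_mean_scaling_restores_symmetric_split(self):
        rng = np.random.default_rng(5)
        frames = [rng.uniform(0, 255, (2, 2, 3)) for _ in range(4)]
        fields = [ft.WarpField.zero((2, 2)) for _ in range(4)]
        h = ft.build_hybrid((frames, fields), (frames, fields))
        model = fit_pca(h)
        res = ft.reconstruct_modality(model, h, "mr", apply_mean_scaling=True)
        # halved loadings times the mean original/reconstructed ratio (2)
        np.testing.assert_allclose(res.recon_loadings, model.loadings, atol=1e-8)

    def test_recon_vectors_lie_in_component_span(self, model10, hybrid10):
        res = ft.reconstruct_modality(model10, hybrid10, "mr")
        coeffs = model10.components.T @ res.recon_vectors
        back = model10.components @ coeffs
        np.testing.assert_allclose(back, res.recon_vectors, atol=1e-6)

    def test_deserialized_images_match_vector_blocks(self, model10, hybrid10):
        res = ft.reconstruct_modality(model10, hybrid10, "mr")
        lo = hybrid10.layout("mr")
        img0 = res.recon_images["mr"][0]
        np.testing.assert_allclose(
            img0[..., 0].ravel(order="F"),
            res.recon_vectors[lo.channel_rows(0), 0],
        )

    def test_unknown_modality_raises(self, model10, hybrid10):
        with pytest.raises(ValueError, match="unknown modality"):
            ft.reconstruct_modality(model10, hybrid10, "audio")

    def test_paired_array_reconstruction_zeroes_both_halves(self, hybrid10):
        paired = ft.build_paired(hybrid10)
        model = fit_pca(paired)
        rv = ft.reconstruct_modality(model, paired, "video")
        rm = ft.reconstruct_modality(model, paired, "mr")
        np.testing.assert_allclose(
            rv.recon_loadings + rm.recon_loadings, model.loadings, atol=1e-8
        )


class TestFidelityMetrics:
    def test_identical_loadings_correlate_perfectly(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert loading_correlation(x, x) == pytest.approx(1.0)

    def test_scale_invariance(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert loading_correlation(x, 0.5 * x) == pytest.approx(1.0)

    def test_matches_textbook_pearson(self):
        orig = [1.0, 2.0, 3.0, 4.0]
        recon = [1.1, 1.9, 3.2, 3.9]
        assert loading_correlation(orig, recon) == pytest.approx(
            pearson_by_hand(orig, recon), abs=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            loading_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            loading_correlation([1.0, 2.0], [1.0, 2.0])

    def test_sse_hand_sum(self):
        assert loading_sse([1.0, 2.0], [0.0, 0.0]) == pytest.approx(5.0)
        assert loading_sse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_per_sample_sse_sums_to_total(self):
        rng = np.random.default_rng(6)
        orig = rng.normal(size=(5, 8))
        recon = rng.normal(size=(5, 8))
        per = loading_sse(orig, recon, per_sample=True)
        assert per.shape == (8,)
        assert per.sum() == pytest.approx(loading_sse(orig, recon), abs=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            loading_sse(np.zeros((2, 3)), np.zeros((3, 2)))
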