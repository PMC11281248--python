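import numpy as np
import pytest

import spax
from spax.unmix import (
    assign_components,
    nnmf_unmix,
    project_abundances,
    superpixel_subsample,
    svd_denoise,
)


def make_stack(grid, data, roi=None):
    h, w = data.shape[1:]
    return spax.MultispectralStack(
        data=data,
        grid=grid,
        bmode=np.zeros((h, w)),
        roi_mask=np.ones((h, w), bool) if roi is None else roi,
    )


class TestSvdDenoise:
    def test_exact_rank_two_matrix_recovered(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.uniform(1, 2, 40), rng.uniform(0, 1, 59)) + np.outer(
            rng.uniform(0, 1, 40), rng.uniform(0, 2, 59)
        )
        X_low, rank, _ = svd_denoise(X, 0.99)
        assert rank == 2
        np.testing.assert_allclose(X_low, X, atol=1e-9)

    def test_full_energy_keeps_matrix(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (10, 12))
        X_low, rank, _ = svd_denoise(X, 1.0)
        assert rank == 10
        np.testing.assert_allclose(X_low, X, atol=1e-9)

    def test_rank_one_plus_tiny_noise_selects_rank_one(self):
        rng = np.random.default_rng(2)
        X = np.outer(np.ones(30), rng.uniform(1, 2, 20))
        X = X + 1e-6 * rng.standard_normal(X.shape)
        _, rank, s = svd_denoise(X, 0.95)
        assert rank == 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            svd_denoise(np.zeros((4, 4)))


class TestSuperpixels:
    def test_one_superpixel_per_pixel_is_identity(self, grid, lib, small_phantom):
        _, stack, _ = small_phantom
        roi = spax.rect_roi(20, 30, 26, 38, stack.spatial_shape)
        sp = superpixel_subsample(stack, roi, int(roi.sum()))
        assert sp.n_superpixels == roi.sum()
        rr, cc = np.nonzero(roi)
        for i in range(0, len(rr), 11):
            lab = sp.labels[rr[i], cc[i]]
            np.testing.assert_allclose(
                sp.mean_spectra[lab], stack.data[:, rr[i], cc[i]]
            )

    def test_homogeneous_roi_gives_equal_mean_spectra(self, grid, lib):
        data = np.ones((59, 32, 32)) * lib["hb"].values[:, None, None]
        stack = make_stack(grid, data)
        sp = superpixel_subsample(stack, stack.roi_mask, 4)
        for row in sp.mean_spectra:
            np.testing.assert_allclose(row, sp.mean_spectra[0], atol=1e-9)

    def test_two_region_phantom_yields_pure_spectra(self, grid, lib):
        data = np.zeros((59, 20, 40))
        data[:, :, :20] = lib["hb"].values[:, None, None]
        data[:, :, 20:] = lib["water"].values[:, None, None]
        stack = make_stack(grid, data)
        sp = superpixel_subsample(stack, stack.roi_mask, 2, compactness=50.0)
        assert sp.n_superpixels == 2
        corrs = np.zeros((2, 2))
        for i in range(2):
            em = spax.Spectrum(grid, sp.mean_spectra[i], f"sp{i}")
            corrs[i, 0] = spax.pearson_similarity(em, lib["hb"])
            corrs[i, 1] = spax.pearson_similarity(em, lib["water"])
        # up to permutation, each superpixel matches one pure spectrum
        assert max(min(corrs[0, 0], corrs[1, 1]), min(corrs[0, 1], corrs[1, 0])) > 0.99

    def test_roi_fully_labeled_and_contiguous_ids(self, small_phantom):
        _, stack, _ = small_phantom
        sp = superpixel_subsample(stack, stack.roi_mask, 50)
        inside = sp.labels[stack.roi_mask]
        assert inside.min() == 0
        np.testing.assert_array_equal(np.unique(inside), np.arange(sp.n_superpixels))
        assert np.all(sp.labels[~stack.roi_mask] == -1)

    def test_too_many_superpixels_rejected(self, small_phantom):
        _, stack, _ = small_phantom
        with pytest.raises(ValueError):
            superpixel_subsample(stack, stack.roi_mask, int(stack.roi_mask.sum()) + 1)


class TestNnmf:
    def test_rank_one_exact_factorization(self, grid, lib):
        a = np.random.default_rng(0).uniform(0.5, 2.0, 80)
        X = np.outer(a, lib["collagen3"].values)
        S, A, info = nnmf_unmix(X, 1)
        em = spax.Spectrum(grid, S[0], "em")
        assert spax.pearson_similarity(em, lib["collagen3"]) == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(X - A @ S) / np.linalg.norm(X) < 1e-6

    def test_disjoint_two_chromophore_recovery(self, grid, lib):
        rng = np.random.default_rng(1)
        a1 = np.concatenate([rng.uniform(0.5, 2, 40), np.zeros(40)])
        a2 = np.concatenate([np.zeros(40), rng.uniform(0.5, 2, 40)])
        X = np.outer(a1, lib["hb"].values) + np.outer(a2, lib["water"].values)
        S, A, _ = nnmf_unmix(X, 2)
        corr = np.zeros((2, 2))
        for i in range(2):
            em = spax.Spectrum(grid, S[i], "em")
            corr[i, 0] = spax.pearson_similarity(em, lib["hb"])
            corr[i, 1] = spax.pearson_similarity(em, lib["water"])
        best = max(min(corr[0, 0], corr[1, 1]), min(corr[0, 1], corr[1, 0]))
        assert best >= 0.99

    def test_deterministic(self, lib):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (30, 59))
        out1 = nnmf_unmix(X, 3, seed=0)
        out2 = nnmf_unmix(X, 3, seed=0)
        np.testing.assert_array_equal(out1[0], out2[0])
        np.testing.assert_array_equal(out1[1], out2[1])

    def test_error_trace_non_increasing(self, lib):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (40, 59))
        _, _, info = nnmf_unmix(X, 3)
        trace = info["error_trace"]
        assert np.all(np.diff(trace) <= 1e-9 * trace[0])

    def test_unit_max_endmember_rows(self, lib):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 2, (25, 59))
        S, _, _ = nnmf_unmix(X, 2)
        np.testing.assert_allclose(S.max(axis=1), 1.0)

    def test_excessive_rank_rejected(self):
        with pytest.raises(ValueError):
            nnmf_unmix(np.ones((3, 5)), 4)

    def test_matches_sklearn_reconstruction_quality(self, lib):
        # independent oracle: sklearn's NMF with the same rank should reach a
        # comparable Frobenius residual on the same data
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(5)
        W0 = rng.uniform(0, 1, (60, 3))
        X = W0 @ np.stack([lib[n].values for n in ("hb", "hbo2", "water")])
        X += 0.01 * rng.uniform(0, 1, X.shape)
        S, A, info = nnmf_unmix(X, 3, max_iter=2000, tol=1e-10, init="nndsvda")
        ours = np.linalg.norm(X - A @ S)
        model = sklearn.NMF(3, init="nndsvda", solver="mu", max_iter=2000, tol=1e-10)
        W = model.fit_transform(X)
        theirs = np.linalg.norm(X - W @ model.components_)
        assert ours <= 1.5 * theirs + 1e-12


class TestProjectAbundances:
    def test_scaled_endmember_pixel(self, grid, lib):
        S = np.stack([lib["hb"].values, lib["water"].values])
        data = np.zeros((59, 1, 2))
        data[:, 0, 0] = 2.0 * S[0]
        stack = make_stack(grid, data)
        A = project_abundances(stack, stack.roi_mask, S)
        np.testing.assert_allclose(A[:, 0, 0], [2.0, 0.0], atol=1e-9)
        np.testing.assert_allclose(A[:, 0, 1], [0.0, 0.0], atol=1e-12)

    def test_orthogonal_design_closed_form(self, grid):
        # disjoint-support rows are orthogonal: NNLS must return the exact mix
        S = np.zeros((2, 59))
        S[0, :30] = 1.0
        S[1, 30:] = 1.0
        data = (1.0 * S[0] + 3.0 * S[1])[:, None, None]
        stack = make_stack(grid, data)
        A = project_abundances(stack, stack.roi_mask, S)
        np.testing.assert_allclose(A[:, 0, 0], [1.0, 3.0], atol=1e-9)

    def test_zero_endmember_row_rejected(self, grid, small_phantom):
        _, stack, _ = small_phantom
        S = np.zeros((1, 59))
        with pytest.raises(ValueError):
            project_abundances(stack, stack.roi_mask, S)

    def test_outside_roi_zero(self, grid, lib, small_phantom):
        _, stack, _ = small_phantom
        roi = spax.rect_roi(20, 20, 30, 40, stack.spatial_shape)
        S = np.stack([lib["hb"].values])
        A = project_abundances(stack, roi, S)
        assert np.all(A[:, ~roi] == 0.0)


class TestAssignComponents:
    def test_library_matches_itself(self, grid, lib):
        S = lib.matrix()
        out = assign_components(S, grid, lib)
        for k, name in enumerate(lib.names):
            assert out[k][0] == name
            assert out[k][1] == pytest.approx(1.0, abs=1e-9)

    def test_small_perturbation_keeps_assignment(self, grid, lib):
        rng = np.random.default_rng(0)
        S = lib.matrix() + 0.01 * rng.standard_normal((5, 59))
        out = assign_components(S, grid, lib)
        for k, name in enumerate(lib.names):
            assert out[k][0] == name
            assert out[k][1] >= 0.95

    def test_more_components_than_chromophores(self, grid, lib):
        small = spax.SpectraLibrary([lib["hb"]])
        S = np.stack([lib["hb"].values, lib["water"].values])
        out = assign_components(S, grid, small)
        names = {v[0] for v in out.values()}
        assert "hb" in names and "unknown" in names
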