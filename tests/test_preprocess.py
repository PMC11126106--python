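"""Flat-field correction, SG smoothing, normalization, trimming and PCA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thyrospec.errors import DegenerateReferenceError, ShapeError
from thyrospec.hsi_io import HyperCube
from thyrospec.preprocess import (
    minmax_normalize,
    pca_apply,
    pca_fit,
    savgol_smooth,
    spectral_profile,
    trim_bands,
    whiteboard_correct,
)


def _cube(data, units="raw_counts", bit_depth=16):
    data = np.asarray(data, dtype=float)
    return HyperCube(data, np.arange(data.shape[2], dtype=float) + 400,
                     bit_depth=bit_depth, units=units)


class TestWhiteboardCorrect:
    def test_board_signal_recovers_board_reflectance(self, rng):
        sw = _cube(rng.uniform(1000, 2000, size=(3, 3, 4)))
        sd = _cube(np.zeros((3, 3, 4)))
        out = whiteboard_correct(sw, sw, sd, rw=0.5)
        np.testing.assert_allclose(out.data, 0.5)
        assert out.units == "reflectance"

    def test_dark_signal_maps_to_zero(self, rng):
        sd = _cube(rng.uniform(50, 150, size=(2, 4, 3)))
        sw = _cube(sd.data + rng.uniform(500, 900, size=sd.data.shape))
        out = whiteboard_correct(sd, sw, sd)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_matches_scalar_loop_oracle(self, rng):
        s = _cube(rng.uniform(100, 4000, size=(2, 2, 3)))
        sw = _cube(rng.uniform(4100, 5000, size=(2, 2, 3)))
        sd = _cube(rng.uniform(0, 90, size=(2, 2, 3)))
        out = whiteboard_correct(s, sw, sd, rw=0.5)
        for i in range(2):
            for j in range(2):
                for b in range(3):
                    expect = (s.data[i, j, b] - sd.data[i, j, b]) / \
                        (sw.data[i, j, b] - sd.data[i, j, b]) * 0.5
                    assert out.data[i, j, b] == pytest.approx(expect)

    def test_degenerate_reference_reports_location(self):
        sw = _cube(np.full((2, 2, 2), 100.0))
        sd = _cube(np.full((2, 2, 2), 100.0))
        with pytest.raises(DegenerateReferenceError, match=r"\(0, 0, 0\)"):
            whiteboard_correct(sw, sw, sd)

    def test_monotone_in_raw_signal(self, rng):
        sw = _cube(rng.uniform(2000, 3000, size=(3, 3, 4)))
        sd = _cube(rng.uniform(0, 100, size=(3, 3, 4)))
        s = _cube(rng.uniform(200, 1900, size=(3, 3, 4)))
        base = whiteboard_correct(s, sw, sd).data
        bumped_data = s.data.copy()
        bumped_data[1, 2, 3] += 50
        bumped = whiteboard_correct(_cube(bumped_data), sw, sd).data
        assert bumped[1, 2, 3] > base[1, 2, 3]
        mask = np.ones_like(base, bool)
        mask[1, 2, 3] = False
        np.testing.assert_array_equal(bumped[mask], base[mask])


class TestSavgolSmooth:
    def test_constant_is_fixed_point(self):
        x = np.full(40, 3.7)
        np.testing.assert_allclose(savgol_smooth(x), x)

    def test_reproduces_degree_five_polynomial(self):
        t = np.linspace(-1, 1, 64)
        x = 2 - t + 0.5 * t**2 - t**3 + 0.1 * t**4 + 3 * t**5
        np.testing.assert_allclose(savgol_smooth(x, 21, 5), x, atol=1e-9)

    def test_matches_per_window_least_squares_oracle(self, rng):
        """Interior point j equals the centre value of an explicit quintic
        least-squares fit over points j-10..j+10."""
        x = rng.normal(size=64)
        out = savgol_smooth(x, 21, 5)
        half = 10
        t = np.arange(-half, half + 1, dtype=float)
        vander = np.vander(t, 6, increasing=True)
        for j in [10, 20, 33, 53]:
            coef, *_ = np.linalg.lstsq(vander, x[j - half:j + half + 1],
                                       rcond=None)
            assert out[j] == pytest.approx(coef[0], abs=1e-9)

    def test_boundary_uses_terminal_window_polynomial(self, rng):
        x = rng.normal(size=40)
        out = savgol_smooth(x, 21, 5)
        t = np.arange(21, dtype=float)
        coef, *_ = np.linalg.lstsq(np.vander(t, 6, increasing=True), x[:21],
                                   rcond=None)
        poly = np.polynomial.polynomial.polyval(0.0, coef)
        assert out[0] == pytest.approx(poly, abs=1e-9)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_linearity(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=(2, 32))
        a, b = r.normal(size=2)
        lhs = savgol_smooth(a * x + b * y)
        rhs = a * savgol_smooth(x) + b * savgol_smooth(y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            savgol_smooth(np.zeros(10), window=21)
        with pytest.raises(ValueError):
            savgol_smooth(np.zeros(40), window=21, polyorder=21)
        with pytest.raises(ValueError):
            savgol_smooth(np.zeros(40), window=20)


class TestMinmaxNormalize:
    def test_linear_map(self):
        np.testing.assert_allclose(minmax_normalize(np.array([2.0, 4.0, 6.0])),
                                   [0, 0.5, 1])

    def test_constant_maps_to_zero(self):
        np.testing.assert_array_equal(
            minmax_normalize(np.full((3, 3), 9.0)), np.zeros((3, 3)))

    def test_per_band_matches_loop(self, rng):
        v = rng.normal(size=(3, 3, 4))
        out = minmax_normalize(v, scope="per_band")
        for b in range(4):
            band = v[:, :, b]
            np.testing.assert_allclose(
                out[:, :, b], (band - band.min()) / (band.max() - band.min()))

    def test_per_spectrum_scope(self, rng):
        v = rng.normal(size=(2, 2, 5))
        out = minmax_normalize(v, scope="per_spectrum")
        assert out.min() == 0.0 and out.max() == 1.0
        for i in range(2):
            for j in range(2):
                assert out[i, j].min() == pytest.approx(0)
                assert out[i, j].max() == pytest.approx(1)


class TestTrimBands:
    def test_acquisition_trim_294_to_196(self, rng):
        cube = _cube(rng.uniform(0, 10, size=(2, 2, 294)))
        out = trim_bands(cube, 49)
        assert out.n_bands == 196
        np.testing.assert_array_equal(out.wavelengths, cube.wavelengths[49:245])

    def test_zero_trim_is_identity(self, small_cube):
        assert trim_bands(small_cube, 0) is small_cube

    def test_slice_enumeration(self):
        cube = HyperCube(np.zeros((1, 1, 10)), np.arange(10.0))
        out = trim_bands(cube, 2)
        np.testing.assert_array_equal(out.wavelengths, np.arange(2.0, 8.0))

    def test_composition(self, rng):
        cube = _cube(rng.uniform(0, 5, size=(2, 2, 30)))
        once = trim_bands(trim_bands(cube, 3), 4)
        direct = trim_bands(cube, 7)
        np.testing.assert_array_equal(once.data, direct.data)

    def test_empty_result_rejected(self, small_cube):
        with pytest.raises(ValueError):
            trim_bands(small_cube, 6)


class TestPCA:
    def test_rank_one_data_lossless(self, rng):
        direction = rng.normal(size=3)
        points = np.outer(rng.normal(size=50), direction) + 5.0
        proj = pca_fit(points, 1)
        recon = pca_apply(proj, points) @ proj.components + proj.mean
        assert np.abs(recon - points).max() < 1e-8

    def test_isotropic_variances_close(self, rng):
        x = rng.normal(size=(4000, 2))
        proj = pca_fit(x, 2)
        ratio = proj.explained_variance[0] / proj.explained_variance[1]
        assert ratio < 1.2

    def test_matches_dense_eigensolver_oracle(self, rng):
        x = rng.normal(size=(50, 6))
        proj = pca_fit(x, 3)
        # independent oracle: eigendecomposition of the covariance matrix
        cov = np.cov(x, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        top = evecs[:, np.argsort(evals)[::-1][:3]]
        # principal angles between the two 3-d subspaces
        s = np.linalg.svd(proj.components @ top, compute_uv=False)
        angles = np.arccos(np.clip(s, -1, 1))
        assert angles.max() < 1e-6
        np.testing.assert_allclose(np.sort(proj.explained_variance),
                                   np.sort(evals[-3:]), rtol=1e-8)

    def test_matches_sklearn_pca(self, rng):
        from sklearn.decomposition import PCA
        x = rng.normal(size=(80, 7))
        proj = pca_fit(x, 3)
        ref = PCA(n_components=3).fit(x)
        np.testing.assert_allclose(np.abs(proj.components),
                                   np.abs(ref.components_), atol=1e-8)
        np.testing.assert_allclose(proj.explained_variance,
                                   ref.explained_variance_, rtol=1e-8)

    def test_components_orthonormal_and_sorted(self, rng):
        proj = pca_fit(rng.normal(size=(40, 8)), 4)
        np.testing.assert_allclose(proj.components @ proj.components.T,
                                   np.eye(4), atol=1e-10)
        assert (np.diff(proj.explained_variance) <= 1e-12).all()

    def test_deterministic_sign_convention(self, rng):
        x = rng.normal(size=(30, 5))
        for proj in (pca_fit(x, 3), pca_fit(-x + 2 * x.mean(0), 3)):
            for row in proj.components:
                assert row[np.argmax(np.abs(row))] > 0

    def test_apply_shapes_and_centring(self, rng):
        x = rng.normal(size=(60, 196))
        proj = pca_fit(x, 3)
        block = rng.normal(size=(50, 50, 196))
        out = pca_apply(proj, block)
        assert out.shape == (50, 50, 3)
        centre = np.tile(proj.mean, (4, 4, 1))
        np.testing.assert_allclose(pca_apply(proj, centre), 0, atol=1e-9)

    def test_apply_matches_per_pixel_loop(self, rng):
        x = rng.normal(size=(30, 6))
        proj = pca_fit(x, 2)
        block = rng.normal(size=(4, 4, 6))
        out = pca_apply(proj, block)
        for i in range(4):
            for j in range(4):
                np.testing.assert_allclose(
                    out[i, j], proj.components @ (block[i, j] - proj.mean))

    def test_projection_is_contraction(self, rng):
        x = rng.normal(size=(40, 10))
        proj = pca_fit(x, 3)
        a, b = rng.normal(size=(2, 10))
        pa, pb = pca_apply(proj, a[None])[0], pca_apply(proj, b[None])[0]
        assert np.linalg.norm(pa - pb) <= np.linalg.norm(a - b) + 1e-12

    def test_reconstruction_error_non_increasing_in_k(self, rng):
        x = rng.normal(size=(80, 8)) @ rng.normal(size=(8, 8))
        errs = []
        for k in range(1, 6):
            proj = pca_fit(x, k)
            recon = pca_apply(proj, x) @ proj.components + proj.mean
            errs.append(float(((x - recon) ** 2).sum()))
        assert all(e1 >= e2 - 1e-9 for e1, e2 in zip(errs, errs[1:]))

    def test_rank_errors(self, rng):
        with pytest.raises(ValueError):
            pca_fit(rng.normal(size=(2, 5)), 3)
        proj = pca_fit(rng.normal(size=(20, 5)), 2)
        with pytest.raises(ShapeError):
            pca_apply(proj, rng.normal(size=(3, 3, 4)))

    def test_save_load_roundtrip(self, tmp_path, rng):
        from thyrospec.preprocess import PCAProjection
        proj = pca_fit(rng.normal(size=(20, 5)), 2)
        proj.save(tmp_path / "p.npz")
        back = PCAProjection.load(tmp_path / "p.npz")
        np.testing.assert_array_equal(back.components, proj.components)
        assert back.k == proj.k


class TestSpectralProfile:
    def test_constant_class_collapses_envelope(self, tiny_params):
        from thyrospec.synthgen import synth_case
        import dataclasses
        params = dataclasses.replace(tiny_params, jitter_sd=0.0, noise_sd=0.0,
                                     dark_noise=0.0, quantize=False)
        case = synth_case(params, "benign", seed=9)
        prof = spectral_profile([case], class_label=2, n_samples=50, seed=0)
        np.testing.assert_allclose(prof.min_curve, prof.mean_curve, atol=1e-9)
        np.testing.assert_allclose(prof.max_curve, prof.mean_curve, atol=1e-9)
        # derivative = forward difference of the smoothed mean, last repeated
        sm = savgol_smooth(prof.mean_curve)
        expect = np.append(np.diff(sm), np.diff(sm)[-1])
        np.testing.assert_allclose(prof.derivative_curve, expect, atol=1e-12)

    def test_linear_ramp_derivative_is_unity(self):
        # smoothing reproduces a linear ramp, so its first difference is 1
        ramp = np.arange(64, dtype=float)
        sm = savgol_smooth(ramp)
        np.testing.assert_allclose(np.diff(sm), 1.0, atol=1e-9)

    def test_envelope_orders_and_matches_endmember(self, tiny_cohort,
                                                   tiny_params):
        from thyrospec.synthgen import make_endmembers
        prof = spectral_profile(tiny_cohort, class_label=3, n_samples=150,
                                seed=1)
        assert (prof.min_curve <= prof.mean_curve + 1e-12).all()
        assert (prof.mean_curve <= prof.max_curve + 1e-12).all()
        # ground truth: the generating malignant endmember
        em = make_endmembers(tiny_params.separation,
                             seed=int(np.random.SeedSequence(5)
                                      .generate_state(7)[0] % 2**31),
                             n_bands=tiny_params.n_bands)
        sd = np.std
        spread = tiny_params.jitter_sd * em["malignant"] + tiny_params.noise_sd
        bound = 3 * spread / np.sqrt(150) + 0.01
        assert np.abs(prof.mean_curve - em["malignant"]).max() < bound.max() + 0.02

    def test_absent_class_rejected(self, tiny_case):
        from thyrospec.errors import EmptyClassError
        with pytest.raises(EmptyClassError):
            spectral_profile([tiny_case], class_label=2)
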