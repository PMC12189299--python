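"""Hyperspectral chain: reflectance calibration, PCA segmentation,
Savitzky-Golay derivatives, mean spectra, and spectral PCA."""

import numpy as np
import pytest

from extractopt.envi import load_cube_npz, read_envi, save_cube_npz, write_envi
from extractopt.exceptions import (
    DegenerateReferenceError,
    NoContrastError,
    ValidationError,
)
from extractopt.hsi import (
    HyperCube,
    SpectrumSet,
    correct_reflectance,
    mean_spectrum,
    pca_spectra,
    savgol_derivative,
    segment_foreground,
    sg_first_derivative,
)
from extractopt.simulate import CubeSpec, simulate_shelf_cubes


def _cube(data, wl=None, **kwargs):
    data = np.asarray(data, dtype=float)
    wl = np.arange(data.shape[2], dtype=float) if wl is None else wl
    return HyperCube(data=data, wavelengths=wl, **kwargs)


class TestReflectanceCorrection:
    def test_raw_equal_white_gives_ones(self):
        white = np.linspace(0.8, 1.0, 5)
        raw = _cube(np.broadcast_to(white, (4, 4, 5)).copy())
        out = correct_reflectance(raw, white=white, dark=np.zeros(5))
        assert np.allclose(out.data, 1.0)
        assert out.corrected

    def test_raw_equal_dark_gives_zeros(self):
        dark = np.full(5, 0.05)
        raw = _cube(np.broadcast_to(dark, (4, 4, 5)).copy())
        out = correct_reflectance(raw, white=np.ones(5), dark=dark)
        assert np.allclose(out.data, 0.0)

    def test_matches_elementwise_formula_oracle(self):
        rng = np.random.default_rng(4)
        raw = _cube(rng.uniform(0.1, 0.9, (3, 5, 7)))
        white = rng.uniform(0.8, 1.0, 7)
        dark = rng.uniform(0.0, 0.1, 7)
        out = correct_reflectance(raw, white=white, dark=dark)
        oracle = np.empty_like(raw.data)
        for i in range(3):
            for j in range(5):
                for k in range(7):
                    oracle[i, j, k] = (raw.data[i, j, k] - dark[k]) / (white[k] - dark[k])
        assert np.allclose(out.data, oracle, atol=1e-12)

    def test_degenerate_band_listed_in_error(self):
        white = np.ones(4)
        dark = np.array([0.0, 1.0, 0.0, 1.0])  # bands 1 and 3 collapse
        raw = _cube(np.zeros((2, 2, 4)))
        with pytest.raises(DegenerateReferenceError) as err:
            correct_reflectance(raw, white=white, dark=dark)
        assert err.value.bands == [1, 3]


class TestSegmentation:
    def test_recovers_ground_truth_mask_on_simulated_scene(self):
        frame = simulate_shelf_cubes(CubeSpec(seed=2), times=("T1",))[0]
        corrected = correct_reflectance(frame.cube)
        mask = segment_foreground(corrected)
        agreement = (mask == frame.truth_foreground).mean()
        assert agreement >= 0.99

    def test_mask_partitions_the_frame(self):
        frame = simulate_shelf_cubes(CubeSpec(seed=3), times=("T1",))[0]
        mask = segment_foreground(correct_reflectance(frame.cube))
        assert mask.dtype == bool
        assert mask.sum() + (~mask).sum() == mask.size

    def test_constant_cube_raises_no_contrast(self):
        cube = _cube(np.full((6, 6, 10), 0.5), corrected=True)
        with pytest.raises(NoContrastError):
            segment_foreground(cube)


class TestSavitzkyGolayDerivative:
    def test_constant_spectrum_has_zero_derivative(self):
        out = savgol_derivative(np.full(20, 3.7))
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_exact_on_quadratic_sequences(self):
        k = np.arange(30, dtype=float)
        a, b, c = 2.0, -0.7, 0.05
        y = a + b * k + c * k**2
        out = savgol_derivative(y)
        expected = b + 2 * c * k[3:-3]
        assert np.allclose(out, expected, atol=1e-10)

    def test_matches_local_polyfit_oracle(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=40)
        out = savgol_derivative(y, window=7, polyorder=2)
        for center in range(3, 37):
            window = y[center - 3:center + 4]
            coeffs = np.polyfit(np.arange(-3, 4), window, 2)
            slope_at_center = coeffs[1]  # d/dk of c2 k^2 + c1 k + c0 at k=0
            assert out[center - 3] == pytest.approx(slope_at_center, abs=1e-10)

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError):
            savgol_derivative(np.zeros(20), window=6)

    def test_derivative_commutes_with_averaging(self):
        rng = np.random.default_rng(12)
        wl = np.arange(50, dtype=float)
        specs = rng.normal(size=(5, 50))
        sset = SpectrumSet(wl, {f"s{i}": specs[i] for i in range(5)})
        deriv = sg_first_derivative(sset)
        mean_then_sg = savgol_derivative(specs.mean(axis=0))
        sg_then_mean = np.mean([deriv.spectra[f"s{i}"] for i in range(5)], axis=0)
        assert np.allclose(mean_then_sg, sg_then_mean, atol=1e-10)

    def test_trims_window_edges_and_sets_provenance(self):
        wl = np.arange(20, dtype=float)
        sset = SpectrumSet(wl, {"a": np.zeros(20)})
        deriv = sg_first_derivative(sset)
        assert len(deriv.wavelengths) == 14
        assert deriv.wavelengths[0] == 3.0
        assert deriv.provenance == "sg_derivative"


class TestMeanSpectrum:
    def test_single_pixel_mask_returns_that_spectrum(self):
        rng = np.random.default_rng(1)
        cube = _cube(rng.uniform(size=(4, 4, 6)))
        mask = np.zeros((4, 4), dtype=bool)
        mask[2, 3] = True
        assert np.array_equal(mean_spectrum(cube, mask), cube.data[2, 3])

    def test_homogeneous_cube_returns_common_spectrum(self):
        spectrum = np.linspace(0.2, 0.8, 6)
        cube = _cube(np.broadcast_to(spectrum, (3, 3, 6)).copy())
        assert np.allclose(mean_spectrum(cube), spectrum)

    def test_matches_explicit_loop_average(self):
        rng = np.random.default_rng(5)
        cube = _cube(rng.uniform(size=(5, 4, 3)))
        mask = rng.uniform(size=(5, 4)) > 0.4
        result = mean_spectrum(cube, mask)
        acc = np.zeros(3)
        count = 0
        for i in range(5):
            for j in range(4):
                if mask[i, j]:
                    acc += cube.data[i, j]
                    count += 1
        assert np.allclose(result, acc / count, atol=1e-12)

    def test_empty_mask_rejected(self):
        cube = _cube(np.zeros((2, 2, 3)))
        with pytest.raises(ValidationError, match="no pixels"):
            mean_spectrum(cube, np.zeros((2, 2), dtype=bool))


class TestPcaSpectra:
    def test_rank_one_data_explained_by_first_component(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=30)
        X = np.outer(rng.normal(size=8), base)
        result = pca_spectra(X, n_components=2)
        assert result.explained_variance_pct[0] == pytest.approx(100.0, abs=1e-8)

    def test_explained_variance_non_increasing_and_bounded(self):
        rng = np.random.default_rng(7)
        result = pca_spectra(rng.normal(size=(10, 25)), n_components=5)
        ev = result.explained_variance_pct
        assert np.all(np.diff(ev) <= 1e-12)
        assert ev.sum() <= 100.0 + 1e-6

    def test_centered_data_reconstructed_from_all_components(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(6, 12))
        result = pca_spectra(X, n_components=5)  # full rank for 6 samples
        reconstructed = result.scores @ result.loadings.T + result.mean
        assert np.allclose(reconstructed, X, atol=1e-8)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(10)
        result = pca_spectra(rng.normal(size=(9, 20)), n_components=4)
        gram = result.loadings.T @ result.loadings
        assert np.allclose(gram, np.eye(4), atol=1e-10)

    def test_requesting_too_many_components_truncates_with_warning(self):
        rng = np.random.default_rng(11)
        with pytest.warns(UserWarning, match="truncating"):
            result = pca_spectra(rng.normal(size=(3, 10)), n_components=5)
        assert result.scores.shape[1] == 2


class TestCubeIO:
    def test_envi_round_trip(self, tmp_path):
        rng = np.random.default_rng(13)
        cube = _cube(rng.uniform(size=(5, 6, 8)).astype(np.float32).astype(float),
                     wl=np.linspace(935, 991, 8))
        write_envi(cube, tmp_path / "cube")
        back = read_envi(tmp_path / "cube")
        assert np.allclose(back.data, cube.data, atol=1e-7)
        assert np.allclose(back.wavelengths, cube.wavelengths, atol=1e-3)

    def test_npz_round_trip_preserves_references(self, tmp_path):
        frame = simulate_shelf_cubes(CubeSpec(shape=(8, 8), seed=4), times=("T1",))[0]
        path = save_cube_npz(frame.cube, tmp_path / "cube.npz")
        back = load_cube_npz(path)
        assert np.array_equal(back.data, frame.cube.data)
        assert np.array_equal(back.white_ref, frame.cube.white_ref)
        assert not back.corrected
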