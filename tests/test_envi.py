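import numpy as np
import pytest

from oleospec.envi import (
    EnviFormatError,
    Hypercube,
    average_replicates,
    average_reference_frames,
    calibrate_reflectance,
    mean_spectrum,
    read_envi,
    segment_roi,
    write_envi,
)
from oleospec.synthetic import SpectralSceneSpec, generate_hypercube


def random_cube(rng, shape=(6, 5, 8), dtype=np.float32, interleave="bsq"):
    data = rng.random(shape).astype(dtype)
    wl = np.linspace(900, 1600, shape[2])
    return Hypercube(data=data, wavelengths=wl, interleave=interleave)


class TestEnviIO:
    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    @pytest.mark.parametrize("dtype", [np.float32, np.float64, np.uint16])
    def test_roundtrip_bit_exact(self, tmp_path, interleave, dtype):
        rng = np.random.default_rng(0)
        if dtype is np.uint16:
            data = rng.integers(0, 4000, size=(6, 5, 8)).astype(np.uint16)
            cube = Hypercube(data=data, wavelengths=np.linspace(900, 1600, 8),
                             interleave=interleave)
        else:
            cube = random_cube(rng, dtype=dtype, interleave=interleave)
        hdr, _ = write_envi(cube, str(tmp_path / "cube"))
        back = read_envi(hdr)
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_allclose(back.wavelengths, cube.wavelengths, atol=1e-6)

    def test_interleaves_agree(self, tmp_path):
        rng = np.random.default_rng(1)
        cube = random_cube(rng)
        outs = {}
        for il in ("bsq", "bil"):
            c = Hypercube(data=cube.data, wavelengths=cube.wavelengths, interleave=il)
            hdr, _ = write_envi(c, str(tmp_path / il))
            outs[il] = read_envi(hdr).data
        np.testing.assert_array_equal(outs["bsq"], outs["bil"])

    def test_band_count_mismatch_rejected(self, tmp_path):
        rng = np.random.default_rng(2)
        cube = random_cube(rng)
        hdr, _ = write_envi(cube, str(tmp_path / "bad"))
        text = open(hdr).read().replace("bands = 8", "bands = 7")
        open(hdr, "w").write(text)
        with pytest.raises(EnviFormatError):
            read_envi(hdr)

    def test_missing_wavelengths_rejected(self, tmp_path):
        rng = np.random.default_rng(3)
        cube = random_cube(rng)
        hdr, _ = write_envi(cube, str(tmp_path / "nw"))
        lines = [ln for ln in open(hdr) if not ln.startswith("wavelength =")]
        open(hdr, "w").writelines(lines)
        with pytest.raises(EnviFormatError):
            read_envi(hdr)

    def test_unknown_interleave_rejected(self, tmp_path):
        rng = np.random.default_rng(4)
        cube = random_cube(rng)
        hdr, _ = write_envi(cube, str(tmp_path / "il"))
        text = open(hdr).read().replace("interleave = bsq", "interleave = xyz")
        open(hdr, "w").write(text)
        with pytest.raises(EnviFormatError):
            read_envi(hdr)


class TestCalibration:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.dark = rng.random((4, 4, 6)) * 0.1
        self.white = self.dark + 0.5 + rng.random((4, 4, 6)) * 0.2
        self.wl = np.linspace(900, 1600, 6)

    def _cube(self, data):
        return Hypercube(data=data, wavelengths=self.wl)

    def test_trivial_points(self):
        assert np.allclose(calibrate_reflectance(self._cube(self.white), self.white, self.dark).data, 1.0)
        assert np.allclose(calibrate_reflectance(self._cube(self.dark), self.white, self.dark).data, 0.0)
        mid = (self.white + self.dark) / 2
        assert np.allclose(calibrate_reflectance(self._cube(mid), self.white, self.dark).data, 0.5)

    def test_gain_invariance(self):
        raw = (self.white + self.dark) / 3
        r1 = calibrate_reflectance(self._cube(raw), self.white, self.dark).data
        r2 = calibrate_reflectance(self._cube(raw * 7.5), self.white * 7.5, self.dark * 7.5).data
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    def test_white_equals_dark_names_band(self):
        white = self.white.copy()
        white[:, :, 3] = self.dark[:, :, 3]
        with pytest.raises(ValueError, match="band index 3"):
            calibrate_reflectance(self._cube(self.dark), white, self.dark)

    def test_reference_frame_averaging(self):
        rng = np.random.default_rng(6)
        frames = rng.random((10, 3, 3, 4))
        np.testing.assert_allclose(average_reference_frames(frames), frames.mean(axis=0))


class TestSegmentation:
    def test_recovers_synthetic_disk(self):
        from scipy.ndimage import binary_dilation

        cube, truth = generate_hypercube(0.8, SpectralSceneSpec(), shape=(48, 48), seed=1)
        roi = segment_roi(cube)
        overlap = (roi.mask & truth).sum() / truth.sum()
        assert overlap >= 0.95
        assert np.all(binary_dilation(truth, iterations=2) | ~roi.mask)

    def test_all_background_rejected(self):
        data = np.full((20, 20, 5), 0.02)
        cube = Hypercube(data=data, wavelengths=np.arange(5.0) + 1)
        with pytest.raises(ValueError):
            segment_roi(cube)

    def test_mask_area_monotone_in_threshold(self):
        cube, _ = generate_hypercube(0.8, SpectralSceneSpec(), shape=(48, 48), seed=2)
        areas = [segment_roi(cube, threshold=t).count for t in np.linspace(0.05, 0.3, 8)]
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestSpectrumExtraction:
    def test_single_pixel_mask(self):
        rng = np.random.default_rng(7)
        cube = random_cube(rng)
        mask = np.zeros((6, 5), dtype=bool)
        mask[2, 3] = True
        np.testing.assert_allclose(mean_spectrum(cube, mask), cube.data[2, 3])

    def test_uniform_cube(self):
        cube = Hypercube(data=np.full((4, 4, 3), 0.4), wavelengths=np.arange(3.0) + 1)
        mask = np.ones((4, 4), dtype=bool)
        np.testing.assert_allclose(mean_spectrum(cube, mask), 0.4)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        cube = random_cube(rng)
        mask = rng.random((6, 5)) > 0.4
        got = mean_spectrum(cube, mask)
        expected = np.zeros(8)
        count = 0
        for i in range(6):
            for j in range(5):
                if mask[i, j]:
                    expected += cube.data[i, j]
                    count += 1
        np.testing.assert_allclose(got, expected / count, rtol=1e-6)

    def test_full_mask_equals_global_mean(self):
        rng = np.random.default_rng(9)
        cube = random_cube(rng)
        np.testing.assert_allclose(
            mean_spectrum(cube, np.ones((6, 5), bool)), cube.data.mean(axis=(0, 1)), rtol=1e-6
        )

    def test_replicate_average(self):
        reps = [np.array([1.0, 2.0]), np.array([3.0, 4.0]), np.array([5.0, 6.0])]
        np.testing.assert_allclose(average_replicates(reps), [3.0, 4.0])
        with pytest.raises(ValueError):
            average_replicates([np.ones(3), np.ones(4)])
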