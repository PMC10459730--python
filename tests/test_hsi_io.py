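import numpy as np
import pytest

from leafspec.hsi_io import (
    CalibrationFrames,
    DegenerateReferenceError,
    ROIEllipse,
    SpectraMatrix,
    SpectralCube,
    correct_reflectance,
    mean_spectrum,
    read_cube,
    roi_pixels,
    write_cube,
)


def _cube(data):
    data = np.asarray(data, dtype=float)
    return SpectralCube(data=data, wavelengths=np.arange(data.shape[2], dtype=float) + 400)


class TestCorrectReflectance:
    def test_raw_equals_white_gives_one(self):
        raw = _cube(np.full((3, 4, 5), 0.9))
        out = correct_reflectance(CalibrationFrames(raw=raw, white=np.full((4, 5), 0.9), dark=np.full((4, 5), 0.1)))
        np.testing.assert_allclose(out.data, 1.0)

    def test_raw_equals_dark_gives_zero(self):
        raw = _cube(np.full((3, 4, 5), 0.1))
        out = correct_reflectance(CalibrationFrames(raw=raw, white=np.full((4, 5), 0.9), dark=np.full((4, 5), 0.1)))
        np.testing.assert_allclose(out.data, 0.0)

    def test_hand_arithmetic(self):
        # (0.5 - 0.1) / (0.9 - 0.1) = 0.5
        raw = _cube(np.full((2, 2, 2), 0.5))
        out = correct_reflectance(CalibrationFrames(raw=raw, white=np.full((2, 2), 0.9), dark=np.full((2, 2), 0.1)))
        np.testing.assert_allclose(out.data, 0.5)

    def test_affine_invariance(self, rng):
        raw = _cube(rng.uniform(0.2, 0.8, (3, 4, 6)))
        white = rng.uniform(0.85, 0.95, (4, 6))
        dark = rng.uniform(0.01, 0.05, (4, 6))
        r1 = correct_reflectance(CalibrationFrames(raw=raw, white=white, dark=dark))
        scaled = SpectralCube(data=raw.data * 3.7, wavelengths=raw.wavelengths)
        r2 = correct_reflectance(CalibrationFrames(raw=scaled, white=white * 3.7, dark=dark * 3.7))
        np.testing.assert_allclose(r1.data, r2.data, rtol=1e-12)

    def test_degenerate_reference_named(self):
        raw = _cube(np.full((2, 2, 3), 0.5))
        white = np.full((2, 3), 0.9)
        white[1, 2] = 0.1
        with pytest.raises(DegenerateReferenceError, match="band=2"):
            correct_reflectance(CalibrationFrames(raw=raw, white=white, dark=np.full((2, 3), 0.1)))

    def test_full_cube_references_accepted(self, rng):
        raw = _cube(rng.uniform(0.2, 0.8, (3, 4, 6)))
        white = np.full((3, 4, 6), 0.9)
        dark = np.full((3, 4, 6), 0.1)
        out = correct_reflectance(CalibrationFrames(raw=raw, white=white, dark=dark))
        assert out.shape == (3, 4, 6)


class TestRoiPixels:
    @staticmethod
    def brute_force(center, a, b, shape):
        # independent oracle: test every pixel of the image
        cy, cx = center
        out = []
        for r in range(shape[0]):
            for c in range(shape[1]):
                xi, yi = c - cx, r - cy
                if xi**2 / a**2 + yi**2 / b**2 <= 1:
                    out.append((r, c))
        return out

    def test_unit_circle_five_pixels(self):
        got = roi_pixels(ROIEllipse(center=(5, 5), semi_axes=(1, 1)), (11, 11))
        assert got == [(4, 5), (5, 4), (5, 5), (5, 6), (6, 5)]

    def test_half_unit_single_pixel(self):
        assert roi_pixels(ROIEllipse(center=(3, 3), semi_axes=(0.5, 0.5)), (7, 7)) == [(3, 3)]

    def test_two_by_one_seven_pixels(self):
        got = roi_pixels(ROIEllipse(center=(5, 5), semi_axes=(2, 1)), (11, 11))
        assert len(got) == 7
        assert got == self.brute_force((5, 5), 2, 1, (11, 11))

    @pytest.mark.parametrize("a,b", [(1.5, 2.5), (3, 3), (4.2, 1.1)])
    def test_matches_brute_force(self, a, b):
        got = roi_pixels(ROIEllipse(center=(10, 12), semi_axes=(a, b)), (25, 25))
        assert got == self.brute_force((10, 12), a, b, (25, 25))

    def test_symmetry_about_center(self):
        got = roi_pixels(ROIEllipse(center=(10, 10), semi_axes=(3, 2)), (21, 21))
        offs = {(r - 10, c - 10) for r, c in got}
        assert offs == {(-r, c) for r, c in offs} == {(r, -c) for r, c in offs}

    def test_row_major_ordering(self):
        got = roi_pixels(ROIEllipse(center=(8, 8), semi_axes=(2.5, 2.5)), (20, 20))
        assert got == sorted(got)

    def test_boundary_clipping(self):
        got = roi_pixels(ROIEllipse(center=(0, 0), semi_axes=(1, 1)), (5, 5))
        assert got == [(0, 0), (0, 1), (1, 0)]

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError):
            roi_pixels(ROIEllipse(center=(50, 50), semi_axes=(1, 1)), (5, 5))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            ROIEllipse(center=(1, 1), semi_axes=(0, 1))
        with pytest.raises(ValueError):
            ROIEllipse(center=(1, 1), semi_axes=(1, 1), step=(0, 1))


class TestMeanSpectrum:
    def test_identical_pixels(self):
        cube = _cube(np.full((4, 4, 3), 0.6))
        np.testing.assert_allclose(mean_spectrum(cube, [(0, 0), (1, 1)]), 0.6)

    def test_two_pixel_average(self):
        data = np.zeros((2, 2, 4))
        data[0, 0] = 0.0
        data[0, 1] = 1.0
        np.testing.assert_allclose(mean_spectrum(_cube(data), [(0, 0), (0, 1)]), 0.5)

    def test_pooled_three_ellipse_harvest(self, rng):
        cube = _cube(rng.uniform(0, 1, (30, 30, 5)))
        ellipses = [
            ROIEllipse(center=(5, 5), semi_axes=(2, 2)),
            ROIEllipse(center=(15, 15), semi_axes=(3, 2)),
            ROIEllipse(center=(24, 10), semi_axes=(2, 3)),
        ]
        pooled = []
        for e in ellipses:
            pooled.extend(roi_pixels(e, (30, 30)))
        # oracle: plain mean over the pooled coordinate multiset
        expected = np.mean([cube.data[r, c] for r, c in pooled], axis=0)
        np.testing.assert_allclose(mean_spectrum(cube, pooled), expected, rtol=1e-12)

    def test_permutation_invariance(self, rng):
        cube = _cube(rng.uniform(0, 1, (10, 10, 4)))
        pix = roi_pixels(ROIEllipse(center=(5, 5), semi_axes=(3, 3)), (10, 10))
        shuffled = list(pix)
        rng.shuffle(shuffled)
        np.testing.assert_allclose(mean_spectrum(cube, pix), mean_spectrum(cube, shuffled))

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            mean_spectrum(_cube(np.zeros((2, 2, 2))), [])


class TestEnviRoundTrip:
    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    def test_roundtrip_bit_identical(self, tmp_path, rng, interleave):
        cube = _cube(rng.uniform(0, 1, (4, 5, 6)))
        hdr = write_cube(cube, str(tmp_path / "c.img"), interleave=interleave)
        back = read_cube(hdr)
        np.testing.assert_array_equal(back.data, cube.data)
        np.testing.assert_array_equal(back.wavelengths, cube.wavelengths)

    def test_interleave_equivalence(self, tmp_path, rng):
        cube = _cube(rng.uniform(0, 1, (3, 4, 5)))
        a = read_cube(write_cube(cube, str(tmp_path / "a.img"), "bsq"))
        b = read_cube(write_cube(cube, str(tmp_path / "b.img"), "bil"))
        np.testing.assert_array_equal(a.data, b.data)

    def test_float32_preserved(self, tmp_path, rng):
        cube = SpectralCube(
            data=rng.uniform(0, 1, (2, 3, 4)).astype(np.float32),
            wavelengths=np.arange(4.0),
        )
        back = read_cube(write_cube(cube, str(tmp_path / "f.img")))
        assert back.data.dtype == np.float32
        np.testing.assert_array_equal(back.data, cube.data)

    def test_band_count_mismatch_rejected(self, tmp_path, rng):
        cube = _cube(rng.uniform(0, 1, (2, 2, 4)))
        hdr = write_cube(cube, str(tmp_path / "c.img"))
        text = open(hdr).read().replace("bands = 4", "bands = 5")
        open(hdr, "w").write(text)
        with pytest.raises(ValueError, match="wavelength list length"):
            read_cube(hdr)

    def test_missing_wavelengths_rejected(self, tmp_path, rng):
        cube = _cube(rng.uniform(0, 1, (2, 2, 3)))
        hdr = write_cube(cube, str(tmp_path / "c.img"))
        lines = [l for l in open(hdr).read().splitlines() if not l.startswith("wavelength")]
        open(hdr, "w").write("\n".join(lines))
        with pytest.raises(ValueError, match="wavelength"):
            read_cube(hdr)

    def test_wavelength_range_subset(self, tmp_path, rng):
        data = rng.uniform(0, 1, (2, 2, 10))
        cube = SpectralCube(data=data, wavelengths=np.linspace(400, 1000, 10))
        hdr = write_cube(cube, str(tmp_path / "c.img"))
        sub = read_cube(hdr, wavelength_range=(430, 900))
        assert sub.wavelengths.min() >= 430 and sub.wavelengths.max() <= 900
        assert sub.data.shape[2] == sub.wavelengths.size


class TestSpectraMatrix:
    def test_csv_roundtrip(self, tmp_path, rng):
        mat = SpectraMatrix(
            values=rng.uniform(0, 1, (3, 5)),
            wavelengths=np.linspace(430, 900, 5),
            sample_ids=["a", "b", "c"],
        )
        mat.to_csv(tmp_path / "m.csv")
        back = SpectraMatrix.from_csv(tmp_path / "m.csv")
        np.testing.assert_allclose(back.values, mat.values, rtol=1e-9)
        assert back.sample_ids == mat.sample_ids

    def test_decreasing_axis_rejected(self):
        with pytest.raises(ValueError):
            SpectraMatrix(values=np.zeros((1, 3)), wavelengths=[3.0, 2.0, 1.0])
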