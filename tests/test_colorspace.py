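import numpy as np
import pytest
from skimage.color import deltaE_ciede2000 as skimage_ciede2000

from glavenstats import colorspace as cs
from glavenstats.colorspace import (
    ColorImage,
    MonitorCalibration,
    Spectrum,
    calibration_to_matrix,
    ciede2000,
    lms_to_mbdkl,
    project_isoluminant,
    rgb_to_lms,
    spectrum_to_tristimulus,
    xyz_to_lab,
)

DELTA = 6.0 / 29.0


# ---------------------------------------------------------------------------
# Spectrum / calibration types
# ---------------------------------------------------------------------------


class TestSpectrum:
    def test_rejects_decreasing_wavelengths(self):
        with pytest.raises(ValueError, match="increasing"):
            Spectrum(np.array([500.0, 400.0, 600.0]), np.zeros(3))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([400.0, 500.0]), np.zeros(3))

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="finite"):
            Spectrum(np.array([400.0, 500.0]), np.array([0.1, np.nan]))

    def test_resample_zero_fills_outside_support(self):
        s = Spectrum(np.array([450.0, 550.0]), np.array([1.0, 1.0]))
        r = s.resample(np.array([400.0, 500.0, 600.0]))
        assert r.values[0] == 0.0 and r.values[2] == 0.0 and r.values[1] == 1.0

    def test_csv_round_trip(self, tmp_path):
        s = Spectrum(np.linspace(400, 700, 7), np.linspace(0, 1, 7))
        path = tmp_path / "s.csv"
        s.to_csv(path)
        back = Spectrum.from_csv(path)
        np.testing.assert_allclose(back.wavelengths_nm, s.wavelengths_nm)
        np.testing.assert_allclose(back.values, s.values)


class TestCalibrationToMatrix:
    def test_equal_energy_primaries_give_unit_columns(self):
        cal = MonitorCalibration(
            primaries_xyY=np.array([[1 / 3, 1 / 3, 1.0]] * 3) +
            np.array([[0, 0, 0], [1e-3, 0, 0], [0, 1e-3, 0]])  # break singularity
        )
        # strict version of the example: each column maps to (x/y*Y, Y, (1-x-y)/y*Y)
        mat = calibration_to_matrix(cal)
        np.testing.assert_allclose(mat[:, 0], [1.0, 1.0, 1.0], atol=5e-3)

    def test_printed_monitor_white_luminance(self, cal):
        # sum of the printed phosphor luminances
        white = cal.white_xyz()
        assert white[1] == pytest.approx(37.223 + 86.659 + 7.9206, abs=1e-9)
        assert white[1] == pytest.approx(131.80, abs=0.01)

    def test_red_column_x_from_xyY(self, cal):
        mat = cal.rgb_to_xyz_matrix()
        assert mat[0, 0] == pytest.approx(0.6733 * 37.223 / 0.3088, rel=1e-12)

    def test_zero_y_is_invalid(self):
        with pytest.raises(cs.CalibrationError):
            MonitorCalibration(
                primaries_xyY=np.array(
                    [[0.6, 0.0, 30.0], [0.2, 0.7, 80.0], [0.15, 0.06, 8.0]]
                )
            ).rgb_to_xyz_matrix()

    def test_coincident_primaries_are_degenerate(self):
        cal = MonitorCalibration(primaries_xyY=np.array([[1 / 3, 1 / 3, 1.0]] * 3))
        with pytest.raises(cs.CalibrationError, match="degenerate"):
            calibration_to_matrix(cal)

    def test_matrix_times_ones_is_white(self, cal):
        mat = cal.rgb_to_xyz_matrix()
        np.testing.assert_allclose(mat @ np.ones(3), cal.white_xyz())


# ---------------------------------------------------------------------------
# CIELAB
# ---------------------------------------------------------------------------


class TestXyzToLab:
    def test_white_maps_to_L100(self, cal):
        white = cal.white_xyz()
        img = ColorImage(white.reshape(1, 1, 3), "XYZ")
        lab = xyz_to_lab(img, white).data[0, 0]
        np.testing.assert_allclose(lab, [100.0, 0.0, 0.0], atol=1e-10)

    def test_monitor_max_rgb_is_white(self, cal):
        img = ColorImage(np.ones((1, 1, 3)), "linearRGB")
        lab = cs.rgb_to_lab(img, cal).data[0, 0]
        np.testing.assert_allclose(lab, [100.0, 0.0, 0.0], atol=1e-10)

    def test_black_maps_to_origin(self, cal):
        img = ColorImage(np.zeros((1, 1, 3)), "XYZ")
        lab = xyz_to_lab(img, cal.white_xyz()).data[0, 0]
        # linear branch at zero: L* = 116 * (4/29) - 16 = 0
        np.testing.assert_allclose(lab, [0.0, 0.0, 0.0], atol=1e-12)

    def test_branch_continuity_at_delta_cubed(self):
        t = DELTA**3
        upper = np.cbrt(t)
        lower = t / (3 * DELTA**2) + 4.0 / 29.0
        assert upper == pytest.approx(DELTA, abs=1e-15)
        assert abs(upper - lower) < 1e-12
        # the implementation itself is continuous across the branch point
        eps = 1e-14
        vals = cs._lab_f(np.array([t - eps, t, t + eps]))
        assert np.max(np.abs(np.diff(vals))) < 1e-12

    def test_nonpositive_white_rejected(self):
        img = ColorImage(np.ones((1, 1, 3)), "XYZ")
        with pytest.raises(ValueError):
            xyz_to_lab(img, np.array([1.0, 0.0, 1.0]))

    def test_round_trip_lab_xyz(self, cal, rng):
        white = cal.white_xyz()
        xyz = ColorImage(rng.uniform(0, 1, (8, 8, 3)) * white, "XYZ")
        back = cs.lab_to_xyz(xyz_to_lab(xyz, white), white)
        np.testing.assert_allclose(back.data, xyz.data, atol=1e-10)


class TestRgbXyzRoundTrip:
    def test_round_trip_error_below_1e10(self, cal, rng):
        img = ColorImage(rng.uniform(0, 1, (16, 16, 3)), "linearRGB")
        back = cs.xyz_to_rgb(cs.rgb_to_xyz(img, cal), cal)
        assert np.max(np.abs(back.data - img.data)) < 1e-10


# ---------------------------------------------------------------------------
# CIEDE2000
# ---------------------------------------------------------------------------

# Standard verification pairs (Lab1, Lab2, expected dE00); expected values
# cross-computed with an independent reference implementation and spot-
# checked against the published table.
CIEDE_PAIRS = [
    ((50.0000, 2.6772, -79.7751), (50.0000, 0.0000, -82.7485), 2.0425),
    ((50.0000, 3.1571, -77.2803), (50.0000, 0.0000, -82.7485), 2.8615),
    ((50.0000, 2.8361, -74.0200), (50.0000, 0.0000, -82.7485), 3.4412),
    ((50.0000, -1.3802, -84.2814), (50.0000, 0.0000, -82.7485), 1.0000),
    ((50.0000, -1.1848, -84.8006), (50.0000, 0.0000, -82.7485), 1.0000),
    ((50.0000, -0.9009, -85.5211), (50.0000, 0.0000, -82.7485), 1.0000),
    ((50.0000, 0.0000, 0.0000), (50.0000, -1.0000, 2.0000), 2.3669),
    ((50.0000, -1.0000, 2.0000), (50.0000, 0.0000, 0.0000), 2.3669),
    ((50.0000, 2.4900, -0.0010), (50.0000, -2.4900, 0.0009), 7.1792),
    ((50.0000, 2.4900, -0.0010), (50.0000, -2.4900, 0.0010), 7.1792),
    ((50.0000, 2.4900, -0.0010), (50.0000, -2.4900, 0.0011), 7.2195),
    ((50.0000, 2.4900, -0.0010), (50.0000, -2.4900, 0.0012), 7.2195),
    ((50.0000, -0.0010, 2.4900), (50.0000, 0.0009, -2.4900), 4.8045),
    ((50.0000, -0.0010, 2.4900), (50.0000, 0.0010, -2.4900), 4.8045),
    ((50.0000, -0.0010, 2.4900), (50.0000, 0.0011, -2.4900), 4.7461),
    ((50.0000, 2.5000, 0.0000), (50.0000, 0.0000, -2.5000), 4.3065),
    ((50.0000, 2.5000, 0.0000), (73.0000, 25.0000, -18.0000), 27.1492),
    ((50.0000, 2.5000, 0.0000), (61.0000, -5.0000, 29.0000), 22.8977),
    ((50.0000, 2.5000, 0.0000), (56.0000, -27.0000, -3.0000), 31.9030),
    ((50.0000, 2.5000, 0.0000), (58.0000, 24.0000, 15.0000), 19.4535),
    ((50.0000, 2.5000, 0.0000), (50.0000, 3.1736, 0.5854), 1.0000),
    ((50.0000, 2.5000, 0.0000), (50.0000, 3.2972, 0.0000), 1.0000),
    ((50.0000, 2.5000, 0.0000), (50.0000, 1.8634, 0.5757), 1.0000),
    ((50.0000, 2.5000, 0.0000), (50.0000, 3.2592, 0.3350), 1.0000),
    ((60.2574, -34.0099, 36.2677), (60.4626, -34.1751, 39.4387), 1.2644),
    ((63.0109, -31.0961, -5.8663), (62.8187, -29.7946, -4.0864), 1.2630),
    ((61.2901, 3.7196, -5.3901), (61.4292, 2.2480, -4.9620), 1.8731),
    ((35.0831, -44.1164, 3.7933), (35.0232, -40.0716, 1.5901), 1.8645),
    ((22.7233, 20.0904, -46.6940), (23.0331, 14.9730, -42.5619), 2.0373),
    ((36.4612, 47.8580, 18.3852), (36.2715, 50.5065, 21.2231), 1.4146),
    ((90.8027, -2.0831, 1.4410), (91.1528, -1.6435, 0.0447), 1.4441),
    ((90.9257, -0.5406, -0.9208), (88.6381, -0.8985, -0.7239), 1.5381),
    ((6.7747, -0.2908, -2.4247), (5.8714, -0.0985, -2.2286), 0.6377),
    ((2.0776, 0.0795, -1.1350), (0.9033, -0.0636, -0.5514), 0.9082),
]


class TestCiede2000:
    def test_identical_colors_give_zero(self, rng):
        lab = rng.uniform(-50, 80, (20, 3))
        np.testing.assert_allclose(ciede2000(lab, lab), 0.0, atol=1e-14)

    def test_symmetry(self, rng):
        p = rng.uniform(-60, 90, (50, 3))
        q = rng.uniform(-60, 90, (50, 3))
        np.testing.assert_allclose(ciede2000(p, q), ciede2000(q, p), atol=1e-12)

    @pytest.mark.parametrize("lab1,lab2,expected", CIEDE_PAIRS)
    def test_verification_pairs(self, lab1, lab2, expected):
        assert ciede2000(lab1, lab2) == pytest.approx(expected, abs=1e-4)

    def test_agrees_with_independent_implementation(self, rng):
        p = rng.uniform(-60, 90, (200, 3))
        q = rng.uniform(-60, 90, (200, 3))
        ref = skimage_ciede2000(p, q)
        np.testing.assert_allclose(ciede2000(p, q), ref, atol=1e-9)

    def test_nonnegative(self, rng):
        p = rng.uniform(-60, 90, (100, 3))
        q = rng.uniform(-60, 90, (100, 3))
        assert np.all(np.asarray(ciede2000(p, q)) >= 0)


# ---------------------------------------------------------------------------
# LMS / MB-DKL
# ---------------------------------------------------------------------------


class TestRgbToLms:
    def test_weighted_sum_of_primary_excitations(self, cal):
        mat = cal.rgb_to_lms_matrix()
        img = ColorImage(np.array([[[0.5, 0.2, 0.5]]]), "linearRGB")
        lms = rgb_to_lms(img, cal).data[0, 0]
        # the stated form: channel-wise weighted sums of per-primary excitations
        expected = np.array(
            [
                0.5 * mat[0, 0] + 0.2 * mat[0, 1] + 0.5 * mat[0, 2],
                0.5 * mat[1, 0] + 0.2 * mat[1, 1] + 0.5 * mat[1, 2],
                0.5 * mat[2, 0] + 0.2 * mat[2, 1] + 0.5 * mat[2, 2],
            ]
        )
        np.testing.assert_allclose(lms, expected, rtol=1e-12)

    def test_black_maps_to_zero(self, cal):
        img = ColorImage(np.zeros((1, 1, 3)), "linearRGB")
        np.testing.assert_allclose(rgb_to_lms(img, cal).data, 0.0)

    def test_homogeneity(self, cal, rng):
        c = rng.uniform(0, 1, (4, 4, 3))
        full = rgb_to_lms(ColorImage(c, "linearRGB"), cal).data
        half = rgb_to_lms(ColorImage(0.5 * c, "linearRGB"), cal).data
        np.testing.assert_allclose(half, 0.5 * full, rtol=1e-12)

    def test_requires_spectra_or_matrix(self):
        cal = MonitorCalibration(primaries_xyY=cs.EIZO_PRIMARIES_XYY)
        img = ColorImage(np.ones((1, 1, 3)), "linearRGB")
        with pytest.raises(cs.CalibrationError, match="spectra"):
            rgb_to_lms(img, cal)


class TestLmsToMbdkl:
    def test_background_maps_to_origin(self):
        bg = np.array([0.4, 0.3, 0.2])
        img = ColorImage(np.tile(bg, (2, 2, 1)), "LMS")
        np.testing.assert_allclose(lms_to_mbdkl(img, bg).data, 0.0, atol=1e-15)

    def test_pure_luminance_increment(self):
        bg = np.array([0.5, 0.5, 0.5])
        k = 0.1
        img = ColorImage((bg + k).reshape(1, 1, 3), "LMS")
        out = lms_to_mbdkl(img, bg).data[0, 0]
        np.testing.assert_allclose(out, [0.0, -k, 3 * k], atol=1e-14)

    def test_matches_matrix_oracle(self, rng):
        bg = np.array([0.3, 0.35, 0.25])
        lms = rng.uniform(0.01, 1.0, (6, 5, 3))
        out = lms_to_mbdkl(ColorImage(lms, "LMS"), bg).data
        oracle_mat = np.array([[1, -1, 0], [-1, -1, 1], [1, 1, 1]], dtype=float)
        expected = (lms - bg) @ oracle_mat.T
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_unit_contrast_divides_by_background(self):
        bg = np.array([0.5, 0.25, 0.125])
        lms = ColorImage(np.array([[[0.6, 0.25, 0.125]]]), "LMS")
        out = lms_to_mbdkl(lms, bg, scale="unit_contrast").data[0, 0]
        np.testing.assert_allclose(out, [0.2, -0.2, 0.2], atol=1e-12)

    def test_nonpositive_background_rejected(self):
        img = ColorImage(np.ones((1, 1, 3)), "LMS")
        with pytest.raises(ValueError):
            lms_to_mbdkl(img, np.array([0.5, 0.0, 0.5]))


class TestProjectIsoluminant:
    def test_mbdkl_drops_axis3(self):
        img = ColorImage(np.array([[[0.2, -0.1, 0.7]]]), "MBDKL")
        np.testing.assert_allclose(project_isoluminant(img)[0, 0], [0.2, -0.1])

    def test_lab_drops_lightness(self):
        img = ColorImage(np.array([[[55.0, 10.0, -4.0]]]), "LAB")
        np.testing.assert_allclose(project_isoluminant(img)[0, 0], [10.0, -4.0])

    def test_idempotent_on_retained_components(self, rng):
        data = rng.normal(0, 1, (4, 4, 3))
        img = ColorImage(data, "MBDKL")
        once = project_isoluminant(img)
        np.testing.assert_allclose(once, data[..., :2])

    def test_unsupported_space(self):
        img = ColorImage(np.ones((1, 1, 3)), "LMS")
        with pytest.raises(ValueError):
            project_isoluminant(img)


# ---------------------------------------------------------------------------
# Spectral integration
# ---------------------------------------------------------------------------


class TestSpectrumToTristimulus:
    def test_zero_spectrum(self, fundamentals):
        grid = fundamentals[0].wavelengths_nm
        zero = Spectrum(grid, np.zeros_like(grid))
        np.testing.assert_allclose(spectrum_to_tristimulus(zero, fundamentals), 0.0)

    def test_equal_energy_with_normalized_fundamentals(self, fundamentals):
        grid = fundamentals[0].wavelengths_nm
        flat = Spectrum(grid, np.ones_like(grid))
        out = spectrum_to_tristimulus(flat, fundamentals)
        np.testing.assert_allclose(out, [1.0, 1.0, 1.0], rtol=1e-10)

    def test_additivity(self, fundamentals, rng):
        grid = fundamentals[0].wavelengths_nm
        s1 = Spectrum(grid, rng.uniform(0, 1, grid.size))
        s2 = Spectrum(grid, rng.uniform(0, 1, grid.size))
        both = Spectrum(grid, s1.values + s2.values)
        np.testing.assert_allclose(
            spectrum_to_tristimulus(both, fundamentals),
            spectrum_to_tristimulus(s1, fundamentals)
            + spectrum_to_tristimulus(s2, fundamentals),
            rtol=1e-12,
        )

    def test_disjoint_support_rejected(self, fundamentals):
        far = Spectrum(np.array([1000.0, 1100.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="overlap"):
            spectrum_to_tristimulus(far, fundamentals)


# ---------------------------------------------------------------------------
# Structural properties
# ---------------------------------------------------------------------------


def test_conversions_are_pixelwise(cal, rng):
    """Permuting pixels commutes with every image conversion."""
    img = ColorImage(rng.uniform(0.01, 1.0, (6, 7, 3)), "linearRGB")
    perm = rng.permutation(6 * 7)

    def permuted(data):
        flat = data.reshape(-1, 3)[perm]
        return flat.reshape(6, 7, 3)

    for conv in (
        lambda im: cs.rgb_to_xyz(im, cal).data,
        lambda im: cs.rgb_to_lms(im, cal).data,
        lambda im: cs.rgb_to_lab(im, cal).data,
    ):
        a = conv(ColorImage(permuted(img.data), "linearRGB"))
        b = permuted(conv(img))
        np.testing.assert_allclose(a, b, rtol=1e-12)


def test_color_image_validation():
    with pytest.raises(ValueError):
        ColorImage(np.ones((4, 4)), "linearRGB")
    with pytest.raises(ValueError):
        ColorImage(np.full((2, 2, 3), np.inf), "linearRGB")
    with pytest.raises(ValueError):
        ColorImage(np.ones((2, 2, 3)), "HSV")
    hdr = ColorImage(np.full((2, 2, 3), 1.5), "linearRGB")
    assert hdr.is_hdr
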