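"""White-to-white detector unit tests: spectrum conservation, peak triple
ordering, region extraction against generated-label oracles, sub-pixel
boundary tracing and the illumination/scaling invariances."""

import numpy as np
import pytest

import limbus3d as l3
from limbus3d.exceptions import (
    DegenerateMask,
    PeakCountError,
    SeedOutsideDark,
)
from limbus3d.wtw import (
    IntensitySpectrum,
    WhiteToWhiteModel,
    dynamic_threshold,
    extract_iris_region,
    intensity_spectrum,
    locate_colour_peaks,
    trace_wtw_contour,
    wtw_axis_distances,
)


def three_population_image(shape=(300, 400), seed=0):
    """Random pixel mix 0.15/0.35/0.50 at means 20/110/220, sd 5/8/10.

    Returns the image and the pre-noise labels — the oracle for which
    population each pixel belongs to.
    """
    rng = np.random.default_rng(seed)
    labels = rng.choice(3, size=shape, p=[0.15, 0.35, 0.50])
    means, sds = np.array([20.0, 110.0, 220.0]), np.array([5.0, 8.0, 10.0])
    img = rng.normal(means[labels], sds[labels])
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return l3.EyeImage(img, cal_h=0.02, cal_v=0.02), labels


class TestIntensitySpectrum:
    def test_uniform_image_single_bin(self):
        img = l3.EyeImage(np.full((100, 100), 128, np.uint8), 0.02, 0.02)
        spec = intensity_spectrum(img)
        assert spec.counts[128] == 10000
        assert spec.counts.sum() == 10000

    def test_counts_and_smoothed_conserve_pixel_total(self):
        img, _ = three_population_image()
        spec = intensity_spectrum(img, smooth_window=7)
        n = img.pixels.size
        assert spec.counts.sum() == n
        assert spec.smoothed.sum() == pytest.approx(n, rel=1e-9)

    def test_population_mass_near_each_mode(self):
        img, labels = three_population_image()
        spec = intensity_spectrum(img)
        n = img.pixels.size
        edges = [(0, 65), (66, 165), (166, 255)]
        for k, (lo, hi) in enumerate(edges):
            mass = spec.counts[lo : hi + 1].sum() / n
            expected = (labels == k).mean()
            assert mass == pytest.approx(expected, abs=0.02)


class TestLocateColourPeaks:
    def test_spikes_at_extremes_are_peaks(self):
        counts = np.zeros(256)
        counts[[0, 128, 255]] = [100, 200, 300]
        spec = IntensitySpectrum(counts, counts.astype(float), 1)
        peaks = locate_colour_peaks(spec)
        assert (peaks.pupil_I, peaks.iris_I, peaks.sclera_I) == (0, 128, 255)

    def test_three_population_peaks_near_generator_means(self):
        img, _ = three_population_image()
        peaks = locate_colour_peaks(intensity_spectrum(img))
        assert peaks.pupil_I == pytest.approx(20, abs=3)
        assert peaks.iris_I == pytest.approx(110, abs=3)
        assert peaks.sclera_I == pytest.approx(220, abs=3)

    def test_bimodal_spectrum_raises(self):
        counts = np.zeros(256)
        counts[[100, 200]] = [500, 500]
        spec = IntensitySpectrum(counts, counts.astype(float), 1)
        with pytest.raises(PeakCountError):
            locate_colour_peaks(spec)

    def test_order_is_by_intensity_not_prominence(self):
        """The pupil peak may be the smallest; ordering must not depend on
        peak height."""
        counts = np.zeros(256)
        counts[20], counts[110], counts[220] = 50, 900, 5000
        spec = IntensitySpectrum(counts, counts.astype(float), 1)
        peaks = locate_colour_peaks(spec, min_prominence=0.001)
        assert (peaks.pupil_I, peaks.iris_I, peaks.sclera_I) == (20, 110, 220)


class TestExtractIrisRegion:
    def test_mask_area_matches_generated_disc(self, noiseless_circle_image):
        image = noiseless_circle_image.image
        peaks = locate_colour_peaks(intensity_spectrum(image))
        mask = extract_iris_region(image, peaks)
        assert mask.sum() == pytest.approx(np.pi * 295**2, rel=0.01)

    def test_pupil_hole_filled(self, noiseless_circle_image):
        image = noiseless_circle_image.image
        truth = noiseless_circle_image.truth
        peaks = locate_colour_peaks(intensity_spectrum(image))
        mask = extract_iris_region(image, peaks)
        h, w = image.pixels.shape
        yy, xx = np.ogrid[:h, :w]
        pupil = (xx - (w - 1) / 2) ** 2 + (yy - (h - 1) / 2) ** 2 <= truth.pupil_radius_px**2
        assert mask[pupil].all()

    def test_highlight_holes_filled(self, default_image_sample):
        image = default_image_sample.image
        res = WhiteToWhiteModel(image).fit()
        bright = image.pixels >= 250
        h, w = image.pixels.shape
        yy, xx = np.ogrid[:h, :w]
        inside = (xx - (w - 1) / 2) ** 2 + (yy - (h - 1) / 2) ** 2 < 100**2
        assert res.mask[bright & inside].all()

    def test_seed_on_sclera_raises(self, noiseless_circle_image):
        image = noiseless_circle_image.image
        peaks = locate_colour_peaks(intensity_spectrum(image))
        with pytest.raises(SeedOutsideDark):
            extract_iris_region(image, peaks, seed_point=(5, 5))


class TestTraceContour:
    def test_circular_mask_radius(self, noiseless_circle_image):
        image = noiseless_circle_image.image
        res = WhiteToWhiteModel(image).fit()
        assert np.allclose(res.contour.radius_mm, 5.90, atol=0.02)

    def test_elliptical_mask_axes(self):
        sample = l3.make_eye_image(
            l3.ImageTruth(noise_sd=0.0, highlights=False)
        )
        res = WhiteToWhiteModel(sample.image).fit()
        r = res.contour.radius_mm
        assert r[0] == pytest.approx(5.90, abs=0.02)
        assert r[180] == pytest.approx(5.90, abs=0.02)
        assert r[90] == pytest.approx(5.75, abs=0.02)
        assert r[270] == pytest.approx(5.75, abs=0.02)

    def test_tiny_mask_degenerate(self):
        img = l3.EyeImage(np.zeros((50, 50), np.uint8), 0.02, 0.02)
        mask = np.zeros((50, 50), bool)
        mask[25, 25] = True
        with pytest.raises(DegenerateMask):
            trace_wtw_contour(mask, img)

    def test_scaling_equivariance(self):
        """Doubling cal_h doubles NT and leaves SI unchanged."""
        mask = np.zeros((301, 301), bool)
        yy, xx = np.ogrid[:301, :301]
        mask[(xx - 150) ** 2 + (yy - 150) ** 2 <= 100**2] = True
        img1 = l3.EyeImage(np.zeros((301, 301), np.uint8), 0.02, 0.02)
        img2 = l3.EyeImage(np.zeros((301, 301), np.uint8), 0.04, 0.02)
        d1 = wtw_axis_distances(trace_wtw_contour(mask, img1))
        d2 = wtw_axis_distances(trace_wtw_contour(mask, img2))
        assert d2["NT"] == pytest.approx(2 * d1["NT"], rel=1e-6)
        assert d2["SI"] == pytest.approx(d1["SI"], rel=1e-6)


class TestAxisDistances:
    def test_constant_contour(self):
        c = l3.WTWContour(np.zeros(2), np.full(360, 5.9))
        d = wtw_axis_distances(c)
        assert d["NT"] == pytest.approx(11.80)
        assert d["SI"] == pytest.approx(11.80)

    def test_rotating_contour_by_90_swaps_axes(self):
        radii = 5.9 + 0.2 * np.cos(np.deg2rad(2 * np.arange(360.0)))
        c = l3.WTWContour(np.zeros(2), radii)
        c90 = l3.WTWContour(np.zeros(2), np.roll(radii, 90))
        d, d90 = wtw_axis_distances(c), wtw_axis_distances(c90)
        assert d90["NT"] == pytest.approx(d["SI"])
        assert d90["SI"] == pytest.approx(d["NT"])


class TestIlluminationShift:
    def test_constant_offset_shifts_peaks_and_nothing_else(self):
        truth = l3.ImageTruth(intensities=(15, 95, 185), highlights=False, seed=6)
        base = l3.make_eye_image(truth)
        assert base.image.pixels.max() + 30 <= 255  # the no-clipping premise
        shifted = l3.EyeImage(
            base.image.pixels.astype(np.int16) + 30, cal_h=0.02, cal_v=0.02
        )
        r0 = WhiteToWhiteModel(base.image).fit()
        r1 = WhiteToWhiteModel(shifted).fit()
        assert r1.peaks.pupil_I - r0.peaks.pupil_I == 30
        assert r1.peaks.iris_I - r0.peaks.iris_I == 30
        assert r1.peaks.sclera_I - r0.peaks.sclera_I == 30
        assert r1.threshold - r0.threshold == 30
        assert np.array_equal(r0.mask, r1.mask)
        assert np.array_equal(r0.contour.radius_mm, r1.contour.radius_mm)


class TestModelInterface:
    def test_summary_and_json(self, default_image_sample):
        res = WhiteToWhiteModel(default_image_sample.image).fit()
        assert "NT distance" in res.summary()
        d = res.to_json_dict()
        assert d["peaks"]["pupil_I"] < d["peaks"]["iris_I"] < d["peaks"]["sclera_I"]
        assert 0 < d["threshold"] < 255

    def test_spectrum_plot_renders(self, default_image_sample):
        import matplotlib.pyplot as plt

        res = WhiteToWhiteModel(default_image_sample.image).fit()
        ax = res.plot_spectrum()
        assert ax.lines
        plt.close("all")

    def test_threshold_between_iris_and_sclera(self, default_image_sample):
        res = WhiteToWhiteModel(default_image_sample.image).fit()
        assert res.peaks.iris_I < res.threshold <= res.peaks.sclera_I
        assert res.threshold == dynamic_threshold(res.spectrum, res.peaks)
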