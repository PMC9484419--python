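"""Synthetic speckle statistics: pattern properties and contrast noise floor."""

import numpy as np
import pytest
from scipy import stats

from uotcnr.errors import InvalidParameterError
from uotcnr.speckle import (
    contrast,
    contrast_noise_floor,
    fit_noise_floor_coefficient,
    generate_speckle,
    modulated_speckle_contrast,
)


class TestGenerateSpeckle:
    def test_autocorrelation_fwhm_matches_speckle_width(self):
        pattern = generate_speckle(512, 2.0, seed=1)
        img = pattern.intensity - pattern.intensity.mean()
        F = np.fft.fft2(img)
        ac = np.fft.ifft2(np.abs(F) ** 2).real
        ac /= ac[0, 0]
        # half maximum reached one pixel from the peak for 2 px wide speckles
        assert ac[0, 1] == pytest.approx(0.5, abs=0.05)
        assert ac[1, 0] == pytest.approx(0.5, abs=0.05)
        assert ac[0, 2] < 0.1

    def test_single_pattern_contrast_near_unity(self):
        assert contrast(generate_speckle(512, 2.0, seed=2)) == pytest.approx(1.0, abs=0.02)

    def test_exponential_intensity_histogram(self):
        # fully developed polarized speckle: P(I) ~ exp(-I/<I>); KS on
        # speckle-decorrelated subsamples must not reject at alpha = 0.01
        pattern = generate_speckle(1024, 2.0, seed=3)
        sub = pattern.intensity[::4, ::4].ravel()
        sub = sub / sub.mean()
        assert stats.kstest(sub, "expon").pvalue > 0.01

    def test_invalid_sizes_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_speckle(4, 2.0, seed=0)
        with pytest.raises(InvalidParameterError):
            generate_speckle(64, 40.0, seed=0)


class TestContrast:
    def test_uniform_image_zero(self):
        assert contrast(np.ones((8, 8))) == 0.0

    def test_two_valued_image_unity(self):
        img = np.zeros((8, 8))
        img[::2] = 2.0
        assert contrast(img) == pytest.approx(1.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(ZeroDivisionError):
            contrast(np.zeros((8, 8)))


class TestContrastNoiseFloor:
    def test_scaling_exponent_near_half(self):
        # std(C) ~ N_px^-1/2: quadrupling the pixel count halves the spread
        floors = [contrast_noise_floor(s, 2.0, 150, seed=9) for s in (64, 128, 256)]
        c, p = fit_noise_floor_coefficient(floors)
        assert p == pytest.approx(0.5, abs=0.1)
        assert floors[0].std_contrast / floors[2].std_contrast == pytest.approx(
            4.0, rel=0.3
        )

    def test_coefficient_order_unity_and_stable(self):
        # measured coefficient for 2 px speckles is ~1.5 (correlated pixels);
        # it is a property of the speckle size, not of the pattern count
        f1 = contrast_noise_floor(128, 2.0, 150, seed=1)
        f2 = contrast_noise_floor(128, 2.0, 150, seed=2)
        assert 1.0 < f1.coefficient < 2.0
        assert f1.coefficient == pytest.approx(f2.coefficient, rel=0.25)

    def test_mean_contrast_near_unity(self):
        floor = contrast_noise_floor(128, 2.0, 200, seed=4)
        assert floor.mean_contrast == pytest.approx(1.0, abs=0.01)

    def test_too_few_repeats_rejected(self):
        with pytest.raises(InvalidParameterError):
            contrast_noise_floor(64, 2.0, 10, seed=0)


class TestModulatedSpeckle:
    def test_zero_tagged_fraction_keeps_unit_contrast(self):
        c = modulated_speckle_contrast(0.0, side_px=256, seed=1)
        assert c == pytest.approx(1.0, abs=0.03)

    @pytest.mark.parametrize("fraction", [0.005, 0.01, 0.02])
    def test_contrast_reduction_matches_closed_form(self, fraction):
        # ensemble mean of C approaches 1 - 2 f
        cs = [
            modulated_speckle_contrast(fraction, side_px=256, seed=s)
            for s in range(6)
        ]
        assert np.mean(cs) == pytest.approx(1.0 - 2.0 * fraction, abs=0.006)

    def test_monotone_in_tagged_fraction(self):
        cs = [
            np.mean(
                [modulated_speckle_contrast(f, side_px=128, seed=s) for s in range(8)]
            )
            for f in (0.0, 0.02, 0.05, 0.1)
        ]
        assert np.all(np.diff(cs) < 0)

    def test_out_of_regime_rejected(self):
        with pytest.raises(InvalidParameterError):
            modulated_speckle_contrast(0.2, side_px=64, seed=0)
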