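"""Closed-form CNR models: limits, symmetries and Monte-Carlo counting oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import photorefractive_counting_oracle, shb_counting_oracle
from uotcnr.cnr import (
    cnr_generic,
    cnr_holography,
    cnr_photorefractive,
    cnr_shb,
    cnr_speckle_contrast,
    speckle_contrast_signal,
)
from uotcnr.detection import DetectionConfig
from uotcnr.errors import RegimeError
from uotcnr.tagging import PhotonLevels


def levels(a, b, u, z=1.0):
    return PhotonLevels(N_T_A=a, N_T_B=b, N_U=u, z=z)


class TestGenericCNR:
    def test_equal_signals_give_zero(self):
        assert cnr_generic(5.0, 5.0, 1.0, 2.0).cnr == 0.0

    def test_unit_cnr(self):
        assert cnr_generic(3.0, 0.0, 3.0, 0.0).cnr == pytest.approx(1.0)

    def test_three_four_five(self):
        assert cnr_generic(10.0, 4.0, 3.0, 4.0).cnr == pytest.approx(1.2)

    def test_zero_noise_raises(self):
        with pytest.raises(ZeroDivisionError):
            cnr_generic(1.0, 0.0, 0.0, 0.0)


class TestSHB:
    def test_equal_tagged_levels_zero(self):
        det = DetectionConfig(method="SHB")
        assert cnr_shb(levels(1e4, 1e4, 1e10), det).cnr == 0.0

    def test_pure_tagged_shot_noise_limit(self):
        det = DetectionConfig(method="SHB", T_U=0.0)
        res = cnr_shb(levels(1e4, 0.0, 1e10), det)
        assert res.cnr == pytest.approx(np.sqrt(2 * 1.0 * 0.075 * 1e4), rel=1e-12)

    def test_tu_zero_makes_cnr_independent_of_untagged(self):
        det = DetectionConfig(method="SHB", T_U=0.0)
        a = cnr_shb(levels(1e4, 5e3, 1e10), det).cnr
        b = cnr_shb(levels(1e4, 5e3, 1e14), det).cnr
        assert a == pytest.approx(b, rel=1e-12)

    def test_filter_variants_coincide_when_leak_negligible(self):
        # 30 dB and 80 dB filters agree within 1% once T_U N_U <= 1% of tagged
        lv = levels(1e6, 6e5, 1e7)
        c30 = cnr_shb(lv, DetectionConfig(method="SHB", T_U=1e-3)).cnr
        c80 = cnr_shb(lv, DetectionConfig(method="SHB", T_U=1e-8)).cnr
        assert c30 == pytest.approx(c80, rel=0.01)

    def test_against_poisson_counting_oracle(self, rng):
        det = DetectionConfig(method="SHB", T_U=1e-3)
        form = cnr_shb(levels(1e4, 5e3, 1e10), det).cnr
        oracle = shb_counting_oracle(1e4, 5e3, 1e10, 1.0, 0.075, 1e-3, 100_000, rng)
        assert form == pytest.approx(0.612, abs=0.001)  # frozen closed-form value
        assert oracle == pytest.approx(form, rel=0.05)


class TestPhotorefractive:
    def test_equal_levels_zero(self):
        det = DetectionConfig(method="PR")
        assert cnr_photorefractive(levels(1e4, 1e4, 1e10), det).cnr == 0.0

    def test_vanishing_grating_efficiency(self):
        det = DetectionConfig(method="PR", eta_pr=1e-9)
        assert cnr_photorefractive(levels(1e4, 5e3, 1e10), det).cnr < 1e-6

    def test_monotone_in_eta_pr(self):
        lv = levels(1e6, 8e5, 1e10)
        values = [
            cnr_photorefractive(lv, DetectionConfig(method="PR", eta_pr=e)).cnr
            for e in np.linspace(0.01, 0.35, 10)
        ]
        assert np.all(np.diff(values) > 0)

    def test_out_of_regime_warns(self):
        det = DetectionConfig(method="PR")
        with pytest.warns(UserWarning):
            PhotonLevels(N_T_A=5e9, N_T_B=4e9, N_U=1e10, z=1.0)

    def test_against_poisson_counting_oracle(self, rng):
        det = DetectionConfig(method="PR", eta_pr=0.1)
        form = cnr_photorefractive(levels(1e6, 8e5, 1e10), det).cnr
        oracle = photorefractive_counting_oracle(
            1e6, 8e5, 1e10, 1.0, 0.4, 0.1, 100_000, rng
        )
        assert oracle == pytest.approx(form, rel=0.05)

    def test_noisy_baseline_costs_sqrt2(self):
        lv = levels(1e6, 8e5, 1e10)
        quiet = cnr_photorefractive(lv, DetectionConfig(method="PR")).cnr
        noisy = cnr_photorefractive(
            lv, DetectionConfig(method="PR", pr_baseline_noisy=True)
        ).cnr
        assert quiet / noisy == pytest.approx(np.sqrt(2), rel=1e-12)


class TestHolography:
    def test_equal_levels_zero(self):
        det = DetectionConfig(method="HOL")
        assert cnr_holography(0.3, 0.3, det).cnr == 0.0

    def test_dim_regime_slope_is_one(self):
        # far below one tagged photon per pixel the CNR is linear in the level
        det = DetectionConfig(method="HOL")
        nbars = np.array([1e-4, 1e-3])
        vals = [cnr_holography(2 * nb, nb, det).cnr for nb in nbars]
        slope = np.diff(np.log(vals))[0] / np.diff(np.log(nbars))[0]
        assert slope == pytest.approx(1.0, abs=0.01)

    def test_bright_regime_slope_is_half(self):
        det = DetectionConfig(method="HOL")
        nbars = np.array([1e4, 1e5])
        vals = [cnr_holography(2 * nb, nb, det).cnr for nb in nbars]
        slope = np.diff(np.log(vals))[0] / np.diff(np.log(nbars))[0]
        assert slope == pytest.approx(0.5, abs=0.01)

    def test_regime_transition_at_one_photon_per_pixel(self):
        det = DetectionConfig(method="HOL")
        dim = cnr_holography(0.1, 0.05, det)
        assert dim.regime == "camera-noise-floor"
        bright = cnr_holography(200.0, 150.0, det)
        assert bright.regime == "tagged-shot-noise"


class TestSpeckleContrast:
    def test_contrast_signal_values(self):
        assert speckle_contrast_signal(0.0, 1e10) == 1.0
        assert speckle_contrast_signal(5e7, 1e10) == pytest.approx(0.99)

    def test_contrast_signal_out_of_regime(self):
        with pytest.raises(RegimeError):
            speckle_contrast_signal(6e9, 1e10)

    def test_formula_value(self):
        det = DetectionConfig(method="SC", N_px=10**6)
        res = cnr_speckle_contrast(levels(1.5e7, 5e6, 1e10), det)
        assert res.cnr == pytest.approx(np.sqrt(2e6) * 1e-3, rel=1e-9)

    def test_sqrt_npx_scaling(self):
        lv = levels(1.5e7, 5e6, 1e10)
        one = cnr_speckle_contrast(lv, DetectionConfig(method="SC", N_px=10**6)).cnr
        fifty = cnr_speckle_contrast(
            lv, DetectionConfig(method="SC", N_px=5 * 10**7)
        ).cnr
        assert fifty / one == pytest.approx(np.sqrt(50), rel=1e-9)


@given(
    st.floats(0.0, 1e8),
    st.floats(0.0, 1e8),
    st.floats(1e6, 1e12),
)
@settings(deadline=None, max_examples=60, derandomize=True)
def test_every_method_symmetric_under_region_swap(a, b, u):
    """CNR is invariant under A<->B and zero iff the tagged levels coincide."""
    lv, swapped = levels(a, b, u), levels(b, a, u)
    for det, fn in [
        (DetectionConfig(method="SHB"), cnr_shb),
        (DetectionConfig(method="PR"), cnr_photorefractive),
        (DetectionConfig(method="SC"), cnr_speckle_contrast),
    ]:
        x, y = fn(lv, det).cnr, fn(swapped, det).cnr
        assert x == pytest.approx(y, rel=1e-12, abs=1e-300)
        assert (x == 0.0) == (a == b)
    h1 = cnr_holography(a * 1e-8, b * 1e-8, DetectionConfig(method="HOL"))
    h2 = cnr_holography(b * 1e-8, a * 1e-8, DetectionConfig(method="HOL"))
    assert h1.cnr == pytest.approx(h2.cnr, rel=1e-12, abs=1e-300)
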