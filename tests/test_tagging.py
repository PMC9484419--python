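"""Acousto-optic tagging models and their calibration."""

import numpy as np
import pytest
from scipy.special import j1

from uotcnr.errors import CalibrationError, InvalidParameterError
from uotcnr.tagging import PhotonLevels, TaggingModel, calibrate_tagging, tagged_fraction


class TestTaggedFraction:
    def test_zero_path_and_zero_pressure(self):
        for model in (
            TaggingModel(mechanism="parametric", tagging_coefficient=0.1),
            TaggingModel(mechanism="phase-modulation", modulation_index_per_cm=1e-7),
        ):
            assert tagged_fraction(0.0, 2e6, model) == 0.0
            assert tagged_fraction(1.0, 0.0, model) == 0.0

    def test_quadratic_pressure_scaling(self):
        # small-modulation limit: doubling the pressure quadruples the fraction
        model = TaggingModel(
            mechanism="phase-modulation", modulation_index_per_cm=1e-8
        )
        f1 = tagged_fraction(0.5, 1e6, model)
        f2 = tagged_fraction(0.5, 2e6, model)
        assert f2 / f1 == pytest.approx(4.0, rel=1e-3)

    def test_phase_modulation_matches_bessel(self):
        model = TaggingModel(
            mechanism="phase-modulation", modulation_index_per_cm=1e-7
        )
        phi = 1e-7 * 2e6 * 0.8
        assert tagged_fraction(0.8, 2e6, model) == pytest.approx(j1(phi) ** 2)
        assert tagged_fraction(0.8, 2e6, model) == pytest.approx(
            phi**2 / 4.0, rel=0.01
        )  # small-phi series

    def test_parametric_linear_in_path_and_clipped(self):
        model = TaggingModel(mechanism="parametric", tagging_coefficient=0.02)
        assert tagged_fraction(0.5, 2e6, model) == pytest.approx(0.01)
        assert tagged_fraction(1e4, 2e6, model) == 1.0

    def test_monotone_in_pressure(self):
        model = TaggingModel(
            mechanism="phase-modulation", modulation_index_per_cm=1e-7
        )
        fracs = [tagged_fraction(0.5, p, model) for p in np.linspace(0, 3e6, 8)]
        assert np.all(np.diff(fracs) >= 0)

    def test_negative_path_rejected(self):
        model = TaggingModel()
        with pytest.raises(InvalidParameterError):
            tagged_fraction(-0.1, 2e6, model)


class TestPhotonLevels:
    def test_weak_tagging_warning(self):
        with pytest.warns(UserWarning):
            PhotonLevels(N_T_A=2e9, N_T_B=1e9, N_U=1e10, z=1.0)

    def test_negative_levels_rejected(self):
        with pytest.raises(InvalidParameterError):
            PhotonLevels(N_T_A=-1.0, N_T_B=0.0, N_U=1.0, z=1.0)

    def test_swap_helper(self):
        lv = PhotonLevels(N_T_A=3.0, N_T_B=1.0, N_U=100.0, z=1.0)
        sw = lv.swapped()
        assert (sw.N_T_A, sw.N_T_B) == (1.0, 3.0)
        assert sw.delta_T == lv.delta_T


class TestCalibration:
    def test_target_ratio_reproduced(self, homogeneous_transport):
        target = 1e-3
        model = calibrate_tagging(target, homogeneous_transport)
        f = tagged_fraction(
            homogeneous_transport.path_in_voxel, homogeneous_transport.pressure, model
        )
        w = homogeneous_transport.weights
        ratio = np.sum(w * f) / np.sum(w * (1 - 2 * f))
        assert ratio == pytest.approx(target, rel=0.01)

    def test_linear_in_coefficient_at_small_fraction(self, homogeneous_transport):
        model = calibrate_tagging(1e-4, homogeneous_transport)
        w = homogeneous_transport.weights
        path = homogeneous_transport.path_in_voxel
        f1 = tagged_fraction(path, homogeneous_transport.pressure, model)
        from dataclasses import replace

        doubled = replace(model, tagging_coefficient=2 * model.tagging_coefficient)
        f2 = tagged_fraction(path, homogeneous_transport.pressure, doubled)
        r1 = np.sum(w * f1) / np.sum(w)
        r2 = np.sum(w * f2) / np.sum(w)
        assert r2 / r1 == pytest.approx(2.0, rel=1e-6)

    def test_tagged_untagged_conserve_weight(self, homogeneous_transport):
        model = calibrate_tagging(5e-3, homogeneous_transport)
        f = np.asarray(
            tagged_fraction(
                homogeneous_transport.path_in_voxel,
                homogeneous_transport.pressure,
                model,
            )
        )
        # +1st, -1st and untagged fractions add to one packet weight
        total = 2 * f + (1 - 2 * f)
        assert np.allclose(total, 1.0)

    def test_no_voxel_packets_raises(self, homogeneous_transport):
        from dataclasses import replace

        empty = replace(
            homogeneous_transport,
            path_in_voxel=np.zeros_like(homogeneous_transport.path_in_voxel),
        )
        with pytest.raises(CalibrationError):
            calibrate_tagging(1e-3, empty)

    def test_invalid_target_rejected(self, homogeneous_transport):
        with pytest.raises(InvalidParameterError):
            calibrate_tagging(0.0, homogeneous_transport)
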