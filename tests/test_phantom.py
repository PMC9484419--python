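"""Geometry and optical-property relations of the tissue phantom."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uotcnr.errors import GeometryError, InvalidParameterError
from uotcnr.phantom import (
    OpticalProperties,
    Phantom,
    ScatteringPowerLaw,
    build_scan,
    min_geometric_path,
    reduced_scattering,
    scattering_from_reduced,
)


def make_phantom(contrast=2.0, depth=1.5):
    bg = OpticalProperties(mu_a=0.2, mu_s=50.0, g=0.9)
    incl = OpticalProperties(mu_a=0.2 * contrast, mu_s=50.0, g=0.9)
    return Phantom(bg, incl, inclusion_center=np.array([0.0, 0.0, depth]))


class TestOpticalProperties:
    def test_reduced_scattering_recovered(self):
        props = OpticalProperties(mu_a=0.2, mu_s=50.0, g=0.9)
        assert props.mu_s_prime == pytest.approx(5.0)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(mu_a=-0.1, mu_s=1.0, g=0.5), dict(mu_a=0.1, mu_s=1.0, g=1.0),
         dict(mu_a=0.1, mu_s=-1.0, g=0.5), dict(mu_a=0.1, mu_s=1.0, g=0.5, n_medium=0.9)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            OpticalProperties(**kwargs)


class TestScatteringPowerLaw:
    def test_muscle_average_gives_5_per_cm_at_800nm(self):
        # anchored power law reproduces mu_s' ~ 5 /cm at 800 nm
        law = ScatteringPowerLaw.from_reduced_at(5.0, 800.0, b=1.0)
        assert reduced_scattering(law) == pytest.approx(5.0, rel=1e-12)

    def test_anchor_point_at_500nm_is_a(self):
        law = ScatteringPowerLaw(a=7.3, b=1.4, wavelength=500.0)
        assert reduced_scattering(law) == pytest.approx(7.3)

    def test_simple_power_law_value(self):
        law = ScatteringPowerLaw(a=10.0, b=1.0, wavelength=1000.0)
        assert reduced_scattering(law) == pytest.approx(5.0)

    def test_nonpositive_wavelength_rejected(self):
        with pytest.raises(InvalidParameterError):
            ScatteringPowerLaw(a=1.0, b=1.0, wavelength=0.0)


class TestScatteringFromReduced:
    @pytest.mark.parametrize(
        "mu_s_prime,g,expected", [(5.0, 0.9, 50.0), (3.3, 0.0, 3.3), (2.5, 0.5, 5.0)]
    )
    def test_values(self, mu_s_prime, g, expected):
        assert scattering_from_reduced(mu_s_prime, g) == pytest.approx(expected)

    def test_g_of_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            scattering_from_reduced(5.0, 1.0)

    @given(st.floats(0.1, 100.0), st.floats(0.0, 0.99))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_roundtrip_with_reduction(self, mu_s, g):
        props = OpticalProperties(mu_a=0.0, mu_s=mu_s, g=g)
        assert scattering_from_reduced(props.mu_s_prime, g) == pytest.approx(
            mu_s, rel=1e-12
        )


class TestMinGeometricPath:
    @pytest.mark.parametrize("z,expected", [(1.5, 3.9), (4.5, 9.4)])
    def test_printed_values_2sf(self, z, expected):
        assert min_geometric_path(z) == pytest.approx(expected, abs=0.05)

    def test_zero_depth(self):
        assert min_geometric_path(0.0) == pytest.approx(2 * np.sqrt(1.625))

    def test_negative_depth_rejected(self):
        with pytest.raises(InvalidParameterError):
            min_geometric_path(-0.1)

    @given(st.floats(0.0, 8.0), st.floats(0.01, 8.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_in_depth(self, z, dz):
        assert min_geometric_path(z + dz) > min_geometric_path(z)


class TestPhantom:
    def test_inclusion_must_share_scattering(self):
        bg = OpticalProperties(mu_a=0.2, mu_s=50.0, g=0.9)
        incl = OpticalProperties(mu_a=0.4, mu_s=40.0, g=0.9)
        with pytest.raises(InvalidParameterError):
            Phantom(bg, incl)

    def test_inclusion_outside_medium_rejected(self):
        with pytest.raises(GeometryError):
            make_phantom(depth=9.5)

    def test_contrast_helper(self):
        assert make_phantom(contrast=2.5).absorption_contrast == pytest.approx(2.5)
        assert make_phantom().with_contrast(1.7).absorption_contrast == pytest.approx(1.7)


class TestBuildScan:
    def test_positions_and_offsets(self):
        scan_A, scan_B = build_scan(make_phantom(), z=1.5)
        assert scan_B.voxel.center[2] == pytest.approx(1.5)
        assert np.linalg.norm(scan_A.voxel.center - scan_B.voxel.center) == pytest.approx(0.5)

    def test_source_to_voxel_distance_is_half_min_path(self):
        scan_A, scan_B = build_scan(make_phantom(), z=1.5)
        d = np.linalg.norm(scan_B.voxel.center - scan_B.source_center)
        assert d == pytest.approx(min_geometric_path(1.5) / 2.0, rel=1e-12)
        assert d == pytest.approx(np.sqrt(1.25**2 + 0.25**2 + 1.5**2))

    def test_positions_A_B_geometrically_equivalent(self):
        # source and detector sit on the perpendicular bisector plane of A-B
        scan_A, scan_B = build_scan(make_phantom(), z=2.0)
        for point in (scan_A.source_center, scan_A.detector_center):
            dA = np.linalg.norm(scan_A.voxel.center - point)
            dB = np.linalg.norm(scan_B.voxel.center - point)
            assert dA == pytest.approx(dB, rel=1e-12)

    def test_shallow_voxel_warns(self):
        with pytest.warns(UserWarning):
            build_scan(make_phantom(depth=0.3), z=0.3)

    def test_invariants_on_depth_grid(self):
        for z in np.arange(0.5, 5.01, 0.5):
            scan_A, scan_B = build_scan(make_phantom(depth=z), z=float(z))
            for scan in (scan_A, scan_B):
                assert scan.source_center[2] == 0.0
                assert scan.detector_center[2] == 0.0
                assert scan.voxel.bounds[0][2] >= 0.0
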