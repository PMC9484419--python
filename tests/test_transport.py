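"""Monte-Carlo transport: sampling, conservation, reproducibility and the
diffusion-theory reflectance oracle."""

import numpy as np
import pytest
from scipy import stats

from uotcnr.diffusion import total_diffuse_reflectance
from uotcnr.errors import InvalidParameterError
from uotcnr.phantom import OpticalProperties, Phantom, build_scan
from uotcnr.tagging import TaggingModel
from uotcnr.transport import (
    PhotonPacket,
    estimate_photon_levels,
    paired_transport,
    run_transport,
    sample_henyey_greenstein,
)


def small_phantom(mu_s=50.0, contrast=1.0):
    bg = OpticalProperties(mu_a=0.2, mu_s=mu_s, g=0.9)
    incl = OpticalProperties(mu_a=0.2 * contrast, mu_s=mu_s, g=0.9)
    return Phantom(bg, incl, inclusion_center=np.array([0.0, 0.0, 1.0]))


class TestHenyeyGreenstein:
    def test_isotropic_limit_uniform_cosine(self, rng):
        u = rng.random((2, 50_000))
        cos_t, phi = sample_henyey_greenstein(0.0, (u[0], u[1]))
        assert stats.kstest(cos_t, stats.uniform(-1, 2).cdf).pvalue > 0.01
        assert np.all((phi >= 0) & (phi < 2 * np.pi))

    def test_mean_cosine_equals_g(self, rng):
        g = 0.9
        n = 1_000_000
        u = rng.random((2, n))
        cos_t, _ = sample_henyey_greenstein(g, (u[0], u[1]))
        se = np.std(cos_t) / np.sqrt(n)
        assert abs(np.mean(cos_t) - g) < 3 * se

    def test_density_matches_closed_form(self, rng):
        # goodness of fit against the analytic HG CDF
        g = 0.9
        u = rng.random((2, 200_000))
        cos_t, _ = sample_henyey_greenstein(g, (u[0], u[1]))

        def hg_cdf(x):
            # integral of the HG density from -1 to x
            return (1 - g**2) / (2 * g) * (
                1 / np.sqrt(1 + g**2 - 2 * g * x) - 1 / (1 + g)
            )

        assert stats.kstest(cos_t, hg_cdf).pvalue > 0.01

    def test_invalid_g_rejected(self):
        with pytest.raises(InvalidParameterError):
            sample_henyey_greenstein(1.0, (0.5, 0.5))


class TestTransport:
    def test_weight_conservation(self, shallow_transport):
        res, _ = shallow_transport
        total = res.detected_weight + res.absorbed_weight + res.escaped_elsewhere_weight
        assert total == pytest.approx(res.launched_weight, rel=1e-6)

    def test_seed_reproducibility_bit_identical(self):
        phantom = small_phantom()
        _, scan_B = build_scan(phantom, 1.0)
        a = run_transport(phantom, scan_B, 20_000, seed=3)
        b = run_transport(phantom, scan_B, 20_000, seed=3)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.path_in_voxel, b.path_in_voxel)
        assert a.absorbed_weight == b.absorbed_weight
        c = run_transport(phantom, scan_B, 20_000, seed=4)
        assert not np.array_equal(a.weights, c.weights)

    def test_ballistic_limit_no_backscatter(self):
        phantom = small_phantom(mu_s=0.0)
        _, scan_B = build_scan(phantom, 1.0)
        res = run_transport(phantom, scan_B, 5_000, seed=1)
        assert res.detected_weight == 0.0
        assert res.total_reflected_weight == 0.0

    def test_diffuse_reflectance_matches_diffusion_theory(self, study_config):
        # homogeneous medium, mu_a = 0.2, mu_s' = 5: total diffuse
        # reflectance within 10% of the diffusion closed form
        phantom, _, scan_B = study_config.scans(1.0, contrast=1.0)
        res = run_transport(phantom, scan_B, 150_000, seed=21)
        mc = res.total_reflected_weight / res.n_packets
        theory = total_diffuse_reflectance(0.2, 5.0)
        assert mc == pytest.approx(theory, rel=0.10)

    def test_hdf5_roundtrip(self, tmp_path):
        phantom = small_phantom()
        _, scan_B = build_scan(phantom, 1.0)
        res = run_transport(phantom, scan_B, 10_000, seed=9)
        path = str(tmp_path / "run.h5")
        res.save(path)
        from uotcnr.transport import TransportResult

        loaded = TransportResult.load(path)
        assert np.array_equal(loaded.weights, res.weights)
        assert loaded.absorbed_weight == res.absorbed_weight
        assert loaded.n_packets == res.n_packets

    def test_variance_halves_with_double_packets(self, study_config):
        # standard MC convergence: Var(mean) ~ 1/N, checked via per-packet
        # variance of the detected-weight estimator on disjoint runs
        phantom, _, scan_B = study_config.scans(1.0, contrast=1.0)
        means = {n: [] for n in (10_000, 20_000)}
        for n in means:
            for s in range(8):
                res = run_transport(phantom, scan_B, n, seed=100 + s + n)
                means[n].append(res.detected_weight / n)
        v1 = np.var(means[10_000])
        v2 = np.var(means[20_000])
        assert v1 / v2 == pytest.approx(2.0, rel=0.9)  # wide: 8 replicates only


class TestPairedTransport:
    def test_shared_paths_and_weights(self, shallow_transport):
        res_A, res_B = shallow_transport
        assert np.array_equal(res_A.weights, res_B.weights)
        assert not np.array_equal(res_A.path_in_voxel, res_B.path_in_voxel)

    def test_symmetric_geometry_balances_voxel_paths(self, study_config):
        # positions A and B are geometrically equivalent: on a homogeneous
        # medium the paired path-weighted estimators agree within their
        # correlated statistical error
        phantom, scan_A, scan_B = study_config.scans(1.0, contrast=1.0)
        res_A, res_B = paired_transport(phantom, scan_A, scan_B, 120_000, seed=77)
        d = res_A.weights * (res_A.path_in_voxel - res_B.path_in_voxel)
        total = float(np.sum(d))
        se = float(np.sqrt(np.sum(d**2)))
        assert abs(total) < 5 * se


class TestEstimatePhotonLevels:
    def test_zero_pressure_gives_untagged_only(self, shallow_transport):
        res_A, res_B = shallow_transport
        model = TaggingModel(mechanism="phase-modulation", modulation_index_per_cm=1e-7)
        from dataclasses import replace

        res_A0 = replace(res_A, pressure=0.0)
        res_B0 = replace(res_B, pressure=0.0)
        lv = estimate_photon_levels(res_A0, res_B0, model)
        assert lv.N_T_A == 0.0 and lv.N_T_B == 0.0
        assert lv.N_U > 0.0

    def test_levels_scale_with_input_photons(self, shallow_transport):
        res_A, res_B = shallow_transport
        model = TaggingModel(mechanism="parametric", tagging_coefficient=1e-3)
        lv1 = estimate_photon_levels(res_A, res_B, model, n_input_photons=1e15)
        lv2 = estimate_photon_levels(res_A, res_B, model, n_input_photons=2e15)
        assert lv2.N_U == pytest.approx(2 * lv1.N_U, rel=1e-12)
        assert lv2.N_T_B == pytest.approx(2 * lv1.N_T_B, rel=1e-12)


class TestPhotonPacket:
    def test_direction_must_be_unit(self):
        with pytest.raises(InvalidParameterError):
            PhotonPacket(np.zeros(3), np.array([1.0, 1.0, 0.0]), 0.5)

    def test_valid_packet(self):
        p = PhotonPacket(np.zeros(3), np.array([0.0, 0.0, 1.0]), 0.5, 0.1, 2.0)
        assert p.weight == 0.5
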