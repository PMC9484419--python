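"""Weighted Monte-Carlo photon transport through the phantom.

Packets are launched uniformly over the source aperture, normally incident,
and propagated with exponentially sampled scattering free paths (rate mu_s),
Henyey-Greenstein deflections, continuous absorption weighting (piecewise per
region, so the absorbing inclusion is exact) and Russian-roulette
termination.  Every packet exiting the surface inside the detection aperture
is recorded together with its geometric path inside the ultrasound voxel -
the raw material for acousto-optic tagging.  The boundary is index-matched
(no Fresnel reflection) and emission is treated as Lambertian downstream: the
numerical-aperture collection loss is applied analytically in the detection
chain, so all exit angles are accepted here.

Together with :mod:`uotcnr.tagging` this module is the study's synthetic-data
generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import transport_kernel, transport_kernel_paired
from .errors import GeometryError, InvalidParameterError
from .phantom import Phantom, ScanGeometry
from .tagging import PhotonLevels, TaggingModel, tagged_fraction

__all__ = [
    "PhotonPacket",
    "TransportResult",
    "run_transport",
    "sample_henyey_greenstein",
    "estimate_photon_levels",
]


@dataclass(frozen=True)
class PhotonPacket:
    """A single weighted photon packet (mainly of diagnostic use)."""

    position: np.ndarray
    direction: np.ndarray
    weight: float
    path_in_voxel: float = 0.0
    total_path: float = 0.0

    def __post_init__(self) -> None:
        direction = np.asarray(self.direction, dtype=float)
        object.__setattr__(self, "direction", direction)
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
            raise InvalidParameterError("direction must be a unit vector")
        if not (0.0 < self.weight <= 1.0):
            raise InvalidParameterError("weight must lie in (0, 1]")
        if self.path_in_voxel > self.total_path + 1e-12:
            raise InvalidParameterError("path_in_voxel cannot exceed total_path")


@dataclass(frozen=True)
class TransportResult:
    """Outcome of one transport run.

    Per-packet arrays hold the packets that exited through the detection
    aperture; weight sinks are normalised such that ``detected_weight +
    absorbed_weight + escaped_elsewhere_weight`` equals the launched weight
    (= ``n_packets``, unit initial weight) to roundoff.
    """

    n_packets: int
    seed: int
    detector_area: float
    pressure: float
    z: float
    exit_x: np.ndarray
    exit_y: np.ndarray
    weights: np.ndarray
    path_in_voxel: np.ndarray
    absorbed_weight: float
    escaped_elsewhere_weight: float
    total_reflected_weight: float

    @property
    def launched_weight(self) -> float:
        return float(self.n_packets)

    @property
    def detected_weight(self) -> float:
        return float(np.sum(self.weights))

    @property
    def detected_weight_through_voxel(self) -> float:
        return float(np.sum(self.weights[self.path_in_voxel > 0.0]))

    @property
    def untagged_transmittance_per_area(self) -> float:
        """Detected weight per launched photon per cm^2 of detector."""
        return self.detected_weight / (self.n_packets * self.detector_area)

    @property
    def path_weight_per_area(self) -> float:
        """sum(w * path_in_voxel) per launched photon per cm^2 (cm^-1).

        This is the Monte-Carlo estimate of the fluence x escape integral
        over the voxel; a linear tagging coefficient c (per cm) gives the
        tagged density as c times this number.
        """
        return float(np.sum(self.weights * self.path_in_voxel)) / (
            self.n_packets * self.detector_area
        )

    def summary(self) -> pd.DataFrame:
        """One-row summary with Monte-Carlo standard errors."""
        n = self.n_packets
        w = self.weights
        mean_w = w.sum() / n
        se_w = np.sqrt(max(np.sum(w**2) / n - mean_w**2, 0.0) / n)
        wl = w * self.path_in_voxel
        mean_wl = wl.sum() / n
        se_wl = np.sqrt(max(np.sum(wl**2) / n - mean_wl**2, 0.0) / n)
        return pd.DataFrame(
            {
                "depth_cm": [self.z],
                "transmittance_untagged": [mean_w / self.detector_area],
                "transmittance_untagged_err": [se_w / self.detector_area],
                "path_weight_per_area": [mean_wl / self.detector_area],
                "path_weight_per_area_err": [se_wl / self.detector_area],
                "n_detected": [len(w)],
                "n_packets": [n],
                "seed": [self.seed],
            }
        )

    def save(self, path: str) -> None:
        """Write the per-packet record table to an HDF5 container."""
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("exit_x", "exit_y", "weights", "path_in_voxel"):
                f.create_dataset(name, data=getattr(self, name))
            for name in (
                "n_packets",
                "seed",
                "detector_area",
                "pressure",
                "z",
                "absorbed_weight",
                "escaped_elsewhere_weight",
                "total_reflected_weight",
            ):
                f.attrs[name] = getattr(self, name)

    @classmethod
    def load(cls, path: str) -> "TransportResult":
        import h5py

        with h5py.File(path, "r") as f:
            arrays = {
                name: f[name][...]
                for name in ("exit_x", "exit_y", "weights", "path_in_voxel")
            }
            attrs = {k: f.attrs[k] for k in f.attrs}
        attrs["n_packets"] = int(attrs["n_packets"])
        attrs["seed"] = int(attrs["seed"])
        return cls(**attrs, **arrays)


def sample_henyey_greenstein(
    g: float, u: tuple[np.ndarray | float, np.ndarray | float]
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Map uniform variates (u1, u2) to a Henyey-Greenstein deflection.

    Returns (cos(theta), phi) with cos(theta) following the HG density with
    anisotropy ``g`` (mean cosine = g) and phi uniform on [0, 2 pi).
    """
    if not (0.0 <= g < 1.0):
        raise InvalidParameterError("anisotropy g must lie in [0, 1)")
    u1 = np.asarray(u[0], dtype=float)
    u2 = np.asarray(u[1], dtype=float)
    if np.any(u1 < 0) or np.any(u1 > 1) or np.any(u2 < 0) or np.any(u2 > 1):
        raise InvalidParameterError("uniform variates must lie in [0, 1]")
    if g == 0.0:
        cos_t = 2.0 * u1 - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
        cos_t = np.clip((1.0 + g * g - tmp * tmp) / (2.0 * g), -1.0, 1.0)
    phi = 2.0 * np.pi * u2
    if np.isscalar(u[0]):
        return float(cos_t), float(phi)
    return cos_t, phi


def run_transport(
    phantom: Phantom,
    scan: ScanGeometry,
    n_packets: int,
    seed: int,
    weight_threshold: float = 1e-4,
    survival_probability: float = 0.1,
    chunk_size: int = 1_000_000,
    max_steps: int = 1_000_000,
) -> TransportResult:
    """Trace ``n_packets`` photon packets through ``phantom`` for ``scan``.

    Reproducible: a fixed (seed, n_packets, chunk_size) triple yields
    bit-identical results.  Large runs are processed in chunks with derived
    sub-seeds to bound memory.
    """
    if n_packets < 1:
        raise InvalidParameterError("n_packets must be >= 1")
    if scan.detector_area <= 0:
        raise GeometryError("zero-area detector")
    bg = phantom.background
    incl_lo, incl_hi = phantom.inclusion_bounds
    vox_lo, vox_hi = scan.voxel.bounds
    ex, ey, ez = phantom.half_space_extent

    xs, ys, ws, ls = [], [], [], []
    absorbed = escaped = reflected = 0.0
    remaining = n_packets
    chunk_idx = 0
    while remaining > 0:
        m = min(chunk_size, remaining)
        sub_seed = (seed * 1_000_003 + chunk_idx) % 2_147_483_647
        out = transport_kernel(
            m,
            sub_seed,
            bg.mu_s,
            bg.g,
            bg.mu_a,
            phantom.inclusion.mu_a,
            np.ascontiguousarray(incl_lo),
            np.ascontiguousarray(incl_hi),
            np.ascontiguousarray(vox_lo),
            np.ascontiguousarray(vox_hi),
            scan.source_center[0],
            scan.source_center[1],
            scan.source_half_width,
            scan.detector_center[0],
            scan.detector_center[1],
            scan.detector_half_width,
            ex / 2.0,
            ey / 2.0,
            ez,
            weight_threshold,
            survival_probability,
            max_steps,
        )
        xs.append(out[0])
        ys.append(out[1])
        ws.append(out[2])
        ls.append(out[3])
        absorbed += out[4]
        escaped += out[5]
        reflected += out[6]
        remaining -= m
        chunk_idx += 1

    return TransportResult(
        n_packets=n_packets,
        seed=seed,
        detector_area=scan.detector_area,
        pressure=scan.voxel.peak_pressure,
        z=scan.z,
        exit_x=np.concatenate(xs),
        exit_y=np.concatenate(ys),
        weights=np.concatenate(ws),
        path_in_voxel=np.concatenate(ls),
        absorbed_weight=absorbed,
        escaped_elsewhere_weight=escaped,
        total_reflected_weight=reflected,
    )


def _level_and_error(
    contributions: np.ndarray, n_packets: int, area: float, n_input: float
) -> tuple[float, float]:
    total = float(np.sum(contributions))
    mean = total / n_packets
    var = max(float(np.sum(contributions**2)) / n_packets - mean**2, 0.0)
    se = np.sqrt(var / n_packets)
    scale = n_input / area
    return mean * scale, se * scale


def estimate_photon_levels(
    result_on_A: TransportResult,
    result_on_B: TransportResult,
    tagging_model: TaggingModel,
    n_input_photons: float = 1e15,
) -> PhotonLevels:
    """Convert paired transport results to absolute photon densities.

    ``result_on_A`` / ``result_on_B`` are runs with the ultrasound voxel at
    position A / B (common random numbers recommended: same seed and phantom,
    only the voxel box differs, so the A-B difference is estimated on
    identical paths).  Detected weights are scaled by ``n_input_photons``
    (default: the per-voxel safety budget 1e15) and the detector area.
    """
    if n_input_photons <= 0:
        raise InvalidParameterError("n_input_photons must be positive")
    levels = {}
    errs = {}
    for key, res in (("A", result_on_A), ("B", result_on_B)):
        f = np.asarray(tagged_fraction(res.path_in_voxel, res.pressure, tagging_model))
        levels[key], errs[key] = _level_and_error(
            res.weights * f, res.n_packets, res.detector_area, n_input_photons
        )
    nu_vals = []
    nu_errs = []
    for res in (result_on_A, result_on_B):
        f = np.asarray(tagged_fraction(res.path_in_voxel, res.pressure, tagging_model))
        v, e = _level_and_error(
            res.weights * (1.0 - 2.0 * f),
            res.n_packets,
            res.detector_area,
            n_input_photons,
        )
        nu_vals.append(v)
        nu_errs.append(e)
    n_u = 0.5 * (nu_vals[0] + nu_vals[1])
    if result_on_A.detected_weight == 0.0 and result_on_B.detected_weight == 0.0:
        return PhotonLevels(
            0.0, 0.0, 0.0, result_on_A.z, np.inf, np.inf, np.inf
        )
    return PhotonLevels(
        N_T_A=levels["A"],
        N_T_B=levels["B"],
        N_U=n_u,
        z=result_on_A.z,
        stderr_T_A=errs["A"],
        stderr_T_B=errs["B"],
        stderr_U=0.5 * float(np.hypot(nu_errs[0], nu_errs[1])),
    )


def paired_transport(
    phantom: Phantom,
    scan_A: ScanGeometry,
    scan_B: ScanGeometry,
    n_packets: int,
    seed: int,
    weight_threshold: float = 1e-4,
    survival_probability: float = 0.1,
    chunk_size: int = 1_000_000,
    max_steps: int = 1_000_000,
) -> tuple[TransportResult, TransportResult]:
    """Common-random-numbers transport for voxel positions A and B.

    The ultrasound voxel does not alter photon propagation, only the scoring
    of in-voxel path lengths, so both positions are scored along the same
    photon paths in a single pass.  The returned pair of results shares exit
    positions and weights and differs only in ``path_in_voxel``; the A-B
    tagged difference is therefore estimated with exactly correlated noise.
    """
    if n_packets < 1:
        raise InvalidParameterError("n_packets must be >= 1")
    if scan_A.detector_area <= 0:
        raise GeometryError("zero-area detector")
    bg = phantom.background
    incl_lo, incl_hi = phantom.inclusion_bounds
    voxA_lo, voxA_hi = scan_A.voxel.bounds
    voxB_lo, voxB_hi = scan_B.voxel.bounds
    ex, ey, ez = phantom.half_space_extent

    xs, ys, ws, lAs, lBs = [], [], [], [], []
    absorbed = escaped = reflected = 0.0
    remaining = n_packets
    chunk_idx = 0
    while remaining > 0:
        m = min(chunk_size, remaining)
        sub_seed = (seed * 1_000_003 + chunk_idx) % 2_147_483_647
        out = transport_kernel_paired(
            m,
            sub_seed,
            bg.mu_s,
            bg.g,
            bg.mu_a,
            phantom.inclusion.mu_a,
            np.ascontiguousarray(incl_lo),
            np.ascontiguousarray(incl_hi),
            np.ascontiguousarray(voxA_lo),
            np.ascontiguousarray(voxA_hi),
            np.ascontiguousarray(voxB_lo),
            np.ascontiguousarray(voxB_hi),
            scan_A.source_center[0],
            scan_A.source_center[1],
            scan_A.source_half_width,
            scan_A.detector_center[0],
            scan_A.detector_center[1],
            scan_A.detector_half_width,
            ex / 2.0,
            ey / 2.0,
            ez,
            weight_threshold,
            survival_probability,
            max_steps,
        )
        xs.append(out[0])
        ys.append(out[1])
        ws.append(out[2])
        lAs.append(out[3])
        lBs.append(out[4])
        absorbed += out[5]
        escaped += out[6]
        reflected += out[7]
        remaining -= m
        chunk_idx += 1

    common = dict(
        n_packets=n_packets,
        seed=seed,
        detector_area=scan_A.detector_area,
        exit_x=np.concatenate(xs),
        exit_y=np.concatenate(ys),
        weights=np.concatenate(ws),
        absorbed_weight=absorbed,
        escaped_elsewhere_weight=escaped,
        total_reflected_weight=reflected,
    )
    res_A = TransportResult(
        pressure=scan_A.voxel.peak_pressure,
        z=scan_A.z,
        path_in_voxel=np.concatenate(lAs),
        **common,
    )
    res_B = TransportResult(
        pressure=scan_B.voxel.peak_pressure,
        z=scan_B.z,
        path_in_voxel=np.concatenate(lBs),
        **common,
    )
    return res_A, res_B
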