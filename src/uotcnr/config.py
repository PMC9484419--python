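"""Structured study configuration with the default imaging-example values.

The defaults encode the reference study conditions: muscle-like background
(mu_s' = 5 1/cm at 800 nm, g = 0.9 -> mu_s = 50 1/cm, mu_a = 0.2 1/cm), a
3x3x3 mm^3 absorbing inclusion with absorption contrast 2, a 3x3x3 mm^3
ultrasound voxel at 2 MPa, reflection geometry with 1 cm^2 source and
detection apertures, and 1e15 input photons per voxel (the 300 mW/cm^2 safety
budget divided over a 30x30 voxel image).

Configurations round-trip through YAML via :func:`StudyConfig.to_yaml` /
:func:`StudyConfig.from_yaml`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .detection import DetectionConfig
from .errors import InvalidParameterError
from .phantom import (
    DEFAULT_DETECTOR_OFFSET,
    DEFAULT_SOURCE_OFFSET,
    OpticalProperties,
    Phantom,
    ScanGeometry,
    build_scan,
    scattering_from_reduced,
)

__all__ = ["StudyConfig", "default_variants"]

#: Tagged/untagged photon ratio (+1st order) at the shallow reference depth
#: used to pin the free tagging-efficiency scale; see docs/methods.md for how
#: this constant is anchored to the published spectral-hole-burning imaging
#: depth.
DEFAULT_REFERENCE_TAGGED_RATIO = 5.0e-3
DEFAULT_REFERENCE_DEPTH = 1.0  # cm


@dataclass
class TissueConfig:
    mu_a: float = 0.2  # 1/cm
    mu_s_prime: float = 5.0  # 1/cm at `wavelength`
    g: float = 0.9
    wavelength: float = 800.0  # nm

    @property
    def mu_s(self) -> float:
        return scattering_from_reduced(self.mu_s_prime, self.g)


@dataclass
class InclusionConfig:
    absorption_contrast: float = 2.0
    edge: float = 0.3  # cm


@dataclass
class UltrasoundConfig:
    peak_pressure: float = 2.0e6  # Pa
    edge: float = 0.3  # cm
    frequency: float = 2.0e6  # Hz


@dataclass
class GeometryConfig:
    source_offset: tuple[float, float] = DEFAULT_SOURCE_OFFSET
    detector_offset: tuple[float, float] = DEFAULT_DETECTOR_OFFSET
    position_A_offset: float = 0.5  # cm
    source_area: float = 1.0  # cm^2
    detector_area: float = 1.0  # cm^2
    extent: tuple[float, float, float] = (10.0, 10.0, 8.0)  # cm


@dataclass
class TaggingConfig:
    mechanism: str = "phase-modulation"
    reference_tagged_ratio: float = DEFAULT_REFERENCE_TAGGED_RATIO
    reference_depth: float = DEFAULT_REFERENCE_DEPTH  # cm


@dataclass
class DetectionDefaultsConfig:
    NA: float = 0.7
    collection_loss_mode: str = "rounded"
    speckle_diameter: float = 600.0  # nm at the tissue surface
    pixels_per_speckle: int = 16


@dataclass
class SimulationConfig:
    n_packets: int = 1_000_000
    seed: int = 1
    input_photons: float = 1.0e15
    depth_min: float = 0.5  # cm
    depth_max: float = 5.0  # cm
    depth_step: float = 0.25  # cm


@dataclass
class StudyConfig:
    tissue: TissueConfig = field(default_factory=TissueConfig)
    inclusion: InclusionConfig = field(default_factory=InclusionConfig)
    ultrasound: UltrasoundConfig = field(default_factory=UltrasoundConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    tagging: TaggingConfig = field(default_factory=TaggingConfig)
    detection: DetectionDefaultsConfig = field(default_factory=DetectionDefaultsConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    # -- builders ----------------------------------------------------------

    def phantom(self, contrast: float | None = None, depth: float = 1.5) -> Phantom:
        if contrast is None:
            contrast = self.inclusion.absorption_contrast
        bg = OpticalProperties(
            mu_a=self.tissue.mu_a, mu_s=self.tissue.mu_s, g=self.tissue.g
        )
        incl = OpticalProperties(
            mu_a=contrast * self.tissue.mu_a, mu_s=self.tissue.mu_s, g=self.tissue.g
        )
        return Phantom(
            background=bg,
            inclusion=incl,
            inclusion_center=np.array([0.0, 0.0, depth]),
            inclusion_edge=self.inclusion.edge,
            half_space_extent=self.geometry.extent,
        )

    def scans(
        self, z: float, contrast: float | None = None
    ) -> tuple[Phantom, ScanGeometry, ScanGeometry]:
        phantom = self.phantom(contrast=contrast, depth=z)
        scan_A, scan_B = build_scan(
            phantom,
            z,
            source_offset=tuple(self.geometry.source_offset),
            detector_offset=tuple(self.geometry.detector_offset),
            position_A_offset=self.geometry.position_A_offset,
            source_area=self.geometry.source_area,
            detector_area=self.geometry.detector_area,
            voxel_edge=self.ultrasound.edge,
            peak_pressure=self.ultrasound.peak_pressure,
        )
        return phantom, scan_A, scan_B

    def depth_grid(self) -> np.ndarray:
        sim = self.simulation
        n = int(round((sim.depth_max - sim.depth_min) / sim.depth_step)) + 1
        return sim.depth_min + sim.depth_step * np.arange(n)

    # -- serialisation -----------------------------------------------------

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        sections = {
            "tissue": TissueConfig,
            "inclusion": InclusionConfig,
            "ultrasound": UltrasoundConfig,
            "geometry": GeometryConfig,
            "tagging": TaggingConfig,
            "detection": DetectionDefaultsConfig,
            "simulation": SimulationConfig,
        }
        kwargs = {}
        for name, klass in sections.items():
            data = raw.get(name, {})
            unknown = set(data) - {f_.name for f_ in klass.__dataclass_fields__.values()}
            if unknown:
                raise InvalidParameterError(
                    f"unknown keys in config section {name!r}: {sorted(unknown)}"
                )
            for key, value in data.items():
                if isinstance(value, list):
                    data[key] = tuple(value)
            kwargs[name] = klass(**data)
        return cls(**kwargs)


def default_variants(config: StudyConfig | None = None) -> dict[str, DetectionConfig]:
    """The eight detection configurations of the comparison study.

    SHB with 30 dB / 80 dB filters, photorefractive with grating efficiency
    0.10 / 0.35, holography and speckle contrast with 1 / 50 Mpx cameras.
    """
    det = (config or StudyConfig()).detection
    common = dict(
        NA=det.NA,
        collection_loss_mode=det.collection_loss_mode,
        speckle_diameter=det.speckle_diameter,
    )
    return {
        "SHB_30dB": DetectionConfig(method="SHB", T_U=1e-3, **common),
        "SHB_80dB": DetectionConfig(method="SHB", T_U=1e-8, **common),
        "PR_0.10": DetectionConfig(method="PR", eta_pr=0.10, **common),
        "PR_0.35": DetectionConfig(method="PR", eta_pr=0.35, **common),
        "HOL_1Mpx": DetectionConfig(
            method="HOL", N_px=1_000_000, n=det.pixels_per_speckle, **common
        ),
        "HOL_50Mpx": DetectionConfig(
            method="HOL", N_px=50_000_000, n=det.pixels_per_speckle, **common
        ),
        "SC_1Mpx": DetectionConfig(method="SC", N_px=1_000_000, **common),
        "SC_50Mpx": DetectionConfig(method="SC", N_px=50_000_000, **common),
    }
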