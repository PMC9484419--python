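"""Tissue phantom, ultrasound voxel and reflection-mode scan geometry.

Coordinate convention: right-handed, lengths in cm, the tissue surface is the
plane z = 0 and z grows into the tissue.  The optical source and the detection
aperture both sit on the surface (reflection mode).  The absorbing inclusion is
a cube centred on the scan axis; the ultrasound voxel is an equally sized cube
probed either overlapping the inclusion (position B) or displaced laterally by
0.5 cm (position A).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, InvalidParameterError

__all__ = [
    "OpticalProperties",
    "ScatteringPowerLaw",
    "Phantom",
    "UltrasoundVoxel",
    "ScanGeometry",
    "reduced_scattering",
    "scattering_from_reduced",
    "min_geometric_path",
    "build_scan",
    "DEFAULT_LATERAL_OFFSETS",
]

#: Lateral (dx, dy) offset magnitudes in cm entering the minimum geometric
#: path 2*sqrt(1.25^2 + 0.25^2 + z^2).
DEFAULT_LATERAL_OFFSETS: tuple[float, float] = (1.25, 0.25)

#: Default source / detector centre offsets from ultrasound position B.  The
#: decomposition keeps |offset| = sqrt(1.25^2 + 0.25^2) (so the minimum
#: geometric path above is unchanged) while placing source and detector on the
#: perpendicular bisector plane of the A-B segment: positions A and B are then
#: geometrically equivalent and an absorption contrast of 1 yields exactly
#: zero CNR.
DEFAULT_SOURCE_OFFSET: tuple[float, float] = (0.25, 1.25)
DEFAULT_DETECTOR_OFFSET: tuple[float, float] = (0.25, -1.25)


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of a tissue region.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient (1/cm).
    mu_s : float
        Scattering coefficient (1/cm).
    g : float
        Scattering anisotropy (mean cosine of the single-scattering angle).
    n_medium : float
        Refractive index; the default study assumes an index-matched boundary.
    """

    mu_a: float
    mu_s: float
    g: float = 0.9
    n_medium: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise InvalidParameterError("mu_a and mu_s must be non-negative")
        if not (0.0 <= self.g < 1.0):
            raise InvalidParameterError("anisotropy g must lie in [0, 1)")
        if self.n_medium < 1.0:
            raise InvalidParameterError("refractive index must be >= 1")

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient mu_s * (1 - g) (1/cm)."""
        return self.mu_s * (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s (1/cm)."""
        return self.mu_a + self.mu_s


@dataclass(frozen=True)
class ScatteringPowerLaw:
    """Wavelength dependence of reduced scattering, mu_s' = a (lambda/500 nm)^-b.

    ``a`` is the reduced scattering amplitude at 500 nm (1/cm) and ``b`` the
    dimensionless scattering power.
    """

    a: float
    b: float
    wavelength: float  # nm

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise InvalidParameterError("scattering amplitude a must be positive")
        if self.wavelength <= 0:
            raise InvalidParameterError("wavelength must be positive")

    @classmethod
    def from_reduced_at(
        cls, mu_s_prime: float, wavelength: float, b: float = 1.0
    ) -> "ScatteringPowerLaw":
        """Build a power law anchored to a known mu_s' at ``wavelength`` (nm)."""
        if mu_s_prime <= 0 or wavelength <= 0:
            raise InvalidParameterError("mu_s_prime and wavelength must be positive")
        a = mu_s_prime * (wavelength / 500.0) ** b
        return cls(a=a, b=b, wavelength=wavelength)


def reduced_scattering(law: ScatteringPowerLaw) -> float:
    """Evaluate mu_s' = a (lambda / 500 nm)^-b for the given power law (1/cm)."""
    if law.wavelength <= 0:
        raise InvalidParameterError("wavelength must be positive")
    return law.a * (law.wavelength / 500.0) ** (-law.b)


def scattering_from_reduced(mu_s_prime: float, g: float) -> float:
    """Scattering coefficient mu_s = mu_s' / (1 - g) (1/cm)."""
    if g >= 1.0:
        raise InvalidParameterError("anisotropy g must be < 1")
    return mu_s_prime / (1.0 - g)


def min_geometric_path(
    z: float, lateral_offsets: tuple[float, float] = DEFAULT_LATERAL_OFFSETS
) -> float:
    """Minimum geometric path source -> ultrasound voxel -> detector (cm).

    Both the source and the detector are laterally offset by ``(dx, dy)`` from
    the voxel at depth ``z``, so the shortest path is twice the straight-line
    source-to-voxel distance, 2*sqrt(dx^2 + dy^2 + z^2).
    """
    if z < 0:
        raise InvalidParameterError("depth z must be non-negative")
    dx, dy = lateral_offsets
    return 2.0 * float(np.sqrt(dx * dx + dy * dy + z * z))


def _box_bounds(center: np.ndarray, edge: float) -> tuple[np.ndarray, np.ndarray]:
    half = 0.5 * edge
    c = np.asarray(center, dtype=float)
    return c - half, c + half


@dataclass(frozen=True)
class Phantom:
    """Semi-infinite tissue slab with a cubic absorbing inclusion.

    The medium is modelled as a large box (default 10 x 10 x 8 cm, lateral
    extent centred on x = y = 0) with absorbing outer boundaries, which is
    effectively semi-infinite compared with the transport mean free path
    (~0.2 mm for the default optical properties).
    """

    background: OpticalProperties
    inclusion: OpticalProperties
    inclusion_center: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.5])
    )
    inclusion_edge: float = 0.3
    half_space_extent: tuple[float, float, float] = (10.0, 10.0, 8.0)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "inclusion_center", np.asarray(self.inclusion_center, dtype=float)
        )
        if self.inclusion_edge <= 0:
            raise InvalidParameterError("inclusion edge must be positive")
        if not np.isclose(self.background.mu_s, self.inclusion.mu_s) or not np.isclose(
            self.background.g, self.inclusion.g
        ):
            raise InvalidParameterError(
                "inclusion and background must share mu_s and g "
                "(absorption-only contrast)"
            )
        lo, hi = self.inclusion_bounds
        ex, ey, ez = self.half_space_extent
        if (
            lo[0] < -ex / 2 or hi[0] > ex / 2
            or lo[1] < -ey / 2 or hi[1] > ey / 2
            or lo[2] < 0.0 or hi[2] > ez
        ):
            raise GeometryError("inclusion box must lie fully inside the medium")

    @property
    def inclusion_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return _box_bounds(self.inclusion_center, self.inclusion_edge)

    @property
    def absorption_contrast(self) -> float:
        """mu_a(inclusion) / mu_a(background)."""
        return self.inclusion.mu_a / self.background.mu_a

    def with_contrast(self, contrast: float) -> "Phantom":
        """Return a copy whose inclusion absorption is ``contrast`` times background."""
        if contrast < 0:
            raise InvalidParameterError("absorption contrast must be non-negative")
        incl = replace(self.inclusion, mu_a=contrast * self.background.mu_a)
        return replace(self, inclusion=incl)

    def with_inclusion_depth(self, z: float) -> "Phantom":
        center = self.inclusion_center.copy()
        center[2] = z
        return replace(self, inclusion_center=center)


@dataclass(frozen=True)
class UltrasoundVoxel:
    """Cubic ultrasound focal volume at uniform peak pressure."""

    center: np.ndarray
    edge: float = 0.3
    peak_pressure: float = 2.0e6  # Pa
    frequency: float = 2.0e6  # Hz (nominal; does not enter the CNR models)

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.edge <= 0:
            raise InvalidParameterError("voxel edge must be positive")
        if self.peak_pressure < 0:
            raise InvalidParameterError("peak pressure must be non-negative")

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return _box_bounds(self.center, self.edge)


@dataclass(frozen=True)
class ScanGeometry:
    """One reflection-mode measurement configuration.

    The source and detection apertures are squares on the surface plane z = 0;
    the ultrasound voxel sits at depth ``z``, either at position B (the
    inclusion centre) or position A (displaced laterally).
    """

    source_center: np.ndarray
    detector_center: np.ndarray
    voxel: UltrasoundVoxel
    z: float
    source_area: float = 1.0  # cm^2
    detector_area: float = 1.0  # cm^2
    position_A_offset: float = 0.5  # cm

    def __post_init__(self) -> None:
        object.__setattr__(self, "source_center", np.asarray(self.source_center, float))
        object.__setattr__(
            self, "detector_center", np.asarray(self.detector_center, float)
        )
        if self.source_area <= 0 or self.detector_area <= 0:
            raise GeometryError("source and detector areas must be positive")
        if abs(self.source_center[2]) > 1e-12 or abs(self.detector_center[2]) > 1e-12:
            raise GeometryError("reflection mode: source and detector lie on z = 0")
        if self.z < 0:
            raise InvalidParameterError("depth must be non-negative")

    @property
    def source_half_width(self) -> float:
        return 0.5 * float(np.sqrt(self.source_area))

    @property
    def detector_half_width(self) -> float:
        return 0.5 * float(np.sqrt(self.detector_area))


def build_scan(
    phantom: Phantom,
    z: float,
    source_offset: tuple[float, float] = DEFAULT_SOURCE_OFFSET,
    detector_offset: tuple[float, float] = DEFAULT_DETECTOR_OFFSET,
    position_A_offset: float = 0.5,
    source_area: float = 1.0,
    detector_area: float = 1.0,
    voxel_edge: float = 0.3,
    peak_pressure: float = 2.0e6,
) -> tuple[ScanGeometry, ScanGeometry]:
    """Build the (position A, position B) scan geometries at depth ``z``.

    Position B places the ultrasound voxel at the inclusion centre; position A
    displaces it by ``position_A_offset`` cm along +x.  The source and detector
    centres are placed at the given lateral offsets from position B; with the
    defaults the source-to-voxel distance is sqrt(1.25^2 + 0.25^2 + z^2) and
    the shortest light path equals :func:`min_geometric_path`.
    """
    phantom = phantom.with_inclusion_depth(z)
    bx, by = phantom.inclusion_center[0], phantom.inclusion_center[1]
    source_center = np.array([bx + source_offset[0], by + source_offset[1], 0.0])
    detector_center = np.array([bx + detector_offset[0], by + detector_offset[1], 0.0])

    center_B = np.array([bx, by, z])
    center_A = center_B + np.array([position_A_offset, 0.0, 0.0])

    ex, ey, ez = phantom.half_space_extent
    for name, c in (("A", center_A), ("B", center_B)):
        lo, hi = _box_bounds(c, voxel_edge)
        if lo[0] < -ex / 2 or hi[0] > ex / 2 or lo[1] < -ey / 2 or hi[1] > ey / 2 or hi[2] > ez:
            raise GeometryError(f"ultrasound voxel at position {name} outside medium")
        if lo[2] < 0.0:
            if np.isclose(lo[2], 0.0, atol=1e-12):
                pass
            else:
                raise GeometryError(
                    f"ultrasound voxel at position {name} protrudes above the surface"
                )
    if z <= voxel_edge + 1e-12:
        warnings.warn(
            "ultrasound voxel touches or nearly touches the tissue surface",
            stacklevel=2,
        )

    common = dict(
        source_center=source_center,
        detector_center=detector_center,
        z=z,
        source_area=source_area,
        detector_area=detector_area,
        position_A_offset=position_A_offset,
    )
    scan_A = ScanGeometry(
        voxel=UltrasoundVoxel(center_A, voxel_edge, peak_pressure), **common
    )
    scan_B = ScanGeometry(
        voxel=UltrasoundVoxel(center_B, voxel_edge, peak_pressure), **common
    )
    return scan_A, scan_B
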