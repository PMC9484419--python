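"""Detection-chain arithmetic: collection angle, efficiencies, speckle
geometry, photon safety budget, narrowband filter attenuation and camera data
rate.

The four detection methods are identified by short codes:

* ``SHB`` - spectral hole burning filter + large-area single detector
* ``PR``  - photorefractive (adaptive holography) + single-element detector
* ``HOL`` - single-shot off-axis digital holography on a camera
* ``SC``  - speckle contrast imaging on a camera
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError

__all__ = [
    "DetectionConfig",
    "na_collection_loss",
    "detection_efficiency",
    "speckle_area_scale",
    "speckles_in_area",
    "photons_per_speckle",
    "safety_photon_budget",
    "filter_attenuation_db",
    "camera_data_rate",
    "PLANCK_CONSTANT",
    "SPEED_OF_LIGHT",
]

PLANCK_CONSTANT = 6.62607015e-34  # J s
SPEED_OF_LIGHT = 2.99792458e8  # m/s

METHODS = ("SHB", "PR", "HOL", "SC")

#: Detector quantum efficiencies assumed per method (photomultiplier for SHB,
#: photodiode for PR, camera pixels for HOL and SC).
QUANTUM_EFFICIENCY = {"SHB": 0.15, "PR": 0.80, "HOL": 0.60, "SC": 0.60}


@dataclass(frozen=True)
class DetectionConfig:
    """Per-method etendue and efficiency parameters.

    Parameters
    ----------
    method : {"SHB", "PR", "HOL", "SC"}
    S : float
        Tissue collection area in cm^2 (single-detector methods; 1 cm^2 default).
    NA : float
        Numerical aperture of the collection optics.
    quantum_efficiency : float or None
        Detector quantum efficiency; method default if None.
    T_U : float
        Untagged transmission of the SHB filter (10^-3 for the 30 dB filter,
        10^-8 for the 80 dB filter).
    eta_pr : float
        Photorefractive grating diffraction efficiency.
    N_px : int
        Camera pixel count (HOL, SC).
    n : int
        Camera pixels per speckle for holography (speckle 4 px wide -> n = 16).
    speckle_diameter : float
        Speckle diameter at the tissue surface in nm.
    collection_loss_mode : {"rounded", "exact"}
        "rounded" uses the collection loss 0.5 for NA = 0.7 (sin^2 45 deg);
        "exact" uses NA^2.  The rounded value reproduces the stated method
        efficiencies 7.5 % / 30 % / 40 % exactly.
    """

    method: str
    S: float = 1.0
    NA: float = 0.7
    quantum_efficiency: float | None = None
    T_U: float = 1.0e-3
    eta_pr: float = 0.10
    N_px: int = 1_000_000
    n: int = 16
    speckle_diameter: float = 600.0
    collection_loss_mode: str = "rounded"
    pr_baseline_noisy: bool = False
    pr_efficiency_convention: str = "amplitude"
    sc_noise_coefficient: float = 1.0
    hol_noise_model: str = "printed"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise InvalidParameterError(f"unknown method {self.method!r}")
        if self.quantum_efficiency is None:
            object.__setattr__(
                self, "quantum_efficiency", QUANTUM_EFFICIENCY[self.method]
            )
        if not (0.0 <= self.quantum_efficiency <= 1.0):
            raise InvalidParameterError("quantum efficiency must lie in [0, 1]")
        if not (0.0 <= self.T_U <= 1.0):
            raise InvalidParameterError("filter transmission T_U must lie in [0, 1]")
        if not (0.0 <= self.eta_pr <= 1.0):
            raise InvalidParameterError("eta_pr must lie in [0, 1]")
        if self.n < 1 or self.N_px < self.n:
            raise InvalidParameterError("need N_px >= n >= 1")
        if self.S <= 0:
            raise InvalidParameterError("collection area must be positive")
        if self.sc_noise_coefficient <= 0:
            raise InvalidParameterError("sc_noise_coefficient must be positive")
        if self.hol_noise_model not in ("printed", "quarter-crop"):
            raise InvalidParameterError("hol_noise_model: 'printed' or 'quarter-crop'")
        if self.collection_loss_mode not in ("rounded", "exact"):
            raise InvalidParameterError("collection_loss_mode: 'rounded' or 'exact'")
        if self.pr_efficiency_convention not in ("amplitude", "intensity"):
            raise InvalidParameterError(
                "pr_efficiency_convention: 'amplitude' or 'intensity'"
            )
        na_collection_loss(self.NA)  # validates NA


def na_collection_loss(NA: float) -> float:
    """Collection-angle loss factor for a Lambertian emitter, sin^2(half angle) = NA^2."""
    if not (0.0 < NA <= 1.0):
        raise InvalidParameterError("NA must lie in (0, 1]")
    return NA * NA


def _collection_loss(config: DetectionConfig) -> float:
    if config.collection_loss_mode == "rounded":
        # sin^2(45 deg) rounded to 0.5 for the nominal NA = 0.7 optics
        return 0.5 if math.isclose(config.NA, 0.7) else na_collection_loss(config.NA)
    return na_collection_loss(config.NA)


def detection_efficiency(config: DetectionConfig) -> float:
    """Overall detection efficiency eta_det = collection loss x quantum efficiency.

    For the nominal NA = 0.7 optics this gives 7.5 % (SHB), 30 % (HOL) and
    40 % (PR).  For the speckle contrast method eta_det cancels out of the CNR
    (it takes a ratio of tagged to untagged photons) and 1.0 is returned.
    """
    if config.method == "SC":
        return 1.0
    return _collection_loss(config) * config.quantum_efficiency


def speckle_area_scale(NA: float) -> float:
    """Speckle-area magnification 1/NA^2 imposed by the collection optics.

    The resolution limit of imaging a tissue-surface speckle scales as
    0.61 lambda / NA, so the smallest recordable speckle area grows as 1/NA^2
    (a factor ~2 for NA = 0.7).
    """
    if NA <= 0:
        raise InvalidParameterError("NA must be positive")
    return 1.0 / (NA * NA)


def speckles_in_area(S: float, speckle_diameter: float, NA: float) -> float:
    """Number of resolvable speckles in tissue area ``S`` (cm^2).

    ``speckle_diameter`` is the tissue-surface speckle diameter in nm; the
    recorded speckle area is enlarged by :func:`speckle_area_scale`.
    """
    if S <= 0 or speckle_diameter <= 0:
        raise InvalidParameterError("area and speckle diameter must be positive")
    d_cm = speckle_diameter * 1e-7
    area = math.pi * (d_cm / 2.0) ** 2 * speckle_area_scale(NA)
    return S / area


def photons_per_speckle(N_per_area: float, speckle_diameter: float, NA: float = 0.7) -> float:
    """Mean photons per speckle from a surface photon density (photons/cm^2).

    The limited NA enlarges the recorded speckle area by the same factor as it
    dilutes the intensity, so the photons per speckle at the tissue and at the
    detector coincide; the tissue-surface speckle area is used.
    """
    if N_per_area < 0:
        raise InvalidParameterError("photon density must be non-negative")
    if speckle_diameter <= 0:
        raise InvalidParameterError("speckle diameter must be positive")
    na_collection_loss(NA)  # validate only
    d_cm = speckle_diameter * 1e-7
    return N_per_area * math.pi * (d_cm / 2.0) ** 2


def safety_photon_budget(
    irradiance_limit: float = 300.0,
    beam_area: float = 1.0,
    duration: float = 1.0,
    wavelength: float = 800.0,
    n_regions: int = 1,
) -> float:
    """Photon budget allowed by the skin exposure limit.

    Parameters are the irradiance limit in mW/cm^2, beam area in cm^2,
    acquisition time in s and wavelength in nm.  ``n_regions`` divides the
    budget over that many measurement voxels (900 = 30 x 30 image).  Defaults
    give ~1.2e18 photons; divided over 900 regions, ~1.3e15 per voxel.
    """
    if irradiance_limit < 0 or beam_area <= 0 or duration < 0 or wavelength <= 0:
        raise InvalidParameterError("inputs must be positive (duration >= 0)")
    if n_regions < 1:
        raise InvalidParameterError("n_regions must be >= 1")
    energy = irradiance_limit * 1e-3 * beam_area * duration  # J
    photon_energy = PLANCK_CONSTANT * SPEED_OF_LIGHT / (wavelength * 1e-9)
    return energy / photon_energy / n_regions


def filter_attenuation_db(absorption_coefficient: float, crystal_length: float) -> float:
    """Theoretical attenuation (dB) of a narrowband absorption filter.

    A crystal with absorption coefficient ``absorption_coefficient`` (1/cm)
    over ``crystal_length`` (cm) attenuates out-of-band light by
    10 log10(exp(alpha L)); 15 1/cm over 1.2 cm gives ~78 dB (~80 dB).
    """
    if absorption_coefficient < 0 or crystal_length < 0:
        raise InvalidParameterError("absorption and length must be non-negative")
    return 10.0 * absorption_coefficient * crystal_length * math.log10(math.e)


def camera_data_rate(N_px: int, bit_depth: int = 12, fps: float = 1000.0) -> float:
    """Raw camera data rate in bytes per second (N_px * bit_depth * fps / 8)."""
    if N_px < 0 or bit_depth < 0 or fps < 0:
        raise InvalidParameterError("inputs must be non-negative")
    return N_px * bit_depth * fps / 8.0
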