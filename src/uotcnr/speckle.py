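"""Synthetic fully developed speckle and the stochastic contrast noise floor.

Speckle patterns are generated with the random-phase pupil method: uniform
random phases on a circular pupil in the Fourier plane, inverse FFT, squared
modulus.  The pupil radius is chosen so that the intensity autocorrelation
FWHM equals the requested speckle width in pixels.  Fully developed polarized
speckle then has exponential intensity statistics and unit ensemble contrast.

The empirical standard deviation of the contrast over many independent
patterns, std(C) = c / sqrt(N_px), is the noise floor that enters the
speckle-contrast CNR; pixels within a speckle are correlated, so the
coefficient c is measured rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "SpecklePattern",
    "generate_speckle",
    "generate_speckle_field",
    "contrast",
    "ContrastNoiseFloor",
    "contrast_noise_floor",
    "fit_noise_floor_coefficient",
    "modulated_speckle_contrast",
]

#: 2 J1(x)/x = 1/sqrt(2) at x ~ 1.6163: half-maximum of the jinc^2 intensity
#: autocorrelation of a circular pupil.
_JINC_HALF = 1.61634


@dataclass(frozen=True)
class SpecklePattern:
    """A simulated speckle intensity image (mean-normalised)."""

    intensity: np.ndarray
    speckle_px: float
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.intensity < 0):
            raise InvalidParameterError("intensities must be non-negative")


def _pupil_radius_bins(side_px: int, speckle_px: float) -> float:
    # field autocorrelation 2J1(2 pi R_f r)/(2 pi R_f r); intensity FWHM
    # speckle_px fixes the pupil radius R_f (cycles/px) = 1.6163/(pi FWHM)
    r_f = _JINC_HALF / (np.pi * speckle_px)
    return r_f * side_px


def generate_speckle_field(
    side_px: int, speckle_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Complex fully developed speckle field, unit mean intensity."""
    if side_px < 8:
        raise InvalidParameterError("side_px must be >= 8")
    if speckle_px < 1:
        raise InvalidParameterError("speckle width must be >= 1 px")
    if speckle_px > side_px / 2:
        raise InvalidParameterError("speckle width must be <= side_px / 2")
    fx = np.fft.fftfreq(side_px) * side_px
    FX, FY = np.meshgrid(fx, fx, indexing="ij")
    mask = FX * FX + FY * FY <= _pupil_radius_bins(side_px, speckle_px) ** 2
    pupil = np.zeros((side_px, side_px), dtype=complex)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=int(mask.sum()))
    pupil[mask] = np.exp(1j * phases)
    field = np.fft.ifft2(pupil)
    power = np.mean(np.abs(field) ** 2)
    return field / np.sqrt(power)


def generate_speckle(side_px: int, speckle_px: float, seed: int) -> SpecklePattern:
    """One fully developed speckle intensity pattern (ensemble contrast ~ 1)."""
    rng = np.random.default_rng(seed)
    field = generate_speckle_field(side_px, speckle_px, rng)
    return SpecklePattern(np.abs(field) ** 2, speckle_px, seed)


def contrast(pattern: SpecklePattern | np.ndarray) -> float:
    """Speckle contrast C = std(I) / mean(I)."""
    img = pattern.intensity if isinstance(pattern, SpecklePattern) else np.asarray(pattern)
    mean = float(np.mean(img))
    if mean == 0.0:
        raise ZeroDivisionError("zero-mean image has undefined contrast")
    return float(np.std(img)) / mean


@dataclass(frozen=True)
class ContrastNoiseFloor:
    """Empirical contrast statistics over an ensemble of speckle patterns."""

    mean_contrast: float
    std_contrast: float
    n_px: int
    n_repeats: int

    @property
    def coefficient(self) -> float:
        """c in std(C) = c / sqrt(N_px)."""
        return self.std_contrast * float(np.sqrt(self.n_px))


def contrast_noise_floor(
    side_px: int, speckle_px: float, n_repeats: int, seed: int
) -> ContrastNoiseFloor:
    """Measure mean and standard deviation of the contrast over independent patterns."""
    if n_repeats < 100:
        raise InvalidParameterError(
            "n_repeats >= 100 required for a stable contrast spread estimate"
        )
    rng = np.random.default_rng(seed)
    values = np.empty(n_repeats)
    for i in range(n_repeats):
        field = generate_speckle_field(side_px, speckle_px, rng)
        values[i] = contrast(np.abs(field) ** 2)
    return ContrastNoiseFloor(
        mean_contrast=float(values.mean()),
        std_contrast=float(values.std(ddof=1)),
        n_px=side_px * side_px,
        n_repeats=n_repeats,
    )


def fit_noise_floor_coefficient(
    floors: list[ContrastNoiseFloor],
) -> tuple[float, float]:
    """Fit (c, p) in std(C) = c * N_px^-p over several pattern sizes.

    Least squares on log std vs log N_px; with a single size, p is fixed to
    1/2 and c = std * sqrt(N_px).
    """
    if len(floors) == 1:
        return floors[0].coefficient, 0.5
    logn = np.log([f.n_px for f in floors])
    logs = np.log([f.std_contrast for f in floors])
    slope, intercept = np.polyfit(logn, logs, 1)
    return float(np.exp(intercept)), float(-slope)


def modulated_speckle_contrast(
    tagged_fraction: float,
    side_px: int = 256,
    n_phases: int = 64,
    seed: int = 0,
    speckle_px: float = 2.0,
) -> float:
    """Contrast of a time-integrated, ultrasound-modulated speckle pattern.

    ``tagged_fraction`` is the +1st-order tagged / untagged photon ratio; the
    -1st order carries the same fraction.  The untagged field and the two
    sideband fields are independent speckle patterns; the camera integrates
    over ``n_phases`` uniformly spaced ultrasound phases (exposure much longer
    than one ultrasound period), which averages out all inter-order beats and
    leaves the incoherent sum of the three patterns:  C ~ 1 - 2 f.
    """
    if not (0.0 <= tagged_fraction <= 0.1):
        raise InvalidParameterError(
            "tagged_fraction must lie in [0, 0.1] (weak-modulation regime)"
        )
    if n_phases < 3:
        raise InvalidParameterError("n_phases must be >= 3 to average the beats")
    rng = np.random.default_rng(seed)
    e_u = generate_speckle_field(side_px, speckle_px, rng)
    e_plus = generate_speckle_field(side_px, speckle_px, rng)
    e_minus = generate_speckle_field(side_px, speckle_px, rng)
    amp = np.sqrt(tagged_fraction)
    phases = 2.0 * np.pi * np.arange(n_phases) / n_phases
    integrated = np.zeros(e_u.shape)
    for phi in phases:
        total = e_u + amp * e_plus * np.exp(1j * phi) + amp * e_minus * np.exp(-1j * phi)
        integrated += np.abs(total) ** 2
    return contrast(integrated / n_phases)
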