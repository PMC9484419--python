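"""Shot-noise-limited contrast-to-noise models of the four detection methods.

The generic CNR is |S_A - S_B| / sqrt(sigma_A^2 + sigma_B^2) between two probed
tissue regions.  Each method-specific form below is that definition applied to
Poisson photon counting with the method's own signal and noise bookkeeping:

* spectral hole burning (SHB): both +/-1st-order sidebands pass narrowband
  filters; untagged light leaks with transmission T_U;
* photorefractive (PR): the untagged field and a diffracted reference
  (amplitude ~ eta_pr x untagged) interfere on a single detector; the signal is
  the ultrasound on/off intensity difference;
* off-axis holography (HOL): per-speckle tagged photon numbers, camera with
  N_px pixels and n pixels per speckle;
* speckle contrast (SC): ultrasound modulation lowers the speckle contrast by
  2 N_T / N_U; the noise floor is the stochastic contrast spread 1/sqrt(N_px).

Signals and noises are returned in detected-photon units (SHB/PR/HOL) or
contrast units (SC); the CNR itself is dimensionless.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .detection import DetectionConfig, detection_efficiency, photons_per_speckle
from .errors import InvalidParameterError, RegimeError
from .tagging import PhotonLevels

__all__ = [
    "CNRResult",
    "cnr_generic",
    "cnr_shb",
    "cnr_photorefractive",
    "cnr_holography",
    "cnr_holography_from_levels",
    "speckle_contrast_signal",
    "cnr_speckle_contrast",
]


@dataclass(frozen=True)
class CNRResult:
    method: str
    cnr: float
    signal: float
    noise: float
    regime: str = ""

    def __post_init__(self) -> None:
        if self.cnr < 0:
            raise InvalidParameterError("CNR cannot be negative")


def cnr_generic(
    signal_A: float, signal_B: float, sigma_A: float, sigma_B: float
) -> CNRResult:
    """CNR = |S_A - S_B| / sqrt(sigma_A^2 + sigma_B^2)."""
    noise = math.hypot(sigma_A, sigma_B)
    if noise == 0.0:
        raise ZeroDivisionError("both noise standard deviations are zero")
    signal = abs(signal_A - signal_B)
    return CNRResult("generic", signal / noise, signal, noise)


def cnr_shb(levels: PhotonLevels, config: DetectionConfig) -> CNRResult:
    """Spectral hole burning CNR.

    Signal: 2 S eta_det |N_T,A - N_T,B| detected sideband photons (both
    orders).  Noise: shot noise of detected tagged + leaked untagged photons
    from each region, added in quadrature, giving

        CNR = sqrt(2 S eta_det) |N_T,A - N_T,B|
              / sqrt(N_T,A + N_T,B + T_U N_U).
    """
    eta = detection_efficiency(config)
    S = config.S
    signal = 2.0 * S * eta * levels.delta_T
    counted = S * eta * (
        2.0 * levels.N_T_A + config.T_U * levels.N_U
    ) + S * eta * (2.0 * levels.N_T_B + config.T_U * levels.N_U)
    noise = math.sqrt(counted)
    cnr = 0.0 if noise == 0.0 else signal / noise
    tagged_sum = levels.N_T_A + levels.N_T_B
    regime = (
        "tagged-shot-noise"
        if tagged_sum >= config.T_U * levels.N_U
        else "untagged-dominated"
    )
    return CNRResult("SHB", cnr, signal, noise, regime)


def cnr_photorefractive(levels: PhotonLevels, config: DetectionConfig) -> CNRResult:
    """Photorefractive-detection CNR.

    The diffracted reference has amplitude ``c_pr`` relative to the untagged
    field, where ``c_pr = eta_pr`` under the amplitude convention (default) or
    ``sqrt(eta_pr)`` under the intensity convention.  The on/off subtraction
    signal is 2 S eta_det c_pr |N_T,A - N_T,B|; the detector sits on the
    untagged background S eta_det N_U (1 + c_pr)^2.  With the off baseline
    averaged to negligible noise,

        CNR = sqrt(2 S eta_det) c_pr |N_T,A - N_T,B|
              / ((1 + c_pr) sqrt(N_U));

    ``pr_baseline_noisy=True`` keeps the baseline's shot noise (CNR / sqrt 2).
    """
    if not (0.0 < config.eta_pr <= 1.0):
        raise InvalidParameterError("eta_pr must lie in (0, 1]")
    regime = "untagged-dominated"
    if levels.N_U > 0 and max(levels.N_T_A, levels.N_T_B) > 0.1 * levels.N_U:
        warnings.warn(
            "photorefractive model assumes N_T << N_U; inputs violate this",
            stacklevel=2,
        )
        regime = "out-of-regime"
    c_pr = (
        config.eta_pr
        if config.pr_efficiency_convention == "amplitude"
        else math.sqrt(config.eta_pr)
    )
    eta = detection_efficiency(config)
    S = config.S
    signal = 2.0 * S * eta * c_pr * levels.delta_T
    background = S * eta * levels.N_U * (1.0 + c_pr) ** 2
    n_measurements = 4.0 if config.pr_baseline_noisy else 2.0
    noise = math.sqrt(n_measurements * background)
    cnr = 0.0 if noise == 0.0 else signal / noise
    return CNRResult("PR", cnr, signal, noise, regime)


def cnr_holography(
    nbar_T_A: float, nbar_T_B: float, config: DetectionConfig
) -> CNRResult:
    """Single-shot off-axis holography CNR from per-speckle tagged numbers.

        CNR = sqrt(N_px) (eta_det |Nbar_T,A - Nbar_T,B| / n)
              / sqrt(4 eta_det (Nbar_T,A + Nbar_T,B) / n + 2)

    ``nbar_T_X`` are +1st-order tagged photons per tissue-surface speckle.
    The regime flag reports which denominator term dominates: below ~1
    detected tagged photon per pixel most pixels carry only noise and the CNR
    scales linearly with the tagged level instead of as its square root.

    ``config.hol_noise_model`` selects the noise bookkeeping: ``"printed"``
    (default, above) charges the shot-noise floor of all N_px pixels against
    the single reconstructed sideband lobe; ``"quarter-crop"`` counts only
    the noise a quarter-plane Fourier reconstruction actually admits (floor
    2 -> 1/2, cross term 4 -> 2), which is what a simulated hologram
    estimator realises.  Both share the same two-regime structure.
    """
    if min(nbar_T_A, nbar_T_B) < 0:
        raise InvalidParameterError("per-speckle photon numbers must be non-negative")
    if config.n > config.N_px:
        raise InvalidParameterError("need n <= N_px")
    eta = detection_efficiency(config)
    n = config.n
    signal = math.sqrt(config.N_px) * eta * abs(nbar_T_A - nbar_T_B) / n
    if config.hol_noise_model == "printed":
        noise = math.sqrt(4.0 * eta * (nbar_T_A + nbar_T_B) / n + 2.0)
    else:  # quarter-crop
        noise = math.sqrt(2.0 * eta * (nbar_T_A + nbar_T_B) / n + 0.5)
    tagged_per_px = eta * 0.5 * (nbar_T_A + nbar_T_B) / n
    regime = "tagged-shot-noise" if tagged_per_px >= 1.0 else "camera-noise-floor"
    return CNRResult("HOL", signal / noise, signal, noise, regime)


def cnr_holography_from_levels(
    levels: PhotonLevels, config: DetectionConfig
) -> CNRResult:
    """Holography CNR from per-area levels, via the tissue-surface speckle area."""
    nbar_A = photons_per_speckle(levels.N_T_A, config.speckle_diameter, config.NA)
    nbar_B = photons_per_speckle(levels.N_T_B, config.speckle_diameter, config.NA)
    return cnr_holography(nbar_A, nbar_B, config)


def speckle_contrast_signal(N_T: float, N_U: float) -> float:
    """Speckle contrast C = 1 - 2 N_T / N_U of the time-averaged pattern.

    Valid for weak tagging of a polarized, near-unity-contrast pattern; raises
    :class:`RegimeError` when N_T / N_U > 0.5 (the expansion breaks down).
    """
    if N_U <= 0:
        raise InvalidParameterError("N_U must be positive")
    if N_T < 0:
        raise InvalidParameterError("N_T must be non-negative")
    ratio = N_T / N_U
    if ratio > 0.5:
        raise RegimeError("N_T/N_U > 0.5 is outside the weak-modulation regime")
    return 1.0 - 2.0 * ratio


def cnr_speckle_contrast(levels: PhotonLevels, config: DetectionConfig) -> CNRResult:
    """Speckle-contrast CNR.

    Contrast difference 2 |N_T,A - N_T,B| / N_U against the stochastic
    contrast noise c/sqrt(N_px) per measurement:

        CNR = sqrt(2 N_px) |N_T,A - N_T,B| / (c N_U).

    The noise-floor coefficient c (``config.sc_noise_coefficient``) defaults
    to 1; the empirical coefficient for 2-px-wide speckles measured by
    :func:`uotcnr.speckle.contrast_noise_floor` is ~1.5.  Detection
    efficiency cancels in the tagged/untagged ratio.
    """
    if config.N_px < 1:
        raise InvalidParameterError("N_px must be >= 1")
    if levels.N_U <= 0:
        raise InvalidParameterError("N_U must be positive")
    signal = 2.0 * levels.delta_T / levels.N_U
    noise = config.sc_noise_coefficient * math.sqrt(2.0 / config.N_px)
    return CNRResult("SC", signal / noise, signal, noise, "contrast-noise-floor")
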