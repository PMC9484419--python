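"""Acousto-optic tagging: converting in-voxel path lengths into sideband photons.

A photon packet that spends a geometric path ``l`` inside the ultrasound voxel
has part of its weight shifted into the +/-1st-order sidebands at the
ultrasound frequency.  Two interchangeable models are provided:

* ``phase-modulation`` - the packet accumulates a modulation index
  ``phi = m * P * l`` (m in rad/(cm Pa)); a pure sinusoidal phase modulation
  puts a fraction J1(phi)^2 of the light into each of the +/-1st orders
  (phi^2/4 for small phi).
* ``parametric`` - a single calibratable coefficient: +1st-order fraction
  ``c * l * (P / P_ref)^2``, the quadratic pressure scaling being the
  small-modulation limit of the model above.

The absolute conversion efficiency in tissue is not derivable from the study
parameters alone; :func:`calibrate_tagging` pins the parametric coefficient to
a target tagged/untagged ratio on a given transport result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np
from scipy.special import j1

from .errors import CalibrationError, InvalidParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .transport import TransportResult

__all__ = ["TaggingModel", "PhotonLevels", "tagged_fraction", "calibrate_tagging"]


@dataclass(frozen=True)
class TaggingModel:
    """Sideband conversion model of the ultrasound voxel.

    ``tagging_coefficient`` is the +1st-order sideband fraction per cm of
    in-voxel path at ``reference_pressure`` (parametric mode);
    ``modulation_index_per_cm`` is the phase-modulation index in rad per cm
    per Pa (phase-modulation mode).  Both +/-1st orders carry equal weight, so
    a detector capturing both sees twice the +1st-order number.
    """

    mechanism: str = "phase-modulation"
    tagging_coefficient: float = 0.3
    reference_pressure: float = 2.0e6  # Pa
    modulation_index_per_cm: float = 6.9e-7  # rad / (cm Pa)
    orders: int = 1

    def __post_init__(self) -> None:
        if self.mechanism not in ("parametric", "phase-modulation"):
            raise InvalidParameterError(
                "mechanism must be 'parametric' or 'phase-modulation'"
            )
        if self.tagging_coefficient < 0 or self.modulation_index_per_cm < 0:
            raise InvalidParameterError("tagging coefficients must be non-negative")
        if self.reference_pressure <= 0:
            raise InvalidParameterError("reference pressure must be positive")
        if self.orders != 1:
            raise InvalidParameterError("only +/-1st-order tagging is modelled")


def tagged_fraction(
    path_in_voxel: float | np.ndarray,
    pressure: float,
    model: TaggingModel,
) -> np.ndarray | float:
    """+1st-order sideband fraction for the given in-voxel path (cm).

    Vectorised over ``path_in_voxel``.  Zero path or zero pressure give zero;
    the parametric fraction is clipped at 1.
    """
    path = np.asarray(path_in_voxel, dtype=float)
    if np.any(path < 0):
        raise InvalidParameterError("path_in_voxel must be non-negative")
    if pressure < 0:
        raise InvalidParameterError("pressure must be non-negative")
    if model.mechanism == "parametric":
        frac = np.minimum(
            1.0,
            model.tagging_coefficient
            * path
            * (pressure / model.reference_pressure) ** 2,
        )
    else:
        phi = model.modulation_index_per_cm * pressure * path
        frac = j1(phi) ** 2
    if np.isscalar(path_in_voxel):
        return float(frac)
    return frac


@dataclass(frozen=True)
class PhotonLevels:
    """Tagged and untagged photon densities at the tissue surface.

    ``N_T_A`` / ``N_T_B`` are +1st-order tagged photons per cm^2 with the
    ultrasound voxel at position A / B; ``N_U`` is the untagged density
    (assumed equal for both probe positions).  Standard errors are Monte-Carlo
    sampling errors when the levels come from transport, zero for the
    diffusion model.
    """

    N_T_A: float
    N_T_B: float
    N_U: float
    z: float
    stderr_T_A: float = 0.0
    stderr_T_B: float = 0.0
    stderr_U: float = 0.0

    def __post_init__(self) -> None:
        if min(self.N_T_A, self.N_T_B, self.N_U) < 0:
            raise InvalidParameterError("photon levels must be non-negative")
        if self.N_U > 0 and max(self.N_T_A, self.N_T_B) > 0.1 * self.N_U:
            warnings.warn(
                "tagged level exceeds 10% of untagged level; the weak-tagging "
                "regime assumed by the CNR models is violated",
                stacklevel=2,
            )

    @property
    def delta_T(self) -> float:
        return abs(self.N_T_A - self.N_T_B)

    def swapped(self) -> "PhotonLevels":
        return replace(
            self,
            N_T_A=self.N_T_B,
            N_T_B=self.N_T_A,
            stderr_T_A=self.stderr_T_B,
            stderr_T_B=self.stderr_T_A,
        )


def calibrate_tagging(
    target_tagged_to_untagged_ratio: float,
    transport: "TransportResult",
    pressure: float | None = None,
    tolerance: float = 0.01,
) -> TaggingModel:
    """Parametric tagging model whose ensemble ratio matches the target.

    The target is the +1st-order tagged / untagged photon ratio over the
    detected ensemble of ``transport``.  Raises :class:`CalibrationError` if
    no detected packet traverses the voxel.
    """
    if not (0.0 < target_tagged_to_untagged_ratio < 1.0):
        raise InvalidParameterError("target ratio must lie in (0, 1)")
    if pressure is None:
        pressure = transport.pressure
    w, path = transport.weights, transport.path_in_voxel
    wl = float(np.sum(w * path))
    if wl <= 0.0:
        raise CalibrationError("no detected packets traverse the ultrasound voxel")

    def ratio_for(c: float) -> float:
        model = TaggingModel(
            mechanism="parametric", tagging_coefficient=c, reference_pressure=pressure
        )
        f = tagged_fraction(path, pressure, model)
        return float(np.sum(w * f)) / float(np.sum(w * (1.0 - 2.0 * f)))

    # small-fraction linear estimate, then fixed-point refinement on the
    # exact ensemble ratio (handles clipping and untagged depletion)
    c = target_tagged_to_untagged_ratio * float(np.sum(w)) / wl
    for _ in range(50):
        err = ratio_for(c) / target_tagged_to_untagged_ratio
        if abs(err - 1.0) <= tolerance / 2:
            break
        c /= err
    return TaggingModel(
        mechanism="parametric", tagging_coefficient=c, reference_pressure=pressure
    )
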