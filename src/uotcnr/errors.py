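"""Exception types shared across the package."""


class UotcnrError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(UotcnrError, ValueError):
    """A parameter is outside its physically meaningful range."""


class GeometryError(UotcnrError, ValueError):
    """A geometric configuration is inconsistent (e.g. box outside the medium)."""


class RegimeError(UotcnrError, ValueError):
    """Inputs violate the regime a closed-form expression assumes."""


class CalibrationError(UotcnrError, RuntimeError):
    """A calibration could not be carried out (e.g. no photons through the voxel)."""
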