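"""Exception types shared across the package."""


class RodflickError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(RodflickError, ValueError):
    """Rod geometry with non-physical dimensions."""


class InvalidParameterError(RodflickError, ValueError):
    """Model or stimulus parameter outside its admissible range."""


class ConfigurationError(RodflickError, ValueError):
    """Unknown calibration context, preset, or malformed config file."""


class InputError(RodflickError, ValueError):
    """Malformed or inconsistent input data."""


class InsufficientDataError(RodflickError, ValueError):
    """Too few usable points for the requested fit."""
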