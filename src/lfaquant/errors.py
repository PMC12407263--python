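"""Exception hierarchy shared across the package."""


class LfaQuantError(Exception):
    """Base class for all package errors."""


class ConfigError(LfaQuantError):
    """Invalid configuration: unknown role/analyte, bad proportions, ..."""


class LayoutError(LfaQuantError):
    """Geometry violates strip/scene constraints."""


class GeometryError(LfaQuantError):
    """Image region too small or malformed for the requested operation."""


class ContractError(LfaQuantError):
    """An inter-stage contract (e.g. profile length 512) is violated."""


class DataError(LfaQuantError):
    """Training/calibration data inconsistent with the requested operation."""


class FitError(LfaQuantError):
    """Calibration regression cannot be computed."""


class InvalidTestError(LfaQuantError):
    """The strip is not a valid test (no control line, inconsistent peaks)."""
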