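"""Exception hierarchy shared across the pipeline stages."""


class OmnifluxError(Exception):
    """Base class for all package-specific errors."""


class ArgumentError(OmnifluxError, ValueError):
    """A caller-supplied argument violates a precondition."""


class DataError(OmnifluxError, ValueError):
    """Input data violate a contract (missing genes, misaligned tables, ...)."""


class CalibrationError(OmnifluxError, ValueError):
    """Calibration cannot be fitted (too few usable standards, degenerate fit)."""


class UnitsError(OmnifluxError, ValueError):
    """An operation received a matrix in the wrong units or layer."""


class ModelConstructionError(OmnifluxError, ValueError):
    """A metabolic network violates the invariants needed to build an ec-model."""
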