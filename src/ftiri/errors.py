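"""Exception hierarchy for the FTIR imaging pipeline."""


class FtiriError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FtiriError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class FormatError(FtiriError, ValueError):
    """A map/mask file is malformed or internally inconsistent."""


class RangeError(FtiriError, ValueError):
    """A requested spectral interval is not covered by the data."""


class DegenerateSpectrumError(FtiriError, ValueError):
    """A spectrum is identically zero where a nonzero one is required
    (typically a background pixel hitting vector normalization)."""


class SamplingError(FtiriError, ValueError):
    """A region-of-interest draw asked for more pixels than are eligible."""


class SchemaError(FtiriError, ValueError):
    """Two objects that must share structure (axis, ratio columns) do not."""
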