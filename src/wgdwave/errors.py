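"""Exception types shared across the pipeline."""


class WgdwaveError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(WgdwaveError, ValueError):
    """A function argument or configuration value is invalid."""


class SchemaError(WgdwaveError, ValueError):
    """A file does not match the expected tabular or tree schema."""


class DataError(WgdwaveError, ValueError):
    """Input data are structurally valid but inconsistent or incomplete."""


class DegenerateInputError(WgdwaveError, ValueError):
    """Input is too degenerate for the requested computation."""
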