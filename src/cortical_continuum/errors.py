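"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: config/schema problems -> 2, data
problems -> 3, numerical failures -> 4.
"""


class ConfigError(ValueError):
    """Invalid parameter or configuration value."""


class SchemaError(ConfigError):
    """An input table is missing required columns or identifiers."""


class DataError(RuntimeError):
    """Input data violate a precondition (empty sets, degenerate groups...)."""


class NormalizationError(DataError):
    """A normalization step cannot be carried out (e.g. zero-total sample)."""


class FitError(RuntimeError):
    """A model fit failed or is degenerate."""


class NumericalError(RuntimeError):
    """A numerical routine failed to converge or produced invalid output."""
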