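"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: configuration errors -> 2,
data errors -> 3, numerical failures -> 4.
"""


class ExosigError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ExosigError):
    """Invalid configuration: bad parameter values, unknown keys, bad labels."""


class DataError(ExosigError):
    """Malformed or inconsistent input data (duplicate ids, negative abundances, ...)."""


class NumericalError(ExosigError):
    """A numerical procedure failed (e.g. an optimiser did not converge)."""


class NoSignatureError(DataError):
    """Feature selection retained zero proteins; relax p_cutoff or check cohorts."""


class NonGrowthError(DataError):
    """Cell count did not increase between plating and counting; generation time undefined."""
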