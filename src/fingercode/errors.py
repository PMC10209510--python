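"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (config 2, data/IO 3,
computation 4) so shell pipelines can tell misconfiguration from bad
inputs from genuine numerical failures.
"""


class FingercodeError(Exception):
    """Base class for all package errors."""


class ConfigError(FingercodeError):
    """Invalid configuration or parameter values."""


class DataError(FingercodeError):
    """Malformed, inconsistent, or missing input data."""


class ComputationError(FingercodeError):
    """A numerical procedure failed on valid-looking inputs."""
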