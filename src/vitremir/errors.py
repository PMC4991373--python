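"""Exception hierarchy shared across the pipeline."""


class VitremirError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(VitremirError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(VitremirError):
    """An input file does not match the expected column schema."""


class QcError(VitremirError):
    """A reaction or sample fails a quality-control precondition."""


class EstimationError(VitremirError):
    """A per-reaction estimate (efficiency, baseline) could not be obtained."""


class AnalysisError(VitremirError):
    """A downstream statistic is undefined for the given inputs."""
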