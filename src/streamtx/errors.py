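"""Exception hierarchy shared across the package."""


class StreamtxError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(StreamtxError, ValueError):
    """Invalid scenario, schedule or run configuration."""


class FastqParseError(StreamtxError, ValueError):
    """Malformed FASTQ input; the message names the offending record."""


class MonotonicityError(StreamtxError, RuntimeError):
    """A counter or detected-gene set shrank between iterations."""
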