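"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: DataError -> 1, ConfigError -> 2.
"""


class RetscreenError(Exception):
    """Base class for all package errors."""


class DataError(RetscreenError):
    """Invalid, inconsistent or unreadable data (images, manifests, labels)."""


class ConfigError(RetscreenError):
    """Invalid parameter or configuration value."""


class ChannelCountError(DataError):
    """Raster does not carry the three color planes the pipeline needs."""


class UndefinedMetricError(DataError):
    """A screening metric has an empty denominator (e.g. no positives)."""
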