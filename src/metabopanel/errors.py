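"""Exception hierarchy shared across the pipeline.

``ConfigurationError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class MetabopanelError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MetabopanelError):
    """Invalid configuration (bad counts, non-positive SDs, unknown options)."""


class DataError(MetabopanelError):
    """Invalid or degenerate data (missing annotations, non-positive values,
    undefined statistics)."""
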