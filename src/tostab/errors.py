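"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, every other
TostabError -> 1.
"""


class TostabError(Exception):
    """Base class for all package errors."""


class ConfigError(TostabError):
    """Invalid configuration (bad parameter value, unknown config key)."""


class SchemaError(TostabError):
    """On-disk data does not match the documented schema."""


class DataError(TostabError):
    """Data is schema-valid but internally inconsistent (e.g. non-monotone time)."""


class InsufficientDataError(TostabError):
    """Too few complete observations for the requested statistic."""


class DegenerateDataError(TostabError):
    """Degenerate input (e.g. singular contrast covariance) for a test statistic."""


class SolverError(TostabError):
    """The convex decomposition solver failed to reach its tolerance."""
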