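"""Package-wide exception types."""


class MsntxError(Exception):
    """Base class for all msntx errors."""


class DegenerateInputError(MsntxError, ValueError):
    """An input is structurally valid but statistically degenerate
    (zero variance, constant vector, undefined correlation)."""


class RankDeficientDesignError(MsntxError, ValueError):
    """A regression design matrix is rank deficient (collinear columns)."""


class ConfigError(MsntxError, ValueError):
    """Invalid generator or analysis configuration."""
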