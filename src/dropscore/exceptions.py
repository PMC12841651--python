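"""Exception hierarchy for dropscore."""


class DropScoreError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DropScoreError):
    """Invalid or inconsistent configuration (weights, point tables, schema)."""


class ValidationError(DropScoreError):
    """Invalid input data (out-of-range values, malformed cohort rows)."""


class SeparationError(DropScoreError):
    """Perfect separation detected while fitting a logistic model."""


class DiscriminationUndefinedError(DropScoreError):
    """Discrimination metric requested on a single-class outcome."""
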