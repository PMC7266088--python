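"""Exception hierarchy shared across the package."""


class XylotraitError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(XylotraitError):
    """Invalid generator or pipeline configuration; message names the field."""


class FormatError(XylotraitError):
    """A table file does not conform to the canonical schema."""


class ValidationError(XylotraitError):
    """A record violates a value-level invariant; message cites the row."""


class CompletenessError(XylotraitError):
    """A trait table is missing one of the catalogue columns."""


class GenerationError(XylotraitError):
    """A parameter combination produced infeasible (non-positive) geometry."""


class ComputationError(XylotraitError):
    """A trait cannot be computed from the given cells (e.g. empty ring)."""


class InsufficientDataError(XylotraitError):
    """Too few observations for the requested fit or test."""


class CollinearityError(XylotraitError):
    """Rank-deficient design matrix in a regression."""
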