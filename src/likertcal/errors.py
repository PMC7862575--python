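"""Exception hierarchy.

Every distinct validation failure gets its own named class so callers (and
tests) can discriminate failure modes without string matching.
"""


class LikertCalError(Exception):
    """Base class for all package errors."""


class SurveyValidationError(LikertCalError, ValueError):
    """Base class for survey-table validation failures."""


class MissingColumnError(SurveyValidationError):
    """A required attribute/id column is absent from the input CSV."""


class CategoryRangeError(SurveyValidationError):
    """A response is not an integer in [1, 5]."""


class UnknownLabelError(SurveyValidationError):
    """A response label is not present in the configured label map."""


class EmptyFileError(SurveyValidationError):
    """The input file contains no survey records."""


class MissingFieldError(LikertCalError, ValueError):
    """A correction-table file is missing a required attribute or key."""


class UndefinedFitError(LikertCalError, ValueError):
    """A regression fit is undefined (constant series)."""


class MinSitesError(LikertCalError, ValueError):
    """Fewer sites than the configured hard floor."""


class DegenerateScaleError(LikertCalError, ValueError):
    """Agreement and disagreement pole extents coincide (zero span)."""


class DegenerateCorrectionError(LikertCalError, ValueError):
    """A corrected-coordinate normalizer is not strictly positive."""


class DisconnectedGraphError(LikertCalError, ValueError):
    """Pole nodes cannot be reached from the anchor in the edge graph."""


class ConfigError(LikertCalError, ValueError):
    """A run-configuration value is outside its documented bounds."""


class TruthValidationError(LikertCalError, ValueError):
    """A synthetic ground-truth specification violates its invariants."""
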