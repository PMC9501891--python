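"""Exception hierarchy for the immunosig pipeline.

Every stage raises a subclass of :class:`ImmunosigError` so that callers
(and the CLI) can distinguish pipeline contract violations from plain bugs.
"""


class ImmunosigError(Exception):
    """Base class for all immunosig errors."""


class FormatError(ImmunosigError):
    """Malformed input file (duplicate identifiers, bad header, ...)."""


class MissingGeneError(ImmunosigError):
    """A required gene is absent from the expression matrix."""

    def __init__(self, missing, context=""):
        self.missing = sorted(missing)
        msg = f"missing genes: {', '.join(self.missing)}"
        if context:
            msg = f"{context}: {msg}"
        super().__init__(msg)


class AnnotationError(ImmunosigError):
    """Sample annotation is absent, inconsistent or incomplete."""


class ConfigError(ImmunosigError):
    """Invalid configuration value."""


class MetricError(ImmunosigError):
    """Ranking metric cannot be computed for the given group sizes."""


class EmptySetError(ImmunosigError):
    """Gene set has no overlap with the measured panel."""


class DegenerateSetError(ImmunosigError):
    """All in-set ranking metrics are zero; the weighted sum is undefined."""


class EmptyCollectionError(ImmunosigError):
    """Every gene set was discarded after restriction to the panel."""


class SelectionError(ImmunosigError):
    """Fewer enrichment results than requested top pathways."""


class EmptySignatureError(ImmunosigError):
    """No gene reaches the required number of contributing pathways."""


class DichotomizationError(ImmunosigError):
    """Scores cannot be split into two nonempty strata."""


class SurvivalTestError(ImmunosigError):
    """Survival comparison is undefined (e.g. zero events)."""


class ConvergenceError(ImmunosigError):
    """Iterative estimator failed to converge (e.g. monotone Cox likelihood)."""

    def __init__(self, message, direction=None):
        super().__init__(message)
        #: +1 / -1 when the likelihood is monotone in that direction.
        self.direction = direction


class VocabularyError(ImmunosigError):
    """Variant effect class outside the closed vocabulary."""
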