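"""Exception types shared across the package."""


class BamsaError(Exception):
    """Base class for all package-specific errors."""


class MissingDataError(BamsaError):
    """A field required by a scoring rule is absent.

    Scores are never silently computed from imputed values: the analysis is
    complete-case, so a missing required field is an error, not a zero.
    """


class ValidationError(BamsaError):
    """A field value violates its documented range or type."""


class ReconstructionError(BamsaError):
    """No integer 2x2 table is consistent with the printed statistics."""


class AmbiguousReconstructionError(ReconstructionError):
    """More than one integer 2x2 table matches the printed statistics.

    Ambiguity is surfaced to the caller rather than resolved silently; the
    candidate cell counts are carried in ``candidates``.
    """

    def __init__(self, message: str, candidates=None):
        super().__init__(message)
        self.candidates = candidates or []


class SingleClassError(BamsaError):
    """ROC-type analysis requested on an outcome with only one class."""
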