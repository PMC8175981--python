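"""Exception hierarchy.

All package-specific failures derive from :class:`EpilexError` so callers
(and the CLI exit-code mapping) can distinguish validation problems from
mathematically undefined quantities.
"""


class EpilexError(Exception):
    """Base class for all epilex errors."""


class ValidationError(EpilexError):
    """Malformed input: bad config, bad corpus file, broken invariant."""


class InvalidLabelError(ValidationError):
    """A label is not a member of the active label space."""


class ZeroProbabilityCorpusError(ValidationError):
    """A corpus has probability zero under the model.

    Raised when one speaker produces different tokens for the same object:
    speakers commit to a single labeling intention per object, so such data
    cannot be generated and no posterior is defined over them.
    """


class ImpossibleObservationError(EpilexError):
    """An observation with zero prior probability (e.g. an incorrect label
    from a group whose members are knowledgeable with probability 1)."""


class UndefinedDivergenceError(EpilexError):
    """KL divergence is undefined: the posterior puts mass where the prior
    has none (incorrect data under a knowledgeability prior of 1)."""


class EnumerationCapError(EpilexError):
    """The exact hypothesis space is too large to enumerate; use Gibbs."""
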