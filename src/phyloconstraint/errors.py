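"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`PhyloconstraintError`
so callers (and the CLI) can distinguish validation problems (bad input,
exit code 2) from computation problems (exit code 3).
"""


class PhyloconstraintError(Exception):
    """Base class for all package errors."""


class ValidationError(PhyloconstraintError):
    """Input violates a precondition (malformed file, unknown label, ...)."""


class ComputationError(PhyloconstraintError):
    """A computation is undefined for otherwise-valid input."""


class NewickParseError(ValidationError):
    pass


class DuplicateTipLabelError(ValidationError):
    pass


class UnknownLabelError(ValidationError):
    pass


class UnrootedTreeError(ValidationError):
    """Operation requires a rooted tree; root with root_by_outgroup first."""


class NonMonophyleticOutgroupError(ValidationError):
    pass


class AlignmentError(ValidationError):
    pass


class AlphabetError(ValidationError):
    pass


class InsufficientOverlapError(ComputationError):
    """Too few comparable columns between a sequence pair."""


class SaturationError(ComputationError):
    pass


class TopologyError(ComputationError):
    """Reference node not ancestral to the lineage: subtraction undefined."""


class CoordinateError(ValidationError):
    pass


class FrameError(ValidationError):
    pass


class ReliabilityError(ComputationError):
    """Too many saturation-capped pairs for a trustworthy estimate."""
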