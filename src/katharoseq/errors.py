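"""Exception hierarchy.

All package errors derive from :class:`KatharoSeqError` so callers can
catch the package's failures with a single except clause; validation
problems (bad files, bad metadata, missing controls) and computation
problems (fits that cannot be performed) are kept on separate branches
because the command line maps them to different exit codes.
"""


class KatharoSeqError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(KatharoSeqError):
    """Invalid input data or configuration (CLI exit code 2)."""


class ComputationError(KatharoSeqError):
    """A computation could not be carried out (CLI exit code 3)."""


# --- data_model ---------------------------------------------------------

class TableFormatError(ValidationError):
    """Malformed feature-table file (bad header, wrong shape, bad JSON)."""


class DuplicateIdError(ValidationError):
    """Duplicate sample or feature identifiers."""


class NegativeCountError(ValidationError):
    """A count is negative."""


class NonIntegerCountError(ValidationError):
    """A count is fractional or non-numeric; counts are exact integers."""


class UnknownControlClassError(ValidationError):
    """A control_class token outside the documented vocabulary."""


class MissingInputCellsError(ValidationError):
    """A positive control without a known cell/genome-copy input."""


# --- target_composition -------------------------------------------------

class UnknownSampleError(ValidationError, KeyError):
    """Sample identifier not present in the table."""


class MissingTaxonomyError(ValidationError):
    """A lineage-substring target was given but the table has no taxonomy."""


class UndefinedCompositionError(ComputationError):
    """Target fraction requested for a zero-depth sample."""


# --- hill_fit / exclusion_qc -------------------------------------------

class InsufficientPointsError(ComputationError):
    """Too few points / distinct dose levels for the requested fit."""


class DegenerateFitError(ComputationError):
    """Fit inputs violate the model preconditions (non-monotone, equal y)."""


class UnreachableHalfMaxError(ComputationError):
    """The fitted curve never reaches 50% target composition."""


class MissingControlsError(ValidationError):
    """The study lacks the controls the chosen strategy requires."""
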