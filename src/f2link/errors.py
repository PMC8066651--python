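"""Exception taxonomy.

Every library error derives from :class:`F2LinkError` so callers (and the CLI)
can map failure categories to exit codes.  Most classes also derive from
``ValueError`` so that plain try/except blocks behave as expected.
"""


class F2LinkError(Exception):
    """Base class for all f2link errors."""

    exit_code = 1


class ConfigError(F2LinkError, ValueError):
    """Invalid or inconsistent configuration (loci, map, rules)."""

    exit_code = 2


class InvalidInputError(F2LinkError, ValueError):
    """Malformed user input (counts, codes, probabilities, files)."""

    exit_code = 3


class InvalidGenotypeError(InvalidInputError):
    """Allele dose outside {0, 1, 2} or unknown genotype code."""


class InvalidProbabilityError(InvalidInputError):
    """Probability outside [0, 1]."""


class DegenerateRatioError(InvalidInputError):
    """A hypothesised segregation ratio puts zero expectation on a class."""


class EmptyTableError(InvalidInputError):
    """A count table or vector with no usable observations."""


class InconsistentRecordError(InvalidInputError):
    """Phenotype records that contradict each other (e.g. awn length scored
    on a hooded spike)."""


class DegenerateMarginError(InvalidInputError):
    """A contingency table with an empty row or column margin."""


class EstimationFailureError(F2LinkError, ArithmeticError):
    """No admissible root for the recombination-fraction quadratic."""

    exit_code = 4


class UndefinedCoincidenceError(InvalidInputError):
    """Coincidence coefficient undefined (a flanking interval has r = 0)."""


class InsufficientDataError(InvalidInputError):
    """Too few observations in a group for the requested statistic."""


class EmptyVectorError(InsufficientDataError):
    """All values missing."""
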