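"""Exception hierarchy shared across the package."""


class CoevonetError(Exception):
    """Base class for all package-specific errors."""


class AlignmentShapeError(CoevonetError):
    """Rows of an alignment do not all have the same length."""


class AlphabetError(CoevonetError):
    """A sequence contains a symbol outside the accepted alphabet."""


class EmptyInputError(CoevonetError):
    """An input file or record set is empty."""


class EmptyCoreError(CoevonetError):
    """No alignment column satisfies the core-position gap criterion."""


class UnknownSequenceError(CoevonetError, KeyError):
    """A sequence id is not present in the alignment."""


class ResidueRangeError(CoevonetError, ValueError):
    """A residue number or core-position number is out of range."""


class InsufficientPairsError(CoevonetError):
    """Too few sequences are non-gapped at both columns of a pair."""


class EmptySubsetError(CoevonetError):
    """A sub-alignment selection matched no sequences."""


class InfeasibleDesignError(CoevonetError):
    """No degenerate-codon set encodes the target set exactly within the budget."""


class KeywordExpressionError(CoevonetError, ValueError):
    """A keyword expression could not be parsed."""
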