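"""Exception hierarchy.

Everything user-facing derives from :class:`FragRescueError`; validation
failures additionally derive from ``ValueError`` so callers may catch either.
"""


class FragRescueError(Exception):
    """Base class for all package errors."""


class InvalidInputError(FragRescueError, ValueError):
    """A scalar or record violates a precondition (non-positive Kd, N = 0, ...)."""


class DegenerateComparisonError(FragRescueError, ValueError):
    """Group efficiency requested for two molecules with the same heavy-atom count."""


class SmilesParseError(FragRescueError, ValueError):
    """A SMILES string could not be parsed; the message names the offending record."""


class ConventionError(FragRescueError, ValueError):
    """Mixed sign conventions fed to an operation that would destroy sign information."""


class InvalidSlateError(FragRescueError, ValueError):
    """A fragment slate violates 1 <= x and 0 <= a < x, or has non-positive weights."""


class DeltaInfeasibleError(FragRescueError, ArithmeticError):
    """No real LE-delta can make the unknown fragments hit the requested apparent LE.

    Raised by the weighted-RMS solver when the known fragments alone already
    carry more squared-efficiency mass than the target allows.  The bracket
    (target^2 * W_total - sum of known LE^2 * w) is attached for diagnostics.
    """

    def __init__(self, message: str, bracket: float):
        super().__init__(message)
        self.bracket = bracket


class InvalidLibraryError(FragRescueError, ValueError):
    """A pocket library is unusable for screening (empty pocket, no binders, ...)."""


class SchemaError(FragRescueError, ValueError):
    """An on-disk table is missing a required column or has an unknown value."""


class ConsistencyError(FragRescueError, ValueError):
    """Two redundant fields of one record disagree (e.g. smiles vs. n_heavy)."""
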