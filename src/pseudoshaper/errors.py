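"""Exception hierarchy.

CLI exit-code mapping: InvalidInputError -> 2, InvalidParameterError -> 3,
anything else -> 4.
"""


class PseudoshaperError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PseudoshaperError):
    """Input data violates a precondition (shape, finiteness, symmetry ...)."""


class DegenerateInputError(InvalidInputError):
    """Input is technically well-formed but carries no usable signal
    (e.g. all pseudotime columns constant)."""


class InvalidParameterError(PseudoshaperError):
    """A configuration parameter is out of its admissible range."""


class SizeError(InvalidParameterError):
    """Problem size exceeds what an exact method can handle."""


class InfeasibleKError(PseudoshaperError):
    """Requested cluster count exceeds the number of distinct points.

    Raised by k-means and caught by the k-sweep, which skips the value.
    """


class InternalConsistencyError(PseudoshaperError):
    """A postcondition the algorithm guarantees failed; indicates a bug."""
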