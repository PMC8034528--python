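"""Exception hierarchy.

Every user-facing failure mode raises a subclass of :class:`NetpropError`,
so callers (and the CLI) can catch one type.
"""


class NetpropError(Exception):
    """Base class for all package errors."""


class NetworkFormatError(NetpropError):
    """A network or kernel file could not be parsed in the declared format."""


class ValidationError(NetpropError):
    """A network violates a structural invariant (dangling edge, bad weight...)."""


class ParameterError(NetpropError):
    """A kernel or score parameter is outside its admissible range."""


class DegenerateInputError(NetpropError):
    """The input is structurally valid but the requested operation is undefined
    on it (isolated nodes under the strict normalized-Laplacian policy,
    constant label vector for the z-score, empty layer selection...)."""


class AlignmentError(NetpropError):
    """Two objects that must share a node ordering do not."""


class EmptyOverlapError(NetpropError):
    """No input entity could be mapped onto the network."""


class MergeConflictError(NetpropError):
    """Harmonization found irreconcilable node annotations across layers."""
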