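"""Exception hierarchy shared across the pipeline stages."""


class DefoliascanError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DefoliascanError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(DefoliascanError, ValueError):
    """An on-disk artifact does not match the expected dialect."""


class ComputationError(DefoliascanError, ArithmeticError):
    """A numeric operation is undefined for the given data."""


class DegenerateSelectionError(DefoliascanError, ValueError):
    """A selection step retained too few bands to continue."""


class InsufficientPointsError(DefoliascanError, ValueError):
    """A point cloud has too few above-threshold returns for metrics."""
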