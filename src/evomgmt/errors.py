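"""Exception types shared across the package."""


class EvoMgmtError(Exception):
    """Base class for all package errors."""


class ValidationError(EvoMgmtError, ValueError):
    """An input violates a documented precondition or schema constraint."""


class NonFiniteLifespanError(EvoMgmtError, ValueError):
    """delta * kappa = 1: the discounted excess-profit stream has no finite value."""


class InternalConsistencyError(EvoMgmtError, RuntimeError):
    """A structural property the model guarantees failed to hold; indicates a bug."""
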