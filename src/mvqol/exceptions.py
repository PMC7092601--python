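"""Package-wide exception types."""


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class ConvergenceWarning(UserWarning):
    """Emitted when an iterative fit stops short of its convergence criteria."""
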