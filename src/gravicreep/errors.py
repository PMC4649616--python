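"""Shared exception types."""


class InsufficientDataError(ValueError):
    """Raised when an estimator receives too little data to be meaningful."""


class ProtocolError(ValueError):
    """Raised when the force/acquisition protocol violates a precondition."""


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge; carries diagnostics."""
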