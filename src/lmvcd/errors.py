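"""Package exception hierarchy."""


class LmvcdError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(LmvcdError, ValueError):
    """A physical parameter is outside its admissible range."""


class UnboundStateError(LmvcdError, ValueError):
    """A vibrational quantum number beyond the last bound Morse level."""


class ConvergenceError(LmvcdError, RuntimeError):
    """A numeric procedure (grid diagonalization, nonlinear fit) failed to converge."""


class FitError(LmvcdError, RuntimeError):
    """A least-squares fit is rank deficient, degenerate, or did not converge."""


class ConfigError(LmvcdError, ValueError):
    """A run configuration or requested toggle is invalid or incomplete."""
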