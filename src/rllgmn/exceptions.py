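"""Exception types shared across the package."""


class RLLGMNError(Exception):
    """Base class for package errors."""


class DegenerateInputError(RLLGMNError, ValueError):
    """Input too short / too small for the requested operation."""


class NumericalDegeneracyError(RLLGMNError, FloatingPointError):
    """A probability normalizer underflowed to zero or became non-finite."""


class InvalidParameterError(RLLGMNError, ValueError):
    """Model parameters violate their invariants."""
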