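"""Exception types shared across the package."""


class SlicephysError(Exception):
    """Base class for all package errors."""


class FormatError(SlicephysError, ValueError):
    """A file is missing required metadata or is malformed."""


class StructuralError(SlicephysError, ValueError):
    """Input violates a structural invariant (ragged sweeps, mismatched shapes)."""


class DegenerateInputError(SlicephysError, ValueError):
    """Input is formally valid but carries no usable signal (flat trace, zero pulse)."""


class SimulationError(SlicephysError, RuntimeError):
    """Numerical integration produced a non-finite state."""


class EmptyAnalysisError(SlicephysError, ValueError):
    """Exclusion windows leave nothing to analyze."""


class InsufficientDataError(SlicephysError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(SlicephysError, ValueError):
    """Data admit no variance where the statistic requires some."""
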