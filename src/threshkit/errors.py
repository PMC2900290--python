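"""Exception hierarchy shared by all threshkit modules."""


class ThreshkitError(Exception):
    """Base class for all threshkit errors."""


class ParameterError(ThreshkitError, ValueError):
    """A model or protocol parameter violates its domain (e.g. k_a <= 0)."""


class FitError(ThreshkitError, RuntimeError):
    """A curve fit cannot be carried out (too few points, no signal, ...)."""


class DegenerateDataError(FitError):
    """The data carry no information for the requested fit (e.g. all-zero y)."""


class NoThresholdError(ThreshkitError, ArithmeticError):
    """The requested threshold does not exist for these parameters
    (no critical point, no resting state, or no dV/dt = k_th crossing)."""


class ResolutionError(ThreshkitError, ValueError):
    """The time step is too coarse for the fastest kinetics involved."""


class InstabilityError(ThreshkitError, RuntimeError):
    """Numerical blow-up detected during integration; reduce dt."""


class FormatError(ThreshkitError, ValueError):
    """A file does not conform to the expected columnar format."""


class SchemaError(FormatError):
    """A configuration or parameter file violates its schema."""


class RegistryError(ThreshkitError, KeyError):
    """An unknown name was requested from a registry (rates, fixtures, figures)."""


class AlignmentError(ThreshkitError, ValueError):
    """Two series that must share a time base do not."""
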