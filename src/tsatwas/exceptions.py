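"""Exception hierarchy for tsatwas."""


class TsaTwasError(Exception):
    """Base class for all package errors."""


class ParameterError(TsaTwasError, ValueError):
    """A scalar parameter is outside its admissible range."""


class ConfigurationError(TsaTwasError, ValueError):
    """Mutually inconsistent configuration fields."""


class StructuralError(TsaTwasError, ValueError):
    """Dimension or identifier mismatch between composed objects."""


class ConvergenceError(TsaTwasError, RuntimeError):
    """An iterative solver exhausted its budget without converging.

    Carries the final optimality gap in ``gap``.
    """

    def __init__(self, message, gap=None):
        super().__init__(message)
        self.gap = gap


class SingleTissueError(TsaTwasError, ValueError):
    """An omnibus test was invoked with a single tissue; route to SLR instead."""


class NotTestableError(TsaTwasError, ValueError):
    """A test is undefined on this input (e.g. zero-variance regressor)."""
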