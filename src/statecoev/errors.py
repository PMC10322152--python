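"""Exception hierarchy shared across the pipeline stages."""


class StateCoevError(Exception):
    """Base class for all package errors."""


class AlignmentFormatError(StateCoevError):
    """Input alignment is ragged or not in the declared format."""


class EmptyInputError(StateCoevError):
    """An input file or collection contained no usable records."""


class FrameMismatchError(StateCoevError):
    """Two objects do not share the same column frame / length."""


class ConvergenceError(StateCoevError):
    """An iterative optimizer failed to converge.

    Carries the final gradient norm in ``grad_norm``.
    """

    def __init__(self, message, grad_norm=None):
        super().__init__(message)
        self.grad_norm = grad_norm


class InsufficientDataError(StateCoevError):
    """Not enough examples / frames / states for the requested operation."""


class DataError(StateCoevError):
    """Physically invalid data (e.g. negative distances)."""


class LabelError(StateCoevError):
    """Unknown or missing state label."""


class MappingError(StateCoevError):
    """A residue could not be mapped (region table, column map...)."""


class ConstructionError(StateCoevError):
    """A derived object could not be built from the given inputs."""


class BinningError(StateCoevError):
    """A frame falls outside the configured bin grid."""


class AlignmentGapError(StateCoevError):
    """Free-energy segments do not overlap enough to be aligned."""

    def __init__(self, message, gap=None):
        super().__init__(message)
        self.gap = gap


class OrderingError(StateCoevError):
    """No optimizer restart produced a correctly ordered projection."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConfigError(StateCoevError):
    """Invalid run configuration (unknown key, bad value, unknown process)."""


class DependencyError(StateCoevError):
    """A pipeline stage is missing an upstream artifact."""
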