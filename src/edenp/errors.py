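"""Exception hierarchy for the edenp package."""


class ENPSError(Exception):
    """Base class for all edenp errors."""


class ModelError(ENPSError):
    """A system description is structurally invalid (dangling reference,
    duplicate variable, broken membrane tree, malformed model file)."""


class ExpressionError(ModelError):
    """A production expression does not conform to the supported grammar
    (+, -, *, integer powers, sqrt, numeric constants, variable names)."""


class EvaluationError(ENPSError):
    """A production could not be evaluated (unresolved variable, square
    root of a negative intermediate)."""


class RepartitionError(ENPSError):
    """A repartition protocol cannot distribute the produced amount
    (zero coefficient sum with a non-zero production value)."""


class NonHaltingError(ENPSError):
    """max_steps was exhausted without reaching a halting configuration."""

    def __init__(self, message, steps_executed=None, configuration=None):
        super().__init__(message)
        self.steps_executed = steps_executed
        self.configuration = configuration


class StateError(ENPSError):
    """An operation was attempted in the wrong execution state
    (e.g. extracting an edge map before the system has halted)."""


class BuildError(ENPSError):
    """An EDENP system could not be compiled from the given image/config."""


class FormatError(ENPSError):
    """An image file could not be read or written in the named format."""
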