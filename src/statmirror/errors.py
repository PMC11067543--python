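"""Exception hierarchy for statmirror."""


class StatMirrorError(Exception):
    """Base class for all statmirror errors."""


class InvalidArgumentError(StatMirrorError, ValueError):
    """An argument violates a precondition (empty data, bad flag, n < 1, ...)."""


class DegenerateConstructionError(StatMirrorError, ArithmeticError):
    """The sum of scalements vanishes while the numerator does not,
    so the Kabirian coefficient is undefined."""


class ModalUndefinedError(StatMirrorError, ValueError):
    """Mode requested on data with no repeated value."""


class DomainError(StatMirrorError, ValueError):
    """A translation-model input lies outside its admissible range."""


class UndefinedCVError(StatMirrorError, ArithmeticError):
    """Coefficient of variation requested for data with zero mean."""
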