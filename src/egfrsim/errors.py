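"""Exception hierarchy for egfr-sim."""


class EgfrSimError(Exception):
    """Base class for all package errors."""


class ValidationError(EgfrSimError):
    """A value violates a domain precondition (negative concentration, bad dose...)."""


class ContractError(EgfrSimError):
    """A call violates an interface contract (wrong arity, unknown form...)."""


class IntegrityError(EgfrSimError):
    """Referential integrity of a reaction network is broken."""


class NumericalError(EgfrSimError):
    """A rate or derivative evaluated to NaN/Inf, or the solver failed."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class SbmlFormatError(EgfrSimError):
    """Input file is not SBML, or uses an unsupported construct."""


class ResolutionError(EgfrSimError):
    """An observable or override references an id that does not resolve."""


class FitDegeneracyError(EgfrSimError):
    """A kinetic fit is requested on data that cannot constrain it."""
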