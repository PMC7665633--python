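"""Exception hierarchy for model validation and analysis failures."""


class ScalesidError(Exception):
    """Base class for all package errors."""


class ModelValidationError(ScalesidError):
    """A model document violates a structural invariant."""


class UndeclaredSymbolError(ModelValidationError):
    """An expression references a symbol that is neither a state nor a parameter."""

    def __init__(self, symbol: str, where: str = ""):
        self.symbol = symbol
        msg = f"undeclared symbol '{symbol}'"
        if where:
            msg += f" in {where}"
        super().__init__(msg)


class DuplicateNameError(ModelValidationError):
    """State, parameter or IC-parameter names collide."""


class ObservedNotAStateError(ModelValidationError):
    """An observed name is not a declared state."""


class ExpressionParseError(ModelValidationError):
    """An RHS expression string could not be parsed."""


class EvaluationFailure(ScalesidError):
    """A function evaluated non-finite at every retried sample point."""

    def __init__(self, expression, msg: str = ""):
        self.expression = expression
        super().__init__(msg or f"could not evaluate {expression} at any sampled point")


class IntegrationFailure(ScalesidError):
    """The ODE integrator failed; carries the failing time when known."""

    def __init__(self, msg: str, t_fail: float | None = None):
        self.t_fail = t_fail
        super().__init__(msg)


class SBMLImportError(ScalesidError):
    """SBML import requested but unavailable or the file could not be translated."""


class UnknownCatalogueEntry(ScalesidError, KeyError):
    """Requested catalogue model does not exist; message lists available names."""
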