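"""ODE model declaration, parsing and validation.

A model is a system of autonomous ordinary differential equations

    dx_i/dt = f_i(x_1, ..., x_n; lam_1, ..., lam_m),   x_i(0) = x_{i,0},

together with the subset of states that an experiment observes and a
declaration for every initial condition: known to be zero, known to equal a
fixed number, or equal to an unknown parameter (which then joins the
parameter list of the identifiability analysis).

The text document format is YAML with keys ``states``, ``params``, ``odes``
(state -> infix expression), ``observed`` and ``init`` (state -> 0 | number |
parameter name).  Expressions use ``+ - * / ^`` (or ``**``) and the functions
``exp, log, sin, cos, tan``; rational constants such as ``1/2`` stay exact.
"""

from __future__ import annotations

import keyword
import numbers
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import sympy as sp
import yaml
from sympy.core.function import AppliedUndef
from sympy.parsing.sympy_parser import (
    convert_xor,
    parse_expr,
    rationalize,
    standard_transformations,
)

from .errors import (
    DuplicateNameError,
    ExpressionParseError,
    ModelValidationError,
    ObservedNotAStateError,
    SBMLImportError,
    UndeclaredSymbolError,
)

#: functions admitted by the expression grammar
ALLOWED_FUNCTIONS: dict[str, sp.Function] = {
    "exp": sp.exp,
    "log": sp.log,
    "sin": sp.sin,
    "cos": sp.cos,
    "tan": sp.tan,
}

_TRANSFORMS = standard_transformations + (convert_xor, rationalize)

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


class ICKind(str, Enum):
    KNOWN_ZERO = "known_zero"
    KNOWN_VALUE = "known_value"
    UNKNOWN_PARAMETER = "unknown_parameter"


@dataclass(frozen=True)
class InitialCondition:
    """Declaration of one state's initial value.

    ``value`` is an exact sympy number for ``known_value`` (finite, nonzero —
    a zero value is represented by ``known_zero``) and a parameter name for
    ``unknown_parameter``.
    """

    kind: ICKind
    value: object = None

    def __post_init__(self):
        if self.kind is ICKind.KNOWN_VALUE:
            v = sp.nsimplify(self.value, rational=True)
            if not v.is_finite:
                raise ModelValidationError(f"non-finite initial value {self.value}")
            object.__setattr__(self, "value", v)
        elif self.kind is ICKind.UNKNOWN_PARAMETER:
            if not isinstance(self.value, str):
                raise ModelValidationError(
                    "unknown_parameter initial condition needs a parameter name"
                )

    @classmethod
    def zero(cls) -> "InitialCondition":
        return cls(ICKind.KNOWN_ZERO)

    @classmethod
    def value_of(cls, v) -> "InitialCondition":
        v = sp.nsimplify(v, rational=True)
        if v == 0:
            return cls(ICKind.KNOWN_ZERO)
        return cls(ICKind.KNOWN_VALUE, v)

    @classmethod
    def parameter(cls, name: str) -> "InitialCondition":
        return cls(ICKind.UNKNOWN_PARAMETER, name)


def _check_name(name: str, role: str) -> None:
    if not isinstance(name, str) or not _NAME_RE.match(name) or keyword.iskeyword(name):
        raise ModelValidationError(f"invalid {role} name {name!r}")
    if name in ALLOWED_FUNCTIONS or name == "t":
        raise ModelValidationError(f"{role} name {name!r} is reserved")


@dataclass
class ODEModel:
    """Validated ODE model with observation and initial-condition structure.

    ``params`` is the full parameter list of the analysis: declared rate
    parameters in declaration order followed by any auto-registered
    initial-condition parameters.
    """

    states: list[str]
    params: list[str]
    rhs: dict[str, sp.Expr]
    observed: list[str]
    initial_conditions: dict[str, InitialCondition]
    declared_params: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.declared_params:
            self.declared_params = list(self.params)
        self._validate()

    # -- validation -------------------------------------------------------
    def _validate(self) -> None:
        if len(self.states) < 1:
            raise ModelValidationError("a model needs at least one state")
        names = list(self.states) + list(self.params)
        seen = set()
        for nm in names:
            _check_name(nm, "symbol")
            if nm in seen:
                raise DuplicateNameError(f"duplicate name {nm!r}")
            seen.add(nm)
        if not self.observed:
            raise ModelValidationError("observed set must be non-empty")
        for nm in self.observed:
            if nm not in self.states:
                raise ObservedNotAStateError(f"observed name {nm!r} is not a state")
        if len(set(self.observed)) != len(self.observed):
            raise DuplicateNameError("duplicate observed name")
        allowed = {sp.Symbol(nm) for nm in names}
        for st in self.states:
            if st not in self.rhs:
                raise ModelValidationError(f"missing equation for state {st!r}")
            expr = self.rhs[st]
            extra = expr.free_symbols - allowed
            if extra:
                sym = sorted(extra, key=str)[0]
                raise UndeclaredSymbolError(str(sym), where=f"d{st}/dt")
            undef = expr.atoms(AppliedUndef)
            if undef:
                raise ExpressionParseError(
                    f"unknown function {sorted(undef, key=str)[0]} in d{st}/dt"
                )
        for st in self.states:
            ic = self.initial_conditions.get(st)
            if ic is None:
                raise ModelValidationError(f"missing initial condition for state {st!r}")
            if ic.kind is ICKind.UNKNOWN_PARAMETER and ic.value not in self.params:
                raise ModelValidationError(
                    f"IC parameter {ic.value!r} of {st!r} is not registered as a parameter"
                )
        if len(self.params) < 1:
            raise ModelValidationError("a model needs at least one parameter")

    # -- basic queries ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.states)

    @property
    def m(self) -> int:
        """Number of declared (rate) parameters; IC parameters not counted."""
        return len(self.declared_params)

    @property
    def r(self) -> int:
        return len(self.observed)

    def symbol(self, name: str) -> sp.Symbol:
        return sp.Symbol(name)

    @property
    def state_symbols(self) -> list[sp.Symbol]:
        return [sp.Symbol(s) for s in self.states]

    @property
    def param_symbols(self) -> list[sp.Symbol]:
        return [sp.Symbol(p) for p in self.params]

    @property
    def ic_parameters(self) -> list[str]:
        """Parameters that stand for an unknown initial condition."""
        out = []
        for st in self.states:
            ic = self.initial_conditions[st]
            if ic.kind is ICKind.UNKNOWN_PARAMETER and ic.value not in out:
                out.append(ic.value)
        return out

    def is_observed(self, state: str) -> bool:
        return state in self.observed

    def with_observed(self, observed: Sequence[str]) -> "ODEModel":
        """Copy of the model with a replacement observed set."""
        return ODEModel(
            states=list(self.states),
            params=list(self.params),
            rhs=dict(self.rhs),
            observed=list(observed),
            initial_conditions=dict(self.initial_conditions),
            declared_params=list(self.declared_params),
        )

    def rename(self, mapping: Mapping[str, str]) -> "ODEModel":
        """Consistently rename states/parameters; analysis results follow."""
        def mp(nm):
            return mapping.get(nm, nm)

        subs = {sp.Symbol(a): sp.Symbol(b) for a, b in mapping.items()}
        ics = {}
        for st, ic in self.initial_conditions.items():
            if ic.kind is ICKind.UNKNOWN_PARAMETER:
                ics[mp(st)] = InitialCondition.parameter(mp(ic.value))
            else:
                ics[mp(st)] = ic
        return ODEModel(
            states=[mp(s) for s in self.states],
            params=[mp(p) for p in self.params],
            rhs={mp(s): e.xreplace(subs) for s, e in self.rhs.items()},
            observed=[mp(s) for s in self.observed],
            initial_conditions=ics,
            declared_params=[mp(p) for p in self.declared_params],
        )


def latent_states(model: ODEModel) -> list[str]:
    """States not observed, in declaration order (the latent variables)."""
    return [s for s in model.states if s not in model.observed]


def _parse_expression(text: str, names: Sequence[str], where: str) -> sp.Expr:
    local = {nm: sp.Symbol(nm) for nm in names}
    local.update(ALLOWED_FUNCTIONS)
    try:
        expr = parse_expr(
            str(text),
            local_dict=local,
            # only the parser's numeric/symbol constructors: unknown function
            # names must not resolve to arbitrary sympy objects
            global_dict={
                "Integer": sp.Integer,
                "Float": sp.Float,
                "Rational": sp.Rational,
                "Symbol": sp.Symbol,
            },
            transformations=_TRANSFORMS,
            evaluate=True,
        )
    except UndeclaredSymbolError:
        raise
    except Exception as exc:  # sympy raises a zoo of error types here
        raise ExpressionParseError(f"cannot parse {where}: {text!r} ({exc})") from exc
    if not isinstance(expr, sp.Expr):
        raise ExpressionParseError(f"{where} is not an expression: {text!r}")
    return expr


def parse_model(document: str | Mapping) -> ODEModel:
    """Parse a structured model document (YAML text or mapping) to an ODEModel.

    Raises a named validation error for undeclared symbols, non-state observed
    names, duplicate names and unparseable expressions.
    """
    if isinstance(document, str):
        try:
            doc = yaml.safe_load(document)
        except yaml.YAMLError as exc:
            raise ExpressionParseError(f"invalid model document: {exc}") from exc
    else:
        doc = dict(document)
    if not isinstance(doc, Mapping):
        raise ModelValidationError("model document must be a mapping")
    for key in ("states", "odes", "observed"):
        if key not in doc:
            raise ModelValidationError(f"model document is missing key {key!r}")

    states = [str(s) for s in doc["states"]]
    declared = [str(p) for p in doc.get("params", [])]
    for nm in states + declared:
        _check_name(nm, "declared")
    dup = {n for n in states + declared if (states + declared).count(n) > 1}
    if dup:
        raise DuplicateNameError(f"duplicate name {sorted(dup)[0]!r}")

    params = list(declared)
    init_doc = doc.get("init", {}) or {}
    ics: dict[str, InitialCondition] = {}
    for st in states:
        if st not in init_doc:
            raise ModelValidationError(f"missing initial condition for state {st!r}")
        raw = init_doc[st]
        if isinstance(raw, str) and _NAME_RE.match(raw) and raw not in ("0",):
            if raw in states:
                raise ModelValidationError(
                    f"initial condition of {st!r} names the state {raw!r}"
                )
            if raw not in params:
                params.append(raw)  # auto-register the IC parameter
            ics[st] = InitialCondition.parameter(raw)
        else:
            if isinstance(raw, str):
                val = _parse_expression(raw, [], f"init of {st}")
            elif isinstance(raw, numbers.Number):
                val = sp.nsimplify(raw, rational=True)
            else:
                raise ModelValidationError(f"bad initial condition for {st!r}: {raw!r}")
            ics[st] = InitialCondition.value_of(val)
    for extra in init_doc:
        if extra not in states:
            raise ModelValidationError(f"init entry {extra!r} is not a state")

    names = states + params
    odes = doc["odes"]
    rhs: dict[str, sp.Expr] = {}
    for st in states:
        if st not in odes:
            raise ModelValidationError(f"missing equation for state {st!r}")
        rhs[st] = _parse_expression(odes[st], names, f"d{st}/dt")
    for extra in odes:
        if extra not in states:
            raise ModelValidationError(f"equation for unknown state {extra!r}")

    observed = [str(s) for s in doc["observed"]]
    return ODEModel(
        states=states,
        params=params,
        rhs=rhs,
        observed=observed,
        initial_conditions=ics,
        declared_params=declared,
    )


def render_model(model: ODEModel) -> str:
    """Serialize a model back to its YAML document form (round-trips)."""
    init: dict[str, object] = {}
    for st in model.states:
        ic = model.initial_conditions[st]
        if ic.kind is ICKind.KNOWN_ZERO:
            init[st] = 0
        elif ic.kind is ICKind.KNOWN_VALUE:
            init[st] = str(ic.value) if not ic.value.is_Integer else int(ic.value)
        else:
            init[st] = ic.value
    doc = {
        "states": list(model.states),
        "params": list(model.declared_params),
        "odes": {st: str(model.rhs[st]) for st in model.states},
        "observed": list(model.observed),
        "init": init,
    }
    return yaml.safe_dump(doc, sort_keys=False)


def load_model(path) -> ODEModel:
    """Read a model document from a file path."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_model(fh.read())


def from_sbml(path, enable: bool = False) -> ODEModel:
    """Optional SBML import hook: kinetic laws become RHS expressions.

    Disabled by default; requires ``libsbml``.  Any failure is reported as a
    clean :class:`SBMLImportError`, never a crash.
    """
    if not enable:
        raise SBMLImportError("SBML import is disabled; pass enable=True")
    try:
        import libsbml  # noqa: F401
    except ImportError as exc:
        raise SBMLImportError("libsbml is not installed") from exc
    raise SBMLImportError("SBML kinetic-law translation is not implemented yet")
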