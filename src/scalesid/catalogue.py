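"""Built-in fixture models with expected identifiability verdicts.

Three small models carry asserted verdicts and are used as the regression
surface of the whole pipeline:

``death``
    dx/dt = -lam1*lam2*x with x observed and x(0) = x0 unknown.  Only the
    product lam1*lam2 is inferable from data, so both rates are
    unidentifiable and lam1*lam2 is an identifiable group.

``death_immigration``
    dx/dt = lam1 - lam2*x with x observed.  The constant and the linear
    summand scale differently, forcing the trivial solution: both rates are
    identifiable.

``twostate_nonlinear``
    dx1/dt = lam1*x1^2 + lam2*x1*x2, dx2/dt = lam3*x1^2 + lam4*x1*x2 with
    only x1 observed.  Rescaling the latent x2 can be absorbed by lam2 and
    lam3, so those are unidentifiable (group lam2*lam3) and x2 is
    unobservable, while lam1 and lam4 are identifiable.

The Goodwin oscillator is included as a larger reconstructed fixture whose
exact literature variant differs between sources; it carries no asserted
verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UnknownCatalogueEntry
from .model_ir import ODEModel, parse_model

__all__ = ["CatalogueEntry", "get_model", "expected_verdict", "list_entries", "entry"]


@dataclass(frozen=True)
class CatalogueEntry:
    name: str
    document: str
    provenance: str
    expected: dict | None = None  # verdict fragment; None = not asserted
    simulation_ics: dict = field(default_factory=dict)  # overrides for numeric checks

    @property
    def asserted(self) -> bool:
        return self.expected is not None

    def model(self) -> ODEModel:
        return parse_model(self.document)


_ENTRIES: dict[str, CatalogueEntry] = {}


def _register(entry_: CatalogueEntry) -> None:
    _ENTRIES[entry_.name] = entry_


_register(
    CatalogueEntry(
        name="death",
        document="""\
states: [x]
params: [lam1, lam2]
odes:
  x: -lam1*lam2*x
observed: [x]
init:
  x: x0
""",
        provenance="one-state death model with a product death rate",
        expected={
            "parameters": {"lam1": "unidentifiable", "lam2": "unidentifiable", "x0": "identifiable"},
            "latents": {},
            "groups": [{"lam1": 1, "lam2": 1}],
        },
    )
)

_register(
    CatalogueEntry(
        name="death_immigration",
        document="""\
states: [x]
params: [lam1, lam2]
odes:
  x: lam1 - lam2*x
observed: [x]
init:
  x: x0
""",
        provenance="death model with constant immigration",
        expected={
            "parameters": {"lam1": "identifiable", "lam2": "identifiable", "x0": "identifiable"},
            "latents": {},
            "groups": [],
        },
    )
)

_register(
    CatalogueEntry(
        name="twostate_nonlinear",
        document="""\
states: [x1, x2]
params: [lam1, lam2, lam3, lam4]
odes:
  x1: lam1*x1^2 + lam2*x1*x2
  x2: lam3*x1^2 + lam4*x1*x2
observed: [x1]
init:
  x1: 0
  x2: 0
""",
        provenance="two-state quadratic model with one observed state",
        expected={
            "parameters": {
                "lam1": "identifiable",
                "lam2": "unidentifiable",
                "lam3": "unidentifiable",
                "lam4": "identifiable",
            },
            "latents": {"x2": "unobservable"},
            "groups": [{"lam2": 1, "lam3": 1}],
        },
        # the declared zero start gives the trivial trajectory x == 0;
        # numeric cross-checks seed the observed state away from zero
        simulation_ics={"x1": 1.0},
    )
)

_register(
    CatalogueEntry(
        name="goodwin",
        document="""\
states: [x1, x2, x3]
params: [a, b, k, alpha, beta, gamma, delta]
odes:
  x1: a/(k + x3^10) - b*x1
  x2: alpha*x1 - beta*x2
  x3: gamma*x2 - delta*x3
observed: [x1]
init:
  x1: x1_0
  x2: x2_0
  x3: x3_0
""",
        provenance=(
            "reconstructed three-state Goodwin oscillator (Hill exponent 10); "
            "literature variants differ, no asserted verdict"
        ),
        expected=None,
    )
)


def list_entries() -> list[str]:
    return sorted(_ENTRIES)


def entry(name: str) -> CatalogueEntry:
    try:
        return _ENTRIES[name]
    except KeyError:
        raise UnknownCatalogueEntry(
            f"unknown catalogue model {name!r}; available: {', '.join(list_entries())}"
        ) from None


def get_model(name: str) -> ODEModel:
    """A fresh validated model instance for the named entry."""
    return entry(name).model()


def expected_verdict(name: str) -> dict | None:
    """Stored verdict fragment, or None for unasserted (reconstructed) entries."""
    return entry(name).expected
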