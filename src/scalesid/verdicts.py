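"""Classification of parameters and latent states from symmetry generators.

A parameter is locally identifiable by the scaling test exactly when its
log-scaling exponent is zero in every symmetry generator (the only
admissible factor is u = 1); a latent state is observable under the same
condition.  Parameters whose exponents are coupled across generators form
identifiable groups: monomial combinations prod lam_j^{c_j} invariant under
every generator, estimable even when the individual factors are not.
"""

from __future__ import annotations

import datetime
import json
import math
from dataclasses import dataclass, field

import sympy as sp

from .decompose import SamplingConfig, decompose_model
from .model_ir import ICKind, ODEModel, latent_states
from .scaling_core import (
    MonomialRelation,
    ScalingSystem,
    SymmetryGenerator,
    _primitive_integer,
    assemble_system,
    render_identifiability_equations,
    solve_generators,
)

__all__ = [
    "ParameterGroup",
    "IdentifiabilityReport",
    "classify",
    "identifiable_groups",
    "what_if_observed",
    "run_analysis",
]

REPORT_SCHEMA = "scalesid-report/1"

_STANDING_CAVEAT = (
    "scaling test only: a positive verdict means no continuous scaling "
    "symmetry was found (locally identifiable by this test); discrete "
    "symmetries and scalings fixed at values other than 1 are invisible "
    "to the log-linear formulation"
)


@dataclass(frozen=True)
class ParameterGroup:
    """An identifiable monomial combination prod lam_j^{c_j} of parameters.

    Exponent vectors are primitive integers (gcd 1, first nonzero positive);
    the group value is invariant under every symmetry generator.
    """

    exponents: tuple[tuple[str, int], ...]

    def as_dict(self) -> dict[str, int]:
        return dict(self.exponents)

    def value_at(self, values: dict[str, float]) -> float:
        return math.prod(values[nm] ** e for nm, e in self.exponents)

    def __str__(self) -> str:
        parts = []
        for nm, e in self.exponents:
            parts.append(nm if e == 1 else f"{nm}^{e}")
        return "*".join(parts)


@dataclass
class IdentifiabilityReport:
    """Full outcome of the scaling-invariance identifiability analysis."""

    model: ODEModel
    parameters: dict[str, str]  # name -> "identifiable" | "unidentifiable"
    latents: dict[str, str]  # name -> "observable" | "unobservable"
    equations: list[MonomialRelation]
    groups: list[ParameterGroup]
    generators: list[SymmetryGenerator]
    caveats: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def all_identifiable(self) -> bool:
        return all(v == "identifiable" for v in self.parameters.values())

    def unidentifiable_parameters(self) -> list[str]:
        return [p for p, v in self.parameters.items() if v == "unidentifiable"]

    def to_text(self) -> str:
        lines = ["Identifiability equations:"]
        if self.equations:
            lines += [f"  {eq}" for eq in self.equations]
        else:
            lines.append("  (no constraints)")
        lines.append("Parameters:")
        for nm in self.model.params:
            lines.append(f"  {nm}: {self.parameters[nm]}")
        if self.latents:
            lines.append("Latent states:")
            for nm, v in self.latents.items():
                lines.append(f"  {nm}: {v}")
        if self.groups:
            lines.append("Identifiable groups:")
            lines += [f"  {g}" for g in self.groups]
        if self.caveats:
            lines.append("Caveats:")
            lines += [f"  - {c}" for c in self.caveats]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "schema": REPORT_SCHEMA,
            "parameters": dict(self.parameters),
            "latent_states": dict(self.latents),
            "identifiability_equations": [
                {nm: e for nm, e in eq.exponents} for eq in self.equations
            ],
            "identifiable_groups": [g.as_dict() for g in self.groups],
            "generators": [
                {u.name: str(e) for u, e in zip(g.unknowns, g.exponents) if e != 0}
                for g in self.generators
            ],
            "caveats": list(self.caveats),
            "provenance": dict(self.provenance),
        }

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def identifiable_groups(
    generators: list[SymmetryGenerator], parameter_names: list[str]
) -> list[ParameterGroup]:
    """Minimal generating set of invariant parameter monomials.

    Computed as the exact rational kernel of the generator matrix restricted
    to the columns of parameters that are touched by some generator, then
    scaled to primitive integer vectors.  Parameters untouched by every
    generator are trivially invariant on their own and are left out.
    """
    if not generators:
        return []
    touched = [
        nm
        for nm in parameter_names
        if any(g[nm] != 0 for g in generators if nm in g.as_dict())
    ]
    if not touched:
        return []
    gmat = sp.Matrix(
        [[g.as_dict().get(nm, sp.S.Zero) for nm in touched] for g in generators]
    )
    groups = []
    for vec in gmat.nullspace():
        ints = _primitive_integer(list(vec))
        exps = tuple((nm, int(e)) for nm, e in zip(touched, ints) if e != 0)
        if exps:
            groups.append(ParameterGroup(exponents=exps))
    return groups


def classify(
    model: ODEModel,
    generators: list[SymmetryGenerator],
    *,
    system: ScalingSystem | None = None,
    decomposition=None,
    provenance: dict | None = None,
) -> IdentifiabilityReport:
    """Turn solved generators into the final per-symbol verdicts.

    An empty generator list means every parameter is identifiable and every
    latent state observable.
    """
    def exponent(g: SymmetryGenerator, nm: str):
        return g.as_dict().get(nm, sp.S.Zero)

    parameters = {
        nm: (
            "identifiable"
            if all(exponent(g, nm) == 0 for g in generators)
            else "unidentifiable"
        )
        for nm in model.params
    }
    latents = {
        nm: (
            "observable"
            if all(exponent(g, nm) == 0 for g in generators)
            else "unobservable"
        )
        for nm in latent_states(model)
    }
    equations = render_identifiability_equations(system) if system is not None else []
    groups = identifiable_groups(generators, model.params)

    caveats = [_STANDING_CAVEAT]
    rhs_symbols = {str(s) for e in model.rhs.values() for s in e.free_symbols}
    for nm in model.params:
        if nm not in rhs_symbols and nm not in model.ic_parameters:
            parameters[nm] = "unidentifiable"
            caveats.append(
                f"parameter {nm} appears in no equation or initial condition "
                "(structurally absent); reported unidentifiable"
            )
    for st in model.observed:
        ic = model.initial_conditions[st]
        if ic.kind is not ICKind.KNOWN_ZERO:
            caveats.append(
                f"initial condition of observed state {st} declared as "
                f"{ic.kind.value}; observedness already pins its scaling"
            )
    if decomposition is not None and decomposition.merge_events:
        for ev in decomposition.merge_events:
            caveats.append(f"scaling-blind merged summand: {ev}")
    return IdentifiabilityReport(
        model=model,
        parameters=parameters,
        latents=latents,
        equations=equations,
        groups=groups,
        generators=list(generators),
        caveats=caveats,
        provenance=provenance or {},
    )


def run_analysis(
    model: ODEModel,
    sampling: SamplingConfig = SamplingConfig(),
    method: str = "symbolic",
) -> IdentifiabilityReport:
    """End-to-end pipeline: decompose -> assemble -> solve -> classify."""
    decomposition = decompose_model(model, sampling)
    system = assemble_system(model, decomposition, sampling, method=method)
    generators = solve_generators(system)
    provenance = {
        "method": method,
        "seed": sampling.seed,
        "rank_rtol": sampling.rank_rtol,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "observed": list(model.observed),
    }
    return classify(
        model,
        generators,
        system=system,
        decomposition=decomposition,
        provenance=provenance,
    )


def what_if_observed(
    model: ODEModel,
    extra_observed: list[str] | set[str],
    sampling: SamplingConfig = SamplingConfig(),
    method: str = "symbolic",
) -> IdentifiabilityReport:
    """Re-run the analysis pretending additional latent states were measured.

    Useful for experiment design: groups involving a latent variable suggest
    observing it to decouple the group.
    """
    extra = list(extra_observed)
    lat = set(latent_states(model))
    for nm in extra:
        if nm not in lat:
            raise ValueError(f"{nm!r} is not a latent state of the model")
    if not extra:
        return run_analysis(model, sampling, method)
    augmented = model.with_observed(list(model.observed) + extra)
    return run_analysis(augmented, sampling, method)
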