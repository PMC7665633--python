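"""Identifiability equations as a homogeneous linear system in log-scalings.

The scaling transformation multiplies every parameter and every latent state
by a positive factor u.  Writing u = e^(eps*a) and differentiating the
per-summand invariance condition

    f_ik(x, lam) = (1/u_{x_i}) * f_ik(u_x * x, u_lam * lam)

at eps = 0 turns the finite matching of the method into a linear condition
on the log-scaling exponents a:

    sum_s a_s * c_s(x, lam) == 0   identically,   c_s = s * d f_ik / d s,

with an extra term c_{x_i} = -f_ik when the equation belongs to a latent
state.  Collecting the condition over a basis of independent functions of
(x, lam) yields exact rational constraint rows; the nullspace of the stacked
matrix is the space of symmetry generators.  An empty nullspace means the
only admissible scaling is the trivial one (all u = 1).

Two row-extraction paths are provided and cross-checked in the test suite:
symbolic collection of monomial coefficients (canonical) and evaluation of
the coefficient functions at exact rational sample points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import sympy as sp

from .decompose import SamplingConfig, SummandDecomposition
from .errors import EvaluationFailure
from .model_ir import ICKind, ODEModel, latent_states

__all__ = [
    "Unknown",
    "ScalingSystem",
    "SymmetryGenerator",
    "MonomialRelation",
    "generator_condition",
    "assemble_system",
    "solve_generators",
    "render_identifiability_equations",
]


@dataclass(frozen=True)
class Unknown:
    """One log-scaling factor: a parameter's, a latent state's."""

    name: str
    kind: str  # "param" | "state"

    def __str__(self) -> str:
        return f"u_{self.name}"


@dataclass
class ScalingSystem:
    """Exact-rational constraint matrix over the log-scaling unknowns.

    Observed states carry no unknown (their scaling is pinned to 1, w = 0);
    rows record their provenance as (state, summand) or
    (state, "initial_condition").
    """

    unknowns: list[Unknown]
    matrix: sp.Matrix  # rows x unknowns, exact entries
    row_provenance: list[tuple[str, str]] = field(default_factory=list)

    @property
    def unknown_names(self) -> list[str]:
        return [u.name for u in self.unknowns]

    def column(self, name: str) -> int:
        return self.unknown_names.index(name)

    def to_dict(self) -> dict:
        return {
            "unknowns": [{"name": u.name, "kind": u.kind} for u in self.unknowns],
            "rows": [
                {
                    "coefficients": [str(v) for v in self.matrix.row(i)],
                    "provenance": list(self.row_provenance[i]),
                }
                for i in range(self.matrix.rows)
            ],
        }


@dataclass(frozen=True)
class SymmetryGenerator:
    """A nonzero rational exponent vector a with matrix @ a == 0 exactly.

    Normalized to lowest integer terms with the first nonzero entry positive;
    the finite symmetry it generates is lam -> e^(eps*a_lam) * lam,
    latent x(0) -> e^(eps*a_x) * x(0), for every eps.
    """

    unknowns: tuple[Unknown, ...]
    exponents: tuple[sp.Rational, ...]

    def __post_init__(self):
        if all(e == 0 for e in self.exponents):
            raise ValueError("a symmetry generator must be nonzero")

    def __getitem__(self, name: str) -> sp.Rational:
        for u, e in zip(self.unknowns, self.exponents):
            if u.name == name:
                return e
        raise KeyError(name)

    def as_dict(self) -> dict[str, sp.Rational]:
        return {u.name: e for u, e in zip(self.unknowns, self.exponents)}

    def support(self) -> list[str]:
        return [u.name for u, e in zip(self.unknowns, self.exponents) if e != 0]


@dataclass(frozen=True)
class MonomialRelation:
    """A rendered identifiability equation: prod_s u_s^{c_s} = 1."""

    exponents: tuple[tuple[str, int], ...]  # (unknown name, integer exponent)

    def as_dict(self) -> dict[str, int]:
        return dict(self.exponents)

    def __str__(self) -> str:
        num, den = [], []
        for name, e in self.exponents:
            if e > 0:
                num.append(f"u_{name}" + (f"^{e}" if e != 1 else ""))
            elif e < 0:
                den.append(f"u_{name}" + (f"^{-e}" if e != -1 else ""))
        head = "*".join(num) or "1"
        if den:
            head += "/" + ("(" + "*".join(den) + ")" if len(den) > 1 else "/".join(den))
        return f"{head} = 1"


# ---------------------------------------------------------------------------
# invariance condition of a single summand


def generator_condition(
    summand: sp.Expr,
    state: str,
    model: ODEModel,
    latent: bool,
) -> dict[str, sp.Expr]:
    """Coefficient functions of the infinitesimal invariance condition.

    Returns {scaled symbol -> c_s(x, lam)} such that the summand's condition
    is  sum_s a_s * c_s == 0 identically in states and parameters, with
    c_s = s * d(summand)/ds for every scaled symbol in the summand and the
    extra term -summand on the equation's own state when it is latent.
    """
    latents = set(latent_states(model))
    coeffs: dict[str, sp.Expr] = {}
    free = {str(s) for s in summand.free_symbols}
    for nm in model.params:
        if nm in free:
            s = sp.Symbol(nm)
            coeffs[nm] = s * sp.diff(summand, s)
    for nm in model.states:
        if nm in free and nm in latents:
            s = sp.Symbol(nm)
            coeffs[nm] = s * sp.diff(summand, s)
    if latent:
        coeffs[state] = coeffs.get(state, sp.S.Zero) - summand
    return {k: v for k, v in coeffs.items() if v != 0}


def _poly_generators(expr: sp.Expr, exclude: set[sp.Symbol]) -> list[sp.Expr]:
    """Generators for coefficient collection: plain symbols, transcendental
    function applications, and powers with non-integer exponents, all treated
    as algebraically independent."""
    gens: set[sp.Expr] = {s for s in expr.free_symbols if s not in exclude}
    gens |= set(expr.atoms(sp.Function))
    for p in expr.atoms(sp.Pow):
        if not (p.exp.is_Integer or p.base in gens):
            gens.add(p)
    return sorted(gens, key=sp.default_sort_key)


def _symbolic_rows(
    coeffs: dict[str, sp.Expr], unknown_names: list[str]
) -> list[list[sp.Rational]] | None:
    """Collect sum_s a_s c_s over independent functions of (x, lam).

    One row per independent coefficient group; returns None when the
    expression resists polynomial collection (caller falls back to sampling).
    """
    dummies = {nm: sp.Dummy(f"a_{nm}") for nm in coeffs}
    g = sp.Add(*[dummies[nm] * c for nm, c in coeffs.items()])
    if g.has(sp.sin, sp.cos, sp.tan):
        g = sp.trigsimp(g)
    g = sp.together(sp.expand(g))
    num = sp.expand(sp.fraction(g)[0])
    if num == 0:
        return []
    try:
        poly = sp.Poly(num, *_poly_generators(num, set(dummies.values())))
    except (sp.PolynomialError, sp.GeneratorsError, sp.GeneratorsNeeded):
        return None
    rows: list[list[sp.Rational]] = []
    for coeff in poly.coeffs():
        row = [sp.S.Zero] * len(unknown_names)
        rest = coeff
        for nm, d in dummies.items():
            c = sp.expand(coeff).coeff(d)
            if c.free_symbols:
                return None
            rest = rest - c * d
            if nm in unknown_names:
                row[unknown_names.index(nm)] = c
        if sp.expand(rest) != 0:
            return None  # condition not homogeneous-linear; should not happen
        if any(v != 0 for v in row):
            rows.append(row)
    return _dedupe_rows(rows)


def _dedupe_rows(rows: list[list[sp.Rational]]) -> list[list[sp.Rational]]:
    seen, out = set(), []
    for row in rows:
        key = tuple(_primitive_integer(row))
        if key not in seen:
            seen.add(key)
            out.append(row)
    return out


def _primitive_integer(vec) -> list[sp.Integer]:
    """Scale a rational vector to coprime integers, first nonzero positive."""
    fracs = [Fraction(int(sp.Rational(v).p), int(sp.Rational(v).q)) for v in vec]
    denom_lcm = math.lcm(*[f.denominator for f in fracs]) if fracs else 1
    ints = [int(f * denom_lcm) for f in fracs]
    g = math.gcd(*[abs(i) for i in ints]) if any(ints) else 1
    if g:
        ints = [i // g for i in ints]
    for i in ints:
        if i != 0:
            if i < 0:
                ints = [-j for j in ints]
            break
    return [sp.Integer(i) for i in ints]


def _rational_points(symbols, rng, max_den: int = 97):
    """Exact rational sample point, coordinates in (0, max_den]."""
    return {
        s: sp.Rational(int(rng.integers(1, max_den + 1)), int(rng.integers(1, max_den + 1)))
        for s in symbols
    }


def _sampling_rows(
    coeffs: dict[str, sp.Expr],
    unknown_names: list[str],
    model: ODEModel,
    sampling: SamplingConfig,
    rng,
) -> list[list[sp.Expr]]:
    """Evaluate the coefficient functions at exact rational points.

    Each point contributes one row; rows stay exact so rank needs no
    tolerance.  Points landing on poles are rejection-resampled.
    """
    symbols = [sp.Symbol(nm) for nm in model.states + model.params]
    n_rows = len(unknown_names) + 5
    rows = []
    for _ in range(n_rows):
        for _attempt in range(sampling.max_retries + 1):
            point = _rational_points(symbols, rng)
            vals = {}
            ok = True
            for nm, c in coeffs.items():
                v = c.subs(point)
                if not v.is_finite:
                    ok = False
                    break
                vals[nm] = v
            if ok:
                row = [sp.S.Zero] * len(unknown_names)
                for nm, v in vals.items():
                    if nm in unknown_names:
                        row[unknown_names.index(nm)] = v
                rows.append(row)
                break
        else:
            raise EvaluationFailure(list(coeffs.values())[0])
    return rows


# ---------------------------------------------------------------------------
# system assembly


def _system_unknowns(model: ODEModel) -> list[Unknown]:
    unknowns = [Unknown(nm, "param") for nm in model.params]
    unknowns += [Unknown(nm, "state") for nm in latent_states(model)]
    return unknowns


def assemble_system(
    model: ODEModel,
    decomposition: SummandDecomposition,
    sampling: SamplingConfig = SamplingConfig(),
    method: str = "symbolic",
) -> ScalingSystem:
    """Stack the per-summand invariance rows and the initial-condition rows.

    Initial conditions contribute:
      * latent state with unknown-parameter IC: tie row  w_x - w_{x0} = 0
        (the state's scaling equals its IC parameter's);
      * observed state with unknown-parameter IC: pin row  w_{x0} = 0;
      * latent state with known nonzero IC: pin row  w_x = 0;
      * known-zero ICs: no row (scaling a zero IC is vacuous).
    """
    if method not in ("symbolic", "sampling"):
        raise ValueError(f"unknown method {method!r}")
    import numpy as np

    rng = np.random.default_rng(sampling.seed)
    unknowns = _system_unknowns(model)
    names = [u.name for u in unknowns]
    latents = set(latent_states(model))
    rows: list[list] = []
    prov: list[tuple[str, str]] = []

    for st in model.states:
        for summand in decomposition.summands[st]:
            coeffs = generator_condition(summand.expr, st, model, st in latents)
            if not coeffs:
                continue
            got = None
            if method == "symbolic":
                got = _symbolic_rows(coeffs, names)
            if got is None:
                got = _sampling_rows(coeffs, names, model, sampling, rng)
            for row in got:
                rows.append(row)
                prov.append((st, str(summand.expr)))

    for st in model.states:
        ic = model.initial_conditions[st]
        if ic.kind is ICKind.UNKNOWN_PARAMETER:
            row = [sp.S.Zero] * len(names)
            row[names.index(ic.value)] = sp.S.One
            if st in latents:
                row[names.index(st)] = sp.S.NegativeOne
            # observed state: w_x = 0 already, so the row pins w_{x0}
            rows.append(row)
            prov.append((st, "initial_condition"))
        elif ic.kind is ICKind.KNOWN_VALUE and st in latents:
            row = [sp.S.Zero] * len(names)
            row[names.index(st)] = sp.S.One
            rows.append(row)
            prov.append((st, "initial_condition"))

    matrix = sp.Matrix(len(rows), len(names), lambda i, j: rows[i][j]) if rows else sp.zeros(0, len(names))
    return ScalingSystem(unknowns=unknowns, matrix=matrix, row_provenance=prov)


def solve_generators(system: ScalingSystem) -> list[SymmetryGenerator]:
    """Exact nullspace basis of the constraint matrix, normalized.

    Empty list means only the trivial scaling (all u = 1) is admissible.
    """
    if not system.unknowns:
        return []
    if system.matrix.rows == 0:
        basis = [sp.Matrix([sp.S.Zero] * len(system.unknowns)) for _ in system.unknowns]
        for i, b in enumerate(basis):
            b[i] = sp.S.One
    else:
        basis = system.matrix.nullspace()
    gens = []
    for vec in basis:
        ints = _primitive_integer(list(vec))
        gens.append(
            SymmetryGenerator(
                unknowns=tuple(system.unknowns),
                exponents=tuple(sp.Rational(i) for i in ints),
            )
        )
    return gens


def render_identifiability_equations(system: ScalingSystem) -> list[MonomialRelation]:
    """Reduced identifiability equations: RREF rows as monomial relations.

    Each nonzero row of the reduced row-echelon form of the constraint
    matrix becomes prod_s u_s^{c_s} = 1 with coprime integer exponents and
    the first nonzero exponent positive.
    """
    if system.matrix.rows == 0 or not system.unknowns:
        return []
    rref, _ = system.matrix.rref()
    relations = []
    for i in range(rref.rows):
        row = list(rref.row(i))
        if all(v == 0 for v in row):
            continue
        ints = _primitive_integer(row)
        exps = tuple(
            (u.name, int(e)) for u, e in zip(system.unknowns, ints) if e != 0
        )
        relations.append(MonomialRelation(exponents=exps))
    return relations
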