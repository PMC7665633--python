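"""Additive summand decomposition and functional-independence certification.

Each right-hand side f_i is expanded to additive normal form and split into
candidate summands f_ik.  The scaling method matches each summand to its
scaled version separately, which is only legitimate when the summands of one
equation are functionally independent as functions of time along trajectories
— no nontrivial constant linear combination of them vanishes identically.

Independence is certified numerically: every summand is evaluated at N
sampled points of state space (parameters held at fixed generic positive
values), and the summands are declared independent iff the resulting
points x functions value matrix has full column rank.  Summands that fail the
test are merged back into a single combined summand, for which the unsplit
invariance condition remains valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .errors import EvaluationFailure
from .model_ir import ODEModel

__all__ = [
    "SamplingConfig",
    "IndependenceCertificate",
    "Summand",
    "SummandDecomposition",
    "split_summands",
    "check_independence",
    "decompose_model",
]


@dataclass(frozen=True)
class SamplingConfig:
    """How sample points for the numerical rank tests are drawn.

    ``n_points`` defaults to 3 * (#functions) + 5 when left as None.
    Coordinates are uniform on [low, high]; generic positive points keep the
    evaluations away from poles and sign cancellations.
    """

    seed: int = 0
    n_points: int | None = None
    low: float = 0.5
    high: float = 1.5
    rank_rtol: float = 1e-9
    max_retries: int = 20
    joint_parameter_sampling: bool = False

    def points_for(self, n_funcs: int) -> int:
        return self.n_points if self.n_points is not None else 3 * n_funcs + 5


@dataclass(frozen=True)
class IndependenceCertificate:
    """Numeric evidence for an independence verdict (reproducible by seed)."""

    independent: bool
    rank: int
    n_functions: int
    n_points: int
    seed: int
    rank_rtol: float

    def to_dict(self) -> dict:
        return {
            "independent": self.independent,
            "rank": self.rank,
            "n_functions": self.n_functions,
            "n_points": self.n_points,
            "seed": self.seed,
            "rank_rtol": self.rank_rtol,
        }


@dataclass(frozen=True)
class Summand:
    """One retained summand f_ik with its exact symbol supports."""

    expr: sp.Expr
    states: frozenset[str]
    params: frozenset[str]
    merged_from: tuple[sp.Expr, ...] = ()

    @property
    def was_merged(self) -> bool:
        return len(self.merged_from) > 1


@dataclass
class SummandDecomposition:
    """Per-equation retained summands plus the independence certificates."""

    model: ODEModel
    summands: dict[str, list[Summand]]
    certificates: dict[str, IndependenceCertificate]
    merge_events: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {st: len(terms) for st, terms in self.summands.items()}


def split_summands(expr: sp.Expr) -> list[sp.Expr]:
    """Expand to additive normal form; each top-level term is one candidate.

    Signs stay with their terms; a non-sum is returned as a single summand.
    """
    expanded = sp.expand(expr)
    if expanded == 0:
        return []
    if isinstance(expanded, sp.Add):
        return list(expanded.args)
    return [expanded]


def _make_summand(expr: sp.Expr, model: ODEModel, merged_from=()) -> Summand:
    free = {str(s) for s in expr.free_symbols}
    return Summand(
        expr=expr,
        states=frozenset(free & set(model.states)),
        params=frozenset(free & set(model.params)),
        merged_from=tuple(merged_from) or (expr,),
    )


def _value_matrix(
    funcs: list[sp.Expr],
    state_names: list[str],
    param_names: list[str],
    sampling: SamplingConfig,
) -> tuple[np.ndarray, int]:
    """Evaluate each function at sampled points; rows = points, cols = funcs.

    States are sampled per point; parameters are fixed at one generic draw
    (independence is a statement about functions of time along trajectories),
    unless joint sampling is requested.
    """
    rng = np.random.default_rng(sampling.seed)
    n_pts = sampling.points_for(len(funcs))
    all_syms = [sp.Symbol(nm) for nm in state_names + param_names]
    fns = [sp.lambdify(all_syms, f, modules="numpy") for f in funcs]

    param_vals = rng.uniform(sampling.low, sampling.high, size=len(param_names))
    rows = []
    for _ in range(n_pts):
        for attempt in range(sampling.max_retries + 1):
            states = rng.uniform(sampling.low, sampling.high, size=len(state_names))
            if sampling.joint_parameter_sampling:
                param_vals = rng.uniform(
                    sampling.low, sampling.high, size=len(param_names)
                )
            args = np.concatenate([states, param_vals])
            with np.errstate(all="ignore"):
                vals = np.array([float(fn(*args)) for fn in fns])
            if np.all(np.isfinite(vals)):
                rows.append(vals)
                break
        else:
            bad = [f for f, fn in zip(funcs, fns) if not np.isfinite(float(fn(*args)))]
            raise EvaluationFailure(bad[0] if bad else funcs[0])
    return np.array(rows), n_pts


def _numerical_rank(matrix: np.ndarray, rtol: float) -> int:
    if matrix.size == 0:
        return 0
    svals = np.linalg.svd(matrix, compute_uv=False)
    if svals.size == 0 or svals[0] == 0:
        return 0
    return int(np.sum(svals > rtol * svals[0]))


def check_independence(
    funcs: list[sp.Expr],
    state_names: list[str],
    param_names: list[str],
    sampling: SamplingConfig = SamplingConfig(),
) -> IndependenceCertificate:
    """Sampled-rank functional-independence test.

    Verdict "independent" iff the numerical rank of the value matrix equals
    the number of functions.  A singleton nonzero function is independent.
    """
    if not funcs:
        raise ValueError("need at least one function")
    matrix, n_pts = _value_matrix(funcs, state_names, param_names, sampling)
    rank = _numerical_rank(matrix, sampling.rank_rtol)
    return IndependenceCertificate(
        independent=(rank == len(funcs)),
        rank=rank,
        n_functions=len(funcs),
        n_points=n_pts,
        seed=sampling.seed,
        rank_rtol=sampling.rank_rtol,
    )


def _merge_dependent(
    terms: list[sp.Expr],
    model: ODEModel,
    sampling: SamplingConfig,
    state: str,
    events: list[str],
) -> list[list[sp.Expr]]:
    """Group candidate summands so that group sums are independent.

    Greedy scan with a union-find over groups: a term whose value vector lies
    in the span of the current groups is merged into every group that carries
    weight in the dependency.
    """
    matrix, _ = _value_matrix(terms, model.states, model.params, sampling)
    groups: list[list[int]] = []
    cols: list[np.ndarray] = []  # value vector of each group's sum
    for j, term in enumerate(terms):
        v = matrix[:, j]
        if cols:
            basis = np.column_stack(cols)
            coef, *_ = np.linalg.lstsq(basis, v, rcond=None)
            resid = v - basis @ coef
            scale = max(np.linalg.norm(v), 1.0)
            if np.linalg.norm(resid) <= 1e-8 * scale:
                # dependent: merge into every group with nonzero weight
                involved = [
                    i for i, c in enumerate(coef) if abs(c) > 1e-8 * max(1.0, abs(coef).max())
                ] or [len(groups) - 1]
                keep = involved[0]
                merged = groups[keep] + [j]
                merged_cols = cols[keep] + v
                for i in sorted(involved[1:], reverse=True):
                    merged += groups.pop(i)
                    merged_cols = merged_cols + cols.pop(i)
                groups[keep] = sorted(merged)
                cols[keep] = merged_cols
                events.append(
                    f"{state}: merged dependent summand {term} "
                    f"into group {[str(terms[i]) for i in groups[keep]]}"
                )
                continue
        groups.append([j])
        cols.append(v)
    return [[terms[i] for i in grp] for grp in groups]


def decompose_model(
    model: ODEModel, sampling: SamplingConfig = SamplingConfig()
) -> SummandDecomposition:
    """Split every RHS into certified functionally independent summands.

    Dependent candidates within one equation are merged into a single
    combined summand (the unsplit invariance condition stays valid); every
    merge is recorded as a scaling-blind caveat for the report.
    """
    summands: dict[str, list[Summand]] = {}
    certificates: dict[str, IndependenceCertificate] = {}
    events: list[str] = []
    for st in model.states:
        terms = split_summands(model.rhs[st])
        if not terms:
            summands[st] = []
            certificates[st] = IndependenceCertificate(
                True, 0, 0, 0, sampling.seed, sampling.rank_rtol
            )
            continue
        cert = check_independence(terms, model.states, model.params, sampling)
        if cert.independent:
            grouped = [[t] for t in terms]
        else:
            grouped = _merge_dependent(terms, model, sampling, st, events)
            retained = [sp.Add(*grp) for grp in grouped]
            cert = check_independence(retained, model.states, model.params, sampling)
        summands[st] = [
            _make_summand(sp.Add(*grp), model, merged_from=grp) for grp in grouped
        ]
        certificates[st] = cert
    return SummandDecomposition(
        model=model, summands=summands, certificates=certificates, merge_events=events
    )
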