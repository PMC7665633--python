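"""Numerical cross-validation of the symbolic verdicts.

Forward sensitivities S_ij = dx_i/dlam_j are integrated with the variational
system dS/dt = J_x S + J_lam alongside the states; elasticities are the
relative (log-log) sensitivities K_ij = (lam_j / x_i) S_ij, so K_ij = 1
means a 10% bump in lam_j moves x_i by 10%.  A symmetry generator predicts
an exact linear dependence among the elasticity columns it couples, and a
finite scaling along a generator must leave every observed trajectory
unchanged — both are checked here against the integrated trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from .errors import IntegrationFailure
from .model_ir import ICKind, ODEModel, latent_states
from .scaling_core import SymmetryGenerator

__all__ = [
    "ElasticityTrajectory",
    "ElasticityMatrix",
    "sample_point",
    "choose_horizon",
    "simulate_with_sensitivities",
    "elasticity_matrix",
    "dependence_check",
    "finite_invariance_check",
]

#: relative floor below which |x_i| makes the elasticity row undefined
X_FLOOR_REL = 1e-12


def _initial_values(model: ODEModel, parameter_values: dict, ic_values: dict | None):
    ics = {}
    for st in model.states:
        ic = model.initial_conditions[st]
        if ic.kind is ICKind.KNOWN_ZERO:
            ics[st] = 0.0
        elif ic.kind is ICKind.KNOWN_VALUE:
            ics[st] = float(ic.value)
        else:
            ics[st] = float(parameter_values[ic.value])
    if ic_values:
        ics.update({k: float(v) for k, v in ic_values.items()})
    return ics


@dataclass
class ElasticityTrajectory:
    """States, sensitivities and elasticities along one solution.

    ``S`` has shape (T, n, m + n): parameter columns first (zero at t = 0),
    then one initial-condition column per state (identity at t = 0).  ``K``
    shares the grid and shape; entries where |x_i| is below the floor are
    masked (NaN) and tracked in ``mask``.
    """

    model: ODEModel
    t: np.ndarray
    x: np.ndarray  # (T, n)
    S: np.ndarray  # (T, n, m + n)
    K: np.ndarray
    mask: np.ndarray  # True where K is defined
    parameter_values: dict[str, float]
    ic_values: dict[str, float]
    metadata: dict = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.model.params) + [f"{st}_0" for st in self.model.states]

    def state_index(self, name: str) -> int:
        return self.model.states.index(name)

    def total_parameter_sensitivity(self, name: str) -> np.ndarray:
        """d x / d lam including the initial-condition route of IC parameters."""
        j = self.model.params.index(name)
        out = self.S[:, :, j].copy()
        for i, st in enumerate(self.model.states):
            ic = self.model.initial_conditions[st]
            if ic.kind is ICKind.UNKNOWN_PARAMETER and ic.value == name:
                out += self.S[:, :, len(self.model.params) + i]
        return out


def sample_point(model: ODEModel, seed: int = 0) -> dict[str, float]:
    """Generic positive test point: log-uniform values in [1/2, 2]."""
    rng = np.random.default_rng(seed)
    return {
        nm: float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
        for nm in model.params
    }


#: magnitude at which a trajectory is declared blown up
_BLOWUP = 1e12


def _integrate(model, parameter_values, y0, grid, rtol, atol, rhs_fn, n_eq):
    def blowup(t, y):
        return _BLOWUP - np.max(np.abs(y))

    blowup.terminal = True
    sol = solve_ivp(
        rhs_fn,
        (float(grid[0]), float(grid[-1])),
        y0,
        t_eval=np.asarray(grid, dtype=float),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        events=blowup,
    )
    if not sol.success or sol.status == 1:
        t_fail = float(sol.t[-1]) if sol.t.size else None
        msg = sol.message if sol.status != 1 else f"trajectory blow-up near t={t_fail}"
        raise IntegrationFailure(msg, t_fail=t_fail)
    return sol


def _plain_rhs(model: ODEModel):
    syms = model.state_symbols + model.param_symbols
    fns = sp.lambdify(syms, [model.rhs[st] for st in model.states], modules="numpy")

    def rhs(pvals):
        pv = np.array([pvals[nm] for nm in model.params], dtype=float)

        def f(t, y):
            return np.asarray(fns(*y, *pv), dtype=float)

        return f

    return rhs


def simulate_trajectory(
    model: ODEModel,
    parameter_values: dict[str, float],
    grid,
    ic_values: dict | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the plain (unaugmented) model; returns (t, x)."""
    ics = _initial_values(model, parameter_values, ic_values)
    y0 = np.array([ics[st] for st in model.states], dtype=float)
    sol = _integrate(
        model, parameter_values, y0, grid, rtol, atol, _plain_rhs(model)(parameter_values), model.n
    )
    return sol.t, sol.y.T


def choose_horizon(
    model: ODEModel,
    parameter_values: dict[str, float],
    t_end: float = 1.0,
    min_change: float = 0.1,
    max_extensions: int = 10,
    ic_values: dict | None = None,
) -> float:
    """Pick an integration horizon at which observed states have moved.

    Starting from ``t_end``, the horizon doubles (up to 10x) until every
    observed state changes by at least ``min_change`` relative to its range,
    and shrinks when the trajectory blows up before the horizon (finite-time
    blow-up is generic for polynomial right-hand sides).
    """
    horizon = t_end
    for _ in range(3 * max_extensions):
        try:
            _, x = simulate_trajectory(
                model,
                parameter_values,
                np.linspace(0.0, horizon, 20),
                ic_values=ic_values,
                rtol=1e-8,
                atol=1e-10,
            )
        except IntegrationFailure as exc:
            shrunk = (0.5 * exc.t_fail) if exc.t_fail else horizon / 4.0
            if shrunk <= 0 or not np.isfinite(shrunk):
                raise
            horizon = shrunk
            continue
        if not np.all(np.isfinite(x)):
            horizon /= 4.0
            continue
        obs = [model.states.index(s) for s in model.observed]
        x0 = x[0, obs]
        scale = np.maximum(np.abs(x0), np.abs(x[:, obs]).max(axis=0))
        scale[scale == 0] = 1.0
        change = np.abs(x[:, obs] - x0).max(axis=0) / scale
        if np.all(change >= min_change) or horizon >= max_extensions * t_end:
            return horizon
        horizon *= 2.0
    return horizon


def simulate_with_sensitivities(
    model: ODEModel,
    parameter_values: dict[str, float],
    grid,
    ic_values: dict | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> ElasticityTrajectory:
    """Integrate states together with the forward variational system.

    The Jacobians d f/d x and d f/d lam are derived symbolically and the
    augmented system (n + n*(m+n) equations) is integrated in one pass.
    Parameter sensitivity columns start at zero, initial-condition columns at
    the identity.
    """
    n, m = model.n, len(model.params)
    ncols = m + n
    syms = model.state_symbols + model.param_symbols
    f_vec = sp.Matrix([model.rhs[st] for st in model.states])
    jac_x = f_vec.jacobian(model.state_symbols)
    jac_p = f_vec.jacobian(model.param_symbols)
    f_fn = sp.lambdify(syms, f_vec, modules="numpy")
    jx_fn = sp.lambdify(syms, jac_x, modules="numpy")
    jp_fn = sp.lambdify(syms, jac_p, modules="numpy")
    pv = np.array([parameter_values[nm] for nm in model.params], dtype=float)

    def rhs(t, y):
        x = y[:n]
        S = y[n:].reshape(n, ncols)
        fx = np.asarray(f_fn(*x, *pv), dtype=float).ravel()
        Jx = np.asarray(jx_fn(*x, *pv), dtype=float)
        Jp = np.asarray(jp_fn(*x, *pv), dtype=float)
        dS = Jx @ S
        dS[:, :m] += Jp
        return np.concatenate([fx, dS.ravel()])

    ics = _initial_values(model, parameter_values, ic_values)
    x0 = np.array([ics[st] for st in model.states], dtype=float)
    S0 = np.zeros((n, ncols))
    S0[:, m:] = np.eye(n)
    y0 = np.concatenate([x0, S0.ravel()])
    sol = _integrate(model, parameter_values, y0, grid, rtol, atol, rhs, y0.size)

    T = sol.t.size
    x = sol.y[:n, :].T
    S = sol.y[n:, :].T.reshape(T, n, ncols)

    ic_vec = np.array([ics[st] for st in model.states], dtype=float)
    scales = np.concatenate([pv, ic_vec])  # lam_j or x_{j,0}
    floor = X_FLOOR_REL * np.maximum(np.abs(x).max(axis=0), 1e-300)
    mask = np.abs(x) > floor[None, :]
    with np.errstate(all="ignore"):
        K = scales[None, None, :] * S / x[:, :, None]
    K[~mask, :] = np.nan
    return ElasticityTrajectory(
        model=model,
        t=sol.t,
        x=x,
        S=S,
        K=K,
        mask=mask,
        parameter_values=dict(parameter_values),
        ic_values=ics,
        metadata={"method": "LSODA", "rtol": rtol, "atol": atol},
    )


@dataclass
class ElasticityMatrix:
    """Elasticities stacked over (observed state, time point) rows.

    Parameter columns use the total derivative (initial-condition route of
    IC parameters included); latent states with a fixed initial value get an
    IC column (zero when the initial value is zero).
    """

    matrix: np.ndarray  # (rows, cols), NaN where masked
    columns: list[str]
    column_kinds: list[str]  # "param" | "state"
    row_labels: list[tuple[str, float]]

    def column_for(self, name: str) -> np.ndarray:
        return self.matrix[:, self.columns.index(name)]

    def rank(self, rtol: float = 1e-8) -> int:
        mat = np.nan_to_num(self.matrix)
        if mat.size == 0:
            return 0
        svals = np.linalg.svd(mat, compute_uv=False)
        if svals.size == 0 or svals[0] == 0:
            return 0
        return int(np.sum(svals > rtol * svals[0]))


def elasticity_matrix(traj: ElasticityTrajectory) -> ElasticityMatrix:
    """Stack elasticities of the observed states over the time grid."""
    model = traj.model
    obs_idx = [model.states.index(s) for s in model.observed]
    m = len(model.params)
    columns: list[str] = []
    kinds: list[str] = []
    cols: list[np.ndarray] = []
    pv = traj.parameter_values
    for j, nm in enumerate(model.params):
        Stot = traj.total_parameter_sensitivity(nm)  # (T, n)
        with np.errstate(all="ignore"):
            Kcol = pv[nm] * Stot / traj.x
        Kcol[~traj.mask] = np.nan
        cols.append(Kcol[:, obs_idx].reshape(-1))
        columns.append(nm)
        kinds.append("param")
    for i, st in enumerate(model.states):
        if st in model.observed:
            continue
        ic = model.initial_conditions[st]
        if ic.kind is ICKind.UNKNOWN_PARAMETER:
            continue  # covered by its parameter column
        x0 = traj.ic_values[st]
        with np.errstate(all="ignore"):
            Kcol = x0 * traj.S[:, :, m + i] / traj.x
        Kcol[~traj.mask] = np.nan
        cols.append(Kcol[:, obs_idx].reshape(-1))
        columns.append(st)
        kinds.append("state")
    rows = [(st, float(t)) for st in model.observed for t in traj.t]
    matrix = np.column_stack(cols) if cols else np.zeros((len(rows), 0))
    return ElasticityMatrix(
        matrix=matrix, columns=columns, column_kinds=kinds, row_labels=rows
    )


def dependence_check(
    K: ElasticityMatrix,
    generators: list[SymmetryGenerator],
    tol: float = 1e-6,
) -> list[float]:
    """Residual of the predicted column dependence, one per generator.

    For a generator a the columns it couples must combine to zero:
    residual = max over rows |sum_s a_s K[row, s]| relative to the row norm.
    Masked entries are excluded.
    """
    residuals = []
    for gen in generators:
        combo = np.zeros(K.matrix.shape[0])
        used = np.ones(K.matrix.shape[0], dtype=bool)
        for name, e in gen.as_dict().items():
            if e == 0 or name not in K.columns:
                continue
            col = K.column_for(name)
            valid = np.isfinite(col)
            used &= valid
            combo = combo + float(e) * np.nan_to_num(col)
        row_norm = np.sqrt(np.nansum(np.nan_to_num(K.matrix[used]) ** 2, axis=1))
        scale = max(row_norm.max(initial=0.0), 1e-30)
        resid = np.abs(combo[used]).max(initial=0.0) / scale
        residuals.append(float(resid))
    return residuals


def _scaled_values(model, parameter_values, generator, eps):
    gdict = generator.as_dict()
    scaled_params = {
        nm: parameter_values[nm] * float(np.exp(eps * float(gdict.get(nm, 0))))
        for nm in model.params
    }
    scaled_ics = {}
    for st in latent_states(model):
        ic = model.initial_conditions[st]
        if ic.kind is ICKind.KNOWN_VALUE:
            scaled_ics[st] = float(ic.value) * float(
                np.exp(eps * float(gdict.get(st, 0)))
            )
        # unknown-parameter ICs ride on their scaled parameter;
        # known-zero ICs are fixed points of any scaling
    return scaled_params, scaled_ics


def finite_invariance_check(
    model: ODEModel,
    generator: SymmetryGenerator,
    eps: float,
    grid,
    parameter_values: dict[str, float],
    ic_values: dict | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> float:
    """Max deviation of observed trajectories under a finite scaling.

    Integrates the model at the base point and at the scaled point
    lam -> e^(eps*a) lam (latent fixed ICs scaled likewise) and returns the
    largest absolute difference of any observed state over the grid.  Near
    zero for true generators; clearly nonzero for injected non-symmetries.
    """
    _, x_base = simulate_trajectory(
        model, parameter_values, grid, ic_values=ic_values, rtol=rtol, atol=atol
    )
    scaled_params, scaled_ics = _scaled_values(model, parameter_values, generator, eps)
    if ic_values:
        merged = dict(scaled_ics)
        gdict = generator.as_dict()
        for st, v in ic_values.items():
            if st in model.observed:
                merged[st] = v
            else:
                merged[st] = float(v) * float(np.exp(eps * float(gdict.get(st, 0))))
        scaled_ics = merged
    _, x_scaled = simulate_trajectory(
        model, scaled_params, grid, ic_values=scaled_ics, rtol=rtol, atol=atol
    )
    obs = [model.states.index(s) for s in model.observed]
    return float(np.abs(x_base[:, obs] - x_scaled[:, obs]).max())
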