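"""Forward sensitivities, elasticities and numeric symmetry validation."""

import numpy as np
import pytest
import sympy as sp
from scipy.integrate import solve_ivp

from scalesid import catalogue, parse_model, run_analysis
from scalesid.elasticity import (
    choose_horizon,
    dependence_check,
    elasticity_matrix,
    finite_invariance_check,
    sample_point,
    simulate_trajectory,
    simulate_with_sensitivities,
)
from scalesid.scaling_core import SymmetryGenerator, Unknown

DEATH_VALUES = {"lam1": 0.8, "lam2": 1.5, "x0": 1.3}


@pytest.fixture
def death_traj(death_model, short_grid):
    grid = np.linspace(0.0, 1.0, 30)
    return simulate_with_sensitivities(death_model, DEATH_VALUES, grid)


class TestSensitivities:
    def test_death_matches_closed_form(self, death_model, death_traj):
        """x = x0 e^(-lam1 lam2 t), so d x/d lam1 = -lam2 t x (RHS route)."""
        t = death_traj.t
        lam1, lam2, x0 = (DEATH_VALUES[k] for k in ("lam1", "lam2", "x0"))
        x_exact = x0 * np.exp(-lam1 * lam2 * t)
        np.testing.assert_allclose(death_traj.x[:, 0], x_exact, rtol=1e-7)
        j = death_model.params.index("lam1")
        np.testing.assert_allclose(
            death_traj.S[:, 0, j], -lam2 * t * x_exact, rtol=1e-6, atol=1e-12
        )
        # IC route: d x / d x0 = e^(-lam1 lam2 t), via the x0 parameter column
        np.testing.assert_allclose(
            death_traj.total_parameter_sensitivity("x0")[:, 0],
            np.exp(-lam1 * lam2 * t),
            rtol=1e-6,
        )

    def test_initial_sensitivity_structure(self, death_traj, death_model):
        m = len(death_model.params)
        assert np.allclose(death_traj.S[0, :, :m], 0.0)  # parameter columns
        assert np.allclose(death_traj.S[0, :, m:], np.eye(death_model.n))  # IC cols

    def test_twostate_matches_independent_integrator(
        self, twostate_model, twostate_sim_ics, short_grid
    ):
        """Trajectory agrees with a separate high-accuracy Radau integration."""
        values = sample_point(twostate_model, seed=0)
        traj = simulate_with_sensitivities(
            twostate_model, values, short_grid, ic_values=twostate_sim_ics
        )
        syms = twostate_model.state_symbols + twostate_model.param_symbols
        f = sp.lambdify(syms, [twostate_model.rhs[s] for s in twostate_model.states])
        pv = [values[nm] for nm in twostate_model.params]
        sol = solve_ivp(
            lambda t, y: f(*y, *pv),
            (0.0, short_grid[-1]),
            [twostate_sim_ics.get("x1", 0.0), 0.0],
            t_eval=short_grid,
            method="Radau",
            rtol=1e-10,
            atol=1e-12,
        )
        assert sol.success
        np.testing.assert_allclose(traj.x, sol.y.T, rtol=1e-6, atol=1e-9)

    @pytest.mark.parametrize("name", ["death", "death_immigration", "twostate_nonlinear"])
    def test_sensitivities_match_finite_differences(self, name):
        """Central finite differences (relative step 1e-6) agree to 1e-4."""
        entry = catalogue.entry(name)
        model = entry.model()
        values = sample_point(model, seed=0)
        grid = np.linspace(0.0, choose_horizon(model, values, ic_values=entry.simulation_ics), 15)
        traj = simulate_with_sensitivities(
            model, values, grid, ic_values=entry.simulation_ics
        )
        for nm in model.params:
            h = 1e-6 * values[nm]
            up = dict(values, **{nm: values[nm] + h})
            dn = dict(values, **{nm: values[nm] - h})
            _, x_up = simulate_trajectory(model, up, grid, ic_values=entry.simulation_ics)
            _, x_dn = simulate_trajectory(model, dn, grid, ic_values=entry.simulation_ics)
            fd = (x_up - x_dn) / (2 * h)
            S = traj.total_parameter_sensitivity(nm)
            scale = np.abs(S).max() + 1e-12
            np.testing.assert_allclose(S, fd, atol=1e-4 * scale)


class TestElasticityMatrix:
    def test_death_columns_equal_with_known_magnitude(self, death_model, death_traj):
        """Both rate columns carry |K| = lam1*lam2*t and coincide exactly."""
        K = elasticity_matrix(death_traj)
        lam1, lam2 = DEATH_VALUES["lam1"], DEATH_VALUES["lam2"]
        k1, k2 = K.column_for("lam1"), K.column_for("lam2")
        np.testing.assert_allclose(k1, k2, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(
            np.abs(k1), lam1 * lam2 * death_traj.t, rtol=1e-6, atol=1e-10
        )

    def test_single_parameter_decay_column(self):
        """dx/dt = -lam x gives the exact column K = -lam t."""
        m = parse_model(
            """
states: [x]
params: [lam]
odes: {x: -lam*x}
observed: [x]
init: {x: 2}
"""
        )
        grid = np.linspace(0.0, 1.5, 20)
        traj = simulate_with_sensitivities(m, {"lam": 0.7}, grid)
        K = elasticity_matrix(traj)
        np.testing.assert_allclose(K.column_for("lam"), -0.7 * grid, rtol=1e-7, atol=1e-10)

    def test_elasticity_predicts_relative_response(self):
        """Where K = k, a small relative bump delta in lam moves x by ~k*delta."""
        m = parse_model(
            """
states: [x]
params: [lam]
odes: {x: -lam*x}
observed: [x]
init: {x: 2}
"""
        )
        grid = np.array([0.0, 1.0])
        traj = simulate_with_sensitivities(m, {"lam": 0.7}, grid)
        k = elasticity_matrix(traj).column_for("lam")[-1]
        delta = 1e-3
        _, x_base = simulate_trajectory(m, {"lam": 0.7}, grid)
        _, x_up = simulate_trajectory(m, {"lam": 0.7 * (1 + delta)}, grid)
        rel_response = (x_up[-1, 0] - x_base[-1, 0]) / x_base[-1, 0]
        assert rel_response == pytest.approx(k * delta, rel=1e-3)

    @pytest.mark.parametrize("name", ["death", "death_immigration", "twostate_nonlinear"])
    def test_rank_plus_nullity_over_parameter_columns(self, name):
        """rank(K | parameter columns) + dim(generators restricted to
        parameters) equals the number of parameter columns."""
        entry = catalogue.entry(name)
        model = entry.model()
        rep = run_analysis(model)
        values = sample_point(model, seed=0)
        n_par = len(model.params)
        grid = np.linspace(
            0.0, choose_horizon(model, values, ic_values=entry.simulation_ics), 2 * n_par + 5
        )
        traj = simulate_with_sensitivities(model, values, grid, ic_values=entry.simulation_ics)
        K = elasticity_matrix(traj)
        par_cols = [i for i, k in enumerate(K.column_kinds) if k == "param"]
        mat = np.nan_to_num(K.matrix[:, par_cols])
        svals = np.linalg.svd(mat, compute_uv=False)
        rank = int(np.sum(svals > 1e-8 * svals[0]))
        par_vectors = sp.Matrix(
            [[g.as_dict()[nm] for nm in model.params] for g in rep.generators]
        )
        nullity = 0 if not rep.generators else par_vectors.rank()
        assert rank + nullity == len(par_cols)


class TestDependenceCheck:
    def test_death_generator_columns_collinear(self, death_model, death_traj):
        rep = run_analysis(death_model)
        K = elasticity_matrix(death_traj)
        (residual,) = dependence_check(K, rep.generators)
        assert residual < 1e-6

    def test_no_generators_vacuous(self, immigration_model):
        grid = np.linspace(0.0, 1.0, 10)
        traj = simulate_with_sensitivities(immigration_model, DEATH_VALUES, grid)
        assert dependence_check(elasticity_matrix(traj), []) == []

    def test_twostate_generator_columns_collinear(
        self, twostate_model, twostate_sim_ics, short_grid
    ):
        rep = run_analysis(twostate_model)
        values = sample_point(twostate_model, seed=0)
        traj = simulate_with_sensitivities(
            twostate_model, values, short_grid, ic_values=twostate_sim_ics
        )
        (residual,) = dependence_check(elasticity_matrix(traj), rep.generators)
        assert residual < 1e-6


class TestFiniteInvariance:
    def test_zero_eps_identity(self, death_model, short_grid):
        rep = run_analysis(death_model)
        dev = finite_invariance_check(
            death_model, rep.generators[0], 0.0, short_grid, DEATH_VALUES
        )
        assert dev == 0.0

    def test_death_generator_invariance(self, death_model):
        """e^{0.5} lam1 * e^{-0.5} lam2 = lam1 lam2: trajectories coincide."""
        rep = run_analysis(death_model)
        grid = np.linspace(0.0, 2.0, 30)
        dev = finite_invariance_check(
            death_model, rep.generators[0], 0.5, grid, DEATH_VALUES
        )
        assert dev < 1e-8

    def test_fake_generator_detected(self, immigration_model):
        """Negative control: (1, -1) is not a symmetry of lam1 - lam2*x."""
        unknowns = tuple(
            Unknown(nm, "param") for nm in immigration_model.params
        )
        fake = SymmetryGenerator(
            unknowns, (sp.Integer(1), sp.Integer(-1), sp.Integer(0))
        )
        grid = np.linspace(0.0, 2.0, 30)
        dev = finite_invariance_check(
            immigration_model, fake, 0.5, grid, DEATH_VALUES
        )
        assert dev > 1e-2

    def test_fake_generator_deviation_grows_with_eps(self, immigration_model):
        unknowns = tuple(Unknown(nm, "param") for nm in immigration_model.params)
        fake = SymmetryGenerator(
            unknowns, (sp.Integer(1), sp.Integer(-1), sp.Integer(0))
        )
        grid = np.linspace(0.0, 2.0, 20)
        devs = [
            finite_invariance_check(immigration_model, fake, e, grid, DEATH_VALUES)
            for e in (0.05, 0.1, 0.2, 0.4)
        ]
        assert devs == sorted(devs) and devs[0] > 0

    def test_twostate_generator_invariance_with_latent_ic(
        self, twostate_model, twostate_sim_ics, short_grid
    ):
        rep = run_analysis(twostate_model)
        values = sample_point(twostate_model, seed=0)
        dev = finite_invariance_check(
            twostate_model,
            rep.generators[0],
            0.5,
            short_grid,
            values,
            ic_values=twostate_sim_ics,
        )
        assert dev < 1e-8
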