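# scalesid

Local structural identifiability testing for ODE models by scaling
invariance.

## The problem

Fitting a mechanistic model `dx_i/dt = f_i(x_1,…,x_n; λ_1,…,λ_m)` to data
only constrains the parameters that the observed outputs can actually pin
down. A model is *structurally unidentifiable* when different parameter sets
produce exactly the same observable trajectories — no amount or quality of
data can then recover the true values. This is typical of partially observed
systems in cell biology, pharmacokinetics and epidemiology, where only a few
of the state variables (the rest are *latent*) can be measured. Checking
structural identifiability should precede any fit; `scalesid` makes that
check a one-command operation for modelers.

## The method

`scalesid` looks for one-parameter scaling symmetries. Multiply every
parameter and every latent state by an unknown positive factor,

    λ_j → u_{λ_j} λ_j,     x_k → u_{x_k} x_k   (latent k only),

and demand that the observed trajectories do not change. Writing each
right-hand side as a sum of functionally independent summands
`f_i = Σ_k f_ik(x̃_k, λ̃_k)`, invariance must hold summand by summand:

    f_ik(x̃, λ̃) = (1/u_{x_i}) f_ik(u_x̃ x̃, u_λ̃ λ̃),

with `u_{x_i} = 1` for observed equations. Substituting `u = e^w` and
differentiating at `w = 0` turns these matching conditions into a
**homogeneous linear system in the log-scaling factors w**, assembled here
with exact rational arithmetic. Its nullspace is the space of *symmetry
generators* `a`: each nonzero generator is a one-parameter family
`λ_j → e^{εa_j} λ_j` that leaves every observation invariant for all ε.
Then:

- a parameter is **locally identifiable** (by this test) iff `a_j = 0` in
  every generator — its only admissible factor is `u = 1`;
- a latent state is **observable** iff its generator coordinate is always 0;
- monomials `Π λ_j^{c_j}` with `Σ_j c_j a_j = 0` for every generator are
  **identifiable groups**: combinations the data do determine, analogous to
  the Π-groups of dimensional analysis.

A numeric layer cross-validates every finding: forward sensitivities
`S_ij = ∂x_i/∂λ_j`, the elasticity matrix `K_ij = (λ_j/x_i) S_ij` (whose
columns become linearly dependent exactly where a generator couples them),
and direct integration of scaled vs. unscaled trajectories.

The test is *local*: discrete symmetries and scalings fixed at values other
than 1 are invisible to it, so positive verdicts read "no scaling symmetry
found".

## Worked example

The two-state quadratic model

    ẋ1 = λ1·x1² + λ2·x1·x2
    ẋ2 = λ3·x1² + λ4·x1·x2,    x1(0) = x2(0) = 0,  only x1 observed,

ships in the catalogue:

```sh
$ scalesid check --catalogue twostate_nonlinear
Identifiability equations:
  u_lam1 = 1
  u_lam2*u_x2 = 1
  u_lam3/u_x2 = 1
  u_lam4 = 1
Parameters:
  lam1: identifiable
  lam2: unidentifiable
  lam3: unidentifiable
  lam4: identifiable
Latent states:
  x2: unobservable
Identifiable groups:
  lam2*lam3
```

Reading: rescaling the hidden state `x2 → c·x2` can be absorbed by
`λ2 → λ2/c, λ3 → c·λ3` without changing the observed `x1(t)`, so λ2 and λ3
cannot be estimated individually — but their product λ2·λ3 can, and
observing `x2` would remove the symmetry entirely (`--observe x2` exits 0
with every parameter identifiable). The exit code is 3 whenever
unidentifiable parameters are found, 0 when none are, ≥10 on errors, so the
check can gate a fitting pipeline.

The same analysis from Python:

```python
from scalesid import get_model, run_analysis, what_if_observed
report = run_analysis(get_model("twostate_nonlinear"))
report.parameters          # {'lam1': 'identifiable', 'lam2': 'unidentifiable', ...}
[str(g) for g in report.groups]   # ['lam2*lam3']
what_if_observed(get_model("twostate_nonlinear"), ["x2"]).all_identifiable  # True
```

Your own models are plain YAML documents (`scalesid check --model my.yaml`):

```yaml
states: [x]
params: [lam1, lam2]
odes: {x: -lam1*lam2*x}
observed: [x]
init: {x: x0}        # 0, a number, or an unknown-parameter name
```

Add `--elasticity` to integrate sensitivities and confirm each symbolic
symmetry numerically (elasticity-column dependence residuals and
finite-scaling trajectory deviations, both at integration-noise level for
true symmetries).

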