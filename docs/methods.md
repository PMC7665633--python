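# Methods

This note records the model of the analysis, the numerical choices behind
it, and the boundaries of what the implementation and its tests establish.

## Scope of the test

`scalesid` decides *local structural identifiability under scaling
transformations*. The admissible symmetries are one-parameter families

    λ_j → e^{εa_j} λ_j,    x_k(0) → e^{εa_k} x_k(0)   (latent k),

acting on parameters and latent states only; time is never rescaled and
observed states are never transformed (they are pinned by the data). A
nonzero generator `a` certifies non-identifiability. The converse is not a
theorem: a parameter with `a_j = 0` in every generator may still be
non-identifiable through a non-scaling continuous symmetry or a discrete
one (e.g. swap-type symmetries, or scalings fixed at values other than 1,
which the log-linear form cannot represent). Positive verdicts are
therefore phrased "no scaling symmetry found", and every report carries
that standing caveat.

Additive reparametrizations such as `(a+b)·x` are likewise outside the
reach of a multiplicative test. The decomposition stage detects the
symptom — additively dependent summands — merges them into one combined
summand (whose unsplit invariance condition remains valid) and flags the
merge as "scaling-blind" in the report, so the user knows a translation
symmetry may hide there.

## From invariance to a linear system

Each right-hand side is expanded to additive normal form; top-level terms
are candidate summands. Matching each summand separately to its scaled
version is only sound when the summands of one equation are functionally
independent along trajectories, so independence is certified first (below).
For a certified summand `f` of equation i, the finite matching condition

    f(x̃, λ̃) = (1/u_{x_i}) f(u_x̃ x̃, u_λ̃ λ̃)

is differentiated at `u = e^{εa}, ε = 0`, giving the linear identity

    Σ_s a_s · c_s(x, λ) ≡ 0,    c_s = s · ∂f/∂s,

plus the prefactor term `−f` on the coefficient of the equation's own state
when that state is latent. For a monomial summand all `c_s` are multiples
of `f` and the identity collapses to one exact row — precisely the
pen-and-paper matching rule. For exponential, rational, sigmoid and
trigonometric summands the same construction yields one row per independent
coefficient function, which strictly generalizes the finite matching to
every function class the method covers.

Two row-extraction paths are implemented and must agree (this is a tested
invariant, and it caught one real bug during development):

- **symbolic collection** (default): bring `Σ a_s c_s` over a common
  denominator, expand the numerator and collect coefficients with the model
  symbols, transcendental function applications and non-integer powers as
  algebraically independent polynomial generators. Trigonometric
  expressions are passed through `trigsimp` first so Pythagorean-type
  dependencies cancel before collection. If collection fails (exotic
  expression shapes), the summand silently falls back to sampling;
- **exact rational sampling**: evaluate the `c_s` at random rational points
  (numerators and denominators ≤ 97, rejection-resampled away from poles,
  up to 20 retries per point, `#unknowns + 5` points per summand). Because
  the points are exact rationals, the rows are exact and rank needs no
  tolerance; a non-generic sample could in principle miss a constraint, but
  it can never invent one, and the seed-stability test exercises many draws.

Initial conditions contribute rows directly: a latent state whose IC is an
unknown parameter ties the two scalings (`w_x = w_{x0}`); a latent state
with a known nonzero IC is pinned (`w_x = 0`), since scaling it would
visibly rescale a known number; known-zero ICs constrain nothing (zero is a
fixed point of every scaling); an unknown IC parameter of an *observed*
state is pinned outright. Unknown IC parameters are registered as analysis
parameters and receive verdicts like any other parameter. The convention
for observed states is deliberate: all three IC kinds are accepted there,
because observedness already fixes the state's scaling; the report notes
the declaration.

The stacked matrix is exact-rational; `sympy`'s exact nullspace gives the
generators, normalized to coprime integers with the first nonzero entry
positive (the normalized representative of a line is unique up to that sign
convention — tests compare lines, not signs, where declaration order
varies). The reduced row-echelon form of the same matrix, rendered row by
row as `Π u_s^{c_s} = 1` in lowest integer terms, is the human-readable
identifiability-equation system.

## Functional independence testing

Independence is a statement about functions of time along trajectories, so
the sampled-rank test draws `3·(#functions) + 5` state-space points
uniformly from [1/2, 3/2] while holding parameters at one generic positive
draw (a joint-sampling mode exists behind a flag). The verdict is
"independent" iff the SVD rank of the value matrix equals the number of
functions, with relative tolerance 1e-9 against the largest singular value;
seed, point count and tolerance are stored in a certificate so the verdict
is reproducible. Non-finite evaluations are resampled up to 20 times before
failing, which tolerates rational right-hand sides with poles. Generic
positive points in a unit-scale box avoid sign cancellations and poles at
zero. A rank-deficient sample could in principle be non-generic; the exact
Gram-determinant cross-check used in the tests (fine grid, 40-digit
arithmetic) guards the canonical cases. When candidates are dependent, a
greedy union-find merge over value-vector spans groups them; merging is
preferred over failing because the merged condition is still a valid
constraint.

## Identifiable groups

Groups are computed as the exact kernel of the generator matrix restricted
to the parameter columns that some generator touches, scaled to primitive
integer vectors. The result is a *minimal generating set* of the invariant
lattice — a basis, unique up to unimodular transforms — rather than an
enumeration of all invariant products; parameters untouched by every
generator are trivially invariant singletons and are left out of the list.
With several generators the kernel is taken jointly, so multi-dimensional
symmetry spaces are handled uniformly.

## Numerical cross-validation

The variational system `dS/dt = J_x S + J_λ` is integrated alongside the
states (LSODA, rtol 1e-10, atol 1e-12 by default; Jacobians derived
symbolically). Parameter columns start at zero, IC columns at the identity;
the total derivative with respect to an IC parameter is the sum of its two
routes. Elasticities `K_ij = (λ_j/x_i) S_ij` are masked where
`|x_i| < 1e-12·max|x_i|` (the definition divides by `x_i`), and masked
entries are excluded from residuals. Default test points are log-uniform in
[1/2, 2]; the horizon starts at 1 time unit and doubles (up to 10×) until
every observed state has moved by at least 10%, shrinking instead when the
trajectory blows up — finite-time blow-up is generic for polynomial
right-hand sides, so the integrator carries a terminal guard at magnitude
1e12. SVD ranks use relative tolerance 1e-8, matching double-precision
integration noise.

Three independent confirmations tie the symbolic result to trajectories:
(i) for each generator, the elasticity columns it couples combine to zero
within integration noise (latent states with fixed ICs contribute their IC
elasticity column, which vanishes when the IC is zero); (ii) finite
scalings `ε ∈ {0.1, 0.5}` along a generator leave observed trajectories
unchanged to tolerance, while injected non-generators produce deviations
that grow monotonically in |ε|; (iii) sensitivities agree with central
finite differences (relative step 1e-6) to 1e-4.

## Fixture catalogue and what the tests show

The asserted catalogue entries are the three desk-scale models whose
verdicts the test suite reproduces end to end: the death model (group
λ1·λ2), death with immigration (all identifiable), and the two-state
quadratic model (group λ2·λ3, x2 unobservable, all identifiable once x2 is
observed). Two conventions were needed where the source material is silent:
the immigration model's IC is declared as an unknown parameter x0 — it is
pinned identifiable by observedness, so the verdict is insensitive to the
choice — and the two-state model's printed zero initial conditions give the
identically zero trajectory, so numeric checks seed the observed state at
x1(0) = 1; the structural analysis itself is IC-kind-driven and unaffected.
The Goodwin oscillator (Hill exponent fixed at 10) is included as a larger
reconstructed fixture exercising rational/Hill summands and
multi-dimensional nullspaces, without an asserted verdict because published
variants of its equations differ.

These fixtures are exact symbolic objects, not noisy data: passing tests
show that the symbolic pipeline reproduces known symmetry structure and
that the numeric layer confirms it at generic parameter values. They say
nothing about practical identifiability — finite, noisy data can fail to
determine parameters this test declares structurally fine.

## Known limitations

- Only multiplicative (scaling) symmetries are detected; verdicts are
  local and one-sided as described above.
- Observation functions `y = g(x, λ)` are not supported; observations are
  states directly.
- Autonomous systems only: explicitly time-dependent forcing is rejected at
  parse time, since the invariance conditions assume it.
- The SBML import hook requires `libsbml` and is disabled by default;
  without it, the YAML document format is the interface.
- The sampled independence test is probabilistic in principle (generic with
  probability one); the certificate records everything needed to audit a
  verdict.
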