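# Methods

## The model

`mathanx` implements a six-compartment behavioural-epidemic model of
mathematics anxiety spreading by social contact among higher-institution
students.  The compartments are susceptible S, protected P, exposed E,
anxiety-infected A, permanently anxious Q and recovered R, with total
N = S + P + E + A + Q + R.  Transmission follows standard incidence:

    lambda_n = beta (A + phi Q) / N,

so it is the *prevalence* of anxious students that drives new exposures
(phi >= 0 weights the permanently anxious relative to the currently
infected).  The integer-order dynamics are

    S' = (1-eps) Delta + omega R + (1-kappa) rho P - (lambda_n + mu) S
    P' = eps Delta - (mu + (1-kappa) rho) P
    E' = lambda_n S - (mu + psi) E
    A' = (1-sigma) psi E - (mu + delta + gamma) A
    Q' = delta A - mu Q
    R' = gamma A + sigma psi E - (mu + omega) R

Students are recruited at rate Delta (a fraction eps directly into the
protected class, with protection efficiency kappa), leave at per-capita
rate mu, progress out of the exposed class at rate psi (a fraction sigma
straight to recovery), are treated at rate gamma, become permanently
anxious at rate delta, and lose protection and recovery at rates
(1-kappa) rho and omega.  Adding the six equations gives
N' = Delta - mu N exactly, which pins the long-run total at Delta/mu.

The Caputo fractional-order variant of order theta in (0, 1] replaces
every rate *and* every dimensionless fraction p by p^theta:

    D^theta x_i = f_i(x; p -> p^theta).

Exponentiating proportions such as eps or kappa is dimensionally unusual,
but it is how the fractional system is stated in the published formulation of this model;
we follow it uniformly (including gamma in the R-equation, where
uniformity is also required for the exact fractional sum identity
sum_i D^theta x_i = Delta^theta - mu^theta N).  At theta = 1 the
fractional field is bit-for-bit the integer one.  The package realises
the transform once, in `ModelParameters.powered(theta)`.

Assumptions worth keeping in mind: a single well-mixed student
population; no demographic stochasticity; no age or network structure;
anxiety dynamics faster than or comparable to the enrolment turnover
implied by mu.

## Equilibria and the reproduction number

The anxiety-free equilibrium has the closed form

    S0 = Delta^th ((1-eps^th) mu^th + (1-kappa^th) rho^th)
         / (mu^th (mu^th + (1-kappa^th) rho^th)),
    P0 = eps^th Delta^th / (mu^th + (1-kappa^th) rho^th),

with S0 + P0 = Delta^th / mu^th.  The effective reproduction number is
computed along two independent routes that the `ReffReport` container
forces to agree within 1e-9 relative:

* the closed form
  R_eff = beta^th (1-sigma^th) psi^th S0 (mu^th + phi^th delta^th)
          / (mu^th D1 (S0+P0)),
  D1 = (mu^th + psi^th)(mu^th + delta^th + gamma^th);
* the spectral radius of the next-generation matrix F V^{-1} assembled
  numerically over the infected block (E, A, Q) at the anxiety-free
  point.

For the baseline parameter set (below) these give R_eff = 0.1377 at
theta = 1 and 0.1181 at theta = 0.5.  Published headline values for this
parameter set (5.41 and 2.83, and the thresholds beta = 0.601,
gamma = 0.832, eps = 0.861) are not reproducible from the closed form
with the printed parameters; this package treats the closed form plus
the NGM cross-check as ground truth and exposes `critical_parameter` to
locate genuine thresholds (for the baseline, R_eff(beta) = 1 at
beta = 10.163).

### Endemic equilibria

Setting the six right-hand sides to zero and summing shows every
equilibrium has total N* = Delta^th / mu^th.  Fixing the force of
infection lambda, the last five equations are linear and give
P* = eps^th Delta^th / m3 and E*, A*, Q*, R* proportional to lambda S*;
the S-equation then yields S*(lambda) in closed form.  Substituting into
the incidence definition, the non-trivial branch reduces to a *linear*
equation in lambda:  the full polynomial factors as
lambda (a2* lambda + a1*) with a1* proportional to (1 - R_eff), so a
positive endemic root exists iff R_eff > 1 and is then unique — there is
no backward-bifurcation window in this model.  `endemic_solve` uses this
exact reduction, verifies each candidate by the incidence
self-consistency check (1e-8 relative) and reports the vector-field
residual at the reconstructed state.

The sixteen auxiliary constants m1..m16 and the transcribed quadratic
coefficients (a2, a1, a0) of the historical endemic algebra are computed
and reported as diagnostics.  The transcription's constant term a0 is
proportional to (1 - R_eff) exactly, making it a convenient threshold
indicator, and the classification rule (`unique_endemic` when
R_eff > 1, `possibly_two_endemic` when R_eff < 1 with a1 < 0, else
`no_endemic`) is retained for comparability.  The transcribed roots are
*not* used to locate equilibria: the transcription does not satisfy the
steady-state equations it was derived from (numerically checkable with
this package: at baseline with beta = 15 its positive root is 0.116
while the self-consistent root is 0.238), and its claimed a2 > 0 fails
for some admissible parameter sets (a warning is emitted).  The
reconstruction route is the authoritative one.

### Stability

Local stability uses the Matignon condition: a Caputo equilibrium of
order theta is locally asymptotically stable iff every Jacobian
eigenvalue satisfies |arg(lambda_i)| > theta pi / 2.  Jacobians are
formed by central finite differences of the fractional vector field
(step 1e-6 times the state scale) rather than transcribed analytic
matrices; `StabilityReport.margin` records
min_i |arg(lambda_i)| - theta pi/2.  Eigenvalues with magnitude below
1e-10, or with |arg| within 1e-10 of the critical ray, are marginal: the
criterion is silent there, so the report flags them and returns
not-stable.  Because the infected block at the anxiety-free point is
F - V with F non-negative and V a non-singular M-matrix, the sign of its
dominant eigenvalue matches the sign of R_eff - 1, which is why the
suite can assert the clean stability dichotomy.  Symbolic Routh-Hurwitz
determinants are deliberately not implemented; numeric eigenvalues
subsume them.

## Numerical machinery

**Mittag-Leffler.**  E_{t1,t2}(t) = sum_{k>=0} t^k / Gamma(t1 k + t2),
truncated once three consecutive terms fall below the tolerance
(default 1e-14, scaled by max(1, |t|)); the k = 0 start makes
E_theta(0) = 1, which the positivity theory of linear Caputo systems
requires.  Validated against E_{1,1} = exp, E_{2,1} = cosh(sqrt(t)) and
E_{1/2}(-x) = e^{x^2} erfc(x).

**Caputo integrator.**  The default `caputo_rectangle` scheme is the
explicit product-rectangle rule on the equivalent Volterra equation:

    y_n = y_0 + (h^th / Gamma(th+1))
              sum_{j<n} [(n-j)^th - (n-j-1)^th] f(t_j, y_j).

It is first-order accurate, carries the full power-law memory (O(n^2)
work, vectorized per step), and reduces exactly to forward Euler at
theta = 1.  A `caputo_memoryless` one-step variant
(y_{n+1} = y_n + h^th/Gamma(th+1) f(t_n, y_n)) is provided because
"fractional forward Euler" is used ambiguously in the literature; all
tests and defaults use the rectangle rule.  A classical fixed-step RK4
(`classical_rk`) serves as the theta = 1 reference.  Grids are fixed-step
only.  Negative compartment excursions are *reported* on the trajectory
(`warnings`), never clipped: the exact solution is positive, so an
excursion measures scheme error and clipping would mask it.  On the
scalar relaxation test D^0.5 y = -y the scheme is within 0.02% of the
Mittag-Leffler solution at h = 1e-3.

## Optimal control

Two bounded controls extend the model: c1(t) in [0,1] scales the
incidence by (1 - c1) in the S and E equations (prevention), and c2(t)
in [0,1] gates the treatment term, giving A-outflow
mu^th + delta^th + c2 gamma^th and R-inflow c2 gamma^th A.  Note the
uncontrolled problem (c2 = 0) therefore has *no* treatment pathway; the
original dynamics are recovered at c2 = 1.  The objective

    J = int_0^T ( U1 E + U2 A + B1/2 c1^2 + B2/2 c2^2 ) dt

is evaluated by trapezoidal quadrature.  The Hamiltonian, the adjoint
system D^theta lambda_i = -dH/dx_i with transversality
lambda_i(T) = 0, and the projected stationarity conditions

    c1* = clip((lambda_3 - lambda_1) lambda_n S / B1, 0, 1)
    c2* = clip((lambda_4 - lambda_6) gamma^th A / B2, 0, 1)

are derived *consistently from these dynamics and this objective*, with
the incidence differentiated by the quotient rule (N is part of the
state).  Historical statements of the adjoint and characterization
formulas for this system are mutually inconsistent (terms appear in the
Hamiltonian that the dynamics do not contain, and the stationarity
conditions carry incompatible factors); the implemented derivation is
instead enforced mechanically by a finite-difference gradient test of
the Hamiltonian (agreement to 1e-6 relative).

The solver is the standard forward-backward sweep: forward Caputo solve
of the states under the current controls, backward solve of the
adjoints by time reversal tau = T - t with the same rectangle scheme
(at theta = 1 this is the classical Pontryagin sweep), then a relaxed
projected control update c <- (1-w) c + w c*.  Defaults: w = 0.5,
tol = 1e-4 on max |Delta c|, max_iter = 200; non-convergence returns
`converged=False` rather than raising.  No numeric weights or horizon
are published for this control problem, so the package defaults
U1 = U2 = B1 = B2 = 1 and T = 10 are repository choices — equal unit
weight on the two burden counts, unit effort cost as the natural scale
of the quadratic penalty, and a horizon an order of magnitude longer
than the fastest relaxation times (1/(mu+delta+gamma) ~ 1.2) yet short
enough that the sweep's contraction is robust.  On the baseline scenario
the sweep converges in 16 iterations and reduces J from 64.6 (no
control) to 29.5, beating the best constant policy on an 11 x 11 grid.

## Scenarios and the synthetic-data surface

The baseline parameter set is Delta = 100, mu = 0.5, psi = 0.04,
eps = 0.4, kappa = 0.8, gamma = 0.01, omega = 0.03, rho = 0.2,
delta = 0.3, sigma = 0.04, phi = 1.3, beta = 1.4 (rates per unit time;
eps, kappa, sigma, phi dimensionless).  No initial conditions accompany
this set in the published formulation, so the fixture initial state
(S, P, E, A, Q, R) = (150, 30, 10, 5, 3, 2) is a documented repository
choice: total 200 = Delta/mu (the demographic carrying total, so the
theta = 1 total is constant), most mass susceptible, a small seeded
anxiety burden.  Default grid: h = 0.01, T = 50.

`random_scenario(seed)` draws parameters uniformly from documented
per-parameter ranges bracketing the baseline within an order of
magnitude (fractions kept off the degenerate endpoints) and splits the
carrying total Delta/mu across compartments by a flat Dirichlet draw.
These scenarios emulate the *parametric* diversity of plausible student
populations; they do not emulate measurement noise, reporting delay, or
any observational process — the model here is the study object, there is
no data-fitting step.  Passing property tests therefore demonstrate
internal mathematical correctness (oracle agreement, fixed points,
dichotomies), not agreement with empirical anxiety data.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use: 200 random parameter
sets x 4 orders for the reproduction-number oracle; 100 scenarios for
the fixed-point check; 50 supercritical scenarios for the endemic
structure; 50 scenarios x 2 orders for the stability dichotomy with 4
perturbation simulations; h = 1e-3 on the scalar scheme-accuracy test;
h = 0.01, T = 50 for positivity/boundedness; h = 0.05, T = 300 for
global attraction from 5 starts; and h = 0.01, T = 10 with an 11 x 11
constant-control grid for the control benchmark.  These sizes make the
whole verification run in well under a minute on one CPU while keeping
every tolerance at its stated value.

Tie-breaks and degenerate inputs: N = 0 raises a domain error wherever
incidence is evaluated; eps = 0 empties the protected class; beta = 0 or
psi = 0 gives R_eff = 0; marginal Matignon spectra are reported
not-stable with a flag; an endemic candidate failing the incidence
consistency check is dropped with a warning rather than reported.

## Known limitations

* The memory-effect ordering often quoted for such models ("all burden
  compartments end lower with memory than without") does **not** hold at
  the baseline study conditions, and the corresponding check in the
  suite fails by design rather than being weakened.  With R_eff < 1 both
  orders decay to the anxiety-free state, but the theta = 1 system
  converges exponentially while the theta = 0.5 system converges at a
  Mittag-Leffler power-law rate; by T = 50 the with-memory trajectory is
  therefore *above* the memoryless one in E, A, Q and R (e.g. A: 0.51 vs
  2e-7), the ordering holding only on t below about 1.2.  The package
  reports the measured gap; see the repository's acceptance output.
* The rectangle scheme is first-order; high-accuracy work at small theta
  needs small steps (cost grows as O(n^2) with memory).
* The exponentiated-fraction convention ties parameter units to the
  chosen theta; comparing runs across theta compares different effective
  parameter sets, which is intrinsic to this model formulation.
* The forward-backward sweep finds Pontryagin-stationary controls; no
  sufficiency or uniqueness claim is made (none is available for bounded
  quadratic-cost problems of this type without further structure).
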