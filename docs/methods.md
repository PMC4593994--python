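# Methods

## The model

The state variable throughout is the *synaptic drive* of a neuron (or
population): the convolution of its presynaptic firing rate with the
postsynaptic-potential kernel,

    S_i(t) = ∫_{-∞}^t α_i(t − τ) f_i(v_i(τ)) dτ,

a dimensionless measure of how strongly that neuron currently drives the
rest of the network.  Two kernels are supported.  The exponential kernel
`α(t) = B e^{−t/λ}` makes the drive obey the first-order system

    dS_i/dt = −S_i/λ_i + B_i f_i(Σ_j A_ij S_j + v_th,i(t)),

and the Erlang kernel `α(t) = B t e^{−t/λ}` — which peaks at `t = λ` and so
captures the delayed rise of real postsynaptic potentials — the second-order
system

    d²S_i/dt² = −(2/λ_i) dS_i/dt − S_i/λ_i² + B_i f_i(Σ_j A_ij S_j + v_th,i(t)).

The weights `A_ij` (volts) carry the block sign structure of an E/I network:
nonnegative from excitatory neurons, nonpositive from inhibitory neurons,
with zero self-coupling.  The activation `f` is either half-wave
rectification, the logistic `f_max e^{γx}/(1 + e^{γx})`, or a saturating
linear ramp clipped at `f_max`.  Derivatives of the nonsmooth activations
use the right-hand limit at 0 (and the left-hand limit at `f_max`), a pure
convention: the analyses never differentiate them at the kink.

Anesthetic action enters through the inhibitory decay constants `λ_i^I`:
GABAergic agents prolong the inhibitory postsynaptic potential, and every
analysis below asks what happens to excitatory activity as those constants
grow.

## Mean-field reduction

Averaging the drives within the excitatory and inhibitory populations and
dropping the deviation terms of the weights yields the planar system

    dS̄E/dt = f(a S̄E − b S̄I + vthE) − S̄E/λE,
    dS̄I/dt = f(c S̄E − d S̄I + vthI) − S̄I/λI,

with nonnegative aggregates `a = nE·mean(AEE)`, `b = −nI·mean(AEI)`,
`c = nE·mean(AIE)`, `d = −nI·mean(AII)` and logistic `f`.  The reduction is
exact (not just approximate) when the within-block weights are identical,
and the test suite exploits this: a homogeneous network simulated at network
scale must reproduce the two-state trajectory to 1e−5, for both kernel
orders.

The box `M = [0, f_max λE] × [0, f_max λI]` is positively invariant
(`f ≥ 0` pushes the flow inward at the lower edges, `f ≤ f_max` at the
upper), so trajectories and equilibria live there.

**Equilibria.**  The equilibrium condition is reduced to a scalar residual
in `S̄E`: the `dS̄E/dt = 0` nullcline gives
`S̄I = g(S̄E) = (a S̄E + vthE − f⁻¹(S̄E/λE))/b` with
`f⁻¹(x) = (1/γ) ln(x/(f_max − x))`, and the residual is the `dS̄I/dt`
component evaluated on that curve.  Roots are bracketed by dense sampling
(2000 points by default) of the open interval `(ε₀, f_max λE − ε₀)`,
`ε₀ = 1e−9·f_max λE`, and polished by Brent's method to machine precision;
the logistic is strictly positive, so boundary equilibria cannot occur, but
`f⁻¹` diverges at the edges, hence the guard.  Roots closer together than
the sampling resolution would be missed; the models treated here are far
from that regime.  The Jacobian at a root is evaluated in closed form using
`f′ = γ f (1 − f/f_max)` and classified by its trace and determinant
(`stable`: tr < 0, det > 0; `marginal`: |tr| ≤ 1e−8 with det > 0;
`unstable` otherwise, including saddles).  The inverse of the increasing
`h` nullcline, needed by the uniqueness conditions, is computed by
bisection to 1e−12 rather than symbolically.

**Hopf scanning.**  A one-parameter scan (200 grid points by default)
records trace and determinant of the unique equilibrium; each trace sign
change is polished by Brent's method far below the requested resolution, and
reported as a Hopf candidate when the determinant is positive there — at
such a crossing the eigenvalue pair is purely imaginary.  The supercritical
character is verified behaviorally (limit-cycle detection on the unstable
side), not through first Lyapunov coefficients; with a unique repelling
equilibrium inside an invariant planar box, the Poincaré–Bendixson theorem
already forces a stable cycle.  Limit cycles are detected from the tail of
a trajectory (transient fraction 0.5 discarded): peak-to-peak amplitude
above 10× the zero tolerance, at least three local maxima with 1%-prominence,
inter-peak intervals equispaced within 2%.

For the reference aggregates (a, b, c, d) = (10, 9, 6, 1) with
vthI = −2.5 and unit time constants, the package locates the oscillation
window at vthE ∈ (−1.264, 0.264) and, at vthE = −0.5, at
λI ∈ (0.884, 1.852).  These locations were cross-checked by an independent
oracle — long-horizon integration of the flow with two different solver
stacks (scipy and R/deSolve), bracketing where sustained oscillation
appears — and both routes agree to the third decimal.  They are the values
the package asserts in its unit tests and reports in its acceptance script.

**Biphasic response.**  The second-order mean-field model with aggregates
(10, 12, 4, 1), zero thresholds, λE = 4 s, λI = 6 s reproduces the
paradoxical induction transient: the mean excitatory drive overshoots its
initial value before collapsing toward zero.  The overshoot detector flags
a state whose post-initial peak exceeds the start by 5% (relative, with an
absolute floor for near-zero starts) and whose tail has converged below the
zero tolerance.  The inhibitory-to-inhibitory aggregate of this parameter
set is ambiguous in its source (printed twice); the catalog stores the
reading `b = 12, d = 1` and exposes the other as a named variant.

## Partial synchronization without mean-field assumptions

The structural hypothesis is a subset of inhibitory neurons that receive no
inhibitory input (all-zero row of `AII`).  `partition_inhibitory` finds the
maximal such subset (exact zero test by default; a tolerance flag exists for
matrices read from lossy text), permutes it last, and assembles the coupled
subsystem — all `nE` excitatory neurons plus the `q` inhibitory neurons that
do receive inhibition — with connectivity `Ã`, the feed matrix `B̃` from the
uninhibited subset, and decay `L = blockdiag(LE, L1I)`.  For the
second-order model the same blocks are lifted to companion form
(`Γ`, `Â`, `B̂` acting on stacked `[S; dS/dt]`).

**LMI certificates.**  `V(S) = SᵀPS` is a strict Lyapunov function for the
coupled subsystem whenever symmetric positive-definite `P`, `Q` and diagonal
positive-definite `R` satisfy

    [[Q, −P], [−P, R]] ⪰ 0   and   Ω = PL + LP − Q − ÃᵀRÃ ≻ 0,

provided the threshold premise `ṽ_th ≤ −B̃w` holds, where
`w_i = min(S_i^I(0), τ_i η_i)` bounds each uninhibited drive from below by
its decoupled dynamics (`η_i` is the smallest threshold input it ever
receives; the second-order variant replaces `η_i` by the derivative-aware
`α_i`).  Under premise and certificate the coupled states converge to zero
exponentially — partial synchronization with the uninhibited drives settling
at their own nonzero constants.  Function-valued thresholds are not
supported in the premise computation; callers supply constant bounds.

Feasibility is decided by a small purpose-built semidefinite solver
(`syndrive._sdp`): the certificate search is the concave nonsmooth program
"maximize the joint minimum eigenvalue of the block constraint, Ω, P, and
R", which the solver smooths with an annealed spectral softmin
(−μ log tr exp(−M/μ), μ from 1 to 0.01) and maximizes by L-BFGS with
analytic Gibbs-weight gradients; a quadratic penalty pins the free overall
scale.  Problems here are tiny (operators up to 24×24), so a solve takes
under two seconds.  Feasibility is then declared from hard eigenvalue
checks on the returned matrices, with a target Ω margin of `1e−6·‖L‖`
(achieved-but-smaller margins are reported feasible and flagged marginal);
the `Ω ⪰ 0` consensus case with nullspace spanned by the ones vector is
detected (nullspace threshold 1e−8) and reported informationally.
`verify_certificate` is an independent plain-eigenvalue path used both for
externally supplied matrices and as a cross-check on fresh solves.
Published certificates rounded to two decimals are verified at eigenvalue
tolerance 0.05.  A published 6×6 certificate for the 6-neuron reference
network conforms dimensionally to the full system rather than the 4-state
coupled subsystem; `verify_certificate` therefore accepts either dimension
and checks against the matching operator pair.

**Time-constant conditions.**  For the saturating-linear activation,
explicit vector inequalities certify that *every* excitatory drive converges
to zero.  The mechanism: positive thresholds keep the uninhibited inhibitory
drives above the floor `(L2I)⁻¹ min(f_max, η)` (one more factor of
`(L2I)⁻¹` in the Erlang case), so prolonging their time constants (small
`L2I`) raises the floor until the inhibition delivered through their columns
of `AEI` outweighs the worst-case recurrent excitation
`AEE·max(S0E, f_max(LE)⁻¹e)` plus the excitatory thresholds β.  The
conditions are evaluated elementwise with a strictness slack of 1e−9 for the
`≪ 0` premises, and `ε = 1e−3` for the "small positive constant" in the
floor (any small value works; the inequalities are reported with their
failing indices).  An excitatory neuron receiving no input from the
uninhibited subset can never satisfy its row — the report flags it.  These
conditions are sufficient, not necessary: the 8-neuron short-time-constant
run, whose condition fails, is genuinely bistable, and which attractor the
flow selects depends on the initial state (its initial conditions sit near
the basin boundary).

## Numerical integration

Adaptive Runge–Kutta (scipy `RK45`) at rtol 1e−8 / atol 1e−10 by default.
The right-hand sides are globally Lipschitz even for the nonsmooth
activations, so adaptive stepping without event detection is adequate;
halving the tolerances moves terminal states of the reference problems by
less than 1e−6.  Nonnegativity of drives is a property of the dynamics and
is never enforced by clipping; trajectories may undershoot zero only by
solver tolerance.  For the Erlang-kernel model, nonnegativity holds on the
admissible initial set `{S0 ≥ 0, Ṡ0 + S0/λ ≥ 0}` — both conditions follow
from representing the initial state by a nonnegative firing-rate history —
and the property tests draw initial derivatives accordingly; outside that
set transient negative drives are possible and correct.

The convolution oracle evaluates the defining integral by composite
trapezoid on the caller's grid (second-order accurate; the equivalence
tests use ~1000 points per unit time and require 1e−4 relative agreement
with the ODE path).  History before the grid start is taken as zero rate
unless a history callback supplies the infinite-past integral, in which
case a 40λ pre-grid absorbs it.

Trajectory tail diagnostics use the final 20% of the horizon (at least 50
samples): a state is zero-converging when its tail stays below `zero_tol`
(default 1e−3 drive units), constant-converging when its tail range is
below `zero_tol` but its mean is not.  The exponential decay rate of
pairwise gaps is fitted by least squares on the log of the maximal gap,
restricted to samples above 10× machine epsilon (relative to trajectory
scale), and reported only when the RMS log-residual is below 0.1.  Run
horizons are chosen per problem at ≥ 20× the largest time constant so the
tail window is meaningful.

## Synthetic networks

The generator draws block-signed weights uniformly from a magnitude range
(signs forced by block, diagonals zeroed after the draw), with a density
parameter per block and exactly `q_zero` inhibitory rows of `AII` zeroed;
every other inhibitory row is guaranteed at least one inhibitory input, so
the partition is exact by construction.  Defaults mirror the reference
experiments: unit-scale weights (0.5–1.5), λE ∈ (0.04, 0.06) s,
λI ∈ (0.3, 0.5) s (the "prolonged" regime), small nonnegative thresholds
with larger ones for the uninhibited subset, saturating-linear activation
with `f_max = 10` so the linear branch is active at the drive scales these
networks reach.  A `heterogeneity` parameter interpolates between identical
within-block weights (the regime where the mean-field reduction is exact)
and the full spread.  Generation is bit-reproducible from the seed.

What the generator does not emulate: spatial structure, distance-dependent
connectivity, synaptic delays, stochastic spiking, and plasticity.  Passing
tests on these networks therefore establish the mathematical properties of
the drive equations (nonnegativity, invariance, certificate soundness), not
fidelity to any particular biological circuit.

## Problem sizes and scope of the test suite

Property tests run at desk scale: random networks of 6–9 neurons, horizons
of 2–80 time units, 200 networks for the nonnegativity sweep, 100 runs for
box invariance, 100 parameter sets for the uniqueness conditions, and a
handful of random feasible networks for certificate soundness.  The
reference-network experiments (6, 12, and 8 neurons) run exactly as
specified by their sources.  Formal proofs are out of scope throughout: the
theorems' conclusions are exercised numerically on these instances.

## Known limitations

* The trace-zero scan requires a unique equilibrium across the range and
  raises otherwise; multi-equilibrium continuation is out of scope, as are
  two-parameter continuation and normal-form coefficients.
* The LMI solver certifies feasibility; it does not synthesize extremal
  (e.g. maximum-decay-rate) certificates, and infeasibility is reported as
  "solver could not find a positive margin", which for a convex feasibility
  problem of this size is reliable but not a formal infeasibility proof.
* Time-varying thresholds are integrated faithfully in simulation, but the
  certificate premises require constant (or user-bounded) thresholds.
* The Hill relation is an empirical dose-response summary; nothing in the
  package links its exponent mechanistically to the network parameters.
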