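# Methods

## Model

A cell's payoff is its net proliferation rate in min⁻¹. With HIF-α level
*u* ∈ [0, 1] and binary oxygenation *Y* ∈ {0, 1},

    G_N(u) = r − c·u                      (normoxia, Y = 1)
    G_H(u) = r − c·u − m/(k + b·u)        (hypoxia,  Y = 0)

and the long-run payoff of holding *u* fixed in an environment that is
normoxic a fraction *q* of the time is the time-weighted mixture
G(u; q) = q·G_N + (1−q)·G_H = r − c·u − (1−q)·m/(k + b·u). G is strictly
concave in *u* (for m, b > 0), so the constitutive optimum

    u*(q) = sqrt(m(1−q)/(b·c)) − k/b,  clamped to [0, 1],

is unique; when the clamp binds, the boundary value is optimal by
concavity. The perfect strategy (instantaneous, cost-free switching between
u = 0 and u = 1) has payoff r − (1−q)(c + m/(k+b)), an affine upper envelope
that the constitutive optimum touches exactly at q = 0 and q = 1 under the
calibrated cost.

### Parameters

| symbol | meaning | units | default |
|---|---|---|---|
| r | baseline proliferation rate | min⁻¹ | 0.00048 |
| c | proliferation cost per unit HIF-α | min⁻¹ | 0.0001328 (calibrated) |
| m | hypoxic death rate at zero protection | min⁻¹ | 0.00083 |
| k | intrinsic hypoxia tolerance | – | 1 |
| b | mortality-reduction benefit of HIF-α | – | 4 |
| α0 | HIF-α up-regulation rate | min⁻¹ | 0.01155 |
| α1 | HIF-α down-regulation rate | min⁻¹ | 0.0462 |

The cost calibration c = m·b/(k+b)² is the unique value for which
u\*(q=0) = 1: a permanently hypoxic environment selects full expression.
With the defaults, c = 0.00083·4/25 = 0.0001328. The default relaxation
rates encode the empirical regularity that HIF-α degradation runs about
four times faster than accumulation (α1/α0 = 4). *k* is normalized to 1
because it only enters as m/k (at u = 0) and k/b (in u\*).

Note one internal redundancy the implementation resolves deliberately: the
time-fraction weighting already multiplies the mortality term by (1−q), so
the hypoxic-phase payoff G_H itself carries no additional environment
factor. All closed-form optima and every printed number in this package
follow from the single-factor form above.

## Environments

Oxygen is strictly binary and switches instantaneously. Periodic profiles
alternate T_N minutes of normoxia with T_H of hypoxia, starting normoxic.
Stochastic profiles are discrete-time telegraph processes: at each step of
length dt the state flips with probability p_nh (from normoxia) or p_hn
(from hypoxia), giving geometric dwell times with mean 1/p steps and
stationary normoxic fraction p_hn/(p_nh + p_hn). A cycle time T converts to
a switching probability 1/T per minute.

Defaults chosen where the procedure leaves them open: dt = 1 minute (the
switching probabilities are quoted per minute) and a per-step Bernoulli
draw rather than exponential waiting times — at the probabilities used
(≤ 0.1/min) the two are practically indistinguishable, and the discrete
reading matches "probability of switching" semantics. Stochastic traces
start in normoxia, mirroring the periodic initialization; both choices are
configurable.

## Facultative dynamics and the cycle payoff

Within a constant-oxygen segment the relaxation ODE is linear, so the exact
solution u(t) = target + (u_start − target)·e^(−rate·t) is used everywhere;
no numerical integration enters the dynamics. (The code evaluates it in
`-expm1` form, which is exact at t = 0 and accurate for tiny rate·t.)

Over a periodic schedule the one-cycle map is an affine contraction with
factor e^(−α0·T_H − α1·T_N) < 1, so a unique periodic orbit exists; its
normoxic-phase start value is solved from the 2×2 fixed-point system in
closed form. The cycle-averaged payoff at that orbit is computed exactly:
the linear part of G integrates the exponential directly, and the mortality
term uses the logarithmic antiderivative

    ∫ dt/(C − D·e^(−α0 t)) = [α0·t + ln((C − D·e^(−α0 t))/(C − D))]/(α0·C)

with C = k + b·u_max and D = b·(u_max − u_start); C − D·e^(−α0·t) =
k + b·u(t) > 0 throughout, so no sign or absolute-value convention is
needed. Rather than transcribing a printed closed-form expression whose
sign conventions are easy to get wrong, the package derives the payoff from
these segment antiderivatives and pins it against an independent dense
trapezoidal quadrature of the simulated steady-state cycle (relative
agreement < 1e−6 at dt = 0.01 across 100 random schedule/strategy pairs, in
the test suite). Transients are excluded for fixed schedules — the orbit is
reached geometrically fast — but included in stochastic runs, where no
steady state exists.

The degenerate strategy u_min = u_max is permitted and reduces exactly to
the constitutive expected payoff at q = T_N/T. Trajectories default to a
dt = 1 min sampling grid with segment boundaries always included; the
initial level is half-way between the constitutive optimum at the
environment's q and the strategy's u_max, with the run beginning in
normoxia.

## Optimization

**Fixed schedules.** The closed-form cycle payoff is maximized over
0 ≤ u_min ≤ u_max ≤ 1 with COBYLA (derivative-free, inequality-constrained)
from a deterministic 5×5 lattice of starts (10 feasible pairs); local
optima can appear near the u_max = 1 boundary, and multi-start plus a
250×250 grid cross-check in the tests guards against them. Results are
reproducible bit-for-bit.

**Stochastic environments.** Per replicate, one telegraph trace of 2000
minutes (dt = 1) is generated, and the payoff of every candidate pair from
250 linearly spaced values with u_min < u_max (31 125 pairs) is the plain
average of its instantaneous payoff over all time points; the relaxation
recursion is stepped for all pairs simultaneously (vectorized), so a
replicate costs a fraction of a second. The same trace serves all pairs
(common random numbers), which is what makes per-replicate argmax
comparisons meaningful. Ten replicates give the reported mean and standard
error of (u\*_min, u\*_max). Ties in the grid argmax (within 1e−12) resolve
to the smallest u_min, then smallest u_max. Replicate seeds are spawned
from the root seed and logged for exact replay.

**Sampling variability.** At p = 0.1/min a 2000-minute trace holds ~200
dwell segments and the 10-replicate mean of u\*_min has a standard error
near 0.008; at p = 0.0083/min only ~16 segments fit, the per-replicate
argmax scatters with SD ≈ 0.1, and the mean carries an SE near 0.03. Runs
of 50 000 minutes concentrate the optima near 0.50 (p = 0.1) and ≈ 0.175
(p = 0.0083). Any independent 10-replicate realization should therefore be
read with that uncertainty; the replicate SE is reported alongside every
stochastic result for exactly this reason.

**Selection coefficients.** SC = (G_F − G_C)/G_C compares a facultative
payoff against the *optimal* constitutive payoff at the environment's
nominal q — for symmetric switching rates, q = p_hn/(p_nh + p_hn) = 0.5
rather than the realized trace fraction. A negative comparator payoff
inverts the sign's meaning and triggers a warning; a zero comparator is an
error. Selection surfaces evaluate SC on a (u_min, u_max) grid with
infeasible cells (u_min ≥ u_max) set to NaN.

## Kinetic-rate estimation

The threshold rules assume the full-range response (u_min = 0, u_max = 1):
a rise to fraction f of maximum at time t gives α0 = −ln(1−f)/t, a decay to
fraction f gives α1 = −ln f/t. Defaults f = 0.9 (rise) and f = 0.1 (decay)
reproduce the TOV112D estimates (α0 = ln 10/60 ≈ 0.038 min⁻¹,
α1 = ln 10/1 ≈ 2.3 min⁻¹) and the A2780s estimates (ln 10/240 ≈ 0.0096,
reported at ~0.01 to two significant figures; ln 10/5 ≈ 0.46). Full
precision is kept internally; rounding happens only for display. The
least-squares generalization fits A·(1 − e^(−αt)) or A·e^(−αt) to a
normalized time course and falls back to interpolated threshold crossing if
the fit degenerates; it is a distinct, clearly separated estimator, not the
threshold rule.

## What the synthetic data does and does not capture

All inputs are generated in-package: binary periodic/stochastic oxygen
traces and noiseless or Gaussian-noise exponential time courses. Real tumor
oxygenation is continuous-valued, spatially structured, and autocorrelated
beyond a two-state process; real immunoblot time courses have
multiplicative, non-Gaussian error and loading-control artifacts. Passing
tests therefore certify the mathematics and the estimation machinery under
the model's own assumptions, not the biological fidelity of the two-state
abstraction.

## Numerical choices and degenerate inputs

- Payoff integrals and relaxation steps use `expm1`/`log` forms stable for
  small rate·duration products.
- The constitutive optimum requires c > 0 and b > 0; c = 0 or b = 0 raises
  a degenerate-parameter error rather than returning a boundary value
  silently.
- Strategy grids include both endpoints 0 and 1; the feasibility constraint
  is strict (u_min < u_max) in grid searches, while the continuous
  optimizer permits equality and the degenerate payoff reduction covers it.
- Stochastic trace lengths are rounded to whole steps; segment durations
  must be integer multiples of dt before a trace is expanded to a step
  grid.

## Known limitations

- Oxygen is binary; intermediate oxygenation levels, gradients, and spatial
  structure are out of scope.
- Fitness comparison is pairwise (selection coefficients), not population
  dynamics: no replicator equations, mutation, or frequency dependence.
- The relaxation model has two rates and no delay, hysteresis, or
  saturation kinetics; it is the minimal inducible-response model the
  payoff theory needs.
- Stochastic optima inherit the sampling variability quantified above;
  conclusions about slow-switching environments should rest on the
  replicate SE, not a single mean.
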