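# Methods

## The model

A binary decision circuit is abstracted as `N` Ising spins split into two
equal groups of `N/2`, one per option. A spin is "on" (firing) or "off"
(resting). Couplings are all-to-all: `+1` within a group (mutual
excitation) and `-1` across groups (cross-inhibition), scaled by `1/N`. A
global inhibitory field `eta >= 0` favors "off" in every spin — the
model's stand-in for inhibitory tone (GABA) acting on the whole circuit —
and bias fields `eps1, eps2 >= 0` favor "on" in group I or II,
representing learned evidence. Because the couplings are all-to-all, the
pair of on-counts `(n_on_I, n_on_II)` is a sufficient statistic for the
full configuration, and the package works in that count representation
throughout (the Hamiltonian is exposed only as a diagnostic; the dynamics
are defined by rates).

Spins flip with Glauber (heat-bath) kinetics at temperature `T` (the
noise-to-coupling ratio): the on-rate of a group-I spin is the logistic of
`(2V - eta + eps1)/T` and the off-rate its complement, where
`V = (n_on_I - n_on_II)/N in [-1/2, 1/2]` is the instantaneous firing
imbalance. Group II is the mirror image with `V -> -V`, `eps1 -> eps2`
(the analysis in this package always uses `eps2 = 0`; the symmetric entry
of `eps2` is forced by the Hamiltonian's symmetry). The rate unit is 1,
fixing the time scale. Logistic arguments are clamped at magnitude 700, so
rates saturate to {0, 1} at very low `T` without overflow.

The decision variable (DV) integrates `V` in time, starting at 0 with all
spins off, and a decision fires at the first crossing of `+L` (the
"correct" option when `eps1 > 0`) or `-L`. The reaction time (RT) is the
first-crossing time; the error rate is the fraction of decided trials
absorbed at `-L`.

## Mean-field theory and phase diagram

Because on- and off-rates are complementary, the steady state of the
population rate equations puts each group's on-fraction at half its
on-rate, giving the self-consistency map

    V = [sigma((2V - eta + eps1)/T) - sigma((-2V - eta + eps2)/T)] / 2

with `sigma` the logistic function. This logistic-difference form is the
implementation's primitive; the equivalent sinh/cosh closed forms (the
unbiased `V = sinh(2V/T) / 2(cosh(eta/T) + cosh(2V/T))` and its biased
product-form generalization) are kept as algebraic identities in the test
suite. Fixed points are bracketed by sign changes on a 2001-point uniform
grid over `[-1/2, 1/2]` (the map has at most five roots, well separated
away from criticality), polished with Brent's method to residual 1e-12,
merged within 1e-8, and labeled by the map slope at the root: slope < 1 is
stable under the relaxational population flow, > 1 unstable, and within
1e-6 of 1 "marginal" (a tangency). The slope is analytic (logistic
derivative), not a finite difference: the phase-boundary solves divide
slope residuals by powers of the tangency velocity and finite-difference
noise there is fatal.

Expanding the unbiased map at `V = 0`, the linear coefficient crosses 1 on
the second-order line `eta = T arccosh((1 - T)/T)` (defined for
`0 < T <= 1/2`; it meets `eta = 0` at the zero-field critical temperature
`T = 1/2`). Below the tricritical point a first-order line bounds an
intermittent band where the zero and nonzero stable velocities coexist.
The tricritical point is recomputed numerically by solving
(linear coefficient = 1, cubic coefficient = 0) in `(T, eta)`, with the
Taylor coefficients obtained by least-squares fitting an odd degree-9
polynomial on `|V| <= 0.05`; the result matches the closed form
`(1/3, arccosh(2)/3)` to better than 1e-10.

The first-order line is the nonzero tangency of the map
(`rhs(V*) = V*`, `rhs'(V*) = 1`, `V* != 0`). At the tricritical point the
fixed-temperature version of that system is singular (both residuals are
O(V*) and parallel to O(V*²)), so the branch is continued in the tangency
velocity instead: for each `V*` (stepped by 0.005 from 0) the residual
pair is diagonalized into a stability-like and a cubic-like combination
and solved for `(T, eta)`, seeded by the previous point. Requested
temperatures are then polished at fixed `T`, falling back to the
continuation interpolant within the ill-conditioned neighborhood of the
tricritical point. Phase classification reads the stable-fixed-point
structure directly; a point numerically on a boundary resolves to
whichever side the marginal root lands on — arbitrary but deterministic.

## Stochastic simulation

Trials are simulated exactly with the Gillespie algorithm over four
channels (on/off flips per group) with propensities
`(N0_I r_on_I, N1_I r_off_I, N0_II r_on_II, N1_II r_off_II)`. `V` takes
only `N + 1` values, so all four per-spin rates are precomputed into
lookup tables indexed by the count difference; the event loop (compiled
with numba) contains no transcendental calls and sustains ~1e7 events/s on
one core. Between events `V` is constant and the DV advances linearly, so
threshold crossings are resolved at the exact linear crossing time inside
the waiting interval — never by post-event detection — and a frozen
configuration (all propensities zero, possible only at extremely low `T`)
is handled by extrapolating the held velocity. Trials that reach
`max_time` (default 1e6 rate units) are returned flagged as timeouts,
never dropped; ensembles with more than 0.1% timeouts trigger a warning.
Child seeds derive from `SeedSequence(master, spawn_key=(trial_index,))`,
so trial `i` of an ensemble depends only on `(master seed, i)`.

## Decision statistics

Error rates and RT means exclude timeouts but count them. RT distributions
are compared on the `rt / mean(rt)` axis with a shared default binning of
60 bins on [0, 5]; distribution MSE is the mean squared density difference
on the model's grid (the reference is linearly rebinned when grids
differ), and paired conditions are compared by summing their MSEs.
Quantile-quantile comparisons use percentiles 1–99. Two RT-ratio
estimators exist and are kept distinct: ratios of ensemble means (the
model-side convention used everywhere here) versus per-unit ratios
averaged afterwards (how the behavioral tables were built from
participants). Error rates carry Wilson intervals; RT ratios carry a
seeded 1000-resample bootstrap.

## Drift-diffusion and run-and-tumble scaffolding

In the disordered phase the DV is driven Brownian motion and everything
depends on the Peclet number `Pe = vL/D`: `Error = 1/(e^Pe + 1)` and
`RT = (L/v) tanh(Pe/2)`, equal for correct and wrong decisions. At matched
`D` and `L` the two-condition RT ratio is a closed function of the two
error rates; an error of exactly 1/2 contributes the driftless limit
`L²/2D` (the standard unbiased first-passage mean, reached continuously as
`Pe -> 0`). Deep in the ordered phase the ballistic approximation gives
`RT = L/|V_mf|` per side and a correct/wrong ratio `|V_mf(-)|/V_mf(+)`.
A minimal telegraph (run-and-tumble) simulator with exact exponential runs
covers the regime near the transition; tumbles are instantaneous
(finite-duration stops, which can push the correct/wrong ratio above 1,
are a known extension left unimplemented).

Drift and diffusion of the DV are estimated from threshold-free
trajectories sampled at a uniform lag: drift is the mean increment rate,
`D` half the increment variance rate. The lag must exceed the velocity
autocorrelation time, which is of order `1/(1 - slope)` rate units and
grows toward the transition; measured convergence at the disordered
reference points sets the default lag to 25 (a lag of ~1 underestimates
`D` several-fold). Doubling the lag and checking stability is the
recommended diagnostic.

### Initial-condition transient in the ballistic regime

Starting from all spins off, both groups charge up for roughly one rate
unit before the symmetry breaks, so the measured deep-ordered RT is
`delay + L/V*` with an L-independent delay of ~1.1 rate units at
`T = 0.05, N = 100`. The ballistic formula is therefore accurate to 5%
only once `L/V*` dominates the delay (about `L >= 11` at these
parameters); the tests assert the 5% agreement at `L = 20` and the
additive-delay structure itself at shorter thresholds.

## Behavioral comparison

The behavioral anchors are two-armed-bandit experiments summarized as
mean ± SE tables shipped verbatim as CSV fixtures: intermixed gain/loss
games (errors 0.09/0.24, gain/loss RT ratio 0.70 ± 0.04, correct/wrong RT
ratios 0.82/0.93) and separate games with MRS-measured GABA (a
fast-accurate "green" group, error 0.09, biased-over-unbiased RT 0.81 ±
0.02; a slow-accurate "blue" group, error 0.11, ratio 1.28 ± 0.06, with
biased-condition GABA higher by 1.17 ± 0.11). The text's 1.17 ratio is
used as the point estimate even though the table's group means give 1.108;
its SE propagates only into reporting bands, never into the shift itself.

At fixed `(T, eta)` the bias is the only parameter that lowers error and
RT together, so it is the single per-condition free parameter. Bias
calibration exploits the monotone error-vs-bias relation: a bracketing
doubling pass and eight bisection steps at 2000 trials per evaluation,
then up to three secant corrections at the full ensemble budget (default
10,000 trials) on the log-odds scale — in the diffusive regime the
log-odds of the error is approximately proportional to the bias, which
makes the multiplicative update well-behaved everywhere we fit. The final
high-budget ensemble is returned with the fit so achieved errors and RT
statistics are mutually consistent. Targets are accepted within ±0.01
absolute (the scale of the tables' standard errors).

The intermixed-game scan fits `eps_gain` and `eps_loss` per grid point
(temperature and inhibition held fixed within a game), reports the
gain/loss ratio of mean RTs, the per-condition correct/wrong ratios, and
the Z-score `|ratio - 0.70|/0.04`. The separate-game pipeline fits the
green error per point, forms the biased-over-unbiased RT ratio (the
unbiased condition is `eps1 = 0` by design: with no correct option the
unbiased error is 0.5 by construction — an interpretation, recorded as
such), selects the points matching the green normalized-RT band and then
the green correct/wrong band, maps each selected point to
`(T, 1.17 * eta)` under the linear GABA-to-inhibition assumption, refits
the bias to the blue error, and reports the blue/green biased-RT ratio
next to the observed 1.31 ± 0.17. The inhibition-shift analysis locates,
per temperature, the inhibition giving a target error (default 0.3) at
fixed bias 0.01 by bisection, then re-simulates at `eta + 0.05`.

## Problem sizes and defaults

`N = 100` (50 per group) and `L = 5` are the package defaults; both are
plain config knobs and every reported run states its values. Near the
transition the dynamics' `N`-dependence weakens, which is what makes a
moderate default safe. Scans that only need matched-error RT *ratios* use
`L = 2`: in the diffusive regime those ratios are threshold-independent
(the analytic ratio depends on the error rates alone), and the shorter
threshold cuts first-passage times roughly sixfold. The disordered-region
average ratio uses a 12-point grid `T in {0.40..0.55} x eta in
{0.575, 0.65, 0.725}`, 2000 trials per fit iteration and 10,000 per final
ensemble — the budgets the statistics need, chosen once. The
region-localization checks run at `L = 20`: the near-tricritical gain/loss
RT ratio decreases toward the observed value as the threshold grows
(~0.80 at `L = 5`, ~0.74 at `L = 10`, ~0.725 at `L = 20` at `N = 100`),
and `L = 20` is the largest threshold whose near-line first passages stay
affordable. Single-point Z-scores inherit a ±0.3 noise floor from the
accepted calibration mismatch (the ratio's sensitivity to the gain error
is about +2 per unit error), so the localization comparison corrects the
measured ratio to first order using the closed-form matched-error ratio
evaluated at the achieved versus target errors.

## What the simulations do and do not show

All ensembles here are synthetic draws from the model itself; the
behavioral tables enter only as calibration targets and comparison bands.
Passing tests therefore demonstrate internal consistency (simulation vs
mean-field vs closed forms) and that the model, under the stated
calibration protocol, lands inside the published behavioral bands — not
that the brain implements this mechanism. Real reaction-time data carry
non-decision time, across-trial parameter drift, learning within the
session, and lapses, none of which the generator emulates; the model's
time unit is arbitrary, so only dimensionless quantities (error rates, RT
ratios, normalized RT distributions) are ever compared.

## Known limitations

- Asymmetric or structured couplings, random initial spin configurations,
  finite-duration tumbles, and learning dynamics across trials are out of
  scope.
- Mean-field boundaries ignore finite-N rounding of the transition.
- The bias calibration assumes error is monotone in bias at fixed
  `(T, eta)`; this holds throughout the scanned region but is not proven
  globally.
- Very deep inhibition freezes the circuit (no decisions before
  `max_time`); such points are flagged as timeouts or skipped with a log
  entry rather than extrapolated.
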