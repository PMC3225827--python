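# Methods

## Model and scope

`rkleap` simulates well-stirred reaction networks as Markov jump processes:
`N` species, `m` channels, integer update vectors `nu_j` and propensities
`a_j(x) >= 0`.  Three engines are provided: the exact SSA (direct method),
the Poisson tau-leap, and a family of explicit s-stage Runge-Kutta (RK)
tau-leap schemes.  All analysis in this package is *linear* stability and
variance theory — accuracy statements are exact for unimolecular (linear)
kinetics and carried over empirically to nonlinear systems (the Schlogl
benchmark); nonlinear order theory is out of scope.

## The RK tau-leap step

One step of length `tau` from state `X_n` draws a single Poisson set
`K_j ~ Poisson(tau a_j(X_n))` and forms the compensated fluctuation
`d_n = sum_j nu_j K_j - tau f(X_n)` with drift `f(x) = sum_j nu_j a_j(x)`.
Stages and update are

    Y_i     = X_n + tau sum_{j<i} alpha_ij f(Y_j) + omega_i d_n,
    X_{n+1} = X_n + tau sum_j beta_j f(Y_j) + d_n,

with `omega_i = sum_j alpha_ij` (propensities are autonomous; the
abscissae enter only through `omega_i d_n`).  With `s = 1`, `A = 0`,
`beta_1 = 1` this *is* the Poisson tau-leap.  Because the kernels compute
the update in the algebraically equivalent form
`X_n + sum_j nu_j K_j + tau (sum_j beta_j f(Y_j) - f(X_n))` and the stage
offsets as `sum_j alpha_ij (tau f(Y_j) + d_n)`, the single-stage scheme
reproduces the integer Poisson kernel and the subdiagonal "efficient"
kernel reproduces the general kernel *exactly* (same draws imply equal
floating-point states) — both equivalences are asserted bitwise in tests.

Subdiagonal schemes (`beta_s = 1`, `A` nonzero only on the first
subdiagonal) evaluate the drift once per stage beyond the shared
evaluation at `X_n`, i.e. `s - 1` extra evaluations and exactly `m`
Poisson draws per step regardless of `s`.

## Stability and stationary variance

On the reversible isomerisation `S1 <-> S2` (rates `k1`, `k2`, conserved
total `T`) the exact stationary law of `X1` is `Binomial(T, k2/(k1+k2))`,
with variance `T k1 k2/(k1+k2)^2`.  An RK tau-leap ensemble propagates its
mean by the matrix stability function, `E[X_{n+1}] = R(tau W) E[X_n]`
(`W = sum_j nu_j c_j^T` for linear propensities `a_j = c_j^T x`), and its
stationary variance is `psi(z)` times the exact one, where
`z = -tau (k1 + k2)` and

    psi(z) = (2/z) (R(z) - 1)/(R(z) + 1),     psi(0) := 1  (removable).

`psi` has a pole where `R(z) = -1`.  For explicit methods
`R(z) = 1 + sum_{j=1..s} r_j z^j` with `r_j = b^T A^{j-1} e`; consistency
of the mean fixes `r_1 = 1`.  Only implicit methods with
`R = (1+z/2)/(1-z/2)` (implicit midpoint/trapezoid) give `psi == 1`
everywhere; they are supported by the analysis layer but rejected by the
simulators, which are explicit-method engines.

Interval searches (`stability_interval`, `variance_bounded_interval`) use
a dense pre-scan (default 10^4 points on `(-200, 0]`, both configurable)
plus bisection to absolute tolerance 1e-6.  Scan density matters: `psi`
constraints can be violated on thin windows for larger `s`, which is also
why optimizer results are re-certified (below).  "No violation up to the
horizon" is reported as the distinguished value `UNBOUNDED` (`math.inf`),
never as a large float.

## Coefficient optimization

The design problem is: maximize `l` such that `|psi(z) - 1| < eps` on
`(-l, 0]`.  Through `R = (1 + (z/2) psi)/(1 - (z/2) psi)` this is a
two-sided rational sandwich on `R(z)` which implies `|R(z)| < 1`, so the
variance bound subsumes linear stability.  Two stages admit closed forms
(`two_stage_gamma`, `two_stage_interval`); note that the closed-form
interval is the `psi = 1 - eps` endpoint crossing for `gamma > 1/8` and
the `psi = 1 + eps` crossing in the monotone regime `gamma <= 1/8`.

For general `s` the package solves the problem exactly rather than by
local nonlinear programming: at fixed `l` the sandwich constraints are
*linear* in `(r_2, ..., r_s)`, so the inner minimax problem ("minimize the
maximum constraint violation over a Chebyshev grid of 2000 points on
`(-l, 0]`") is a linear program (HiGHS), solved globally and
deterministically with no multistart or seeds; an outer bisection on `l`
(tolerance 1e-5) finds the largest feasible interval.  Numerical choices:

- Violations are measured relative to the local sandwich half-width, which
  vanishes like `eps |z|` as `z -> 0`; an absolute margin would be
  meaningless there.
- The optimum equioscillates: `psi` touches `1 +- eps` tangentially inside
  the interval.  Feasibility therefore demands a strict relative margin of
  1e-4, which keeps interior tangencies strictly inside the band (grid-gap
  interpolation error is ~1e-5) while moving the endpoint by O(1e-4).
- The returned `l` is *re-certified a posteriori*: it is the measured
  variance-bounded interval of the returned polynomial on a 10^4-point
  dense scan, so the reported number does not depend on trusting the LP
  grid.  A mismatch beyond 1% aborts with an error.

For `s = 3` the certified intervals are 3.9456 (eps = 0.1), 5.8958
(0.25), 8.1202 (0.5); for `s = 5` they are 10.719, 15.432 and 20.940 —
the optimizer's certificates are the package's ground truth, and the
`s = 5` certificates demonstrably dominate previously circulated values
for this design problem (the certification scan is part of the shipped
tests).  The two-stage closed form and the `s = 2` LP route agree to
1e-3.  Tableaus are realized in subdiagonal form via nested coefficient
ratios `alpha_{s-j+1,s-j} = r_{j+1}/r_j`, which round-trips exactly
through `stability_polynomial_from_tableau`.

## Failure semantics and numerical conventions

- A tau-leap replicate is **failed** when a Poisson mean is negative or
  non-finite at a step start (negative-population excursion), when a mean
  exceeds the sampler's range (1e15), or when a coordinate exceeds a
  divergence bound (default 1e12).  Failures are counted and reported as a
  rate (flag threshold 1e-3), never raised, by the ensemble drivers.  How
  the original experiments handled negative populations in stable regimes
  is not specified anywhere we know of; this convention is a package
  decision and is applied identically to all methods.
- RK states are real-valued between steps (the `tau f` terms are not
  integer); histograms round to the nearest integer before binning.
  Stage propensities are evaluated by the raw formulas even at slightly
  negative stage values — only the Poisson means at `X_n` are sign-checked.
- Mass-action propensities use molecular combinatorics
  (`x(x-1)/2`, `x(x-1)(x-2)/6`), not concentration powers.
- KL divergence (bits) is computed over the reference support; empty
  method bins are handled by add-half (Jeffreys) smoothing of the *method*
  pmf only, applied identically across methods and flagged in the output.

## Randomness and reproducibility

`simulate_ensemble` derives one `numpy.random.SeedSequence` child per
replicate by spawning the master seed, so ensembles are order-independent
and parallelizable; identical seeds give bitwise-identical ensembles.  The
vectorized fast paths (`ssa_end_states` lockstep SSA, `leap_end_states`
batched leaping) instead drive all replicates from a single seeded stream:
still deterministic given the seed, but draw order couples replicates.
They exist because histogram and variance studies need 1e4-1e5 replicates,
which the per-replicate drivers would spend minutes on.

## Synthetic data and what the tests show

The reference systems *are* the study conditions: the isomerisation with
`k1 = k2 = 10`, `T = 200`, `X(0) = (100, 100)` (so `z = -20 tau`), and the
Schlogl system with the shipped rate table (`k1 = 3e-7`, `k2 = 1e-4`,
`k3 = 3.5`, `k4 = 1e-3`).  The Schlogl buffer counts are not part of that
table; the shipped scenario `A = 1e5`, `B = 2e5`, `x0 = 250` is
reconstructed from the standard Cao/Gillespie/Petzold parameterization and
is verified to be bistable (three nonnegative drift roots, bimodal SSA
histogram).  `random_linear_network` generates conservative unimolecular
fixtures (zero column sums in `W`) for linear-theory property tests.

Stochastic checks run at 1e4-1e5 replicates with 3-standard-error bands
(bootstrap for variance ratios, exact finite-sample formulas for moment
errors): stationary relative variances are checked at `z` in
{-1, -3, -8} per method where stable, Poisson instability at `tau > 0.1`,
and mean propagation `E[X_n] = R(tau W)^n X(0)` for all presets on two
linear fixtures.  These ensembles demonstrate the linear theory and the
qualitative nonlinear (bimodality) behaviour; they do not validate
nonlinear accuracy orders, adaptive step selection, or species-count
regimes beyond the tested ranges.

## Known limitations

- No adaptive `tau` selection, binomial or implicit leaping, delayed
  reactions, or multiple Poisson sets per step.
- Stability analysis is restricted to the negative real axis; no
  complex-plane region shaping.
- The mean-convergence argument for the isomerisation assumes nonnegative
  underlying RK coefficients; the shipped optimal tableaus satisfy this,
  arbitrary user tableaus may not.
- Small-count networks near absorbing boundaries can fail (negative
  excursions) at step sizes well inside the linear stability interval;
  the failure rate is the diagnostic to watch.
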