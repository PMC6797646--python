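# Methods

## The LUT-iCDF sampler

Inverse-CDF sampling maps `u ~ U(0,1)` to `Φ⁻¹(u)`. The sampler here
precomputes `Φ⁻¹` on the symmetric grid `x, 2x, …, 1−x` and replaces the
continuous uniform with a uniform integer index, so one table lookup
replaces each special-function evaluation. Properties used throughout:

* the table has `N = (1−x)/x` entries, is strictly increasing and exactly
  antisymmetric (the construction symmetrizes `ndtri` output to cancel
  last-bit asymmetry, so `values[i] == −values[N−1−i]` holds to 0 ulp);
* the atom distribution's CDF is within `x` of the exact normal CDF, with
  equality of the sup-distance to `x` attained at the extreme atoms — this
  is the exact discretization error, verified by enumeration in the tests;
* moments are slightly shrunk: the atom variance at `x = 10⁻⁴` is ≈ 0.9984
  rather than 1, because the grid truncates the tails at `Φ⁻¹(1−x) ≈ 3.72`.

`granularity = 10⁻⁴` is the default everywhere: coarser tables are
detectable by a KS test at n = 10⁶ (and visibly spike at the atoms at
`x = 0.1`), while finer tables buy no measurable accuracy for simulation.
Inverse-CDF values at build time come from `scipy.special.ndtri`
(double-precision accurate), and uniform integers from numpy's PCG64
`Generator`; seeds are explicit arguments everywhere.

The halved table stores the non-negative branch. A draw takes a single
uniform integer `j` over the *full* range `[0, N)` and reflects it about
the centre index `c`: `value = sign(j−c) · half[|j−c|]`. This avoids a
per-draw sign branch and makes the halved sampler exactly equal in
distribution to the full-table sampler (same atoms, same probabilities),
not merely close.

## Simulators

All simulators return a `TrialSet` (`resp` 1-based, 0 = non-terminated;
`rt` in seconds, NaN when non-terminated) and are deterministic given a
seeded `numpy.random.Generator`.

**LBA.** Start points `k ~ U[0, A]`, drift rates from a normal with means
`v_c` (stimulus-matching accumulator) and `v_e` (mismatching), common SD
`s = 1` (the standard scaling constraint), truncated to positive by
mapping uniform quantiles through the truncated-normal inverse CDF.
Crossing time `(b − k)/d`; `rt = t0 + min` crossing. With truncation the
model always terminates. An `truncate_drift=False` option reproduces the
original untruncated formulation, flagging all-negative-drift trials as
non-terminated. `s = 0` is allowed as a degenerate point-mass drift for
exact-value tests.

**Piecewise LBA.** Standard LBA until decision time `T* = swap_time +
t_delay`; survivors continue from the accrued evidence `k + d·T*` with
stage-2 drifts. The switch clock runs in decision time (non-decision time
is treated as pre-decisional encoding). Stage-2 drifts default to
*matched quantiles*: each trial keeps its stage-1 drift percentile under
the new means. This makes a null change (same means) reduce the model to
the LBA exactly — the property the reduction tests assert. The alternative
reading, an independent stage-2 redraw, is available
(`stage2_drift="independent"`); it does **not** reduce under a null change
(survival to `T*` selects slow drifts, so redrawing unconditionally
shifts the late RT tail — itself regression-tested), which is why it is
not the default.

**Diffusion.** Euler–Maruyama on `x ← x + v h + σ√h ε` between absorbing
bounds (upper `a` → response 1, lower 0 → response 2), start `z`,
within-trial noise `σ = 0.1` by convention. Between-trial variability:
drift `Normal(v, sv)`, start `U[z ± sz/2]`, non-decision
`U[ter ± ster/2]` (widths centred on the mean, the usual convention).
Bound checks happen after each update, crossings are inclusive, overshoot
is not interpolated. This discretization biases absorption probabilities
by the classic boundary-overshoot term (outward shift ≈ `0.5826 σ√h` per
bound); tests compare against the exact Wiener closed form with an
allowance equal to 1.5× the probability change that shift induces, plus
3 Monte-Carlo SEs.

**LCA.** `x_i ← max(0, x_i + (v_i − λ x_i − β Σ_{j≠i} x_j) h + σ√h ε_i)`,
all accumulators starting at 0, shared threshold `b` (or a per-step,
per-alternative matrix). The floor applies after the full update including
noise; threshold ties break to the lowest accumulator index. With
`β = λ = 0` the model is an independent race of floored drifting
processes, which is the brute-force cross-check used in the tests.

**UGM.** Momentary input `r = v + σ ε/√h` is low-pass filtered,
`E ← E + (h/τ)(r − E)` (τ defaulting to 100 ms, within the customary
sub-250 ms range), and the decision variable `y = E·(u₀ + u₁·t_ms)`
(urgency linear in milliseconds, `u₀ = 0`, `u₁ = 1` by default) is
compared against symmetric bounds `±a`. The literature leaves the filter
discretization and urgency intercept open; this first-order Euler filter
with optional intercept is the package's documented choice. The UGM
accepts a time-varying drift profile; piecewise and threshold schedules
are rejected (they are not part of the model family as used).

**Schedules.** `SchedulePack` carries per-step drift and threshold
profiles (row count must equal `max_steps`) and the piecewise switch;
constant profiles reproduce the unscheduled simulators bit-for-bit under
matched seeds because they run through the identical code path. Helper
generators provide linear and Weibull-type collapsing bounds
(`a(t) = a_inf + (a0 − a_inf)·exp(−(t/scale)^shape)`); no single collapse
form is hard-coded since none is canonical.

**Step budget.** `h = 1 ms` and `max_steps = 5000` (5 s of decision time)
by default. Trials alive at the budget return `resp = 0` and are counted
in `n_nonterminated`, which the PDA layer exposes for an optional penalty.
Noise is drawn per step for still-active trials only; pre-drawing versus
in-loop drawing is distributionally identical, and compaction keeps the
pure-numpy stepping loop fast (10⁵ diffusion trials ≈ 0.5 s).

## PDA pseudo-likelihood

Per condition and response alternative: Gaussian KDE of the simulated RTs
by linear binning onto a 512-point grid spanning `[min − 3bw, max + 3bw]`
followed by discrete Gaussian convolution (the same binned-convolution
scheme as R's `density`), linear interpolation at the observed RTs, and
scaling by the *defective* weight `count(resp)/n_sim` with the total
including non-terminated trials — without that scaling choice,
probabilities would never enter the likelihood, so a flag (`defective=False`)
rather than the default disables it. Bandwidth is Silverman's rule of
thumb, `0.9·min(SD, IQR/1.34)·n^(−1/5)`, computed on the simulated sample
per alternative (a fixed user bandwidth is accepted); samples with fewer
than two points or zero spread raise a degenerate-sample error in the
bandwidth rule and fall back to the floor inside the likelihood.
Densities are floored at `10⁻¹⁰` — far below any plausible kernel density
at `n_sim = 10⁴–10⁶` — so the log-likelihood is finite for any data.
Non-termination counts are returned alongside the log-likelihood; no
penalty is applied by default because no canonical penalty form exists.
Default `n_sim = 10⁴` per condition, configurable.

## Validation harness

`ks_two_sample` wraps the asymptotic two-sample KS test (all assessments
here use n ≥ 10⁴, where the asymptotic p-value is accurate).
`validate_granularity` compares LUT draws against exact-normal draws
directly, or runs a model under both noise sources and compares pooled
*signed* RTs (alternative-2 RTs negated) so a single statistic summarizes
choice proportions and both RT distributions; per-alternative statistics
are reported alongside. The model registry covers diffusion, LCA and UGM —
the models where within-trial noise, and hence the LUT, enters the
dynamics.

## What the self-generated test data does and does not show

All test inputs are produced by the simulators themselves (the framework's
own study design: no external datasets exist for it). Passing tests
therefore demonstrate internal consistency — sampler-vs-exact-normal
equivalence, simulator-vs-closed-form and simulator-vs-brute-force
agreement, schedule reductions, likelihood discrimination and parameter
recovery on data the model actually generated. They do not show that any
of these models fits empirical response-time data, nor protect against
model misspecification; contaminant processes (fast guesses, lapses,
censoring) present in real data are not emulated.

## Problem sizes and tolerances in the test suite

Exact facts (table sizes, quantile values, reductions) are asserted
bitwise or to printed precision. Stochastic checks use 3 Monte-Carlo SEs
for proportions and the 1% critical value `1.628·√(2/n)` for two-sample
KS distances. The granularity assessment runs at the assessment's own
scale (10⁶ draws per arm); model-level LUT-vs-exact indistinguishability
runs at 3·10⁴ trials per arm over 5 seeds (the discretization error at
granularity 10⁻⁴, ~10⁻³, is an order of magnitude below the KS critical
value at that n, so the check retains the intended power structure);
likelihood-sensitivity uses 20 repetitions of 2000 observed trials against
5·10⁴-trial PDA evaluations, and grid recovery 5 runs of a 5×5 (v, a)
grid at 10⁴ simulations per cell. The KS statistic of the
finest-granularity comparison is itself a stochastic quantity with median
≈ 1.2·10⁻³ at n = 10⁶ under the null; single-run printed values of 0.001
versus 0.002 at the third decimal are therefore seed-dependent, and the
acceptance checks bound the statistic by `granularity + 1.628·√(2/n)`
rather than pinning one rounding outcome.

## Known limitations

* Euler–Maruyama first-passage times carry an `O(√h)` boundary bias; no
  overshoot interpolation or exact-sampling scheme is provided.
* The LBA covers two response alternatives (the LCA handles K ≥ 2).
* The PDA KDE is plain (no Fourier-domain fast variants, no
  resampled-PDA bias correction), and the pseudo-likelihood is the
  product — optimizers/samplers that consume it are out of scope.
* The analytic LBA first-passage density is not implemented; high-n
  simulation serves as the reference distribution where one is needed.
* Timing behaviour (the point of a LUT in compiled code) is
  hardware-dependent; the `benchmark` subcommand reports it but nothing
  asserts it, and in vectorized numpy the LUT's advantage over an exact
  generator is modest compared to scalar-loop implementations.
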