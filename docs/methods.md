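# Methods

`relcap` sets drug-product release limits and an expiry time by trading off
three sources of information: the capability of the manufacturing process at
time zero, the degradation rate estimated from long-term stability data, and
the uncertainty of the analytical (HPLC) method. This note records the
statistical models, the numerical choices, and the places where the design
was genuinely open.

## 1. Calibration and back-calculation uncertainty

The calibration is an ordinary least-squares straight line
`response = b0 + b1·concentration`. An unknown's concentration is
back-calculated as `x0 = f·(y − b0)/b1`, with `f` the dilution factor of the
sample preparation. Its standard deviation is propagated to first order
(delta method) through the gradient of that transform with respect to
`(y, b0, b1)`, using the full OLS coefficient covariance

- `var(b1) = s_r²/Sxx`,
- `var(b0) = s_r²(1/n + x̄²/Sxx)`,
- `cov(b0,b1) = −x̄·s_r²/Sxx`,

where `s_r` is the residual SD and `(n, x̄, Sxx)` summarise the calibration
design. The `cov(b0,b1)` term is **not** optional: for a design centred at
5 µg/mL it changes the propagated SD by more than 10%. The variance of the
new response defaults to `s_r²` (a single injection); pass `s_r²/m` for the
mean of `m` replicate injections. The first-order approximation is accurate
here because the slope's CV is tiny (≈0.3%); the test suite checks it
against a 10⁶-draw Monte-Carlo experiment to within 3%.

The bundled worked example uses the published insulin calibration summary
(b0 = −5.936, b1 = 9.294, s_r = 0.9029). The exact concentration levels
behind that summary were not published; the design is reconstructed as the
seven integer levels 2..8 µg/mL × 4 replicates (n = 28, x̄ = 5, Sxx = 112),
which reproduces the published uncertainty 0.02023 µg/mL exactly. The
reconstruction is a documented assumption, not data.

## 2. Capability under a batch effect

Time-zero release assays from k batches follow the one-way random-effects
model

    y_ij = μ + a_i + e_ij,   a_i ~ N(0, σ²_batch),   e_ij ~ N(0, σ²_within).

With a homogeneous drug solution, σ_within is essentially the analytical
method's variability; σ_batch measures drift between manufacturing runs.
The capability index uses the total SD:

    Cpk = min((USL − μ)/(3σ_tot), (μ − LSL)/(3σ_tot)),
    σ_tot = √(σ²_batch + σ²_within),

and the capability (statistical-control) limits are `μ ± 3σ_tot`. Cp, the
off-centring factor K (with Cpk = Cp(1−K) inside the limits), the
defective-fraction bounds `[2(1−Φ(3·Cpk)), 1−Φ(3·Cpk)]` (maximally
off-centre vs centred process), and the 1.5σ-shift DPMO convention
`10⁶(1−Φ(σ_level − 1.5))` complete the capability summary.

**Estimation.** The point fit is REML (statsmodels `MixedLM`), with a Powell
polish because the default optimiser stops ~1e-5 short of the optimum; on
balanced data with an interior optimum the polished REML fit agrees with the
closed-form ANOVA moment estimator to <1e-6, which the tests assert. If REML
fails, the unbalanced ANOVA method-of-moments estimator (truncated at zero)
is the fallback. The CI for μ is t-based with k−1 degrees of freedom; CIs
for the two SDs are percentile intervals from the parametric bootstrap
below. All-identical data are flagged degenerate rather than crashed on.

**Bootstrap.** The Cpk interval is a seeded parametric bootstrap: batch
effects and residuals are redrawn from the fitted model on the observed
design. Each replicate is refit with the moment estimator, exploiting the
fact that it depends on the data only through the batch means (Gaussian) and
the pooled within-batch sum of squares (scaled χ², independent of the
means) — so replicates are simulated from those sufficient statistics and
the whole 2000-rep bootstrap is a single vectorised computation. Percentile
intervals are reported. Calibration of the interval is checked by a
200-replication coverage study on a k = 12 × n = 8 design at the default
process parameters; tiny-k designs (k = 3) are known to under-cover for
variance-component functionals and would measure the method's small-sample
limits rather than the implementation.

## 3. Stability, poolability, shelf life

Each batch degrades linearly; the poolability question is whether the
batches share slope and intercept. The full-interaction fixed-effects model

    y_ij = α0 + α_i + (β0 + β_i)·t_ij + e_ij,   Σα_i = Σβ_i = 0,

is fitted with sum-to-zero contrasts and tested by type III ANCOVA at the
deliberately permissive α = 0.25 of stability practice, stepwise: a
significant time-by-batch interaction keeps batches separate; otherwise a
significant batch main effect allows a common slope only; otherwise the data
pool fully. One ANCOVA subtlety is worth recording: with an uncentred time
covariate, type I and type III sums of squares coincide on balanced designs
for the Times and Times×Batch rows (those columns are orthogonal to all
preceding terms), but **not** for the Batch row, whose marginal SS tests
intercept differences at t = 0. The suite asserts the identity exactly where
it holds.

**Critical alpha.** Accepting poolability with an underpowered test is
vacuous, so the package computes the significance level α* at which the
interaction F-test would attain power 1−β (default β = 0.10) against a
stated slope-difference alternative (all slopes equal except the last
batch, which differs by Δ): the noncentral-F noncentrality is
λ = Σ w_i(β_i − β̄_w)²/σ², w_i = Σ_j(t_ij − t̄_i)², σ² the residual mean
square, and α* solves power(α) = 1−β by Brent root-finding. Δ is
user-supplied — a 2%-of-LSL-over-shelf-life convention is common — because
no unambiguous construction exists. An unattainable power is returned as a
flagged, censored result.

**Shelf life.** Two one-sided 95% lower bands of the (pooled) regression are
intersected with the LSL: the confidence band for the mean line (the
regulatory definition, appropriate for homogeneous solutions) and the
prediction band for a single future reportable value (uniformly lower;
appropriate when within-batch variability matters, e.g. low-dose tablets).
The crossing is bracketed on a 513-point grid over (0, horizon] and refined
by Brent's method to 1e-6 months (requirement: 1e-4); the horizon defaults
to 60 months and censors non-crossing fits. A zero-residual fit uses the
closed-form crossing. When batches do not pool, the worst (shortest)
per-batch shelf life is reported and flagged. The pooled shelf life uses the
one-line fit over all observations (df = n−2), matching how pooled stability
results are conventionally tabulated.

## 4. Release limits and expiry time

For a batch released at concentration LRL that degrades at slope b for T
months, the requirement that it still meets the LSL with confidence 1−α
gives

    LRL(T) = LSL + |b|·T + t_{1−α,ν} · √(T²·s_b² + s²),

with `s_b` the slope standard error from the pooled fit and `s = σ_tot` the
SD of a new observation from a new batch at time zero, from the capability
fit. The allowance is **added**: an uncertainty buffer must raise the
release floor above the deterministic requirement LSL + |b|T. A variant that
subtracts the allowance is exposed (`literal_printed_sign=True`) for
comparison only; it would release batches below the point-estimate
requirement and is never used by the pipeline.

LRL(T) is strictly increasing in T, so instead of guessing T the procedure
pins LRL at the lower capability limit LCL = μ − 3σ_tot and inverts for T by
bisection (residual ≤ 1e-8, default bracket 0.01–60 months, polished by
Brent if needed). The result is the longest expiry time the process
capability can support; it is deliberately shorter than the band-crossing
shelf life, which is the price of controlling the defective fraction at
expiry. Degrees of freedom ν default to the pooled one-line fit's n−2 and
are configurable, since no convention fixes them. Infeasibility (LCL below
the T→0 release floor: no room for degradation) and non-crossing within the
bracket raise distinct errors.

## 5. ASTM E2709-12 acceptance region

A new batch is released when a sample of n units demonstrates, with
confidence C, that at least a proportion p of the batch lies inside
[LRL, URL]. The Bergum-type confidence-region construction is used: the
joint level is split √C × √C between a two-sided t-interval for the batch
mean and a one-sided χ² upper bound for the batch SD,

    μ ∈ x̄ ± t_{(1+√C)/2, n−1}·s/√n,    σ ≤ s·√((n−1)/χ²_{1−√C, n−1}),

and the conforming fraction Φ((URL−μ)/σ) − Φ((LRL−μ)/σ) is minimised over
that rectangle. For μ inside the limits the fraction is decreasing in σ and
unimodal in μ, so the minimum has a closed form: σ at its upper bound, μ at
the endpoint farther from the centre of the limits. (When the μ-interval
pokes outside the limits the closed form is no longer the rectangle's
infimum, but the fraction is then below ½ and the batch fails any practical
coverage demand; the oracle test compares against brute-force minimisation
in the decision-relevant regime.) The exact variant of the practice —
confidence split, sidedness of the σ bound — is not fixed by any single
convention, so the implementation is validated by its operating
characteristic rather than by printed coordinates: at the coverage boundary
(true conforming fraction exactly p) the simulated release probability never
exceeds 1−C, checked over a 3×3 grid of sample sizes and mean offsets with
10⁴ replicates each.

The acceptance-limit table (`acceptance_region`) gives, for each sample mean
on an even grid over [LRL, URL] (default 201 points), the largest sample SD
that still releases the batch, found by bisection to 1e-7 concentration
units; the criterion is monotone decreasing in the sample SD. The region is
a symmetric dome vanishing at the limits and widening with n.

## 6. Synthetic data

The generator emulates the structure of a multi-batch study of a drug
solution: k batches with a normal batch effect and within-batch/analytical
noise at time zero, and per-batch degradation lines over the standard
long-term sampling times (0, 3, 6, 9, 12 months). Defaults describe a
well-controlled insulin-solution process: μ = 1.4625 µg/mL against a
1.454 µg/mL label, σ_batch = 0.0016, σ_within = 0.0087, slope
−8.708×10⁻³ µg/mL·month⁻¹, three batches, 24 time-zero assays per batch.
The default between-batch slope SD is 0 because the per-batch slope spread
observed in such data is consistent with residual noise alone; set it
positive to study poolability failures. Streams are split per stage and per
batch (`SeedSequence.spawn`), so adding batches never perturbs earlier
draws.

What the generator does **not** emulate: non-normal or autocorrelated
analytical error, nonlinear degradation kinetics, container or orientation
covariates, and any drift in the analytical method over the two-year study.
Passing tests therefore demonstrate correctness of the statistics under the
stated model, not robustness to those departures.

`end_to_end_risk` wires everything together per replicate (capability →
stability → expiry inversion → ASTM release of fresh batches) and reports
the consumer risk (released batches whose true mean at the solved expiry is
below the LSL) and producer risk (conforming batches rejected). At the
default scenario the consumer risk stays below the α = 0.05 used throughout,
which is the property the whole construction exists to deliver.

## 7. Numerical and degenerate-input choices

- Root-finding: Brent everywhere a bracket exists; the expiry solver uses
  explicit bisection first (the documented contract) and a Brent polish.
- Variance components are truncated at zero at the boundary; degenerate
  (zero-variance) inputs return flagged results instead of raising.
- Shelf lives are censored at the horizon, flagged `censored`; a band
  already below the LSL at t = 0 returns a flagged zero shelf life.
- CSV numerics are parsed with correctly-rounded `float()` so read/write
  round-trips are bit-exact (pandas' fast string-to-numeric path is not).
- JSON reports serialise floats at full precision and are byte-identical
  for identical inputs and seed.

## 8. Problem sizes used by the test and validation suites

Simulation sizes were chosen to make each check statistically decisive at
its stated tolerance: 10⁶ draws for the delta-method oracle, 10⁴ replicates
per cell of the ASTM operating-characteristic grid, 200 replications ×
1000-rep bootstraps for the coverage study, 200 replicates for the
poolability power check, and k = 50 × n = 20 for single-draw parameter
recovery (averaged over 25 generator seeds where a single draw would be
dominated by the ~25% sampling error of a small between-batch SD).

## 9. Known limitations

- The random-slopes mixed model for stability data and expected-mean-square
  interpretations of the ANCOVA are deliberately out of scope: on data of
  this shape the former fails to converge and the latter is biased for
  unbalanced designs with a high chance of negative variance estimates.
- Single storage condition, single quality attribute, single-stage release
  testing; no Bayesian release limits; no multi-stage dosage-uniformity
  plans.
- The delta method is first-order; it would degrade for calibrations with
  slope CV above a few percent.
- Percentile bootstrap intervals for Cpk under-cover when k is very small
  (k = 3 designs); the reported interval is then descriptive rather than
  calibrated.
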