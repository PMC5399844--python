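# Methods

## Model and estimands

Two categorical exposures `X1` (levels `1..L1`) and `X2` (levels `1..L2`)
and a binary outcome `D` observed over a fixed window `(0, T)`; no loss to
follow-up, competing risks, confounding or measurement error is assumed
(stratify externally and analyse strata separately if confounders are
measured). The sufficient-component-cause model assigns each subject
`(L1+1)(L2+1)` causal-pie classes `c1, c2` with `c_k ∈ {*, 1..L_k}`; class
`(c1, c2)` requires `X1 = c1` and/or `X2 = c2` as component causes (a `*`
means the factor is not involved). `U_{c1,c2} = 1` indicates arrival of the
class's unknown complement components during the window.

Estimands are cumulative *completion risks* `Pr(U_ij = 1)` of specific
interaction classes (`i, j ≥ 1`), the *global* completion risk
`Pr(∪_{i,j≥1} U_ij = 1)`, and their *relative prevalences* — specific:
divided by the profile risk `R_ij`; global: divided by the any-class
completion risk, whose observable value equals `1 − ∏(1−R_ij)`. None of
these is point-identified; under the no-redundancy assumption (at most one
class completes in any infinitesimal interval — a weak, rare-disease-free
Poisson-like condition) they admit the sharp bounds implemented in
`risk_bounds` and, for rare diseases sampled case-control, the odds-ratio
approximations in `or_bounds`.

## Contrast enumeration

The global lower bound optimises over pairs of contrast vectors per axis:
for even `L`, `L/2` entries `+1` and `L/2` entries `−1`; for odd `L`,
exactly one `0` and balanced signs elsewhere. All distinct arrangements are
enumerated (`C(L, L/2)` even, `L·C(L−1, (L−1)/2)` odd), the zero positions
of the two axes varying independently. Enumeration is lexicographic and the
full sign-flip-redundant set is kept: for desk-scale `L` the cost is
negligible, the argmin pair reported alongside the bound is deterministic,
and the enumeration stays trivially comparable with a brute-force oracle.

## Numerical conventions

* Signed survival products are accumulated in log space
  (`Σ u_i v_j log(1−R_ij)`), so large grids cannot overflow.
* Risks equal to 1 (zero survival) take the continuous-limit conventions:
  a zero *denominator* factor makes that comparison term uninformative
  (capped at 1); a zero *numerator* with positive denominator drives the
  lower bound to 1. In the global product, a zero-survival cell with
  positive exponent sends the product to 0 (bound 1); with negative
  exponent the term diverges and is capped (uninformative); a pair with
  both kinds is treated as uninformative. Inputs containing risks of
  exactly 1 trigger a `RuntimeWarning`.
* Relative-prevalence bounds are defined as 0 whenever their denominator
  risk is 0 (the numerator bound is then 0 as well).
* The specific-bound minimum separates: the binding comparison combines
  the largest competing survival on the target's row and column, which is
  what the vectorised kernels exploit; the `3−i / 3−j` binary shorthand is
  the same code path at `L = 2`, validated against the closed forms
  (PRISM, RERI) in tests at 1e−12.
* Bounds are computed at full precision; reports round to 4 decimals only
  at render time.
* Exposure levels are 1-based (or label-addressed) in the public API,
  matching the `profile = i, j` convention of the field.

## Odds-ratio scale (case-control)

`OR_ij = (cases_ij/controls_ij) / (cases_11/controls_11)` with the
reference profile `(1,1)` taken from level order (overridable). The bounds
are rare-disease approximations of the risk-scale relative-prevalence
bounds; no de-approximation via sampling fractions is attempted. A zero
count among the four numbers entering an odds ratio is a hard error naming
the cell; an opt-in Haldane–Anscombe correction adds 0.5 to all four counts
of the *affected* cell's 2×2 comparison only, so complete cells keep their
exact odds ratios. At risks of order 1e−4 the two scales agree to ~1%
relative on bounds of order 1; bounds that are themselves O(ε) carry an
O(ε) absolute approximation error, which is what the validation asserts.

## Bootstrap

Percentile bootstrap, 10,000 replicates and `alpha = 0.05` by default, one
seeded generator, fixed replicate order.

* Cohort: profile totals are treated as design constants; case counts are
  resampled `Binomial(n_ij, cases_ij/n_ij)` within profile.
* Case-control: case and control totals are fixed; profile memberships are
  resampled as two independent multinomials, matching the sampling design.

Limits are one-sided by default (5th percentile for an LCL, 95th for a
UCL), the natural reading of a single limit per bound; `two_sided=True`
switches to 2.5th/97.5th. Replicates in which an odds ratio becomes
undefined (a zero control cell or an emptied reference cell) are dropped
and counted rather than silently continuity-corrected; a warning fires when
more than 1% are lost. No BCa, studentisation or delta-method intervals are
offered. Published limits for the bundled examples are reproduced within
±0.02, the slack reflecting Monte-Carlo noise plus the (unknowable)
resampling variant behind the published numbers.

## Simulator

`SCCModel` parameterises each class by a *peril* (cumulative hazard), so
completion probability is `1 − exp(−q)` and, under the default independent
arrivals, perils add: profile risk is `1 − exp(−(q_** + q_i* + q_*j +
q_ij))`, the specific truths are `1 − exp(−q_ij)` and the global truth
`1 − exp(−Σ q_ij)`. Independence is the simplest law satisfying
no-redundancy and gives closed-form truths; an optional equicorrelated
Gaussian copula over arrival indicators (`dependence ∈ [0, 1)`, default 0)
generates dependent-arrival cohorts, for which the closed-form accessors
deliberately refuse to answer. Exposure profiles are multinomial with
user-supplied probabilities; the null label `*` is stored at index 0 and
translated in reports.

What passing simulator-based tests shows: the bounds trap the true
completion risks for *this* family of data-generating processes (500
random models per run) and become exact when background, competing
main-effect and competing interaction perils vanish. What it does not
show: behaviour under confounding, selection, measurement error or
arrival laws outside the copula family — real-data caveats remain.

## Problem sizes and test design

Validation sizes were chosen at desk scale: dominance over the
assumption-free bound on 10⁴ random matrices per shape; brute-force oracle
equality of the contrast minimisation for `L1, L2 ≤ 4`; containment on 500
random models; bootstrap coverage checked over 200 simulated cohorts of
n = 2,000 with 400 replicates each (a conservative ≥ 90% criterion at
nominal 95%, as the percentile bootstrap is approximate). Monte-Carlo
checks of the simulator's closed forms use 10⁶ draws and 3-standard-error
margins.

## Known limitations

Two exposures only; aggregate counts (no individual-level covariate
adjustment); no matched/stratified case-control designs; no
monotonicity-assumption variants (which would identify the model); no
time-to-event outcomes. The confidence limits are percentile-bootstrap
approximations, not exact small-sample intervals.
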