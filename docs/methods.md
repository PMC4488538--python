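# Methods

## Estimand and estimators

For a marker `X` in the non-diseased group and `Y` in the diseased group
(assumed stochastically larger — the package never auto-flips orientation,
it only logs a warning when the estimate falls below 0.05), the Youden
Index is `J = max_c [P(X ≤ c) − P(Y < c)]`.  The indicator conventions are
fixed throughout: ties at the cut count toward specificity (`X ≤ c`
inclusive) and not against sensitivity (`Y < c` strict).

The empirical objective `D(c) = #{Xᵢ ≤ c}/m − #{Yⱼ < c}/n` is a step
function that changes value only at observed data points, so it is
maximised exactly over the sorted unique pooled values plus one sentinel
below the pooled minimum.  At the sentinel both counts are zero, so the
value 0 is always attainable and the empirical estimate is never negative
(negative values of J have no practical interpretation).  Among tied
maximisers the smallest cut is returned, for determinism; to make that
tie-break immune to floating-point noise the argmax is taken over the
integer numerator `#{X ≤ c}·n − #{Y < c}·m` rather than the float ratio.

The Agresti–Coull (AC) adjusted estimator replaces each proportion by
`(count + z²/2)/(size + z²)` with `z = z_{1−α/2}` (≈ "add two successes
and two failures" at α = 0.05) and re-maximises over the same candidate
set, independently of the empirical maximiser.  Its argmax uses the
rescaled score `#{X ≤ c}·(n+z²) − #{Y < c}·(m+z²)`, which differs from the
adjusted objective only by a constant, so the same tie-break logic applies
(exactly so when m = n).

## Interval constructions

**NP / NPAC.**  With the cut fixed, `J = p₁ − p₂` for two independent
binomial proportions.  Each proportion receives a Wilson score interval —
the two roots of `(p − p̂)² = z² p(1−p)/n`, computed in closed form and
clamped so `0 ≤ l ≤ p̂ ≤ u ≤ 1` holds exactly — and the two intervals are
combined by the square-and-add (MOVER) rule `(Ĵ − A, Ĵ + B)` with the
half-widths built from the variance of each proportion evaluated at the
plugged-in limit nearest the relevant bound.  The final interval is
clipped to the theoretical range [−1, 1] of J (clipping is logged).

NP uses the empirical proportions with denominators m and n everywhere.
For NPAC the adjusted proportions are ratios out of `m + z²` (resp.
`n + z²`) effective trials, and the construction that reproduces the
method's published worked example to 3 decimals evaluates the Wilson
roots at those effective sizes while keeping the raw m and n inside the
A/B half-width formulas, exactly as those formulas are written.  The
plausible alternative — raw sizes in the Wilson roots as well — gives
(0.178, 0.643) instead of (0.179, 0.647) on the prostate data and is kept
behind `npac_interval(..., wilson_denominator="raw")` for comparison
only.  One α drives both the estimator's z and the interval z.

**BAC.**  B within-group resamples (m values from x, n from y, with
replacement — never pooled), the AC-adjusted estimate recomputed on each
with full re-maximisation, and a Wald-type interval
`mean ± z·sd` from the replicate mean and (B−1)-denominator variance,
clipped to [−1, 1].  The interval is centred at the bootstrap mean, not
the original-sample estimate.  Degenerate resamples (a group collapsing
to a single value) are kept — the estimator is well-defined on them and
redrawing would bias the bootstrap distribution.  The replicate loop is
vectorised by exploiting that every resample's values are a sub-multiset
of the original sample, so all B step objectives can be evaluated exactly
on the one shared candidate grid.  A seed is mandatory; the CLI defaults
to a fixed documented constant so published runs reproduce.

## Scenario truth and calibration

`true_youden` maximises `g(c) = F_X(c) − F_Y(c)` for continuous pairs:
a 513-point grid over the union of both distributions' 10⁻⁴…(1−10⁻⁴)
quantile ranges locates the global mode (g is bimodal when densities
cross twice, as with unequal variances or shapes — the grid stage avoids
capture by the wrong mode), then bounded scalar minimisation refines the
cut to ~1e−8.  `solve_diseased_parameter` wraps this in a Brent
root-solve for the diseased normal mean (J increasing) or gamma rate
(J increasing as the rate falls), growing a sign-changing bracket
automatically and solving to |ΔJ| < 1e−6.  The gamma family is
rate-parameterised (density `θ^κ/Γ(κ)·x^{κ−1}e^{−θx}`, mean κ/θ); the
Student-t scenario uses the standard unscaled t.  A round-trip guard in
the tests checks every published table parameterisation to 5e−3 — the
published parameters are rounded to 4 decimals, so machine-precision
agreement is not expected.  The two published normal-mean calibrations at
variance 1 and 0.5 sit one unit in the fourth decimal above the exact
solutions (e.g. closed form `2·Φ⁻¹(0.7) = 1.04880` vs the printed
1.0489); tests and the acceptance script report our solved values.

## Monte-Carlo engine

`run_cell` simulates a scenario cell: per replicate a fresh sample, every
requested interval on the *same* sample (paired design), containment of
the true J (closed interval; boundary ties are measure-zero here) and
width recorded.  Per-replicate seeds are spawned from the master seed's
`SeedSequence`, and the bootstrap continues on the replicate's own
generator after the sample is drawn, so enabling or disabling BAC never
perturbs NP/NPAC results.  Method-level numerical failures are counted,
not raised (none are expected; a robustness study should not abort on a
rare degenerate resample).  Defaults mirror the published protocol: 5000
replicates, B = 500, 95% nominal level.  At those sizes one cell takes a
few seconds on one CPU, so the full-scale spot-check cells are run
unscaled in the test suite and acceptance script; the `n_sims` and `B`
parameters exist for exploratory scaling.

## What the generator emulates — and what it does not

The synthetic scenarios draw i.i.d. continuous values from the
parametric families above: normal/normal, gamma/gamma with common or
differing shapes, heavy-tailed t(5) against normal, and normal against
gamma.  They reproduce the features that drive interval behaviour in this
problem — skewness, heavy tails, tied candidate structure only through
rounding-free continuous draws — but not features of real diagnostic
data such as measurement rounding (heavy ties), covariate-dependent
marker distributions, verification bias, or non-representative sampling
of the two groups.  Passing coverage checks therefore validate the
interval constructions under clean i.i.d. sampling, not robustness to
those artefacts; the prostate example, whose values are rounded integers
with many ties, is the only realism check of tie handling at scale.

## Known limitations

* Orientation is the user's responsibility (warning only).
* One-sided intervals, continuity-corrected Wilson variants, weighted or
  cost-ratio Youden generalisations, and kernel-smoothed ROC estimation
  are out of scope.
* The scenario solver handles one free parameter (normal mean or gamma
  rate) with J monotone in it over the bracket, which covers all the
  published scenario families but not arbitrary reparameterisations.
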