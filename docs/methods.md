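# Methods

## Generative model

A trait score for subject *s* at site *l* is

    score_ls = β₀ + L₀ₗ + S₀ₛ + e_ls,

with independent Gaussian components: a site intercept L₀ₗ ~ N(0, σ_L)
shared by every animal at the site, a subject intercept S₀ₛ ~ N(0, σ_S)
and a residual e_ls ~ N(0, σ_e). All parameters are in score units and
σ ≥ 0 is enforced at construction. Subjects are nested in sites; traits
are generated independently of each other (no cross-trait correlation
is modeled), and every simulated record stores its realized components
so the decomposition is exactly reconstructible.

With one observation per subject, σ_S and σ_e are not separately
identifiable from data — only σ_S²+σ_e² (the within-site variance)
enters any sampling distribution. Both are kept as parameters because
the model is naturally stated with both; the method-of-moments
estimator (`estimate_variance_components`) accordingly recovers the two
identifiable quantities, σ_L² and σ_S²+σ_e², and can return a slightly
negative between-site estimate by chance when the true σ_L is near 0
(an honest property of unbiased moment estimators, not clipped).

## Default scenario parameters

The shipped scenarios encode a two-trait, two-species design:

| trait        | group      | β₀  | σ_L | σ_S | σ_e |
|--------------|------------|-----|-----|-----|-----|
| neophobia    | chimpanzee | 800 | 100 | 100 | 50  |
| neophobia    | bonobo     | 950 | 100 | 100 | 50  |
| self-control | both       | 80  | 10  | 10  | 5   |

The neophobia difference of 150 is 1.5 between-site SDs; self-control
is identical across species, so its detections are pure false
positives. The default experiment compares n=10 animals per group
(typical of primate cognition samples), each group's sample taken from
one fresh site per replicate, for 100,000 replicates with a two-sided
Welch test at α=.05. The intraclass correlation is 4/9 ≈ 0.444 for both
traits (the variance components are proportional across traits).

The shipped fixture seed (2026) is arbitrary; all entry points accept a
seed override, and single-draw quantities (e.g. one replicate's p-value
or percent difference) are reported only in distribution, never as
fixed values, because they are seed-specific draws.

## Monte-Carlo engine

`run_scenario` draws, per (group, trait) block, an (n_reps × n) score
matrix — one fresh site effect per row, fresh subjects per cell — and
scores all replicates at once with the moment-form Welch test
(statistic and Welch–Satterthwaite df from the closed formula,
p-values from `scipy.stats.t`). The vectorized engine is shared with
`draw_group_sample`, whose row distribution it reproduces exactly; the
suite additionally checks the shortcut against the explicit
population → random site → random animals path with a two-sample test
on replicate means. 100,000 replicates of the two-trait scenario run
in about 1.5 s on one CPU.

Randomness: one top-level integer seed; `numpy` `SeedSequence` children
are spawned in a fixed order (group A's traits in declaration order,
then group B's, A before B within a trait) — one independent stream per
(group, trait) block. This is deterministic, reproducible across
platforms, and keeps blocks independent so they could be generated in
parallel. Spawning per replicate instead would preclude the vectorized
matrix draw; block-level spawning preserves every property the
per-replicate scheme would buy.

Summaries per trait: detection rate (strict p < α) with a normal 95%
CI; mean/SD of the relative estimation error 100·(est−Δ)/Δ; the
exceedance proportion |error| > 100% (strict inequality — the boundary
has probability zero under the continuous model); the sign-error rate
among significant replicates; and a p-value histogram with fixed bin
width 0.01. Error metrics are NaN when Δ=0 (no scale to measure
against) and the sign-error rate is NaN when Δ=0 or nothing is
significant. Percent differences use the first (reference) group's mean
as denominator.

`sweep` re-runs a scenario over a grid of one parameter (σ_L applied to
all traits of both groups, n per group, the true β₀ offset of group B,
or α), reusing the base seed at every grid point: a one-point grid
reproduces the base run exactly and common random numbers make
monotonicity visible at moderate replicate counts.

## Closed-form approximation

The difference of two one-site sample means is exactly Gaussian,
D ~ N(Δ, sd²) with sd² = σ_La² + σ_Lb² + (σ_Sa²+σ_ea²)/n +
(σ_Sb²+σ_eb²)/n. The Welch test's detection event is approximated by
|D| > t_crit·se_naive, where se_naive² is the within-site part only and
t_crit uses df = 2n−2 (exact for equal specs and equal n when sample
variances happen to be equal). Two approximations are made and
documented: the estimated standard error is treated as fixed at its
expectation, and the normal CDF replaces any noncentral-t refinement.
Consequences: at σ_L=0 and Δ=0 the formula returns 2Φ(−t_crit) ≈ .036
rather than .050 at n=10, and across a 3×3 grid of σ_L ∈ {0,50,100} ×
n ∈ {5,10,20} (plus a null grid in σ_L) the formula tracks
20,000-replicate simulations within 2 percentage points, which is the
agreement level the package claims and tests. The exceedance formula is
exact under the model: P(|D−Δ| > (k/100)|Δ|) = 2Φ(−(k/100)|Δ|/sd).

## What the generator does and does not emulate

It emulates balanced, Gaussian, site-clustered behavioral data with
independent traits and equal site sizes. It does not model non-Gaussian
or skewed scores, unbalanced or informative site sizes, cross-trait
correlation within animals, temporal drift, or measurement floors and
ceilings (a bounded 0–100% task score is only locally Gaussian).
Passing tests therefore demonstrate the statistical consequences of
site clustering under the stated model — not that any particular real
dataset has these variance components. The qualitative conclusion
(one-site-per-group designs confound site with group) is robust to the
Gaussian idealization; the specific rates are not.

## Numerical and design choices

- Welch degenerate cases: both samples zero-variance with equal means →
  p=1; with unequal means → the p=0 limit, flagged `degenerate`
  (df falls back to n_a+n_b−2 so the df>0 invariant holds).
- Detection uses strict p < α; exceedance uses strict |err| > k.
- Histogram bins are right-closed at 1.0 so counts always sum to
  n_reps.
- Test problem sizes: unit tests use 2,000–20,000 replicates (binomial
  SEs of a few tenths of a point, checked at 3–4 SE tolerances); the
  end-to-end suite and the acceptance script run the full 100,000
  replicates, where the three headline rates are stable to ~±0.3
  points across seeds.
- The two-route equivalence check uses 3,000 means per route: the
  explicit pandas path is per-replicate and slower, and 3,000 already
  gives high power against any location shift large enough to matter.
- `sigma_L` sweeps set an absolute value on every trait; for
  multi-trait configs with different scales a single-trait scenario is
  the intended sweep input.
- Run manifests carry a SHA-256 digest of the canonical config plus
  package version; `report` refuses to mix a summary and manifest with
  different digests.

## Known limitations

The calculator's fixed-SE approximation degrades below n≈5 and for
strongly unequal variances; mixed-model (multi-site-per-group)
estimators, non-Gaussian effects and trait correlations are out of
scope. The Monte-Carlo module, not the closed form, is the authority
wherever they disagree.
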