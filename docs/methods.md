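# Methods

This note records the models implemented in `mmtraj`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic-data
generator does and does not emulate.

## Cohort model and conventions

A cohort is a set of person-year records plus per-person timelines. A
record describes status accumulated by December 31 of its calendar year;
age is the age attained in that year. Records for a person must cover
contiguous calendar years — the package refuses gaps rather than imputing
them, because there is no principled way to reconstruct annual status for
a year with no data. Eligibility removes persons aged 100+ at study start
and anything outside the study window; entry is dynamic (first in-window
year at age ≥ 65). Deprivation missingness is an explicit category
excluded from percentage denominators.

## Frailty and multimorbidity status

The frailty index is the proportion of accumulated deficits out of a fixed
36-deficit catalog, categorized fit [0, 0.12), mild [0.12, 0.24), moderate
[0.24, 0.36), severe [0.36, 1]. Intervals are closed on the left so that
boundary indices map deterministically (an index of exactly 0.36 is
severe). Multimorbidity is ≥ 2 of 60 chronic-condition groups, with bands
0–1 / 2–5 / 6–10 / > 10.

The prevalence filter computes, per condition, the unweighted mean over
calendar years of that year's prevalence and drops conditions below 2%.
The unweighted mean (rather than pooled person-year prevalence) is used
because the criterion is a *mean annual* prevalence; the two differ when
cohort size changes over time. A never-observed condition is dropped at
any threshold. The audit table (condition x year prevalence, mean,
retained flag) is always emitted.

Two feature sets share the retained condition indicators and differ in a
single quantitative column: age, or the deficit count. No rescaling is
applied beyond the factorization's own standardization.

## PCAmix

Quantitative columns are centered and scaled by the population standard
deviation (correlation-matrix PCA convention). Each binary condition is
treated as a two-level categorical: its indicator columns are centered by
the level proportions and weighted by `1/√p_level` (the MCA metric). The
combined matrix with uniform row weights `1/n` is factorized by a dense
SVD. Total inertia is `p_quant + (levels − p_cat)`; the eigenvalue sum
equals it to machine precision, and the pure-quantitative and pure-binary
cases reduce exactly to correlation PCA and to indicator-matrix
correspondence analysis (eigenvalues scaled by the number of variables).

Dimension retention uses the Karlis–Saporta–Spinaki threshold
`λ̄ (1 + 2√((p−1)/(n−1)))`. The published rule assumes correlation-matrix
PCA, where λ̄ = 1; scaling by the mean eigenvalue preserves the rule's
"significantly above average" reading for mixed tables and reduces to the
published constant in the PCA case. At least two dimensions are always
retained so clustering has a usable space. The model stores every
preprocessing parameter and can project held-out rows; projecting the
training rows reproduces the stored scores to 1e-10.

## Fuzzy c-means

Standard alternating optimization of
`J = Σᵢ Σ_c u_ic^m d²(xᵢ, v_c)` with Euclidean distances in the retained
factor space. Defaults: tolerance 1e-4 on the maximum membership change,
300 iterations, centroids initialized at k distinct random rows. The
membership update is computed on distance *ratios* so small distances
cannot overflow; a point coinciding with one or more centroids splits its
membership equally among them. The objective trace is kept and is
non-increasing in every fit.

Grid validation samples a subset of *persons* (all their person-years
included), fits each (k, m) cell with `n_reps` independently seeded
starts, and aggregates three standard fuzzy validity indices: partition
coefficient (maximize), partition entropy (minimize), Xie–Beni (minimize).
The selected cell has the best mean rank across the three, ties toward
smaller k then smaller m; a user-fixed k can override the analytic choice,
since cluster counts in this literature are also fixed on clinical
grounds. The final model is the minimum-objective converged fit among the
repetitions. Desk-scale defaults run 10 repetitions per cell (the full
protocol is 100, and is a config change away); the manifest records the
value used.

## Pattern profiles

OE ratios use person-year units (prevalence is a record-level notion);
exclusivity uses individuals, counting a person in every pattern they
ever occupied while the condition was active. Consequently per-condition
exclusivities sum to exactly 100% when no person with the condition spans
two patterns and to more than 100% otherwise; the profile table carries
the person-year counts needed to verify the two conservation laws
(condition counts partition exactly across patterns; the person-year-
weighted mean OE is 1). Association labeling is OE ≥ 2 OR exclusivity
≥ 25%, thresholds configurable, output sorted by OE descending.

## Trajectories

A trajectory is the ordered pattern sequence over follow-up. The terminal
state is death when follow-up ended in death; persons lost to follow-up
contribute their last observed pattern (no separate censoring column, so
the transition matrix has exactly K + 1 columns). Both the number of
*distinct* patterns and the number of year-over-year *switches* are
reported, because "changed patterns X times" is ambiguous between the
two. Transition matrices are row-conditional proportions by first
pattern; zero-count rows are omitted and listed.

## Survival models

Counting-process tables carry one row per person-year interval
[t, t + 1) in years since entry; the event sits on the final interval.
Non-fatal outcomes are censored at death (cause-specific hazards under
the multistate convention), at loss to follow-up, and at study end. Fits
use Cox partial likelihood (Efron ties) with the pattern as the sole
categorical time-varying covariate. Reported per fit:

* hazard ratios with 95% CIs against a reference pattern (default: the
  largest pattern, playing the "nonspecific" role);
* AIC from the partial likelihood;
* pseudo-R² = `1 − exp(−LR/n)` with n the number of persons — the
  likelihood-ratio (Cox–Snell-type) index; other R² variants exist for
  Cox models and no particular one is canonical, so equality with any
  externally reported value is not asserted;
* concordance over comparable pairs in the counting-process
  representation: at each event time, event rows are compared with
  at-risk non-event rows on the linear predictor, ties counting one half;
* a proportional-hazards check: Pearson correlation of per-event
  Schoenfeld residuals (Breslow risk-set weighting) with event time, a
  trend test in the spirit of the usual scaled-residual diagnostics.

With time-constant assignments the fit coincides with a standard Cox fit
(verified against an independent Efron-likelihood maximizer to 1e-6).
The annual timescale matches the annual pattern assignment; event dates
finer than a year are not modelled.

## Synthetic-data generator

The generator emulates a dynamic cohort: entry spread over the window
(60% present at baseline; later entrants are people turning 65 or
arriving already older), entry ages 65 + ⌊Exp(8)⌋ capped at 99, annual
loss to follow-up 2%. Each person belongs to one of 5 planted patterns;
each pattern has a disjoint block of 12 signature conditions. Condition
onset is irreversible with annual probability
`expit(logit(p₀) + 0.05 · (age − 65))`, where p₀ is 0.2 for signature and
0.004 for background conditions; pre-entry accrual is simulated in closed
form so older entrants arrive with developed disease. The deficit count
is `Binomial(36, expit(−2.94 + 0.08 · n_cond + 0.03 · (age − 65)))` —
which deficits are set is uniform given the count, since the analysis
uses only the count and the index. Outcomes follow discrete annual
hazards `h = h₀ exp(β_pattern + γ · deficits)` with baselines 0.02
(death), 0.008 (nursing home), 0.012 (home care), per-pattern log-HRs
linspace(0, 1.2) and γ = 0 by default; same-year ties resolve death >
nursing home > home care because death censors the non-fatal states.

Two deliberate departures from strict realism, and what they imply:

* **Signature onset (0.2/year) is high.** It makes each planted pattern
  saturate early into a compact cluster. With slow accrual every pattern
  becomes a long ray from the healthy origin, and row-level clustering
  cannot match person-level planted labels — the population is then
  genuinely dominated by a "nonspecific" low-burden group, as real
  cohorts are. The default therefore demonstrates *recoverability* of a
  planted partition, not prevalence realism; realistic slow-onset
  scenarios are a config change (and make the nonspecific group
  reappear).
* **Patterns are static per person.** Real trajectories shift between
  patterns as diseases accrue; here the planted label is constant, so
  trajectory statistics on the default scenario are near-stable by
  construction. Transition machinery is exercised through death and
  through imperfect cluster assignment, not through planted switching.

Passing tests on this generator show the pipeline recovers known
structure under its own assumptions (annual status, chronic conditions,
proportional hazards on an annual scale); they do not certify behavior
on real EHR data, with its coding noise, reversible statuses, and
informative observation processes.

## Problem sizes and numerical choices

Test and acceptance runs use 1,200–5,000 persons, grids up to k ∈ 2..8
with m = 1.2, and 2–5 repetitions per cell — sizes at which every
qualitative property asserted (planted-k selection, ARI, CI coverage) is
stable across seeds. Convergence and tolerance constants: FCM tol 1e-4 /
300 iterations; Cox Newton precision 1e-9; eigenvalues below 1e-12 of the
leading one treated as null space. All randomness flows from explicit
seeds through `numpy.random.SeedSequence` with fixed per-stage spawn
keys, so stages and grid cells are independently reproducible and two
runs with the same seed produce byte-identical numeric outputs.

## Known limitations

* No Fine–Gray subdistribution hazards; competing risks are handled
  cause-specifically only (by design — the models are unadjusted and
  cause-specific).
* Exclusivity under pattern-switching persons exceeds 100% per condition;
  an alternative person-year-level definition would restore exactness but
  change the meaning.
* The Schoenfeld check is a trend test, not the full score test of the
  usual `cox.zph`; it flags monotone proportional-hazards violations
  only.
* Raw ICD-10/ATC code mapping to condition groups and deficits is out of
  scope; inputs are precomputed binary flags.
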