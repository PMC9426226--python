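# Methods

## The estimation problem

Two raters independently assign n items to one of C admissible
categories.  An agreement index tries to report the *true* agreement —
the share of items on which the raters agree for the right reason —
from the observable contingency table alone.  Percent agreement a_o
makes no correction; the six chance-adjusted indices subtract a modeled
chance agreement a_c through the shared correction
r = (a_o − a_c)/(1 − a_c):

| index | a_c model |
|---|---|
| Bennett S | 1/C (uniform over the declared categories) |
| Perreault–Leigh I_r | 1/C, then r = √S (S ≥ 0; 0 otherwise) |
| Gwet AC1 | (1/(C−1)) Σ p̄_k(1 − p̄_k), pooled marginals p̄_k |
| Scott π | Σ p̄_k² |
| Cohen κ | Σ p_k1 p_k2, per-rater marginals |
| Krippendorff α | Σ n_k(n_k−1)/(n(n−1)), pooled counts, n = 2·items |

C is always the *declared* category count of the rating task, never the
number of labels observed: categories that go unused still lower 1/C
and the AC1 estimator, and that sensitivity is part of what is being
measured.  α is implemented for the only case the experiment uses (two
raters, nominal metric, no missing values); its (n−1) correction makes
α_ac ≤ π_ac with a gap of order 1/n, so α ≥ π in every session.

Degenerate sessions with a_c = 1 (e.g. both raters use a single
category everywhere) make the correction 0/0; the estimate is flagged
undefined (NaN), logged, and excluded from aggregation with the number
of sessions actually used reported per estimator.  Substituting a
convention (κ = 1 or κ = 0) would bias the accuracy metrics.

## Golden standard

Truth labels make the estimands observable.  Agreement splits into
agree-and-right (o_ar) and agree-and-wrong (o_ae).  Because guessing is
confined to two confusable categories and the guess is symmetric, half
of all chance agreements land on the truth, so

    o_ac = 2·o_ae,    o_ri = a_o − o_ac = o_ar − o_ae.

o_ac is a model-based quantity, not a probability: a session where
every item is agree-wrong has o_ac = 2 and o_ri = −1.  Neither is
clamped.  The doubling rule presumes symmetric two-option guessing; the
optional short-bar noise mode (below) satisfies it only approximately,
which is one reason that mode defaults to off.

Setting the correction's output equal to o_ri and solving for a_c gives
the per-session accuracy threshold

    t_h = o_ac / (1 − o_ri),

the unique chance estimate that reproduces o_ri exactly; a_c above t_h
underestimates reliability, below it overestimates (the correction is
strictly decreasing in a_c while a_o < 1).  Since t_h > o_ac whenever
o_ri·o_ac > 0, an index whose a_c equals the true chance agreement
necessarily *over*-reports reliability by the factor 1/(1 − o_ac): no
index can be exact on both estimands outside the measure-zero case
o_ri·o_ac = 0.  Both facts are verified mechanically at 1e−12 in the
test suite.

## Synthetic rating sessions

The generator emulates a two-rater perception task: items whose true
category is one of two confusable alternatives (category 1 with
probability s_k, else category 2), judged under a difficulty-controlled
risk of involuntary guessing.  Per rating decision, a rater reports the
truth with probability 1 − g(d_f) and otherwise guesses uniformly
between categories 1 and 2.  Closed forms under this model:

    E[a_o]  = (1 − g/2)² + (g/2)²     E[o_ae] = g²/4
    E[o_ac] = g²/2                     E[o_ri] = 1 − g

None depend on C or s_k, so observed chance agreement is orthogonal to
the category and skew factors by construction, and the behavioral
parameter is identifiable from the golden standard as ĝ = 1 − mean(o_ri).

**Calibration.**  No parametric law for g(d_f) is assumed.  The guess
rate is a calibrated lookup at the eight design difficulties
d_f = (8 − p_x)/7 (p_x = 8..1 pixel differences between the confusable
stimuli), inverted from the target per-level mean chance agreements
(.020, .021, .036, .062, .116, .168, .236, .380) via g = √(2·o_ac), i.e.
g ≈ .200 … .872, with linear interpolation between levels.  This
reproduces the difficulty profile of chance agreement (grand mean
≈ .130) without asserting an unsupported functional form.  The implied
mean reliability is 1 − mean(g) ≈ .544; a pure two-option guessing
model cannot push that higher while holding the o_ac profile fixed, so
the calibration targets the chance-agreement column and accepts the
small reliability-side discrepancy.

**Short-bar noise (optional, default off).**  With C > 2, a small rate
ε(C) of decisions (1.11%, 1.93%, 5.53% for C = 4, 6, 8) lands uniformly
on the non-confusable categories 3..C.  It is off by default because
the clean model keeps the closed forms exact and the doubling rule
exact; enabling it perturbs the main relations only marginally.

**Design and seeding.**  Defaults: C ∈ {2,4,6,8} × 8 difficulties ×
s_k ∈ {.5,.75,.99}, 4 replicates × 100 items = 384 sessions.  Skew is
applied to the truth frequencies with the majority on category 1;
orientation is immaterial because every index is permutation-invariant
(a tested property).  One master seed; per-session seeds derive
deterministically from (master, cell index, replicate) via
`numpy.random.SeedSequence`, giving bit-reproducible experiments with
independent streams.

## Accuracy metrics

For each estimator–estimand pair across sessions (undefined estimates
excluded pairwise, n_used reported):

* **dr² = r·|r|** — Pearson correlation squared with the sign retained;
  signed share of estimand variance tracked.  A two-sided pretest
  p-value from the exact t transform of r accompanies each dr², labeled
  with the conventional .05/.01/.001 tiers.  Constant estimators (the
  ao_ac ≡ 0 chance model) have no defined correlation and are reported
  "not assessable".
* **m_e = mean|x − y|** — with sd and a normal-approximation 95% CI
  (mean ± 1.96·sd/√n).
* **e_m = mean(x) − mean(y)** — bias, with a CI from the paired
  differences.  Always |e_m| ≤ m_e.

Benchmarks: dr² > .8 primary, dr² > .67 tentative, m_e < .2 secondary.
All three thresholds are configurable (`Benchmarks`); the secondary
default is 0.2 on the [0,1] reliability scale.  Session means are
unweighted — the design is balanced by construction.  No
multiple-testing correction is applied across the report grid, and no
bootstrap CIs are computed.

## Numerical and design notes

* Estimator arithmetic is exact rational arithmetic in floating point;
  the suite checks equality with independently coded closed forms
  (Bennett's original (C·a_o − 1)/(C − 1); α via the
  coincidence-disagreement route 1 − D_o/D_e) at 1e−12 on an exhaustive
  enumeration of small tables.
* The ranking's meta-correlation (chance-prediction accuracy vs
  reliability-prediction accuracy) is computed over the six
  chance-adjusted indices only; percent agreement's constant chance
  estimate has no chance-side dr².
* Ground zero — C = 2, even skew — is the reference condition where all
  chance models coincide near 0.5 (α at 0.5 − O(1/n)), pooled over
  difficulty: 32 of the 384 sessions.
* Problem sizes: the default experiment (384 sessions × 100 items) runs
  in seconds; the moment-check and recovery tests use 100–200 sessions
  at a fixed behavioral parameter, with 3-standard-error tolerances
  computed from the binomial closed forms or the empirical spread.

## What the simulation does and does not show

The generator reproduces the *statistical structure* of a controlled
rating experiment: truth confined to two confusable categories,
difficulty-driven symmetric guessing, factorial manipulation with
orthogonal factors.  Real raters differ in skill, drift over time,
favor categories asymmetrically, and face items whose difficulty varies
within a session; none of that is modeled, and per-session behavioral
heterogeneity beyond the binomial is absent (observed spread of o_ac
within a difficulty level is narrower than with human raters).  Passing
tests therefore certify the estimators, the golden-standard
bookkeeping, and the direction and rough magnitude of the index
behaviors under the stated guessing model — not the indices' numerical
performance on any particular human rating task.
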