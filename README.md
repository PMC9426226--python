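# agreebench

Benchmark chance-corrected interrater agreement indices against known
truth.

Researchers who need to certify a measurement instrument report an
interrater reliability index — Cohen's κ, Scott's π, Krippendorff's α,
Bennett's S, Perreault–Leigh I_r, Gwet's AC1, or plain percent agreement
a_o.  All chance-adjusted indices share one correction,

    r = (a_o − a_c) / (1 − a_c),

and differ only in their model of the chance agreement a_c: 1/C for the
category-based indices (S, I_r), marginal-distribution functions for the
skew-based ones (π, κ, α), and a mixture for AC1.  Whether any of these
models matches what raters actually do is an empirical question that
real data cannot answer, because the true category of each item — hence
the *true* reliability — is unobservable in the field.

`agreebench` makes it observable.  It simulates rating sessions in which
two raters judge items whose truth is known, guessing involuntarily
between the two confusable categories at a rate that rises with task
difficulty.  With truth in hand, agreement decomposes into
agree-and-right and agree-and-wrong; the observed chance agreement is
o_ac = 2·o_ae (half of two-option guesses land on the truth) and the
observed reliability is o_ri = a_o − o_ac.  Every index is then scored
against these golden standards as

* a **predictor**: directional r², dr² = r·|r|, against o_ri (and each
  chance estimator against o_ac), with benchmarks dr² > .8 (primary) and
  dr² > .67 (tentative);
* an **approximator**: mean absolute error m_e (benchmark m_e < .2) and
  bias e_m = mean(estimate) − mean(target).

The factorial design crosses category count C ∈ {2,4,6,8}, true-category
skew s_k ∈ {.5,.75,.99} and eight difficulty levels d_f ∈ [0,1], four
replicate sessions of 100 items per cell: 384 sessions.

## Worked example

```python
from agreebench import ExperimentConfig, run_experiment

result = run_experiment(ExperimentConfig(), seed=1)
print(result.ranking.round(3))
```

```
index  dr2_reliability  dr2_chance
  a_o            0.873         NaN
  ac1            0.600       0.012
    s            0.595      -0.000
  i_r            0.497      -0.000
kappa            0.375      -0.199
   pi            0.372      -0.196
alpha            0.372      -0.196
```

Percent agreement — the index every chance-adjusted coefficient was
designed to improve on — tracks true reliability best (dr² ≈ .87, the
only index above the primary benchmark), though it overestimates by its
ignored chance share (e_m ≈ .13).  AC1 and S follow; π, κ and α trail
far behind and underestimate reliability by ≈ .32, because their
skew-based chance models respond to the unevenness of the true category
distribution, not to actual guessing (their chance estimates correlate
*negatively* with the observed chance agreement, dr² ≈ −.20).  The NaN
is structural: a_o's chance estimate is the constant 0, so no
correlation with o_ac exists.

`result.records` holds the 384 per-session rows, `result.evaluation`
the full accuracy table (dr², m_e, e_m with CIs and benchmark verdicts),
`result.factor_effects` the dr² of every estimator against each design
factor, and `result.cell_means` the estimator means at ground zero
(C = 2, even skew) and by factor level.

The `examples/` directory has one short script per capability: the
indices on a single table, the golden standard and the accuracy
threshold t_h = o_ac/(1 − o_ri), the simulator's difficulty profile, and
the full benchmark.  A thin CLI mirrors the pipeline:

```bash
agreebench run --seed 1 --outdir out/          # everything
agreebench simulate --seed 1 --out sessions.csv
agreebench score sessions.csv --out records.csv
agreebench evaluate records.csv --outdir out/
agreebench report records.csv --out ranking.csv
```

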