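# mmnet

Multimorbidity pattern analysis for older-adult health-survey cohorts:
pairwise disease **association rules** (support, confidence, lift),
**disease co-occurrence networks** with support-weighted node strength,
**EQ-5D-3L** utility scoring with HRQoL grouping, and **survey-weighted
logistic regression** of poor HRQoL on multimorbidity — plus a synthetic
KNHANES-like cohort generator with known ground truth, so every stage of
the pipeline can be validated end to end.

## Who this is for

Epidemiologists and biostatisticians studying how chronic diseases cluster
in people aged 65+, stratified by health-related quality of life (HRQoL)
and sex. The restricted government survey microdata these analyses are
usually run on cannot be redistributed; `mmnet` therefore ships (a) the
analysis engines, (b) the published stratified summary counts as a worked
example, and (c) a calibrated generator that emulates the survey's
structure: 15 correlated binary disease flags, an EQ-5D index with a point
mass at 1.00 and a left-skewed remainder, survey weights, and a logistic
link between disease burden and poor HRQoL.

## The statistics at the core

For diseases X, Y in a stratum of size n with counts n_X, n_Y, n_XY:

- **support** = n_XY / n = P(X,Y) — co-occurrence prevalence;
- **confidence** = n_XY / n_X = P(Y|X);
- **lift** = n·n_XY / (n_X·n_Y) = P(X,Y)/(P(X)P(Y)) — observed-to-expected
  ratio; lift > 1 means the pair co-occurs more than chance.

The multimorbidity network has the 15 diseases as nodes, supports as
undirected edge weights, and **node strength** s_i = Σ_j w_ij (summed over
all 14 partners) as the measure of how strongly a disease co-occurs with
the rest. The EQ-5D-3L index is scored by an additive N3-model value set
(range −0.17 to 1.00) and grouped as poor (≤ 0.721), normal (0.721–1.00
exclusive), or good (exactly 1.00). Poor HRQoL is modelled by weighted
logistic regression with sandwich (cluster-robust) variance.

## Worked example

```python
from mmnet import (SimulationConfig, generate_cohort, mine_rules, top_rules,
                   StratumSpec, build_network, strength_ranking, fit_poor_hrqol_model)
from mmnet.rules import format_rules

cohort = generate_cohort(SimulationConfig(n_per_stratum=2000, seed=1))
rules = top_rules(mine_rules(cohort, StratumSpec("poor", "female")), k=6)
print(format_rules(rules).to_string(index=False))
```

```
    antecedent     consequent   n  n_x  n_y  n_xy  support_pct  confidence_pct  lift
     arthritis   hypertension 838  431  537   281         33.5            65.2   1.0
  hypertension      arthritis 838  537  431   281         33.5            52.3   1.0
hyperlipidemia   hypertension 838  333  537   228         27.2            68.5   1.1
  hypertension hyperlipidemia 838  537  333   228         27.2            42.5   1.1
     arthritis hyperlipidemia 838  431  333   174         20.8            40.4   1.0
hyperlipidemia      arthritis 838  333  431   174         20.8            52.3   1.0
```

Among the 838 women with poor HRQoL in this synthetic cohort, 33.5% have
both arthritis and hypertension; 65.2% of those with arthritis also have
hypertension; lift 1.0 says the pair co-occurs at about chance level given
both diseases' high prevalence. The network and regression stages:

```python
net = build_network(cohort, StratumSpec("poor", "female"))
strength_ranking(net)[:4]
# ['hypertension', 'arthritis', 'hyperlipidemia', 'diabetes']

res = fit_poor_hrqol_model(cohort, terms=["multimorbidity", "sex", "age_group"])
print(res.table.loc[["multimorbidity[1]", "multimorbidity[2]", "multimorbidity[>=3]"]].round(2))
#                      beta    se    or  ci_low  ci_high
# multimorbidity[1]    0.38  0.11  1.46    1.18     1.80
# multimorbidity[2]    0.65  0.11  1.92    1.55     2.40
# multimorbidity[>=3]  0.97  0.11  2.64    2.13     3.28
```

The fitted odds ratios recover the generator's configured truth
(exp(0.39, 0.63, 0.99) ≈ 1.48, 1.88, 2.69): having three or more chronic
diseases roughly triples the odds of poor HRQoL relative to none.

A command-line interface wraps the same stages:

```bash
mmnet simulate --out out/cohort.csv --seed 1
mmnet rules --input out/cohort.csv --out out/rules.csv --stratum female:poor --top-k 20
mmnet network --input out/cohort.csv --out out/net.graphml --stratum all:poor
mmnet all --out out/ --seed 1          # full pipeline with manifest
```

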