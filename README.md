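# neuroblme

Bayesian linear mixed-effects (LME) analysis of longitudinal brain-region
volumes, for biostatisticians and neuroimaging researchers studying healthy
ageing and Alzheimer's disease (AD).

In longitudinal ageing cohorts, participants diagnosed healthy control
(HC), mild cognitive impairment (MCI) or AD are scanned a handful of times
(~18 months apart, with heavy dropout), and region volumes such as the
lateral ventricles and hippocampus — normalised by intracranial volume
(ICV) — track neurodegeneration.  `neuroblme` fits the
random-intercept/random-slope model

```
y_it = β0 + β1 t_it + β2 m_it + β3 a_it + β4 m_it t_it + β5 a_it t_it
       + b_0i + b_1i t_it + ε_it,
ε_it ~ N(0, σ²),   (b_0i, b_1i) ~ MVN(0, Σ),
```

where `t` is standardised age and `(m, a)` are per-visit MCI/AD indicators,
under semiconjugate priors (normal β, inverse-gamma σ², inverse-Wishart Σ)
with a blocked Gibbs sampler written for exactly this structure.  From the
joint posterior draws it computes three kinds of inference that classical
LME fits do not give you:

1. **Group ordering** — per-diagnosis deterioration rates (β1, β1+β4,
   β1+β5), their pairwise differences with credible intervals, and Monte
   Carlo ordering probabilities such as P(MCI deteriorates slower than AD).
2. **Individual ranking** — every participant's total slope is ranked
   within each posterior draw, giving a full rank distribution per person,
   median-rank league tables and probabilities of sitting in the worst 15%.
3. **Diagnosis trajectories** — posterior-predictive probabilities that a
   new individual's volume falls in an age-indexed centile band, inverted
   through an external prevalence table P(diagnosis | age) by Bayes' rule
   to give P(diagnosis | volume band, age) over ages 60–85, with Monte
   Carlo standard errors from repeated independent fits.

Because the cohort that motivated this design is not redistributable, the
package ships a synthetic-cohort generator that emulates it exactly at the
design level: 260 participants (157 stable HC / 34 MCI / 42 AD plus 27
converters), at most four visits 1.5 years apart, staged dropout to 69%
retention, volumes drawn from the model above with configurable true
parameters.  Every analysis stage is therefore testable against known
ground truth.

## Worked example

```python
from neuroblme import (
    generate_cohort, gibbs_sample, MCMCConfig, rhat_summary,
    group_slopes, group_difference_table, pairwise_ordering_probabilities,
)

cohort = generate_cohort(seed=1)                   # 260 participants, 890 visits
draws = gibbs_sample(cohort, "ventricle",
                     config=MCMCConfig.test_profile(seed=1))
print(max(rhat_summary(draws).values()))           # 1.0011  (converged)

slopes = group_slopes(draws)
print(group_difference_table(slopes).round(4))
print(pairwise_ordering_probabilities(slopes))
```

```
1.0011
                                                          mean  ci_low  ci_high
ventricle rate (volume-ICV per standardised-age unit)
HC                                                      0.0053  0.0046   0.0059
MCI                                                     0.0080  0.0072   0.0088
AD                                                      0.0130  0.0121   0.0140
MCI-HC                                                  0.0027  0.0018   0.0036
AD-HC                                                   0.0078  0.0067   0.0088
AD-MCI                                                  0.0051  0.0041   0.0060
{'P(HC slower than MCI)': 1.0, 'P(MCI slower than AD)': 1.0,
 'P(HC slower than AD)': 1.0}
```

Read: the HC ventricle grows by 0.0053 ICV-fractions per standardised-age
unit (divide by the cohort age sd, ~5.6 years, for a per-year rate); AD
enlarges ~2.5× faster; all three pairwise severity orderings have posterior
probability ≥ 0.999 and every group difference excludes zero.  The same
draws feed the ranking and trajectory layers (`individual_slopes`,
`rank_per_draw`, `median_rank_table`, `fit_centile_bands`,
`trajectory_with_mc_se`).

A CLI covers the same surface:

```sh
neuroblme simulate --seed 1 --out cohort.csv
neuroblme fit --cohort cohort.csv --region ventricle --profile test --out draws/
neuroblme ordering --draws draws/
neuroblme rank --cohort cohort.csv --draws draws/ --quantile 0.15 --out ranks.csv
neuroblme trajectory --cohort cohort.csv --region ventricle --out traj.csv
neuroblme run --config config.yaml            # full pipeline from YAML
```

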