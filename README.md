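# clusticc

Intracluster correlation coefficients (ICC), design effects and
design-based sample sizes for single-stage cluster samples — the setting
of multicenter health studies where hospitals are the primary sampling
units and every admitted patient is observed.

Subjects within the same centre tend to resemble each other. The ICC
(ρ) measures that resemblance as the share of total variance lying
between clusters; the design effect

Deff = var_actual(r) / var_SRS(r) ≈ 1 + (m − 1)·ICC

is the factor by which clustering inflates the variance of an estimate
relative to simple random sampling with the same number of subjects, and
hence the factor by which an SRS sample size must be multiplied when
planning a cluster-sampled study with mean cluster size m.

The package provides:

- **ANOVA ICC estimation** for unbalanced clusters, binary or continuous
  outcomes, via two equivalent computing formulas — the survey-sampling
  (Kish) form ρ̂ = (s²_a − s²_b/b)/ŝ² and the F-statistic form
  ρ̂ = (F−1)/(F−1+n0) — with asymptotic confidence intervals based on
  Smith's unequal-group-size variance;
- **exact and approximate design effects** and precision-based sample
  sizes (n = ⌈z²p(1−p)/d²⌉, inflated by 1+(m−1)ICC);
- **batch estimation and summaries** over many variables (medians,
  ranges, threshold proportions, per-table medians);
- **a synthetic multicenter generator** (random-intercept Gaussian and
  beta-binomial with exact population ICC) used to validate every
  estimator by parameter recovery;
- a bundled, machine-readable transcription of the per-variable results
  (261 variables) of the Brazilian Multicenter Study on Preterm Birth, a
  20-hospital cross-sectional study with a mean cluster size of 265 —
  a ready reference table of perinatal ICCs for study planning.

## Worked example

Estimate ICCs from a long-format subject CSV (one row per subject, a
cluster column, one column per outcome; blanks are dropped per variable):

```
$ clusticc estimate --input subjects.csv --cluster-col center
table_id,variable,var_type,estimate,icc,ci_low,ci_high,deff,n_a,censored,error
,preterm,binary,55.6,<0.001,<0.001,0.630,0.4,3,1,
,weight,continuous,2644.4,<0.001,<0.001,0.630,1.0,3,1,
```

Each row reports the prevalence in % (or mean), the ICC with its 95%
interval (values below 0.001 printed `<0.001`, as reference tables do),
the exact design effect and the mean cluster size.

Summarize the bundled reference table:

```
$ clusticc summarize --table fixture --thresholds 0.1,0.3
variables: 261
ICC median 0.028 (range 0.000-0.965)
Deff median 6.1 (range 0.6-148.0)
ICC < 0.1: 78.5% of variables
ICC < 0.3: 95.0% of variables
median ICC [T1]: 0.009
...
median ICC [T9]: 0.274
median ICC [T10]: 0.079
```

Most perinatal variables cluster weakly (median ICC 0.028; 78.5% below
0.1), while protocolised clinical-management variables (table T9:
corticosteroid choice, tocolysis, GBS screening) are highly homogeneous
within hospitals — median 0.274, maximum 0.965 — exactly the variables
for which cluster designs pay the largest sample-size penalty.

Plan a study: a 6.5% prevalence estimated to ±0.25 percentage points at
the 5% level, then inflated for 265-subject clusters at the reference
median ICC:

```
$ clusticc samplesize --p 0.065 --d 0.0025 --icc 0.028 --m 265
SRS sample size: 37355
design effect 1+(m-1)*ICC: 8.39
cluster-design sample size: 313484
clusters of mean size 265 needed: 1183
```

The same operations are available as a library:

```python
import clusticc as cc

data = cc.simulate_binary(cc.SimulationSpec(
    var_type="binary", true_icc=0.1, prevalence=0.3, a=20, mean_size=265, seed=1))
vc, est = cc.estimate_icc(data)          # ANOVA fit + ICC + 95% CI
deff = cc.deff_ratio(data)               # exact variance-ratio Deff
print(round(est.rho, 3), round(deff.deff_ratio, 1))
# 0.061 17.2
```

A single draw at 20 clusters scatters visibly around the truth (ρ = 0.1,
Deff ≈ 27.4); `run_parameter_recovery` averages many such replicates to
show the estimator is unbiased.

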