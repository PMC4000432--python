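# Methods

## Setting and model

`clusticc` analyses single-stage cluster samples: hospitals (or schools,
practices, districts) are the primary sampling units, and every subject in
a selected cluster is observed. The quantity of interest per variable is
the intracluster correlation coefficient (ICC, ρ), the share of total
variance lying between clusters,

ρ = σ²_b / (σ²_b + σ²_w),

together with the design effect — the variance penalty of clustering
relative to simple random sampling (SRS) of the same size — and the sample
sizes that follow from it.

## ICC estimation

Estimation is the one-way ANOVA (method-of-moments) estimator. For a
dataset with `a` clusters, `N` subjects and cluster sizes `n_i`, the
decomposition yields MSB = SSB/(a−1), MSW = SSW/(N−a), F = MSB/MSW, and
the adjusted cluster size for unbalanced designs

n0 = (N − Σn_i²/N) / (a − 1),

which equals the common size when the design is balanced. Two computing
formulas are exposed, mapped onto the ANOVA output as s²_a = MSB/n0
(variance among cluster means on the element scale), s²_b = MSW, b = n0:

- survey-sampling ("Kish") form: ρ̂ = (s²_a − s²_b/b) / ŝ², with
  ŝ² = s²_a + [(b−1)/b]·s²_b;
- ANOVA-F form: ρ̂ = (F−1) / (F−1+n0), the reciprocal-mean-cluster-size
  form (F−1)(a/n) / (1+(F−1)(a/n)) with 1/n0 in place of a/n.

Both are algebraically identical to the textbook
(MSB−MSW)/(MSB+(n0−1)MSW); the test suite verifies three-way agreement
to 10⁻¹² rather than assuming it. Binary (0/1) variables use the same
estimator, which for the beta-binomial data-generating model is a
consistent moment estimator of the pairwise within-cluster correlation.

Conventions for degenerate cases: MSW = 0 with MSB > 0 gives F = +∞ and
ρ̂ = 1 directly; all-identical values raise a degenerate-variance error;
all-singleton clusters raise an error (MSW undefined). Negative raw
estimates (cluster means more alike than chance) are truncated to 0 for
reporting, with the raw value retained for diagnostics — consistent with
reference tables that floor at "<0.001".

## Confidence intervals

The sampling variance uses Smith's (1957) large-sample formula for the
one-way ANOVA ICC with unequal group sizes (also in Donner 1986):

V(ρ) = 2(1−ρ)²/n0² · [ (1+(n0−1)ρ)²/(N−a)
        + ( (a−1)(1−ρ)(1+(2n0−1)ρ) + ρ²(S2 − 2S3/N + S2²/N²) ) / (a−1)² ],

S2 = Σn_i², S3 = Σn_i³. For balanced designs this collapses to the
classical 2(1−ρ)²(1+(m−1)ρ)²(N−1)/(m²(N−a)(a−1)).

The default interval is obtained by **test inversion**: the bounds are the
values ρ0 solving |ρ̂ − ρ0| = z_{1−α/2}·√V(ρ0) (Brent root-finding on
[0, ρ̂] and [ρ̂, 1]), truncated to [0,1]. The plain Wald interval
ρ̂ ± z·√V(ρ̂) is available via `style="wald"`. The inversion form was
chosen because √V(ρ) increases steeply in ρ near 0 for large cluster
sizes, so evaluating the variance at a small ρ̂ makes the Wald upper bound
too short; in simulation at the package's reference design (20 clusters of
265; 3,000 replicates per point) Wald coverage of a nominal 95% interval
is 90–92% across ρ ∈ {0.01, 0.05, 0.1, 0.3} for both Gaussian and
beta-binomial data, while the inversion interval attains 94.9–96.0%.
Standard-normal quantiles are used throughout (no small-sample t
correction); the reported SE is √V(ρ̂). With 20 clusters the normal
asymptotics are an approximation; coverage checks above are part of the
test suite.

## Design effects and sample size

The exact design effect of a sample mean is the variance ratio
Deff = var_actual(r)/var_SRS(r). `var_actual` treats clusters as PSUs
drawn with replacement: the variance among (unweighted) cluster means
divided by `a`; a size-weighted alternative (linearised ratio estimator)
is available via `weighted=True`. `var_srs` is the element variance
(N−1 denominator, chosen for unbiasedness) over N. No finite-population
correction is applied — clusters are modelled as sampled with replacement
from a superpopulation of centres. Deff below 1 is possible (cluster
means more alike than chance) and does occur in the bundled reference
table (minimum 0.6).

The approximation Deff ≈ 1 + (m−1)·ICC (m = mean cluster size) is exposed
separately and used for sample-size inflation:
n_cluster = ⌈n_SRS · Deff⌉, plus the number of clusters ⌈n_cluster/m⌉.
The SRS size for estimating a proportion p to absolute precision d is
n = ⌈z²_{1−α/2}·p(1−p)/d²⌉. Quantiles are exact (scipy `norm.ppf`), not
the two-decimal table value: for p = 0.065, d = 0.0025, α = 0.05 this
gives 37,355 (1.96 would give 37,356). Ceilings, never rounding, for all
required sizes (conservative design convention).

## Synthetic data generator

The generator emulates a 20-centre multicenter perinatal study with a
mean cluster size of 265 subjects (≈5,300 total), the design whose
reference results ship with the package:

- **continuous**: random-intercept Gaussian, y_ij = μ + u_j + e_ij,
  u_j ~ N(0, ρσ²), e_ij ~ N(0, (1−ρ)σ²); population ICC is ρ exactly.
- **binary**: beta-binomial — p_j ~ Beta(πθ, (1−π)θ) with θ = (1−ρ)/ρ,
  subjects Bernoulli(p_j); the pairwise within-cluster correlation is
  1/(θ+1) = ρ in closed form, which is why it was preferred over a
  logistic-normal random intercept (whose latent-scale ρ does not equal
  the outcome-scale correlation): recovery tests are exact in
  expectation. ρ = 0 degenerates to plain Bernoulli(π); ρ = 1 is
  unsupported.
- cluster sizes: fixed, Poisson, an explicit list, or uniform jitter of
  ±50% around the mean (the reference study's centres contributed very
  unequally; exact per-centre sizes were never published, so unbalance is
  emulated, not matched).
- missingness: completely at random, independently per observation; no
  informative mechanism is modelled (none is documented for the
  reference study). An MCAR rate that empties all but one cluster raises
  an error.

`simulate_emip_like_study` bundles 29 variables — a 5×5 grid of binary
variables over prevalences {0.01, 0.1, 0.3, 0.6, 0.9} × ICCs
{0.005, 0.03, 0.1, 0.3, 0.5}, one protocolised-management-like variable
(π = 0.85, ρ = 0.95), and three continuous variables (birth-weight-like:
mean 2321 g, SD 650 g; gestational-age-like; maternal-age-like) — with
shared cluster sizes, per-variable MCAR rates cycling {0, 0.1, 0.3, 0.6},
and a manifest of true parameters. Every generator is a pure function of
(spec, seed).

What passing recovery tests show — and do not show: they demonstrate the
estimators are unbiased (±0.02) and their intervals near-nominal under
the stated generative models at the reference design. Real multicenter
data add features the generator omits (informative missingness,
within-cluster subject correlation beyond exchangeability, centre-level
covariates, ordinal outcomes collapsed to indicators), so performance
there is an extrapolation.

## Problem sizes used in validation

Parameter recovery runs 500 replicates per (generator × ρ) point at the
reference design (a = 20, m = 265), chosen to keep Monte-Carlo error on
a coverage percentage near ±1 point while the full suite completes in
seconds. Rare-outcome comparisons use π = 0.01 vs π = 0.3; all-zero
replicates at π = 0.01 are counted as explicit estimation failures, a
real feature of rare outcomes in 20-cluster designs.

## Known limitations

- The ANOVA estimator and Smith variance assume exchangeable subjects
  within clusters; no covariate adjustment or multilevel modelling
  (REML/Bayesian) is provided.
- Intervals are asymptotic in the number of clusters; with very few
  clusters (< 10) coverage degrades and an exact F-based interval (not
  implemented; Gaussian-balanced only) would be preferable.
- Binary ICCs at very low prevalence are intrinsically unstable — wide
  replicate spread and occasional inestimability; the package surfaces
  this rather than masking it.
- Deff estimates inherit the instability of a between-cluster variance
  estimated from `a` clusters: individual-variable Deffs scatter widely
  around 1+(m−1)ρ even when their average is within 10%.
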