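# Methods

This note documents the models, the default parameters and the numerical
choices behind `casebias`, and what the synthetic experiments do and do not
show about real data.

## Generative models and standardization

All four causal models share one generator. A biallelic genotype
`g ~ Binomial(2, p)` is standardized to *G*; a unit-variance residual ε
(normal, centered exponential, or uniform on ±√3) builds the bacterial
level; disease follows a Bernoulli draw from a logistic in the standardized
bacterial level *B* and/or *G*. Model d inverts the order: disease is drawn
first (it depends only on *G*), and the bacterial level is `γD + ε` with *D*
the standardized status. Effects are therefore on interpretable scales:
β and γ are SD-per-SD, ω_B and ω_G are log-odds per SD.

Standardization uses the population (divide-by-n) variance convention
throughout. This is not cosmetic: with it, the conditional-moment identity
`E[X|d=1] = E[X] + (σ_d/μ_d)E[XD]` is an *algebraic identity on any finite
sample*, so the moment-based Δ equals the brute-force two-regression
difference to floating-point error, which the tests assert at 1e-8 over 100
random parameterizations of n = 200,000.

A negative-binomial "residual" cannot be additive; when requested, the
bacterial level *is* a NB count whose log-mean is shifted by the causal
effect (`mean = m·exp(effect)`). The rank-INT analysis route is invariant to
that monotone link choice. The NB dispersion (size k) is solved from the
zero-probability equation `P(0) = (k/(k+m))^k` by bracketed root-finding;
targets below the Poisson floor `exp(−m)` are clamped with a warning.

The logistic intercept ω₀ is calibrated to a target prevalence by Brent
root-finding on the Monte-Carlo marginal expectation over a fixed 400,000
draw calibration sample (closed form `logit(μ_d)` when no effects enter the
logistic). Calibration error on the prevalence is ≈ 7×10⁻⁴, comfortably
inside the ±0.005 contract checked at n = 10⁶.

## The bias estimator and its approximations

`delta_exact` implements the model-free moment formula (README). The
closed-form per-model approximations implement the published numerators
−βω_B²(1−μ_d)²/((1−β²)·var(G|d=1)), 0, −ω_Gω_B(1−μ_d)²/var(G|d=1) and
−γω_Gσ_d. Two caveats, both verified numerically and reflected in the tests:

* The (1−μ_d)² constant in the a/c forms does not match the exact Δ: at
  μ_d = 0.3, ω_G = 0.4, ω_B = −0.4 the exact bias is ≈ +0.033 while the
  printed form gives +0.078. A second-order expansion of the logistic
  suggests the constant should be μ_d(1−μ_d) (which matches the exact value
  within ~2 % and, unlike (1−μ_d)², vanishes in the rare-disease limit, as
  the bias itself does). The implementation keeps the published forms and
  guarantees the *sign* only; the tests assert sign agreement plus an
  order-of-magnitude ratio, and separately that the exact bias attenuates
  from μ_d = 0.3 to μ_d = 0.01.
* For model d the case-only coefficient is ≈ 0, so Δ_d = −E[BG] ≈ −γω_Gσ_d;
  the sign rule `sign(Δ_d) = −sign(γω_G)` is the operative contract.

`var(G|d=1)` defaults to 1 in the approximations (its small-effect value);
callers with a sample can supply the exact conditional variance.

## Simulation experiments: conditions and scales

All experiments derive replicate generators from a single master seed via
`SeedSequence.spawn`, so results are reproducible and order-independent.

* **Bias grids** — common disease (prevalence 0.30), allele frequency 0.2,
  effects β = −0.3, ω_B ∈ {−0.4, −0.5}, ω_G = 0.4, γ = −0.3; 200 replicates
  of n = 20,000 per model and per residual distribution in the acceptance
  run. The four sign properties are tested by exact binomial sign tests at
  P < 0.01 (directional rules) and 3.5 Monte-Carlo SEs (null rules).
* **Sparsity** — NB counts (mean 10), replicate zero fractions uniform on
  [0, 0.95], allele frequency uniform on [0.05, 0.95], large-effect common
  disease regime (|effects| 0.5–0.7, prevalence 0.3); 200 cases sampled from
  n = 10,000; 2,000 replicates per model in the acceptance run, summarized
  as median signed explained variance over 5 zero-fraction bins. Both the
  true effects (a, b) and the collider bias (c) decay toward the null as
  sparsity grows: zero inflation turns the standardized level into a nearly
  binary variable that carries less of the genotype signal and less of the
  selection-induced covariance.
* **Heterogeneity** — CD from the causal model and UC independent, each at
  prevalence 0.005 (an IBD-scale ~1 %); per-SD genetic log-odds 0.15
  (≈ OR 1.3 per allele), bacteria–disease log-odds −0.4/SD, and for model d
  a case-control level shift of −0.4 SD (γ is the shift × σ_d — a fixed
  standardized γ at 0.5 % prevalence would imply an absurd 14-SD case
  shift). 200 IBD cases sampled from n = 30,000; 1,000 replicates per model
  in the acceptance run. Under models c and d every stratum (IBD, CD-only,
  UC-only) should and does reject at close to the nominal 5 %; under models
  a/b the population-wide G→B link shows in *every* stratum, including the
  independently drawn UC one — subtype admixture does not silence a true
  effect, it only mixes in the admixed stratum's own estimate.
* **Severity** — severity is Binomial(5, p) with the model's logistic as
  per-trial probability (per-trial target solved from the 0.30 disease
  prevalence via 1−(1−μ)^{1/5}); cases are severity ≥ 1. Under model d the
  case-only G–B correlation is real (severity still varies within cases)
  and is removed exactly by residualizing the level on severity; under a–c
  adjustment changes nothing qualitatively.
* **Panels** — 50 taxa per panel, each simulated independently under the
  model with a shared per-taxon "involvement" scale u_t ~ N(1, 0.3) (clipped
  at 0.2) multiplying the model's effect(s), base effects β = −0.4,
  ω_B = −0.5, ω_G = 0.5, γ = −0.4 at prevalence 0.3; β̂^g from 500 cases by
  OLS, β̂^B from 500 cases + 500 controls by logistic regression. The shared
  scale is what makes the mediation/pleiotropy panels concordant: under
  mediation, taxa more involved with disease are also the taxa the genotype
  moves more. Under model c the case-only estimate is the bias −ω_Gω_B,t·
  const, anti-proportional to the taxon's disease effect, hence the negative
  panel correlation; under model d both quantities decouple and the
  correlation is null.
* **End-to-end recovery** — two independent panels (discovery/replication)
  per run; the case-only direction is the panel mean tested against zero and
  classified persistent/null/indeterminate (persistent: same stage signs and
  pooled |z| > 3.29; null: pooled |z| < 1.28 or discordant signs), the
  concordance feature requires permutation p < 0.01. A run with no
  informative feature excludes nothing (full verdict set). 100 runs per
  model in the acceptance run; the verdict contains the generator ≥ 90 % of
  the time and the case-only feature alone separates {a, b} from c and d.

## Association pipeline choices

* Prevalence filter: a taxon is kept when quantified in ≥ 20 % of samples
  (boundary inclusive); "poorly annotated" removal is an optional
  lineage-completeness rule.
* Rank-INT: Blom offset c = 3/8, mid-ranks for ties (the zero mass of a
  sparse taxon becomes one tied block). Exactly invariant to monotone input
  transforms; output passes a Shapiro check at n = 182 absent heavy ties.
* Covariate screen: greedy forward selection among same-rank taxa, admitting
  candidates that explain residual outcome variance (partial p < 0.05) and
  show no genotype association (p > 0.05), up to 5; deterministic given the
  data. This is a stand-in with the published method's admission logic, not
  a re-derivation of it.
* SNP→taxon model: OLS of the INT outcome on the untransformed genotype
  (carrier or dosage coding; composite loci sum or OR their variants) with
  the seven discovery confounders; t-reference p-values; listwise deletion
  of missing covariates (logged); collinear covariate columns dropped, the
  genotype column never. Per-rank Bonferroni flags candidates. Disease type
  is deliberately *not* adjusted for in the discovery model.
* Taxon→disease model: logistic regression; perfect separation yields a
  flagged sentinel excluded downstream.
* Meta-analysis: fixed-effect inverse variance. SEs recovered from printed
  two-sided p-values via the standard-normal quantile; this reproduces the
  published pooled coefficients to 2 decimals, which is the acceptance
  check on the arithmetic.
* Enrichment: exact one-sided binomial on the effect signs (zeros counted to
  neither side). Concordance: Pearson correlation of per-taxon summed β^g
  with β^B, permutation p over taxon labels.
* Pipeline model-fit read-out: when per-rank Bonferroni candidates exist,
  the case-only direction is judged on a Stouffer combination of the
  candidates' Wald z-scores; otherwise on the all-taxa mean. The restriction
  matters under compositional closure: suppressing taxa with a large
  compositional footprint mechanically inflates the remaining relative
  abundances and would pollute an all-taxa sign statistic.

## Synthetic cohort: what it emulates, what it does not

The generator reproduces the study's observable structure: 168 taxa over six
nested ranks (6/12/17/36/63/34), NB counts with per-taxon zero fractions and
heterogeneous lognormal means scaled to a rarefaction-like depth, upward
aggregation (so child ≤ parent per sample and parent–child correlations are
high by construction), an unassigned mass component per node and at the
root, Table-1-scale covariate frequencies (smoking 21.4 %, anti-TNF 49.5 %,
age ~ N(40.6, 12) truncated at 18, 57.7 % female, 63.2 % CD; ileal
involvement among CD set to 60 %), and four risk loci (risk-allele
frequencies 0.55, 0.58, 0.02 and a three-variant composite at 0.04/0.01/
0.02 — literature-scale values, configurable). Controls carry no treatment
flags and optionally no genotypes.

Not emulated: read-level sequencing noise, taxonomic misassignment,
batch/cohort effects, real inter-taxon ecological covariance beyond the
hierarchy, longitudinal dynamics, and genuine linkage structure between
variants. Passing tests therefore demonstrate that the *statistical
machinery* behaves as derived under the stated generative assumptions — not
that any particular real cohort satisfies those assumptions.

## Numerical details and degenerate inputs

Replicate-level regressions use closed-form OLS (slope, SE, t) and a small
Newton IRLS for the two-parameter logistic; both are cross-checked against
statsmodels in unit tests, and the pipeline surface itself uses statsmodels.
Monomorphic genotype draws are resampled (error after 20 attempts);
constant vectors raise naming the offending variable; strata with constant
genotype or fewer than 10 samples emit missing-result records rather than
failing. TSVs are written with 17-significant-digit floats and read with
round-trip float parsing so write→read is bit-exact.

## Known limitations

* The closed-form Δ approximations inherit the published constants; their
  magnitudes are only trustworthy near the small-effect, common-disease,
  near-normal regime (signs are trustworthy everywhere tested).
* The verdict set deliberately never names a single winner; mediation vs
  pleiotropy is only "favored" through the subtype-slope feature, and only
  when the genetic effect is known to concentrate in a subtype.
* Estimating Δ from case-only data alone is impossible without external
  information; the package ranks models by signs instead, which is exactly
  the scope of the counterfactual argument it implements.
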