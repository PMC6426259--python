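# casebias

Case-only ascertainment bias and causal-model ranking for SNP–microbiome
association studies.

## The problem

Clinical microbiome cohorts are usually collected *because* the participants
are patients. When a genetic variant *g* and a bacterial abundance *b* both
affect the disease *d* that defined the sample, the case-only association
between *g* and *b* need not reflect their association in the population —
conditioning on a common consequence (a collider) can create, inflate,
attenuate or erase an association. This package implements a complete
analysis for that setting, built around four parsimonious causal models for
the triplet (g, b, d):

* **a — mediation**: `B = βG + ε`, `logit P(d) = ω₀ + ω_B B`
* **b — pleiotropy**: `B = βG + ε`, `logit P(d) = ω₀ + ω_G G`
* **c — independent risk factors**: `logit P(d) = ω₀ + ω_B B + ω_G G`
* **d — reverse causation**: `logit P(d) = ω₀ + ω_G G`, then `B = γD + ε`

with *G*, *B*, *D* the standardized variables. The quantity of interest is
the ascertainment bias

```
Δ = β_{d=1} − β,
```

the difference between the case-only and whole-population regression
coefficients of *B* on *G*. Writing r = σ_d/μ_d, every conditional moment
reduces exactly to unconditional ones via `E[X|d=1] = E[X] + r·E[XD]`, giving
the model-free closed form

```
var(G|d=1) = 1 + r·E[G²D] − (r·E[GD])²
Δ = (r·E[BGD] − r²·E[GD]E[BD]) / var(G|d=1) + E[BG]·(1 − var(G|d=1)) / var(G|d=1)
```

and, per causal model, the sign rules `sign(Δ_a) = −sign(β)`, `Δ_b ≈ 0`,
`sign(Δ_c) = −sign(ω_G ω_B)`, `sign(Δ_d) = −sign(γ ω_G)`. Confronting these
predicted signs with the observed association pattern (case-only SNP–taxon
direction, concordance of SNP–taxon with taxon–disease effects, subtype
slope) ranks the causal models without ever observing the population.

## What is in the package

| module | contents |
|---|---|
| `casebias.taxonomy`, `casebias.synthetic` | six-rank taxonomy scaffold; negative-binomial, zero-inflated, hierarchy-consistent abundance tables; host covariates and genotypes at published cohort frequencies; causal-structure embedding |
| `casebias.models` | the four generative models, prevalence calibration, case ascertainment |
| `casebias.bias` | exact moment-based Δ, closed-form approximations, per-model sign patterns |
| `casebias.experiments` | replicate bias grids (normal/exponential/uniform residuals), sparsity, subtype-heterogeneity and severity experiments, taxon panels, polynomial check of the logistic linearization |
| `casebias.assoc` | ≥20 % prevalence filter, rank-based inverse-normal transform, greedy same-rank covariate screen, SNP→taxon OLS, taxon→disease logistic, per-rank Bonferroni, subtype strata |
| `casebias.meta` | SE recovery from printed (β, p), fixed-effect inverse-variance pooling, exact-binomial sign enrichment, permutation concordance, slope-vs-1 attenuation test |
| `casebias.modelfit` | observed-sign extraction and the verdict-set model ranking |
| `casebias.io`, `casebias.pipeline`, `casebias.cli` | TSV formats, run configuration, the end-to-end pipeline and the `casebias` CLI (`simulate`, `associate`, `meta`, `infer`, `report`, `all`) |

The numbered scripts under `analysis/` run the study stages in order
(cohort simulation → bias theory checks → replicate grids → sparsity →
heterogeneity → severity → association pipeline → model recovery) and write
their tables under `results/`.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 0
python analysis/07_association.py
```

prints (abridged):

```
wrote cohort under results/cohort
  220 samples (192 cases), 168 taxa over 6 ranks
  mediation embedded on 10 species (NOD2/CARD9 alternating)
taxa funnel: 168 -> 168 retained (0 below the prevalence filter)
candidate associations (per-rank Bonferroni): 10
      NOD2 ~ g__048     (genus): beta -0.904 (p 4.81e-05)
     CARD9 ~ s__010     (species): beta -0.818 (p 7.00e-05)
      NOD2 ~ c__001     (class): beta -0.841 (p 1.27e-04)
enrichment NOD2: 102/168 negative (p 0.00338)
model-fit verdict: a, b
```

The cohort embeds a mediation effect (risk alleles suppress ten species,
which raises disease risk). The pipeline recovers candidate associations at
the species that carry the effect and at their ancestors (the same signal
projected up the taxonomy), finds the all-taxa enrichment for negative
NOD2 effects, and the verdict set {a, b} says the data are consistent with
mediation or pleiotropy — and rules out selection bias (model c) and reverse
causation (model d), exactly the discrimination the sign rules promise.
A direct look at the bias estimator itself:

```bash
python analysis/02_bias_theory.py --n 500000
# model a: exact +0.01497  regressions +0.01497  approx +0.04038  (signs agree)
# model c: exact +0.03335  regressions +0.03335  approx +0.07840  (signs agree)
# model d: exact +0.05342  regressions +0.05342  approx +0.05499  (signs agree)
```

The moment formula matches the brute-force two-regression difference to
~1e-13 (it is an algebraic identity on a finite sample); the closed-form
approximation is a small-effect, near-normal linearization and is guaranteed
in sign only.

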