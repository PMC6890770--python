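# phenoherit

Genetics-free estimation of disease heritability and inter-disease
genetic/environmental correlations from population-scale diagnosis data.

Estimating quantitative-genetic parameters normally requires family
structure or genotypes alongside phenotypes.  This package implements an
alternative route for epidemiologists and statistical geneticists who have
access only to longitudinal diagnosis records (patient id, sex,
age-at-diagnosis, disease code): build two descriptors per disease —

1. a **prevalence curve**: the normalized distribution of a disease's
   diagnoses over patient ages 0–65 within a sex/country stratum, computed
   either against enrollment ("Analysis A", one code per patient per year,
   divided by enrollees) or as the disease's share of all diagnoses
   ("Analysis B"); and
2. a **disease embedding**: a 20-dimensional skip-gram vector learned from
   chronologically ordered patient diagnosis sequences, minimizing
   cost = −Σ_ω log P(ω | ω₋) with negative sampling —

and use them, together with study descriptors (data type, mathematical
model, cohort sex and country), as features in a gradient boosting
regression that imputes heritability *h²* per disease and genetic /
environmental / phenotypic correlations per disease pair from a table of
published ("legacy") estimates.

Around that core the package provides:

- shape-of-curve dissimilarity *D*_soc: base-2 Jensen–Shannon divergence
  minimized over −8..+8-year temporal shifts (overlap windows
  re-normalized), pairwise matrices, complete-linkage clustering, and
  elbow selection of the cluster count from the total intra-cluster
  variation W(K) = Σₖ Σ_{xᵢ∈Cₖ} (xᵢ − μₖ)², evaluated from pairwise
  squared dissimilarities;
- the from-scratch gradient boosting regressor (F₀ = ȳ; stage-wise
  residual trees with shrinkage; defaults M = 200 trees, rate 0.1),
  repeated random 4:1 split evaluation, gain-based feature importance,
  and inverse-variance pooling of estimates;
- downstream statistics: Spearman's ρ with AS 89 p-values (exact
  enumeration at small n), onset-age associations overall and per shape
  cluster, the OLS regression D_soc ~ r_g + r_e + r_g·r_e, and a Wilcoxon
  rank-sum comparison of absolute prediction errors between disease
  groups;
- a synthetic-data generator (`phenoherit.synthetic`) producing
  diagnosis-event streams, enrollment tables and noisy estimate tables
  with known ground truth, so every stage is testable without access to
  licensed registries.

## Worked example

```python
from phenoherit import pipeline

result = pipeline.run_pipeline(n_diseases=60, n_patients=2500, seed=11)
overall = [a for a in result.associations
           if a.analysis == "onset_vs_h2" and a.stratum == "all"][0]
print(result.clusters.K, round(overall.spearman_rho, 3))
```

Running `python examples/05_downstream_analyses.py` (which executes the
call above and prints the full association table) ends with:

```
   onset_vs_h2       all 60     -0.781348    0.000000  -0.006337 ...
D_soc = 0.418 + -0.014 r_g -0.313 r_e +0.015 r_g*r_e   (n = 1770 pairs)
rank-sum comparison of error groups: W = 940.0, p = 0.717
```

The Spearman ρ = −0.78 recovers the negative onset-age/heritability
dependence built into the synthetic world's truth table; the D_soc
regression shows the expected negative coefficient on the environmental
correlation (in this generator, curve shape — and hence D_soc — is driven
by the archetypes behind r_e, while r_g comes from independent latent
vectors, so its coefficient is near zero); and the nonsignificant rank-sum
p indicates comparable imputation error across the two disease groups.
The other scripts in `examples/` each demonstrate one capability:
simulation, curves/clustering, embeddings, and imputation.

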