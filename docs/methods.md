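# Methods

This note documents the models and procedures implemented in `phenoherit`,
the assumptions behind them, the defaults that matter, and what the
synthetic-data tests do and do not demonstrate.

## Prevalence curves

A disease prevalence curve is a probability vector over integer ages 0–65
(66 bins; the upper limit mirrors commercial-claims enrollment, and input
events above age 65 are dropped with a logged warning).  Two definitions
are implemented:

- **Analysis A** (enrollment-normalized): within a sex/country stratum,
  count each (patient, disease, age-in-years) combination once — the
  executable reading of "one code per patient per year" — divide by the
  enrollee count of the (sex, age) stratum, and re-normalize the 66-vector
  to sum to 1.  A stratum with events but no enrollment is an error naming
  the stratum.
- **Analysis B** (share-of-diagnoses): divide the disease's raw code count
  per age by the total code count of all diseases in the same sex/age
  group, then re-normalize.  This needs no enrollment table and is the
  definition used for downstream features.

All-zero curves are rejected rather than silently normalized, because the
downstream Jensen–Shannon machinery is undefined on them.  An optional
pseudo-count (default 0, i.e. off) can be added to every bin before
normalization for sparse diseases; it trades fidelity to the raw data for
informative dissimilarities when supports are nearly disjoint.

**Onset age** is the age at which the curve's cumulative distribution
reaches 0.05 (the maximum age among the 5% youngest diagnosis bearers),
computed with a 1e−12 tolerance so that an exact 0.05 mass at age 0 counts.
**Sex bias** is 0.5·(n_M − n_F)/(n_M + n_F) over raw code counts: 0 when
the sexes are equally represented, ±0.5 for single-sex diseases.
Aggregation is over all calendar time at once (the ordering of
normalization versus multi-year aggregation is not observable in the event
schema used here).

## Shape-of-curve dissimilarity and clustering

D_soc between two curves is the minimum base-2 Jensen–Shannon divergence
(0·log 0 ≡ 0; bounded in [0, 1]) over integer shifts s ∈ [−8, +8] of one
curve along the age axis.  After a shift the curves are restricted to the
overlapping age window and **re-normalized** rather than zero-padded;
zero-padding would saturate large shifts at the disjoint-support maximum
regardless of shape.  Shifts whose overlap carries no mass are skipped.
Ties in the minimized JSD break toward the smallest |s|, negative before
positive, for determinism.  The returned shift is positive when the second
curve's pattern sits later in life than the first's.

Curve shapes are grouped by complete-linkage agglomeration on the
dissimilarity matrix (via `scipy.cluster.hierarchy`).  The cluster count is
chosen from the total intra-cluster variation
W(K) = Σₖ Σ_{xᵢ∈Cₖ} (xᵢ − μₖ)², evaluated without any coordinate embedding
through the identity Σ_{xᵢ∈Cₖ}(xᵢ−μₖ)² = (1/(2|Cₖ|))·Σ_{i,j∈Cₖ} d²ᵢⱼ,
which is exact when d is Euclidean (verified against the direct formula on
planar points).  The elbow — "the decline switches from fast to slow" — is
operationalized as the K maximizing the perpendicular distance between the
min-max-normalized W profile and the chord joining W(1) to W(K_max)
(kneedle criterion), ties toward smaller K.  This is one of several
defensible readings of a visual rule; it is deterministic and
scale-invariant.

## Disease embedding

Patient histories, ordered by age (stable sort, so same-age events keep
input order), are treated as sentences of disease codes.  A skip-gram
model with negative sampling minimizes the negative log-likelihood
surrogate of cost = −Σ_ω log P(ω | ω₋).  Choices:

- **window = 8 codes per side** (a symmetric reading of "context size of
  eight"; window semantics in common implementations count each side);
- **dim = 20**, balancing vocabulary size against predictive power;
- **5 negative samples** per positive pair, drawn from the unigram
  distribution raised to 0.75 — standard and stable for small corpora;
- learning rate decaying linearly from 0.025 to 1e−4; 5 epochs by default
  (3 in the end-to-end pipeline, where corpora are small); min-count 1,
  since the synthetic vocabulary is already curated;
- input vectors initialized uniformly in ±0.5/dim, output vectors at zero;
  a single seeded generator makes training fully deterministic.

The trainer is a compact numpy implementation.  Average per-pair cost is
recorded per epoch; on structured corpora it decreases over early epochs,
though the stochastic negative draws make the trace noisy rather than
strictly monotone on arbitrary corpora.

## Feature assembly

Single-disease features concatenate, in fixed order: the 66 normalized
Analysis-B counts; their 66 cumulative counts (running sum, final element
1); the 20 embedding elements; a 21-level biological-system one-hot (20
systems plus "Other"); sex bias, mean carrier age, onset age; and one-hots
for data type (5 levels), mathematical model (6 levels), cohort sex and
country.  Sex and country vocabularies come from the observed estimate
table plus a reserved "unknown" level; the fixed vocabularies (category,
data type, model) reject unknown labels with an error naming the field.

Pair features use the element-wise **mean** and **absolute difference** of
the three continuous blocks — absolute, because unordered pairs have no
canonical sign and exchange symmetry is required — plus a binary
same-category indicator and absolute deltas of sex bias, mean age and
onset age, and the same study one-hots.  A schema object records block
names, offsets and group tags ("curve", "embedding", "data_type", "model",
"country", "other") and is serialized as a JSON sidecar next to feature
tables.

## Gradient boosting imputer

The regressor is written from scratch: F₀(X) = ȳ; at each of M stages a
regression tree is fitted to the current residuals and added with a
constant shrinkage.  The stage pseudo-code's line search for the stage
coefficient is reconciled with the constant learning rate in the standard
way: leaf values are residual means (the exact per-region line-search
solution under squared error), and a constant rate multiplies each tree.

Defaults: **M = 200 trees, rate 0.1**, max depth 3 (depth is a free choice;
3 is the common boosting default and the sensitivity is covered in tests),
minimum leaf size 1, no subsampling or stratification.  Split candidates
are midpoints between consecutive distinct sorted feature values; gain is
squared-error reduction; ties break toward the lowest feature index, then
the lowest threshold, so fitting is fully deterministic (one-hot columns
are ordinary numeric columns split at 0.5).  Features are presorted once
per fit and children inherit filtered sorted orders; the split scan is
JIT-compiled via numba when available, with an equivalent numpy fallback.
Degenerate stages (no improving split) contribute a constant and are
logged, not errors.  Training predictions equal exactly
F₀ + rate·Σₘ hₘ(X), and the recorded per-stage training MSE is
non-increasing for rates in (0, 1].

Evaluation fits on a random 80% and predicts the held-out 20%, recording
per split the Pearson correlation and the least-squares slope/intercept of
actual (response) on predicted (regressor); the aggregate is the mean with
a 1.96·SE/√(splits) half-width.  Splits with constant held-out actuals or
predictions are skipped and counted.  Feature importance is total gain per
feature across all splits of all trees, normalized to sum to 1 and
aggregated by schema group; a never-split model is flagged.

Inverse-variance pooling combines repeated estimates as
v = Σ(vᵢ/SEᵢ²)/Σ(1/SEᵢ²) with SE = √(1/Σ(1/SEᵢ²)); records with missing
SEs fall back to an unweighted mean with the SE marked undefined.

## Downstream analyses

**Spearman/AS 89.**  ρ uses midranks for ties.  For n ≤ 8 the two-sided
p-value is an exact enumeration over all permutations of one margin; above
that, the tie-corrected ρ is mapped to S = (1−ρ)·n(n²−1)/6 and the AS 89
Edgeworth series gives each tail, doubled and capped at 1.  The exact
branch matches full enumeration to 1e−9 in tests.

**Onset-age associations** are computed overall and per shape cluster
(reusing the global cluster assignment rather than re-clustering per
stratum), for onset age versus diagnosis count and versus pooled h².
Because diagnosis counts span orders of magnitude, the OLS fit uses log₁₀
counts (flagged in the result; Spearman is rank-based and unaffected).
Slope and intercept p-values are Student-t from the OLS fit (statsmodels).
Strata with fewer than 3 diseases are skipped.

**D_soc regression** fits D_soc ~ [1, r_g, r_e, r_g·r_e] by OLS with
coefficient standard errors and t-test p-values; a rank-deficient design
(e.g. a constant correlation column) raises an explicit error.

**Error comparison** between disease groups (e.g. acute versus chronic)
is a two-sided Wilcoxon rank-sum test on absolute prediction errors:
exact enumeration over group assignments when C(n₁+n₂, n₁) ≤ 100,000,
otherwise the normal approximation with midrank tie correction and
continuity correction.

## Synthetic worlds

The generator emulates the statistical structure the analysis assumes,
with known ground truth:

- **Five curve archetypes** on ages 0–65: geometric decay from birth
  (rate 0.05; an L-shape with a heavy right tail), a slowly rising
  logistic (midpoint 25, slope 10), a two-Gaussian mixture (modes 5 and
  45), a steeply rising late logistic (midpoint 50, slope 1.2), and a
  gamma-shaped skewed bell (shape 8, scale 1.4; mode near age 10 with a
  right tail deliberately lighter than the L-shape's).  The free
  parameters were set so the five shapes remain mutually distinct under
  shift-minimized JSD — the analogue of the five distinct shape clusters
  the method is meant to resolve; with near-identical shapes the elbow
  criterion would correctly merge them.
- **Truth table**: archetypes are assigned round-robin; each disease gets
  an iid standard-normal latent vector, a category, a sex bias (uniform
  ±0.3 by default), the onset age of its archetype, and
  h² = clip(0.6 − 0.4·onset/65 + N(0, 0.05), 0, 1) — a built-in negative
  onset-age/heritability dependence for sign-recovery tests.  Pair truth:
  r_g = cosine of latent vectors, r_e = cosine of archetype curves
  rescaled to [−1, 1].
- **Events**: each patient draws a sex, a latent affinity vector, and a
  Poisson-sized disease set sampled without replacement with probability
  ∝ softmax(affinity·latent/temperature)·sex-weight, so co-occurrence
  reflects latent similarity (temperature, default 1, controls how hard
  the block structure is to recover).  Each acquired disease emits
  1 + Poisson(0.7) codes at ages drawn from its sex-modified archetype
  curve, so codes can repeat within a patient-year — deduplication is
  deliberately left to the curve module.  Enrollment counts every patient
  at every age.
- **Estimate tables**: value = truth + N(0, SE) with SE uniform in a
  configurable range, tagged with uniformly drawn data-type/model/sex/
  country labels.

What this does *not* emulate: ICD hierarchies and miscoding, enrollment
churn and censoring, calendar-time effects, category-structured
correlations between r_g and curve shape, or informative missingness in
published estimates.  Passing recovery tests therefore demonstrate the
pipeline's internal consistency — that each stage recovers the structure
the generator put in — not registry-scale validity.

## Problem sizes used in tests and the acceptance script

Desk-scale defaults, chosen once: imputer-recovery runs use 100 diseases ×
10 records (N = 1000) with 50 random 4:1 splits; "noiseless" means
estimate SE 1e−6 (the world's own h² noise remains part of the truth);
the noisy condition uses SE 0.05.  Full-pipeline sign-recovery uses
60-disease worlds with 2,500 patients, 5 records per disease, 3 embedding
epochs, over 20 seeds.  Cluster recovery uses 8 curves per archetype with
log-normal bin noise (SD 0.05).  The D_soc recovery study generates 500
pairs per replicate with noise SD 0.01 over 100 replicates.

## Known limitations

- The elbow criterion needs the generating clusters to be comparably
  separated; strongly hierarchical separations legitimately produce a
  smaller K (visible in `examples/02` at small sample sizes).
- The embedding trainer is single-threaded and intended for vocabularies
  of order 10³, not general NLP corpora.
- AS 89's Edgeworth tail is an approximation for moderate n; it is
  accurate to about 1–2% of a permutation Monte Carlo in the ranges
  tested.
- Exact tree fitting scans all features at every node; for feature counts
  far beyond ~10³ a histogram-based learner would be preferable.
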