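# Methods

This note records the modelling assumptions behind `mealforge`, the
parameters that matter, and the choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The synthetic study conditions

All benchmarks run on corpora from `mealforge.synth`, which emulates the
statistical shape of dietary-recall data without reproducing any real
survey:

* **Catalog.** Foods are assigned round-robin to categories (two
  subcategories each); exactly one `beverages` category exists and is
  low-energy (≈ 0.4 kcal/g). Macro densities are category profiles with
  lognormal jitter; energy density is held within 5% of the Atwater value
  4·protein + 4·carbohydrate + 9·fat. Micronutrient densities are scaled
  to daily reference values so a ~500 g meal supplies a plausible
  fraction of adequacy. Limit nutrients are calibrated against
  guidance-style energy ratios — roughly 1.15 mg sodium per kcal, 10% of
  energy from added sugars, 9% from saturated fat — with salty/sweet
  categories forming an exceeding tail. This calibration is what lets a
  typical meal satisfy the meal-energy share and the hard limit caps
  *jointly*; a food space much saltier than any guidance level would make
  those two portion invariants mutually unsatisfiable.
* **Archetypes.** Each meal type gets archetypes with one dominant
  category each (default weight 0.85), disjoint within the meal type,
  drawn from energy-dense plate categories (profile density
  ≥ 1.4 kcal/g and typical portion ≥ 30 g); beverages take a common
  share and the rest spreads thinly. Single-category dominance keeps each
  archetype's meal cloud unimodal — this is the operational meaning of
  "well separated", and it mirrors the energy-dense plates (cereal bowls,
  sandwiches, pizza) that dominate real meal archetypes. Item counts are
  1 + Poisson(λ = 3), foods are drawn Zipf(s = 1.2) within category
  without replacement, grams are lognormal (σ = 0.4) around
  category-typical medians.
* **What the generator does not emulate:** survey weights, respondent
  demographics, real food-code hierarchies, seasonal/temporal structure,
  or correlated nutrient deficiencies. Passing benchmarks therefore show
  that the machinery recovers planted structure and satisfies its stated
  constraints at realistic scale — not that effect sizes transfer to any
  real survey.

## Preprocessing

* Code harmonization applies the transitive closure of
  expanded/consolidated/renumbered mappings (cycles are an error);
  dropped/revised codes are kept. Consolidation merges grams by sum.
* LOF outlier removal runs on the clustering module's hybrid features
  (the feature set is unspecified upstream; using the same embedding as
  clustering keeps "composition outlier" consistent across stages), with
  k = 20 neighbours and contamination 0.3% by default; exactly
  round(0.003·n) meals are removed, ranked by negative outlier factor.
* Prototype aggregation is greedy facility location per subcategory.
  Food weights are total grams consumed. A step adds the food maximising
  weighted coverage (mass within cosine ≥ 0.70 of a selected prototype),
  breaking ties toward lower fidelity error and then lexicographic food
  code, until coverage ≥ 90% *and* weighted MARE ≤ 7%. Foods below the
  similarity floor become their own prototypes, so the thresholds are
  always attainable. Nutrient-density cosines are computed after scaling
  each nutrient by its catalog mean, otherwise mg-scale nutrients
  (sodium, calcium) dominate the geometry. MARE is the default fidelity
  metric; the greedy objective is submodular in its coverage part, so the
  usual (1 − 1/e) guarantee applies to that part.
* The bootstrap ingredient filter removes a food iff the lower bound of
  the percentile bootstrap CI of its mean presence is ≤ 0 — the only
  parameter-free reading of "lower bound used as a threshold"; the
  comparison value is configurable.

## Archetype discovery

Hybrid features combine a nutrient block (macro grams, energy, macro
energy shares, energy density, fiber per 1,000 kcal, macro diversity =
exp(Shannon) over macro energy shares, meal balance = 1 − Gini of macro
shares, item count, portion variability = SD of log grams) and a category
block (grams per main and subcategory), z-scored within meal type
(zero-variance columns map to 0).

Clustering is HDBSCAN per meal type on the row-L2-normalised z-features
(a cosine-like embedding that discounts overall meal size — raw z-scores
of gram features are heavy-tailed and connect clusters through
small-meal bridges). Defaults: min_cluster_size = max(15, n/200), leaf
cluster selection (fine leaves), followed by two post-processing steps:
merging cluster pairs whose centroids exceed cosine 0.95, and — for
coverage — reassignment of noise points to the nearest cluster centroid.
Leaf selection deliberately over-fragments and the merge step re-glues;
reassignment is what turns high-precision cores into full-coverage
labels. Both post-steps are separately disableable.

Profiling uses Welch t-tests (unequal sizes and variances between a
cluster and its complement), BH across all cluster × feature tests
jointly, significance at q ≤ 0.01 with |Δ| ≥ 0.15, distinctiveness at
|Δ| ≥ 0.20, Cohen's d with pooled SD. Clusters under 3 meals are flagged
unstable and skipped. Stability is subsample (80%) and recluster, ARI
against the baseline restricted to the subsample, reported as median and
a 2.5–97.5% envelope, with a non-noise-restricted variant.

## The conditional VAE

Architecture and training follow the configuration described in the
package README (64-d latent, 3 × Dense(512, GELU) with FiLM in both
encoder and decoder, 8-d embeddings, mask strength 12, Adam 5e-4 with
global-norm clipping 0.5). Implementation choices that were open:

* The network is written in numpy with hand-derived backpropagation
  (verified against numerical gradients in the test suite); single-thread
  determinism under the config seed is part of the contract.
* The encoder mirrors the decoder (FiLM in both); only the decoder side
  is fixed upstream.
* The pair prior (log-odds of within-pair prevalence, clipped to
  [1/(n+2), (n+1)/(n+2)]) is injected as an offset on the decoder output
  logits, not into the latent prior.
* β schedule: linear warmup 0 → β_max over 5 epochs, then a descending
  ramp β_max → β_min (= 0.1·β_max) per 10-epoch cycle, restarting at
  β_max — continuous at the warmup boundary and equal to the midpoint at
  mid-cycle. Free bits: 0.05 nats/dim, applied to the batch-mean KL per
  dimension.
* Dynamic pos-weight: per-batch #negatives/#positives clipped to [1, 50].
* Decode rule: top-m foods by (gated) probability with
  m = round(Σ probabilities) clamped to [1, k]; Bernoulli decoding is a
  config option. Reconstruction (z = posterior mean) does not apply the
  sampling gate, so held-out micro-F1 measures encoder/decoder capacity;
  the gate is a generation-time contract (every sampled food lies in the
  pair's allowed set).
* Ablation (`conditioning=False`, `joint_portioning=True`): FiLM
  conditioning is zeroed, gate and prior pool over meal types only, and
  the decoder additionally regresses standardised log grams of present
  foods (weight 10, putting the gram term on the same scale as the BCE).
  This is the "no archetype conditioning, no separate portioning"
  variant; the benchmark asserts its held-out reconstruction is strictly
  worse. The margin is small at synthetic scale — with a 64-d latent and
  a generous KL budget the encoder alone nearly suffices — so the
  directional claim, not an effect size, is what the benchmark
  establishes.
* Training the benchmark (2,000 meals, 200 foods) uses 150 epochs, batch
  128 — past the point where held-out micro-F1 plateaus above 0.9.

## Portion assignment

Targets: per-meal shares 25/35/40% of the daily RDI/limit table and of
2,000 kcal. The objective runs over nutrients with point targets
(protein, fiber, 11 micros) and upper limits (sodium, added sugars,
saturated fat, plus cholesterol and total sugars in deviation reports);
fat and carbohydrate carry AMDR ranges, not point targets, and enter
evaluation rather than the objective. Asymmetric weights default to 2.0
(under-adequacy and over-limit) vs 1.0. "RDI-per-kcal" is read as
aligned fractions: each meal's nutrient targets and energy target use
the same meal-type share, so targets scale with the kcal allocation.

The gradient loop is projected descent with a normalised direction and an
adaptive step (×1.3 on improvement, ×0.5 otherwise, start 2.0), bounds
[5 g, 400 g]; on 1–2-item meals it matches a 1 g grid search within 2%
relative objective (tested). Constraint stages then run in the fixed
order listed in the README. Interpretations: "group caps" default to
400 g/item, 500 g/category, 500 g beverages; the "soft" 900 g cap is hard
after rebalancing (making the invariant testable); stage 4's "sugars" is
added sugars (the nutrient with a 50 g/day guidance limit). Stage 4 never
scales up, so meals whose limit caps bind strongly can end below their
energy target; such solutions are flagged infeasible with the violated
stages listed rather than silently accepted. Energy tolerance is 1%.

## Metrics and evaluation

MER uses sodium, saturated fat and added sugars by default (configurable;
total sugars is the alternative reading). Percent reduction of RDI
deviation is "not applicable" when the real-meal median deviation is 0.
Diversity groups are main food categories with gram proportions.
Generated-vs-real comparisons bootstrap the difference in cluster
medians (1,000 resamples), flag improvement when the 95% interval lies
below zero, and BH-adjust per-cluster bootstrap p-values at 0.05.
Cross-validation stratifies folds by (cluster, meal type) round-robin;
clusters smaller than k still receive fold labels through the stratum
rotation.

## Substitution

Similarity mixes item-set Jaccard and nutrient-composition cosine at
α = 0.5; energy tolerance 15%, item-count tolerance 1. The trade-off
score is gain + θ·savings% (savings relative to the original meal's
cost); the scalarization is isolated behind the policy object since
other forms are plausible. The knee is the point of maximum
perpendicular distance from the chord joining the curve endpoints.
Transition matrices pair removed/added items greedily by nutrient
cosine; unpaired items enter the add/remove marginals. The grocery
per-100 g pricing dialect is available via `PricingModel(dialect=
"per100g")`.

## Known limitations

* Benchmark effect sizes (ARI, F1, feasibility fractions) are properties
  of the planted synthetic structure, not of any real corpus.
* The portion pipeline's stage order is fixed; a salty food set can end
  energy-deficient by design (hard limits, no upscaling after capping).
* The CVAE is CPU-bound numpy; it is sized for desk-scale corpora
  (thousands of meals), not survey scale.
* Single-threaded floating-point determinism is guaranteed for a fixed
  library stack; across BLAS implementations, discrete outputs (labels,
  sampled sets) are stable but loss traces may differ in the last digits.
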