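# Methods

`necsuff` implements an interpretable diagnosis workflow for three-class
tabular cohorts (cognitively normal CN, mild cognitive impairment MCI,
Alzheimer's disease AD): imbalance-aware multiclass classification,
feature-attribution explainers, counterfactual generation, and a
unification layer that scores how *necessary* and how *sufficient*
top-ranked features are for a model's prediction. This note records the
models, the defaults and why, the numerical choices, and the limits of
what the synthetic experiments show.

## Synthetic cohort model

Real cohorts of this kind (volumetric brain ROI features from T1 MRI plus
AD-risk SNP genotypes) are access-restricted, so the package ships a
generator with planted ground truth instead of data.

Each subject has covariates age ~ U(60, 86) years, sex ~ Bernoulli(0.5),
and total brain volume ~ N(0, 1) in standardised units. A ROI feature is

    x = beta_age * age + beta_sex * sex + beta_bv * bv + delta_c * sigma + eps,

with `eps ~ N(0, sigma^2)` and `delta_c` the class-specific standardised
shift of a *planted* feature (0 elsewhere). An SNP genotype is the sum of
two Bernoulli alleles at the class's risk-allele frequency, coded
0 / 0.5 / 1 for zero, one or two copies. Class effects sit on top of the
covariate effects so the preprocessing stage has genuine confounding to
remove.

The reference configuration (`default_cohort_spec`) uses class sizes
proportional to 449 CN / 740 MCI / 274 AD, 154 ROI and 54 SNP features,
twelve planted ROIs (eight atrophy-like negative shifts of 0.7–1.5 sd,
four enlargement-like positive shifts, MCI effects half the AD effects)
and six planted SNPs with an allele-frequency gradient 0.10 (CN) → 0.25
(MCI) → 0.40 (AD). Unplanted SNPs sit at frequency 0.2 in every class.
These effect sizes are in the range reported for medial-temporal atrophy
and ApoE-like risk alleles; the MCI-at-half-AD gradient encodes the
prodromal position of MCI. A `scale` argument shrinks the class sizes
proportionally for desk-scale runs.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, spatial correlation between ROI volumes, site/scanner effects,
non-linear covariate dependence, and longitudinal structure. Tests passing
on this generator therefore demonstrate correctness of the machinery and
recoverability of independent planted effects, not performance on real
imaging-genetic data.

## Preprocessing

One ordinary-least-squares fit per ROI feature on **control rows only**
(intercept + age + sex + brain volume); every subject is residualised
with the controls' model and z-scored by the controls' residual mean and
standard deviation. The subtracted prediction includes the intercept, so
the control residual mean is exactly zero by construction. Patients are
never refitted — that is what lets disease-associated shifts survive the
adjustment. SNP columns are ordinal genotypes and pass through untouched.
Degenerate control designs (rank-deficient covariates, zero residual
variance) are rejected rather than regularised.

## Classification

Any probabilistic binary learner can back three decomposition schemes:
one-vs-all (OVA), one-vs-one (OVO, m(m−1)/2 pair classifiers combined by
summing each pair's class probabilities and taking the argmax), and
**bagged OVO**: the majority class is randomly split into two disjoint
near-halves; two OVO ensembles are trained, each on all minority rows plus
one half of the majority; their per-class summed probabilities are
averaged before the argmax. Each bag sees a flatter class distribution
while every majority row is still used once.

Numerical choices:

* cross-bag aggregation is the probability average — the symmetric choice;
* exact score ties break by fixed alphabetical label order, for
  determinism;
* margin-only learners (e.g. un-probabilistic SVMs) are wrapped in
  Platt-style sigmoid calibration, because voting is defined on predicted
  probabilities;
* folds are stratified by class in both loops of the 5×4 nested
  cross-validation — with a minority class of a few dozen rows,
  unstratified folds can lose a class entirely;
* the inner 4-fold loop selects hyperparameters by mean balanced accuracy;
  the outer 5-fold loop reports balanced accuracy and support-weighted F1
  with mean / max / sd summaries. A single-point grid degenerates to plain
  outer CV. A stratified 80:20 train/test split mode is also provided.
* classifier comparisons use a paired two-sided t-test on fold-wise
  metrics; identical vectors return the degenerate (t = 0, p = 1).

Balanced accuracy (the unweighted mean of per-class recalls) is the
headline metric because plain accuracy is dominated by the majority class.

## Attribution

All explainers operate on one pair's binary classifier, with the
disease-positive label as the positive class (configurable; default the
alphabetically later label of the pair).

* **Gini importance** — normalised mean impurity decrease, for tree
  ensembles only.
* **Sampled Shapley values** — permutation sampling with marginal
  replacement from a seeded background subsample (default 100 rows). Each
  draw walks a random feature permutation from a random background row to
  the instance, crediting each feature with the induced probability
  change; per-draw credits sum exactly to f(instance) − f(background row),
  so efficiency holds up to Monte-Carlo error. Per-feature standard errors
  are reported. An exact enumerator over all 2^d coalitions (d ≤ 15)
  cross-checks the sampler in the tests. The global ranking is the mean
  absolute local value over an evaluation set.
* **Local surrogate** — a weighted ridge fit on a perturbation
  neighbourhood: Gaussian noise (sd 1, matching the z-scored feature
  scale) for continuous features, uniform resampling of {0, 0.5, 1} for
  SNPs, exponential kernel weights exp(−d²/w²) with default width
  0.75·√d. Coefficients are signed: positive pushes toward the positive
  class.
* **Partial dependence** — mean positive-class probability as one feature
  sweeps a grid; SNP grids are exactly {0, 0.5, 1}.

## Counterfactual generation

A counterfactual is valid iff the predicted class of the modified instance
flips. All generators respect a feature mask (the `allowed` set) — the
mechanism on which necessity and sufficiency are built — and return only
valid, de-duplicated candidates, ranked by (number of changed features,
distance). Distance is the per-feature absolute difference, scaled by the
observed range (unit range for SNPs), averaged over all features.

* `PermuteAttack` — a genetic search whose mutation swaps an allowed
  feature's value for one observed in the reference pool (population 50,
  40 generations, mutation probability 0.3, elitism 5, uniform crossover;
  all configurable). Fitness is lexicographic: flip first, then fewer
  changes, then proximity.
* `DiverseCF` — stochastic search: random candidates change a random
  subset of allowed features (continuous features uniform in the observed
  range, SNPs on {0, 0.5, 1}); from the valid ones, `n_cf` are selected
  greedily to maximise diversity_weight · mean pairwise distance −
  proximity_weight · distance (defaults 1.0 / 0.5).
* `ExhaustiveGenerator` — full enumeration over observed values; exact on
  small discrete spaces and the reference in oracle tests.

When every allowed feature is discrete and the product space fits inside
the evaluation budget, the two stochastic generators fall through to exact
enumeration: at equal budget the full scan dominates any stochastic
strategy, and it makes small-space behaviour exactly reproducible. Budget
semantics (maximum model evaluations) are unchanged.

The `budget` caps model evaluations per query; an exhausted budget with no
flip yields an empty (not exceptional) result. Returned candidates are
de-duplicated after rounding to the uniqueness precision (default 4
decimals) so that a converged population cannot report the same flip
several times.

## Necessity and sufficiency

For a target feature (or feature set) x_j with value a, over N evaluation
instances and n_cf requested counterfactuals per instance:

* **Necessity** = (valid counterfactuals produced with only x_j allowed to
  change) / (n_cf · N). A draw counts when it produced a valid flip;
  uniqueness is not required — the defining equation carries no uniqueness
  qualifier. Values lie in [0, 1].
* **Sufficiency** = A − B, where A is the unique-valid fraction with every
  feature free and B the unique-valid fraction with x_j frozen at a and
  everything else free. Unique counts use the rounding precision above and
  are capped at n_cf per instance. With stochastic generators the raw
  difference can come out negative (B sampled larger than A); both the raw
  and a zero-floored value are reported. An alternative prose-style
  reading, 1 − B, is available behind `prose_variant=True` for comparison;
  the difference form is the default because it is the printed definition.

Every instance contributes to N: in the pairwise binary setting a
counterfactual must flip that instance's own predicted class, so no
instance is ever "already in the counterfactual class".

`necsuff_report` evaluates both metrics for the top-k features of a global
ranking singly, the top-k combined, and their complement ("all but the top
features"), per generator, for n_cf ∈ {1, 2, 4, 8} plus the budget
average. Term A of sufficiency is shared across targets per (generator,
n_cf), which cuts the dominant cost roughly in half.

Under exhaustive generation, necessity is monotone in the target set (a
superset mask can reach every flip a subset can); stochastic generators
satisfy this in expectation only.

## Problem sizes in the shipped experiments

The test suite and the acceptance script run the study at desk scale:
cohorts of a few hundred subjects (15 % of the reference class sizes in
the acceptance script, keeping the 449/740/274 proportions and the full
154 + 54 feature panel), 10–25 explained instances, 50–60 Shapley samples,
counterfactual budgets of 800–2000 evaluations, and toy oracle spaces of
2–5 three-level features. These sizes were chosen so every oracle check is
exact or tightly bounded while a full run stays in the minutes range on
one CPU; the statistical conclusions (scheme ordering, planted-feature
recovery, oracle agreement) are stable across seeds at these sizes.

## Known limitations

* Proximity-first counterfactual search under-selects ordinal SNP edits:
  a genotype step (0.5 of a unit range) is usually a longer normalised
  step than the cheapest continuous ROI edit, so counterfactual-frequency
  rankings systematically favour continuous features even when an SNP
  carries comparable signal. The attribution-based rankings do not share
  this bias.
* A proximity-only generator can report zero necessity where a
  diversity-capable one finds positive necessity on the same model and
  data (it refuses long single-feature moves); necessity/sufficiency
  values are therefore always reported per generator and are not
  comparable across generators.
* Necessity and sufficiency are defined per class pair; there is no
  multiclass version here.
* All explainers assume tabular, feature-independent perturbation
  semantics; correlated features make marginal-replacement Shapley values
  and mask-constrained counterfactuals harder to interpret causally.
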