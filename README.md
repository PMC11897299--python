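# necsuff

Interpretable multiclass diagnosis for tabular imaging-genetic cohorts:
an imbalance-aware **bagged one-vs-one** classification scheme, a suite of
attribution and counterfactual explainers, and a unification layer that
scores the **necessity** and **sufficiency** of top-ranked features by
constrained counterfactual generation.

The package targets three-class cohorts of the CN / MCI / AD kind
(cognitively normal, mild cognitive impairment, Alzheimer's disease):
continuous brain region-of-interest (ROI) volume features confounded by
age, sex and total brain volume, plus ordinal SNP genotypes coded
0 / 0.5 / 1 for zero, one or two risk-allele copies. Real cohorts of this
kind are access-restricted, so a synthetic cohort generator with planted
ground truth is a first-class component: every explainer can be tested
against features known to carry signal.

## What it computes

**Classification.** The majority class (MCI, near half the data) is split
into two disjoint halves; two one-vs-one ensembles are trained, each on all
minority rows plus one half; their per-class summed probabilities are
averaged and the argmax wins. Evaluated by balanced accuracy
(mean per-class recall) and weighted F1 under a stratified 5×4 nested
cross-validation or an 80:20 split. Plain OVO and OVA are provided for
comparison.

**Explanation.** Gini importance for tree ensembles, sampled Shapley
values (permutation sampling; exact 2^d enumeration as a cross-check),
LIME-style local surrogates and partial dependence curves — all per class
pair.

**Unification.** For the top-k features of a global ranking, counterfactual
generators estimate, per instance and per counterfactual budget
n_cf ∈ {1, 2, 4, 8}:

- Necessity = (valid counterfactuals produced when **only** the target may
  change) / (n_cf · N) — how indispensable the target is;
- Sufficiency = (unique valid counterfactuals with all features free −
  unique valid counterfactuals with the target **frozen**) / (n_cf · N) —
  how far the target alone pins the prediction down.

Two generator styles are built in: a proximity-seeking genetic search
(`PermuteAttack`, mutations drawn from observed values) and a
diversity-aware stochastic search (`DiverseCF`), plus an exhaustive
enumerator for small discrete spaces.

## Worked example

```python
import numpy as np
from sklearn.linear_model import LogisticRegression
from necsuff import (
    default_cohort_spec, generate_cohort, fit_residualizer,
    apply_residualize_zscore, train_test_split_eval, fit_pair_model,
    global_shapley_ranking, necessity, sufficiency, PermuteAttack, DiverseCF,
)

spec = default_cohort_spec(seed=0, scale=0.15)   # ~219 subjects, 449:740:274 ratio
cohort = generate_cohort(spec)
z = apply_residualize_zscore(fit_residualizer(cohort, "CN"), cohort)

res = train_test_split_eval(z.features, z.labels,
                            LogisticRegression(max_iter=2000),
                            scheme="bagged-ovo", seed=0)
print(f"bagged-OVO balanced accuracy: {res['balanced_accuracy']:.3f}")
print(f"bagged-OVO weighted F1:       {res['weighted_f1']:.3f}")

pair = fit_pair_model(z.features, z.labels, ("MCI", "AD"),
                      LogisticRegression(max_iter=2000), positive="AD")
rows = z.features[np.isin(z.labels, ["AD", "MCI"])]
rng = np.random.default_rng(0)
bg = rows[rng.choice(len(rows), 100, replace=False)]
ev = rows[rng.choice(len(rows), 12, replace=False)]
ranking = global_shapley_ranking(pair, bg, ev, n_samples=50, seed=0)
top = int(ranking.top(1)[0])
print(f"top SHAP feature: {cohort.feature_names[top]}")

for gen_name, gen in (("permute", PermuteAttack()), ("diverse", DiverseCF())):
    nec = necessity(pair, ev, [top], gen, n_cf=4, seed=1,
                    reference_pool=rows, feature_kinds=z.feature_kinds, budget=800)
    suf = sufficiency(pair, ev, [top], gen, n_cf=4, seed=1,
                      reference_pool=rows, feature_kinds=z.feature_kinds, budget=800)
    print(f"{gen_name:8s} necessity={nec:.3f}  sufficiency={suf:.3f}")
```

Output:

```
bagged-OVO balanced accuracy: 0.746
bagged-OVO weighted F1:       0.628
top SHAP feature: roi_001
permute  necessity=0.333  sufficiency=0.000
diverse  necessity=0.417  sufficiency=0.000
```

Reading it: the two-bag OVO ensemble separates the three synthetic classes
well above the 1/3 chance level; the top-ranked feature is one of the
planted ROIs (`roi_001`, a planted enlargement effect); changing that
feature alone flips the MCI-vs-AD prediction for roughly a third of
requested counterfactual draws (its necessity), more often under the
diversity-seeking generator; and freezing it barely reduces the number of
distinct counterfactuals reachable through the other 207 features (its
sufficiency ≈ 0) — with a feature panel this wide, no single feature pins
the prediction down, while it can still be individually necessary.

A command-line interface mirrors the stages
(`necsuff simulate | preprocess | train | evaluate | explain |
counterfactual | unify | run`); `necsuff run --config config.yaml` drives
the whole pipeline from one file. See `docs/methods.md` for the models,
defaults and limitations.

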