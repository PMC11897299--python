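"""Unifying feature attributions with counterfactual explanations.

Two complementary bridges between attribution rankings and counterfactual
generation:

* **Counterfactual-frequency attribution** — generate one counterfactual
  per test instance with every feature free to change, and score each
  feature by the fraction of counterfactuals that modified it (with the
  majority sign of the change).  Important features get edited often.

* **Necessity and sufficiency** of a feature (or feature set) ``x_j = a``
  for the model's output, estimated by constrained generation:

  - *necessity* = (valid counterfactuals produced when **only** ``x_j``
    may change) / (n_cf * N) — in [0, 1]; how indispensable the target is.
  - *sufficiency* = (unique valid counterfactuals with **all** features
    free) / (n_cf * N) minus (unique valid counterfactuals with ``x_j``
    **frozen**, everything else free) / (n_cf * N) — how far fixing the
    target alone pins down the output.  With stochastic generators the raw
    difference can come out negative; a zero-floored value is reported
    alongside it.  A prose-variant reading (1 minus the frozen-target
    unique fraction) is available behind ``prose_variant=True``.

``necsuff_report`` evaluates both metrics for each of the top-k ranked
features singly, the top-k combined, and their complement, per generator
and per counterfactual budget n_cf in {1, 2, 4, 8}, plus the
budget-averaged value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._common import BinaryModel, ContractError, child_seed
from .attribution import AttributionResult
from .counterfactual import CounterfactualQuery, CounterfactualSet

__all__ = [
    "FrequencyAttribution",
    "NecSuffReport",
    "cf_frequency_attribution",
    "necessity",
    "sufficiency",
    "necsuff_report",
    "DEFAULT_BUDGETS",
]

Generator = Callable[[CounterfactualQuery], CounterfactualSet]
DEFAULT_BUDGETS = (1, 2, 4, 8)


@dataclass
class FrequencyAttribution:
    """Per-feature modification statistics over generated counterfactuals."""

    counts: np.ndarray  # times each feature was modified
    fractions: np.ndarray  # counts / total counterfactuals generated
    directions: np.ndarray  # majority sign of the change (+1/-1/0)
    n_instances: int
    n_counterfactuals: int  # valid counterfactuals generated
    n_no_counterfactual: int  # instances yielding none
    feature_names: list[str] | None = None

    @property
    def ordering(self) -> np.ndarray:
        return np.argsort(-self.fractions, kind="stable")


def _queries(
    model: BinaryModel,
    evaluation_set: np.ndarray,
    allowed: Sequence[int],
    n_cf: int,
    seed: int,
    reference_pool: np.ndarray | None,
    feature_kinds: Sequence[str] | None,
    budget: int,
):
    evaluation_set = np.atleast_2d(np.asarray(evaluation_set, dtype=float))
    if evaluation_set.shape[0] == 0:
        raise ContractError("evaluation set is empty")
    pool = evaluation_set if reference_pool is None else reference_pool
    rng = np.random.default_rng(seed)
    for row in evaluation_set:
        yield CounterfactualQuery(
            instance=row,
            model=model,
            allowed=allowed,
            n_cf=n_cf,
            budget=budget,
            reference_pool=pool,
            seed=child_seed(rng),
            feature_kinds=feature_kinds,
        )


def cf_frequency_attribution(
    model: BinaryModel,
    evaluation_set: np.ndarray,
    generator: Generator,
    seed: int = 0,
    reference_pool: np.ndarray | None = None,
    feature_kinds: Sequence[str] | None = None,
    budget: int = 2000,
    feature_names: Sequence[str] | None = None,
) -> FrequencyAttribution:
    """One counterfactual per instance, all features free; count edits."""
    evaluation_set = np.atleast_2d(np.asarray(evaluation_set, dtype=float))
    d = evaluation_set.shape[1]
    counts = np.zeros(d)
    signs = np.zeros(d)
    n_cfs = 0
    n_missing = 0
    for q in _queries(model, evaluation_set, range(d), 1, seed,
                      reference_pool, feature_kinds, budget):
        cfset = generator(q)
        if cfset.n_valid == 0:
            n_missing += 1
            continue
        n_cfs += cfset.n_valid
        for changed in cfset.changed_features:
            for j, s in changed.items():
                counts[j] += 1
                signs[j] += s
    fractions = counts / n_cfs if n_cfs else np.zeros(d)
    return FrequencyAttribution(
        counts=counts,
        fractions=fractions,
        directions=np.sign(signs).astype(int),
        n_instances=evaluation_set.shape[0],
        n_counterfactuals=n_cfs,
        n_no_counterfactual=n_missing,
        feature_names=list(feature_names) if feature_names else None,
    )


def _as_target(target, d: int) -> np.ndarray:
    tgt = np.atleast_1d(np.asarray(target, dtype=int))
    if tgt.size == 0:
        raise ContractError("target feature set is empty")
    if tgt.min() < 0 or tgt.max() >= d:
        raise ContractError(f"target features {tgt.tolist()} outside [0, {d})")
    return tgt


def necessity(
    model: BinaryModel,
    evaluation_set: np.ndarray,
    target,
    generator: Generator,
    n_cf: int = 1,
    seed: int = 0,
    reference_pool: np.ndarray | None = None,
    feature_kinds: Sequence[str] | None = None,
    budget: int = 2000,
) -> float:
    """Fraction of counterfactual draws that succeed changing only the target.

    For each of the N evaluation instances, ``n_cf`` counterfactuals are
    requested with the mask restricted to the target feature(s); the
    metric is (total valid counterfactuals produced) / (n_cf * N).
    """
    evaluation_set = np.atleast_2d(np.asarray(evaluation_set, dtype=float))
    tgt = _as_target(target, evaluation_set.shape[1])
    produced = 0
    for q in _queries(model, evaluation_set, tgt, n_cf, seed,
                      reference_pool, feature_kinds, budget):
        produced += generator(q).n_valid
    return produced / (n_cf * evaluation_set.shape[0])


def _unique_fraction(
    model, evaluation_set, allowed, generator, n_cf, seed,
    reference_pool, feature_kinds, budget,
) -> float:
    total = 0
    for q in _queries(model, evaluation_set, allowed, n_cf, seed,
                      reference_pool, feature_kinds, budget):
        total += min(generator(q).unique_valid_count, n_cf)
    return total / (n_cf * evaluation_set.shape[0])


def sufficiency(
    model: BinaryModel,
    evaluation_set: np.ndarray,
    target,
    generator: Generator,
    n_cf: int = 1,
    seed: int = 0,
    reference_pool: np.ndarray | None = None,
    feature_kinds: Sequence[str] | None = None,
    budget: int = 2000,
    prose_variant: bool = False,
) -> float:
    """Drop in unique valid counterfactuals caused by freezing the target.

    Term A: unique-valid fraction with every feature allowed to change.
    Term B: unique-valid fraction with the target frozen at its original
    value and all other features free.  Returns A - B (the printed
    definition); with ``prose_variant=True`` returns 1 - B instead.
    """
    evaluation_set = np.atleast_2d(np.asarray(evaluation_set, dtype=float))
    d = evaluation_set.shape[1]
    tgt = _as_target(target, d)
    complement = np.setdiff1d(np.arange(d), tgt)
    term_b = _unique_fraction(
        model, evaluation_set, complement, generator, n_cf, seed + 1,
        reference_pool, feature_kinds, budget,
    )
    if prose_variant:
        return 1.0 - term_b
    term_a = _unique_fraction(
        model, evaluation_set, np.arange(d), generator, n_cf, seed,
        reference_pool, feature_kinds, budget,
    )
    return term_a - term_b


@dataclass
class NecSuffReport:
    """Necessity/sufficiency of ranked-feature targets per generator & budget.

    ``entries[(generator, target_name)]`` holds per-budget dictionaries for
    necessity, raw sufficiency and zero-floored sufficiency, each with a
    ``"mean"`` over the budgets.  Targets are the top-k ranked features
    singly, the top-k combined, and the complement of the top-k.
    """

    entries: dict = field(default_factory=dict)
    n_instances: int = 0
    budgets: tuple = DEFAULT_BUDGETS
    ranking_method: str = ""
    top_features: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (gen, target), vals in self.entries.items():
            for metric in ("necessity", "sufficiency_raw", "sufficiency"):
                for b, v in vals[metric].items():
                    rows.append(
                        {"generator": gen, "target": target, "metric": metric,
                         "n_cf": b, "value": v}
                    )
        return pd.DataFrame(rows)


def necsuff_report(
    model: BinaryModel,
    evaluation_set: np.ndarray,
    ranking: AttributionResult,
    k: int,
    generators: Mapping[str, Generator],
    seed: int = 0,
    budgets: Sequence[int] = DEFAULT_BUDGETS,
    reference_pool: np.ndarray | None = None,
    feature_kinds: Sequence[str] | None = None,
    budget: int = 2000,
) -> NecSuffReport:
    """Necessity/sufficiency for the top-k ranked features (Fig.-6-style).

    ``ranking`` must be a global attribution result; its top-k features
    define k single-feature targets plus the combined top-k set and the
    complement set ("all but the top features").
    """
    if ranking.scope != "global":
        raise ContractError("ranking must be a global attribution result")
    evaluation_set = np.atleast_2d(np.asarray(evaluation_set, dtype=float))
    d = evaluation_set.shape[1]
    if k < 1 or k > d:
        raise ContractError(f"k={k} outside [1, {d}]")
    top = [int(j) for j in ranking.top(k)]
    complement = [int(j) for j in np.setdiff1d(np.arange(d), top)]
    targets: list[tuple[str, list[int]]] = [
        (f"top{r + 1}_feature_{j}", [j]) for r, j in enumerate(top)
    ]
    targets.append(("top_k_combined", top))
    if complement:
        targets.append(("complement", complement))

    report = NecSuffReport(
        n_instances=evaluation_set.shape[0],
        budgets=tuple(budgets),
        ranking_method=ranking.method,
        top_features=top,
    )
    rng = np.random.default_rng(seed)
    for gen_name, gen in generators.items():
        # term A of sufficiency depends only on (generator, n_cf): share it
        term_a = {
            b: _unique_fraction(
                model, evaluation_set, np.arange(d), gen, b, child_seed(rng),
                reference_pool, feature_kinds, budget,
            )
            for b in budgets
        }
        for tname, tgt in targets:
            nec, suff_raw = {}, {}
            for b in budgets:
                nec[b] = necessity(
                    model, evaluation_set, tgt, gen, b, child_seed(rng),
                    reference_pool, feature_kinds, budget,
                )
                term_b = _unique_fraction(
                    model, evaluation_set,
                    np.setdiff1d(np.arange(d), tgt), gen, b, child_seed(rng),
                    reference_pool, feature_kinds, budget,
                )
                suff_raw[b] = term_a[b] - term_b
            nec["mean"] = float(np.mean([nec[b] for b in budgets]))
            suff_raw["mean"] = float(np.mean([suff_raw[b] for b in budgets]))
            report.entries[(gen_name, tname)] = {
                "necessity": nec,
                "sufficiency_raw": suff_raw,
                "sufficiency": {b: max(0.0, v) for b, v in suff_raw.items()},
            }
    return report
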