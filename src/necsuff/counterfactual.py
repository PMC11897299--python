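"""Counterfactual example generation under feature-change constraints.

A *counterfactual* for an instance is a modified copy that the binary
model assigns to the opposite class ("valid" = the argmax prediction
flips).  All generators honour a mask: only features in the query's
``allowed`` set may change; everything else is frozen at the instance's
value.  That mask is the mechanism behind the necessity / sufficiency
metrics built on top of this module.

Three generators, sharing the :class:`CounterfactualQuery` /
:class:`CounterfactualSet` interface:

* :class:`PermuteAttack` — a genetic search whose mutation swaps an
  allowed feature's value for one observed in the reference pool; fitness
  rewards a class flip first, then fewer changed features, then smaller
  distance — a proximity-seeking search.
* :class:`DiverseCF` — an iterated stochastic search balancing validity,
  proximity and diversity among the returned candidates; continuous
  features may take any value in the observed range, not only pool values.
* :class:`ExhaustiveGenerator` — full enumeration of mask-respecting
  candidates over the pool's observed values; exact on small discrete
  spaces, used as the reference generator.

Distance is the per-feature range-normalised absolute difference averaged
over all features; SNP-kind features only ever take values in {0, 0.5, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

from ._common import BinaryModel, ContractError, ParameterError, pos_prob

__all__ = [
    "CounterfactualQuery",
    "CounterfactualSet",
    "PermuteAttack",
    "DiverseCF",
    "ExhaustiveGenerator",
    "permute_attack",
    "diverse_cf",
    "validate_counterfactual",
    "count_unique_valid",
]

SNP_LEVELS = np.array([0.0, 0.5, 1.0])


@dataclass
class CounterfactualQuery:
    """One counterfactual request: instance, model, mask and budget."""

    instance: np.ndarray
    model: BinaryModel
    allowed: Sequence[int]  # feature ids permitted to change
    n_cf: int = 1
    budget: int = 2000  # max candidate model evaluations
    reference_pool: np.ndarray | None = None  # rows supplying observed values
    seed: int = 0
    feature_kinds: Sequence[str] | None = None  # 'roi' (continuous) | 'snp'
    rounding: int = 4  # decimals for uniqueness

    def __post_init__(self) -> None:
        self.instance = np.asarray(self.instance, dtype=float).reshape(-1)
        d = self.instance.size
        self.allowed = np.asarray(sorted(set(int(a) for a in self.allowed)), dtype=int)
        if self.allowed.size and (
            self.allowed.min() < 0 or self.allowed.max() >= d
        ):
            raise ContractError(
                f"allowed feature ids {self.allowed.tolist()} outside [0, {d})"
            )
        if self.n_cf < 1:
            raise ParameterError(f"n_cf must be >= 1, got {self.n_cf}")
        if self.reference_pool is None:
            raise ContractError("reference_pool must be provided and non-empty")
        self.reference_pool = np.atleast_2d(
            np.asarray(self.reference_pool, dtype=float)
        )
        if self.reference_pool.shape[0] == 0:
            raise ContractError("reference_pool is empty")
        if self.reference_pool.shape[1] != d:
            raise ContractError("reference_pool width does not match the instance")
        if self.feature_kinds is None:
            self.feature_kinds = ["roi"] * d
        self.feature_kinds = list(self.feature_kinds)

    # -- derived geometry ---------------------------------------------------

    def pool_values(self, j: int) -> np.ndarray:
        """Distinct observed values of feature ``j`` ({0,0.5,1} for SNPs)."""
        if self.feature_kinds[j] == "snp":
            return SNP_LEVELS.copy()
        return np.unique(self.reference_pool[:, j])

    def ranges(self) -> np.ndarray:
        lo = self.reference_pool.min(axis=0)
        hi = self.reference_pool.max(axis=0)
        r = hi - lo
        snp = np.asarray([k == "snp" for k in self.feature_kinds])
        r[snp] = 1.0
        return np.where(r > 0, r, 1.0)

    def distance(self, candidates: np.ndarray) -> np.ndarray:
        """Mean over features of range-normalised |candidate - instance|."""
        diff = np.abs(np.atleast_2d(candidates) - self.instance) / self.ranges()
        return diff.mean(axis=1)


@dataclass
class CounterfactualSet:
    """Valid counterfactual candidates plus bookkeeping.

    Generators only surface valid, de-duplicated candidates, so
    ``validity`` is all-True and ``unique_valid_count == len(candidates)``;
    the fields exist so externally assembled sets can carry invalid ones.
    """

    instance: np.ndarray
    candidates: np.ndarray  # (k, d)
    validity: np.ndarray  # (k,) bool
    changed_features: list[dict[int, int]]  # per candidate: {feature: sign}
    distances: np.ndarray
    n_requested: int
    n_evaluated: int = 0

    @property
    def unique_valid_count(self) -> int:
        return count_unique_valid(self)

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.validity))


def validate_counterfactual(
    model: BinaryModel, instance: np.ndarray, candidate: np.ndarray
) -> bool:
    """True iff the candidate's predicted class differs from the instance's."""
    p = pos_prob(model, np.vstack([np.atleast_2d(instance),
                                   np.atleast_2d(candidate)]))
    return bool((p[0] > 0.5) != (p[1] > 0.5))


def count_unique_valid(cfset: CounterfactualSet, rounding: int = 4) -> int:
    """Distinct valid candidates after rounding to ``rounding`` decimals."""
    valid = cfset.candidates[cfset.validity]
    if valid.shape[0] == 0:
        return 0
    return np.unique(np.round(valid, rounding), axis=0).shape[0]


def _changed(query: CounterfactualQuery, cand: np.ndarray) -> dict[int, int]:
    diff = cand - query.instance
    return {int(j): int(np.sign(diff[j])) for j in np.flatnonzero(diff != 0)}


def _package(
    query: CounterfactualQuery, valid_cands: np.ndarray, n_evaluated: int
) -> CounterfactualSet:
    """Dedupe, rank by (n changed, distance) and keep the best n_cf."""
    if valid_cands.shape[0]:
        _, idx = np.unique(
            np.round(valid_cands, query.rounding), axis=0, return_index=True
        )
        valid_cands = valid_cands[np.sort(idx)]
        n_changed = (valid_cands != query.instance).sum(axis=1)
        dist = query.distance(valid_cands)
        order = np.lexsort((dist, n_changed))
        valid_cands = valid_cands[order[: query.n_cf]]
    dist = query.distance(valid_cands) if valid_cands.shape[0] else np.empty(0)
    return CounterfactualSet(
        instance=query.instance.copy(),
        candidates=valid_cands,
        validity=np.ones(valid_cands.shape[0], dtype=bool),
        changed_features=[_changed(query, c) for c in valid_cands],
        distances=dist,
        n_requested=query.n_cf,
        n_evaluated=n_evaluated,
    )


def _orig_class(query: CounterfactualQuery) -> int:
    return int(pos_prob(query.model, query.instance[None, :])[0] > 0.5)


def _small_space(query: CounterfactualQuery) -> np.ndarray | None:
    """The full discrete candidate space, if it fits in the budget.

    When every allowed feature is discrete (SNP-kind or few observed pool
    values) and the product space is no larger than the evaluation budget,
    exhaustive scan dominates any stochastic search at the same budget, so
    the stochastic generators fall through to it.  Returns None otherwise.
    """
    pools = [query.pool_values(int(j)) for j in query.allowed]
    sizes = [p.size for p in pools]
    if any(s > 16 for s in sizes):
        return None
    total = int(np.prod(sizes))
    if total > query.budget:
        return None
    cands = np.tile(query.instance, (total, 1))
    for row, combo in zip(cands, product(*pools)):
        row[query.allowed] = combo
    return cands[np.any(cands != query.instance, axis=1)]


def _valid_from(query: CounterfactualQuery, cands: np.ndarray) -> np.ndarray:
    orig = _orig_class(query)
    p = pos_prob(query.model, cands)
    return cands[(p > 0.5).astype(int) != orig]


# ---------------------------------------------------------------------------
# genetic, proximity-seeking search


@dataclass
class PermuteAttack:
    """Genetic counterfactual search mutating features to pool values.

    Fitness is lexicographic: class flip first, then fewer changed
    features, then smaller normalised distance — so the search gravitates
    toward minimal, proximal edits.  Mutation replaces one allowed
    feature's value with a value of that feature observed in the reference
    pool, which keeps every candidate inside the observed data manifold.
    """

    population: int = 50
    generations: int = 40
    mutation_p: float = 0.3
    elitism: int = 5

    def __call__(self, query: CounterfactualQuery) -> CounterfactualSet:
        rng = np.random.default_rng(query.seed)
        allowed = query.allowed
        if allowed.size == 0:
            return _package(query, np.empty((0, query.instance.size)), 0)
        small = _small_space(query)
        if small is not None:
            return _package(query, _valid_from(query, small), small.shape[0])
        orig = _orig_class(query)
        pools = {int(j): query.pool_values(j) for j in allowed}

        def mutate(rows: np.ndarray) -> None:
            for r in rows:
                j = int(allowed[rng.integers(allowed.size)])
                r[j] = pools[j][rng.integers(pools[j].size)]

        # seed the population with perturbations of random allowed subsets so
        # flips needing several simultaneous changes stay reachable
        pop = np.tile(query.instance, (self.population, 1))
        for r in pop:
            k = int(rng.integers(1, allowed.size + 1))
            for j in rng.choice(allowed, size=k, replace=False):
                j = int(j)
                r[j] = pools[j][rng.integers(pools[j].size)]

        archive: list[np.ndarray] = []
        evaluated = 0
        gen = 0
        while evaluated < query.budget and gen < self.generations:
            take = min(self.population, query.budget - evaluated)
            pop = pop[:take]
            p = pos_prob(query.model, pop)
            evaluated += take
            flipped = (p > 0.5).astype(int) != orig
            archive.extend(pop[flipped])
            n_changed = (pop != query.instance).sum(axis=1)
            dist = query.distance(pop)
            fitness = flipped * 1e6 - n_changed * 1e3 - dist
            order = np.argsort(-fitness, kind="stable")
            elite = pop[order[: self.elitism]]

            children = []
            while len(children) < self.population - elite.shape[0]:
                i, j = rng.integers(pop.shape[0], size=2)
                a, b = pop[order[min(i, j)]], pop[order[max(i, j)]]  # tournament
                child = a.copy()
                swap = rng.random(allowed.size) < 0.5  # uniform crossover
                child[allowed[swap]] = b[allowed[swap]]
                if rng.random() < self.mutation_p:
                    mutate(child[None, :])
                children.append(child)
            pop = np.vstack([elite, np.asarray(children)])
            gen += 1
        valid = np.asarray(archive) if archive else np.empty((0, query.instance.size))
        return _package(query, valid, evaluated)


def permute_attack(query: CounterfactualQuery, **params) -> CounterfactualSet:
    return PermuteAttack(**params)(query)


# ---------------------------------------------------------------------------
# diversity-aware stochastic search


@dataclass
class DiverseCF:
    """Stochastic search trading off proximity against candidate diversity.

    Candidates are drawn by changing a random subset of allowed features —
    continuous features to uniform values in the observed range, SNP-kind
    features to a random level in {0, 0.5, 1} — until the evaluation
    budget is spent.  From the valid candidates, ``n_cf`` are selected
    greedily to maximise
    ``diversity_weight * mean pairwise distance - proximity_weight * distance``.
    """

    diversity_weight: float = 1.0
    proximity_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.diversity_weight < 0 or self.proximity_weight < 0:
            raise ParameterError("diversity and proximity weights must be >= 0")

    def __call__(self, query: CounterfactualQuery) -> CounterfactualSet:
        rng = np.random.default_rng(query.seed)
        allowed = query.allowed
        d = query.instance.size
        if allowed.size == 0:
            return _package(query, np.empty((0, d)), 0)
        if all(query.feature_kinds[int(j)] == "snp" for j in allowed):
            small = _small_space(query)
            if small is not None:
                return self._select(
                    query, _valid_from(query, small), small.shape[0]
                )
        orig = _orig_class(query)
        lo = query.reference_pool.min(axis=0)
        hi = query.reference_pool.max(axis=0)
        pools = {int(j): query.pool_values(j) for j in allowed}

        batch = 256
        evaluated = 0
        valid: list[np.ndarray] = []
        while evaluated < query.budget:
            take = min(batch, query.budget - evaluated)
            cands = np.tile(query.instance, (take, 1))
            # change between 1 and |allowed| features per candidate
            k = rng.integers(1, allowed.size + 1, size=take)
            for r in range(take):
                feats = rng.choice(allowed, size=k[r], replace=False)
                for j in feats:
                    j = int(j)
                    if query.feature_kinds[j] == "snp":
                        cands[r, j] = pools[j][rng.integers(pools[j].size)]
                    else:
                        cands[r, j] = rng.uniform(lo[j], hi[j])
            p = pos_prob(query.model, cands)
            evaluated += take
            flipped = (p > 0.5).astype(int) != orig
            valid.extend(cands[flipped])
        valid_arr = np.asarray(valid) if valid else np.empty((0, d))
        return self._select(query, valid_arr, evaluated)

    def _select(
        self, query: CounterfactualQuery, valid: np.ndarray, evaluated: int
    ) -> CounterfactualSet:
        if valid.shape[0] == 0:
            return _package(query, valid, evaluated)
        _, idx = np.unique(np.round(valid, query.rounding), axis=0, return_index=True)
        valid = valid[np.sort(idx)]
        dist = query.distance(valid)
        chosen: list[int] = [int(np.argmin(dist))]
        ranges = query.ranges()
        while len(chosen) < min(query.n_cf, valid.shape[0]):
            best, best_score = None, -np.inf
            sel = valid[chosen]
            for i in range(valid.shape[0]):
                if i in chosen:
                    continue
                pair_d = np.abs(sel - valid[i]) / ranges
                score = (
                    self.diversity_weight * pair_d.mean()
                    - self.proximity_weight * dist[i]
                )
                if score > best_score:
                    best, best_score = i, score
            chosen.append(best)
        picked = valid[chosen]
        return CounterfactualSet(
            instance=query.instance.copy(),
            candidates=picked,
            validity=np.ones(picked.shape[0], dtype=bool),
            changed_features=[_changed(query, c) for c in picked],
            distances=query.distance(picked),
            n_requested=query.n_cf,
            n_evaluated=evaluated,
        )


def diverse_cf(
    query: CounterfactualQuery,
    diversity_weight: float = 1.0,
    proximity_weight: float = 0.5,
) -> CounterfactualSet:
    return DiverseCF(diversity_weight, proximity_weight)(query)


# ---------------------------------------------------------------------------
# exhaustive reference generator


@dataclass
class ExhaustiveGenerator:
    """Enumerate every mask-respecting candidate over observed pool values.

    Exact on small discrete spaces: a flip is found iff one is reachable
    through the mask, and the returned candidates are the (n changed,
    distance)-best distinct valid ones.  Raises if the product space
    exceeds ``max_candidates``.
    """

    max_candidates: int = 200_000

    def __call__(self, query: CounterfactualQuery) -> CounterfactualSet:
        allowed = query.allowed
        d = query.instance.size
        if allowed.size == 0:
            return _package(query, np.empty((0, d)), 0)
        pools = [query.pool_values(int(j)) for j in allowed]
        total = int(np.prod([p.size for p in pools]))
        if total > self.max_candidates:
            raise ParameterError(
                f"enumeration space has {total} candidates "
                f"(> {self.max_candidates}); use a stochastic generator"
            )
        cands = np.tile(query.instance, (total, 1))
        for row, combo in zip(cands, product(*pools)):
            row[allowed] = combo
        keep = np.any(cands != query.instance, axis=1)
        cands = cands[keep]
        if cands.shape[0] == 0:
            return _package(query, np.empty((0, d)), 0)
        orig = _orig_class(query)
        p = pos_prob(query.model, cands)
        flipped = (p > 0.5).astype(int) != orig
        return _package(query, cands[flipped], cands.shape[0])
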