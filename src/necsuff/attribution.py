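"""Feature-attribution explainers for binary probability models.

Four complementary views of feature importance, all defined on one OVO
pair's binary classifier (positive class = disease-positive label):

* ``gini_importance`` — global, impurity-based, for tree ensembles;
* ``sampled_shapley`` / ``global_shapley_ranking`` — local Shapley values
  by permutation sampling with marginal (interventional) replacement from
  a background sample, and the mean-|value| global ranking built from
  them;
* ``exact_shapley`` — exhaustive coalition enumeration, tractable for
  small d, used to cross-check the sampler;
* ``local_surrogate`` — a LIME-style weighted ridge fit on a perturbation
  neighbourhood, giving signed local coefficients;
* ``partial_dependence`` — the model's mean positive-class probability as
  one feature sweeps a grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial
from typing import Sequence

import numpy as np
from sklearn.linear_model import Ridge

from ._common import (
    BinaryModel,
    ContractError,
    MethodNotApplicableError,
    ParameterError,
    pos_prob,
)

__all__ = [
    "AttributionResult",
    "PDPCurve",
    "gini_importance",
    "sampled_shapley",
    "exact_shapley",
    "global_shapley_ranking",
    "local_surrogate",
    "partial_dependence",
]


@dataclass
class AttributionResult:
    """Per-feature importance values and the ranking they imply.

    Global results hold nonnegative values and are ordered by descending
    value; local results are signed and ordered by descending magnitude.
    """

    values: np.ndarray
    method: str  # gini | shapley | surrogate | pdp
    scope: str  # "global" or an instance identifier
    feature_names: list[str] | None = None
    stderr: np.ndarray | None = None
    baseline: float | None = None  # mean background prediction (shapley)

    @property
    def ordering(self) -> np.ndarray:
        key = self.values if self.scope == "global" else np.abs(self.values)
        return np.argsort(-key, kind="stable")

    def top(self, k: int) -> np.ndarray:
        return self.ordering[:k]


@dataclass
class PDPCurve:
    """Partial-dependence curve of one feature."""

    feature: int
    grid: np.ndarray
    mean_probability: np.ndarray
    feature_name: str | None = None


def gini_importance(model, feature_names: Sequence[str] | None = None) -> AttributionResult:
    """Normalised mean impurity decrease of a fitted tree ensemble."""
    est = model
    if not hasattr(est, "feature_importances_"):  # unwrap PairModel
        est = getattr(model, "estimator_", model)
    if not hasattr(est, "feature_importances_"):
        raise MethodNotApplicableError(
            f"{type(est).__name__} is not an impurity-based tree ensemble"
        )
    vals = np.asarray(est.feature_importances_, dtype=float)
    total = vals.sum()
    if total > 0:
        vals = vals / total
    return AttributionResult(
        values=vals, method="gini", scope="global",
        feature_names=list(feature_names) if feature_names else None,
    )


# ---------------------------------------------------------------------------
# Shapley values


def sampled_shapley(
    model: BinaryModel,
    background: np.ndarray,
    instance: np.ndarray,
    n_samples: int = 200,
    seed: int = 0,
) -> AttributionResult:
    """Permutation-sampling Shapley estimate for one instance.

    For each of ``n_samples`` draws: take a random feature permutation and
    a random background row, then walk the permutation switching features
    from the background value to the instance value, crediting each feature
    with the induced change in positive-class probability.  The estimate is
    the average credit; per-sample credits sum exactly to
    f(instance) - f(background row), so the averaged attributions satisfy
    the efficiency axiom up to Monte-Carlo error in the background mean.
    """
    if n_samples < 1:
        raise ParameterError(f"n_samples must be >= 1, got {n_samples}")
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ContractError("background sample is empty")
    x = np.asarray(instance, dtype=float).reshape(-1)
    d = x.size
    rng = np.random.default_rng(seed)

    contribs = np.empty((n_samples, d))
    for s in range(n_samples):
        perm = rng.permutation(d)
        b = background[rng.integers(background.shape[0])]
        # rows[0] = background row; rows[j] has the first j permuted features
        # switched to the instance's values
        rows = np.tile(b, (d + 1, 1))
        for j, k in enumerate(perm, start=1):
            rows[j:, k] = x[k]
        f = pos_prob(model, rows)
        contribs[s, perm] = np.diff(f)
    phi = contribs.mean(axis=0)
    sem = (
        contribs.std(axis=0, ddof=1) / np.sqrt(n_samples)
        if n_samples > 1
        else np.full(d, np.inf)
    )
    return AttributionResult(
        values=phi,
        method="shapley",
        scope="instance",
        stderr=sem,
        baseline=float(pos_prob(model, background).mean()),
    )


def exact_shapley(
    model: BinaryModel, background: np.ndarray, instance: np.ndarray
) -> AttributionResult:
    """Exact Shapley values by enumerating all 2^d coalitions.

    The value of a coalition S is the background-averaged prediction with
    features in S fixed to the instance (marginal expectation).  Only
    sensible for small d (hard limit 15).
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    x = np.asarray(instance, dtype=float).reshape(-1)
    d = x.size
    if d > 15:
        raise ParameterError(f"exact enumeration infeasible for d={d} > 15")
    nb = background.shape[0]

    def coalition_value(S: tuple[int, ...]) -> float:
        rows = background.copy()
        if S:
            rows[:, list(S)] = x[list(S)]
        return float(pos_prob(model, rows).mean())

    values = {
        S: coalition_value(S)
        for r in range(d + 1)
        for S in combinations(range(d), r)
    }
    phi = np.zeros(d)
    for k in range(d):
        others = [i for i in range(d) if i != k]
        for r in range(d):
            w = factorial(r) * factorial(d - r - 1) / factorial(d)
            for S in combinations(others, r):
                phi[k] += w * (values[tuple(sorted(S + (k,)))] - values[S])
    return AttributionResult(
        values=phi,
        method="shapley",
        scope="instance",
        baseline=float(pos_prob(model, background).mean()),
    )


def global_shapley_ranking(
    model: BinaryModel,
    background: np.ndarray,
    evaluation_set: np.ndarray,
    n_samples: int = 200,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> AttributionResult:
    """Mean absolute sampled Shapley value over an evaluation set."""
    evaluation_set = np.atleast_2d(np.asarray(evaluation_set, dtype=float))
    if evaluation_set.shape[0] == 0:
        raise ContractError("evaluation set is empty")
    rng = np.random.default_rng(seed)
    acc = np.zeros(evaluation_set.shape[1])
    for row in evaluation_set:
        local = sampled_shapley(
            model, background, row, n_samples=n_samples,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        acc += np.abs(local.values)
    return AttributionResult(
        values=acc / evaluation_set.shape[0],
        method="shapley",
        scope="global",
        feature_names=list(feature_names) if feature_names else None,
    )


# ---------------------------------------------------------------------------
# local surrogate (LIME-style)


def local_surrogate(
    model: BinaryModel,
    instance: np.ndarray,
    n_perturbations: int = 1000,
    kernel_width: float | None = None,
    seed: int = 0,
    feature_kinds: Sequence[str] | None = None,
    scale: np.ndarray | float = 1.0,
    alpha: float = 1.0,
) -> AttributionResult:
    """Signed local coefficients from a weighted ridge surrogate.

    Continuous (ROI) features are perturbed with Gaussian noise of the
    given per-feature ``scale`` (features are assumed z-scored, hence the
    default 1); SNP features are resampled uniformly from {0, 0.5, 1}.
    Samples are weighted by an exponential kernel
    exp(-||z - x||^2 / kernel_width^2); positive coefficients push the
    prediction toward the positive (disease) class.
    """
    x = np.asarray(instance, dtype=float).reshape(-1)
    d = x.size
    if n_perturbations < 2:
        raise ContractError("need >= 2 perturbations to fit a surrogate")
    kinds = list(feature_kinds) if feature_kinds is not None else ["roi"] * d
    scale = np.broadcast_to(np.asarray(scale, dtype=float), (d,))
    if kernel_width is None:
        kernel_width = 0.75 * np.sqrt(d)
    rng = np.random.default_rng(seed)

    Z = np.tile(x, (n_perturbations, 1))
    for j in range(d):
        if kinds[j] == "snp":
            Z[:, j] = rng.choice([0.0, 0.5, 1.0], size=n_perturbations)
        else:
            Z[:, j] = x[j] + rng.normal(0.0, scale[j], size=n_perturbations)
    if np.allclose(Z.std(axis=0), 0.0):
        raise ContractError("degenerate perturbation set (zero variance)")
    dist2 = ((Z - x) ** 2).sum(axis=1)
    w = np.exp(-dist2 / kernel_width**2)
    y = pos_prob(model, Z)
    reg = Ridge(alpha=alpha)
    reg.fit(Z, y, sample_weight=w)
    return AttributionResult(values=np.asarray(reg.coef_), method="surrogate",
                             scope="instance")


def partial_dependence(
    model: BinaryModel,
    dataset: np.ndarray,
    feature: int,
    grid: Sequence[float],
    feature_name: str | None = None,
) -> PDPCurve:
    """Mean positive-class probability with one feature forced to each grid value."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ParameterError("grid is empty")
    grid = np.sort(grid)
    dataset = np.atleast_2d(np.asarray(dataset, dtype=float))
    means = np.empty(grid.size)
    for i, v in enumerate(grid):
        rows = dataset.copy()
        rows[:, feature] = v
        means[i] = pos_prob(model, rows).mean()
    return PDPCurve(feature=int(feature), grid=grid, mean_probability=means,
                    feature_name=feature_name)
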