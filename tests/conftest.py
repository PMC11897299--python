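"""Shared fixtures: tiny deterministic models, toy spaces and oracles."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from necsuff import CohortSpec, generate_cohort

SNP_LEVELS = (0.0, 0.5, 1.0)


class LinearThresholdModel:
    """Hard binary model 1[w.x + b > 0] exposed as a probability."""

    def __init__(self, w, b=0.0):
        self.w = np.asarray(w, dtype=float)
        self.b = float(b)

    def __call__(self, X):
        return (np.atleast_2d(X) @ self.w + self.b > 0).astype(float)


def step_model(feature=0, threshold=0.0):
    """f = 1[x_feature > threshold]."""

    def f(X):
        return (np.atleast_2d(X)[:, feature] > threshold).astype(float)

    return f


def enumerate_candidates(instance, allowed, levels=SNP_LEVELS):
    """All vectors equal to ``instance`` outside ``allowed``, over ``levels``."""
    instance = np.asarray(instance, dtype=float)
    allowed = list(allowed)
    out = []
    for combo in product(levels, repeat=len(allowed)):
        c = instance.copy()
        c[allowed] = combo
        if not np.array_equal(c, instance):
            out.append(c)
    return np.asarray(out) if out else np.empty((0, instance.size))


def brute_force_counts(model, instance, allowed, n_cf, levels=SNP_LEVELS):
    """Distinct valid counterfactuals reachable through the mask, capped at n_cf."""
    if not len(allowed):
        return 0
    cands = enumerate_candidates(instance, allowed, levels)
    if cands.shape[0] == 0:
        return 0
    orig = model(instance[None, :])[0] > 0.5
    valid = cands[(model(cands) > 0.5) != orig]
    if valid.shape[0] == 0:
        return 0
    return min(n_cf, np.unique(np.round(valid, 4), axis=0).shape[0])


def brute_force_necessity(model, eval_rows, target, n_cf, levels=SNP_LEVELS):
    total = sum(
        brute_force_counts(model, row, target, n_cf, levels) for row in eval_rows
    )
    return total / (n_cf * len(eval_rows))


def brute_force_sufficiency(model, eval_rows, target, n_cf, levels=SNP_LEVELS):
    d = np.asarray(eval_rows).shape[1]
    everything = list(range(d))
    complement = [j for j in everything if j not in set(target)]
    a = brute_force_necessity(model, eval_rows, everything, n_cf, levels)
    b = brute_force_necessity(model, eval_rows, complement, n_cf, levels)
    return a - b


@pytest.fixture
def small_planted_spec():
    """12 ROI + 4 SNP features; ROIs 0 and 1 and SNP 0 carry signal."""
    return CohortSpec(
        n_per_class=(60, 90, 60),
        n_roi=12,
        n_snp=4,
        planted_roi={0: {"MCI": -0.8, "AD": -1.6}, 1: {"MCI": 0.7, "AD": 1.4}},
        planted_snp={0: {"CN": 0.1, "MCI": 0.3, "AD": 0.5}},
        covariate_effects=(-0.02, 0.3, 0.5),
        noise_sd=1.0,
        seed=7,
    )


@pytest.fixture
def small_cohort(small_planted_spec):
    return generate_cohort(small_planted_spec)


def imbalanced_gaussians(seed: int, n_min: int = 60):
    """Three overlapping 2-D Gaussians; class B holds twice the rows of A/C."""
    rng = np.random.default_rng(seed)
    means = {"A": (0.0, 0.0), "B": (1.6, 0.0), "C": (0.8, 1.4)}
    sizes = {"A": n_min, "B": 2 * n_min, "C": n_min}
    X = np.vstack([rng.normal(means[c], 1.0, size=(sizes[c], 2)) for c in means])
    y = np.concatenate([[c] * sizes[c] for c in means])
    return X, y


def toy_discrete_case(seed: int):
    """One random linear-threshold model over 2-5 three-level features.

    Returns (model, evaluation rows, single-feature target, feature kinds).
    All features are SNP-kind so every generator explores exactly the
    {0, 0.5, 1} grid that the brute-force oracle enumerates.
    """
    rng = np.random.default_rng(seed)
    d = int(rng.integers(2, 6))
    w = rng.normal(0.0, 1.0, size=d)
    b = float(rng.normal(0.0, 0.5))
    model = LinearThresholdModel(w, b)
    pool = rng.choice(SNP_LEVELS, size=(12, d))
    eval_rows = rng.choice(SNP_LEVELS, size=(4, d))
    target = [int(rng.integers(d))]
    return model, eval_rows, target, ["snp"] * d, pool
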