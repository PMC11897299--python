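"""Shared exceptions and the probabilistic-model protocol.

Every explainer and counterfactual generator in this package talks to a
*binary probability model*: either an object exposing ``predict_proba(X)``
returning an ``(n, 2)`` array (column 1 = positive class), or a plain
callable mapping an ``(n, d)`` array to the positive-class probability
vector.  The helpers here normalise both forms.
"""

from __future__ import annotations

from typing import Callable, Union

import numpy as np

__all__ = [
    "ContractError",
    "ParameterError",
    "ConfigurationError",
    "MethodNotApplicableError",
    "BinaryModel",
    "pos_prob",
    "predict_class",
    "child_seed",
]


class ContractError(ValueError):
    """An operation was called with inputs violating its contract."""


class ParameterError(ValueError):
    """A parameter value is outside its documented domain."""


class ConfigurationError(ValueError):
    """A component was configured in an unusable way."""


class MethodNotApplicableError(TypeError):
    """The requested explanation method does not apply to this model."""


BinaryModel = Union[Callable[[np.ndarray], np.ndarray], object]


def pos_prob(model: BinaryModel, X: np.ndarray) -> np.ndarray:
    """Positive-class probability for each row of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if hasattr(model, "predict_proba"):
        p = np.asarray(model.predict_proba(X), dtype=float)
        return p[:, 1] if p.ndim == 2 else p
    if callable(model):
        return np.asarray(model(X), dtype=float).reshape(-1)
    raise ConfigurationError(
        "model must be callable or expose predict_proba"
    )


def predict_class(model: BinaryModel, X: np.ndarray) -> np.ndarray:
    """Hard class (0/1) by thresholding the positive probability at 0.5."""
    return (pos_prob(model, X) > 0.5).astype(int)


def child_seed(rng: np.random.Generator) -> int:
    """Draw a derived seed (< 2**31) for an independent substream."""
    return int(rng.integers(0, 2**31 - 1))
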