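"""Losses operating on predicted class probabilities (post-softmax/sigmoid)."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

_EPS = 1e-7


def _clip(p: Tensor) -> Tensor:
    return p.clip(_EPS, 1.0 - _EPS)


def categorical_crossentropy(probs: Tensor, onehot: np.ndarray) -> Tensor:
    t = Tensor(onehot)
    return -(t * _clip(probs).log()).sum(axis=-1).mean()


def binary_crossentropy(probs: Tensor, targets: np.ndarray) -> Tensor:
    t = Tensor(targets)
    p = _clip(probs)
    return -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()


def mean_squared_error(probs: Tensor, onehot: np.ndarray) -> Tensor:
    return ((probs - Tensor(onehot)) ** 2.0).mean()


def mean_squared_logarithmic_error(probs: Tensor, onehot: np.ndarray) -> Tensor:
    a = (probs.clip(0.0, np.inf) + 1.0).log()
    b = np.log(onehot + 1.0)
    return ((a - Tensor(b)) ** 2.0).mean()


def mean_absolute_error(probs: Tensor, onehot: np.ndarray) -> Tensor:
    return (probs - Tensor(onehot)).abs().mean()


LOSSES = {
    "categorical_crossentropy": categorical_crossentropy,
    "binary_crossentropy": binary_crossentropy,
    "mean_squared_error": mean_squared_error,
    "mean_squared_logarithmic_error": mean_squared_logarithmic_error,
    "mean_absolute_error": mean_absolute_error,
}


def get_loss(name: str):
    key = name.lower().replace(" ", "_").replace("-", "_")
    if key not in LOSSES:
        raise ValueError(f"unknown loss {name!r}; choose from {sorted(LOSSES)}")
    return LOSSES[key]
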