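"""Graded response model numerics.

Samejima's graded response model with a pure logistic link (no 1.7
normal-ogive scaling constant): for an item with discrimination ``a`` and
ordered thresholds ``b_1 < ... < b_{K-1}``, the cumulative category
probability is

    P(X > k | theta) = 1 / (1 + exp(-a (theta - b_k))),   k = 1..K-1,

and category probabilities are adjacent differences of the cumulative curves,
with P(X >= 1) = 1.  All functions broadcast over arrays of ``theta``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .bank import ItemBank, ItemParameters

__all__ = [
    "QuadratureGrid",
    "cumulative_probability",
    "category_probabilities",
    "response_loglikelihood",
    "item_information",
    "bank_category_probabilities",
]


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed latent-trait grid with trapezoid integration weights.

    The default (161 equally spaced points on [-6, 6]) is wide enough that
    posteriors recentred by dynamic priors keep essentially all their mass on
    the grid, and dense enough for ~1e-4 accuracy of EAP integrals.
    """

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        wts = np.asarray(self.weights, dtype=float)
        if pts.ndim != 1 or pts.size < 21:
            raise ValueError("quadrature grid needs at least 21 points")
        if not np.all(np.diff(pts) > 0):
            raise ValueError("quadrature points must be strictly increasing")
        if not np.all(wts > 0):
            raise ValueError("quadrature weights must be positive")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", wts)

    @classmethod
    def default(cls, lo: float = -6.0, hi: float = 6.0, n: int = 161) -> "QuadratureGrid":
        pts = np.linspace(lo, hi, n)
        h = (hi - lo) / (n - 1)
        wts = np.full(n, h)
        wts[0] = wts[-1] = h / 2.0
        return cls(points=pts, weights=wts)

    def __len__(self) -> int:
        return self.points.size


def cumulative_probability(theta, item: ItemParameters, k: int):
    """P(X > k | theta) for boundary ``k`` in 1..K-1."""
    if not 1 <= k <= item.n_categories - 1:
        raise IndexError(
            f"boundary k={k} out of range 1..{item.n_categories - 1} for item {item.item_id!r}"
        )
    return expit(item.a * (np.asarray(theta, dtype=float) - item.thresholds[k - 1]))


def category_probabilities(theta, item: ItemParameters) -> np.ndarray:
    """Probability of each response category 1..K at ``theta``.

    Returns an array of shape ``theta.shape + (K,)`` summing to 1 along the
    last axis.
    """
    theta = np.asarray(theta, dtype=float)
    b = np.asarray(item.thresholds)
    # cumulative curves stacked with the P(X>=1)=1 and P(X>K)=0 boundaries
    cum = expit(item.a * (theta[..., None] - b))
    ones = np.ones(theta.shape + (1,))
    zeros = np.zeros(theta.shape + (1,))
    full = np.concatenate([ones, cum, zeros], axis=-1)
    return np.clip(-np.diff(full, axis=-1), 0.0, 1.0)


def response_loglikelihood(theta, responses: Sequence[tuple[ItemParameters, int]]):
    """Log-likelihood of observed (item, category) responses at ``theta``.

    An empty response list gives 0; a category with zero probability at the
    given ``theta`` gives ``-inf`` rather than raising.
    """
    theta = np.asarray(theta, dtype=float)
    total = np.zeros(theta.shape)
    for item, cat in responses:
        if not 1 <= cat <= item.n_categories:
            raise ValueError(
                f"category {cat} out of range 1..{item.n_categories} for item {item.item_id!r}"
            )
        p = category_probabilities(theta, item)[..., cat - 1]
        with np.errstate(divide="ignore"):
            total = total + np.log(p)
    return total


def item_information(theta, item: ItemParameters):
    """Fisher information of the graded item at ``theta``.

    For multinomial observations, I(theta) = sum_k P'_k(theta)^2 / P_k(theta)
    (the second-derivative terms cancel since the P_k sum to 1).  For a
    dichotomous item this reduces to the 2PL form a^2 p (1 - p).
    """
    theta = np.asarray(theta, dtype=float)
    b = np.asarray(item.thresholds)
    cum = expit(item.a * (theta[..., None] - b))
    dcum = item.a * cum * (1.0 - cum)
    ones = np.ones(theta.shape + (1,))
    zeros = np.zeros(theta.shape + (1,))
    p = -np.diff(np.concatenate([ones, cum, zeros], axis=-1), axis=-1)
    dp = -np.diff(np.concatenate([zeros, dcum, zeros], axis=-1), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, dp * dp / np.where(p > 0, p, 1.0), 0.0)
    return terms.sum(axis=-1)


def bank_category_probabilities(bank: ItemBank, grid: QuadratureGrid) -> list[np.ndarray]:
    """Per-item category probability matrices over the grid.

    Element ``i`` has shape (M, K_i); precomputing these once makes repeated
    posterior updates and item-selection sweeps cheap.
    """
    return [category_probabilities(grid.points, item) for item in bank]
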