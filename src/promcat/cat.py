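"""Computerized adaptive test administration.

The engine loops select -> pose -> update posterior -> check stopping rule.
Item selection is either minimum expected posterior variance (MEPV) — pick
the candidate whose posterior-predictive-weighted posterior variance is
smallest — or maximum Fisher information at the current EAP, optionally with
randomesque exposure control (a uniform draw among the n best candidates).
The default configuration mirrors common practice for patient-reported
outcome CATs: EAP scoring, MEPV selection, stop once the SE of measurement
drops below 0.3 (roughly 90% marginal reliability), at least one item per
assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np

from .bank import ItemBank, ItemParameters
from .grm import QuadratureGrid, bank_category_probabilities, item_information
from .scoring import NormalPrior, PosteriorState, ScoreSummary

__all__ = [
    "SelectionCriterion",
    "StoppingRule",
    "CATConfig",
    "AssessmentResult",
    "AdministrationError",
    "SelectionError",
    "predictive_category_probs",
    "expected_posterior_variance",
    "select_next_item",
    "should_stop",
    "run_assessment",
]


class AdministrationError(RuntimeError):
    """A response provider returned an unusable answer."""


class SelectionError(RuntimeError):
    """Item selection was asked to choose from an empty candidate set."""


@dataclass(frozen=True)
class SelectionCriterion:
    """How the next item is chosen.

    ``kind`` is "mepv" or "max_info"; ``randomesque_n`` > 1 draws uniformly
    among the n best candidates (clamped to the number remaining), which
    spreads item exposure at some cost in efficiency.
    """

    kind: Literal["mepv", "max_info"] = "mepv"
    randomesque_n: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("mepv", "max_info"):
            raise ValueError(f"unknown selection criterion {self.kind!r}")
        if self.randomesque_n < 1:
            raise ValueError("randomesque_n must be >= 1")


@dataclass(frozen=True)
class StoppingRule:
    """Stop once the SE of measurement falls below ``se_threshold`` (checked
    only after ``min_items`` items), or after ``max_items`` items."""

    se_threshold: float = 0.3
    max_items: int = 10**9
    min_items: int = 1

    def __post_init__(self) -> None:
        if not self.se_threshold >= 0:
            raise ValueError("se_threshold must be nonnegative")
        if self.min_items < 1 or self.min_items > self.max_items:
            raise ValueError("need 1 <= min_items <= max_items")


@dataclass
class CATConfig:
    """Everything an administration needs besides the bank and the prior."""

    criterion: SelectionCriterion = field(default_factory=SelectionCriterion)
    rule: StoppingRule = field(default_factory=StoppingRule)
    grid: QuadratureGrid = field(default_factory=QuadratureGrid.default)
    rng: Optional[np.random.Generator] = None


@dataclass(frozen=True)
class AssessmentResult:
    """Record of one adaptive assessment."""

    administered: tuple[tuple[str, int], ...]
    step_summaries: tuple[ScoreSummary, ...]
    final: ScoreSummary
    termination_reason: Literal["se_met", "max_items", "bank_exhausted"]

    @property
    def n_items(self) -> int:
        return len(self.administered)


def predictive_category_probs(
    item: ItemParameters,
    state: PosteriorState,
    item_probs: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior-predictive probability of each category of ``item``.

    Entry k is the current posterior expectation of P(X = k | theta).
    """
    if item_probs is None:
        from .grm import category_probabilities

        item_probs = category_probabilities(state.grid.points, item)
    w = state.grid.weights * state.density
    return w @ item_probs


def expected_posterior_variance(
    item: ItemParameters,
    state: PosteriorState,
    item_probs: np.ndarray | None = None,
) -> float:
    """Expected posterior variance of theta after administering ``item``.

    Averages, over the posterior-predictive category distribution, the
    variance of the posterior updated with each possible response.  By the
    law of total variance this never exceeds the current posterior variance.
    """
    if item_probs is None:
        from .grm import category_probabilities

        item_probs = category_probabilities(state.grid.points, item)
    w = state.grid.weights * state.density  # (M,)
    joint = w[:, None] * item_probs  # (M, K): posterior x category mass
    pred = joint.sum(axis=0)  # predictive category probabilities
    theta = state.grid.points
    epv = 0.0
    for k in range(item_probs.shape[1]):
        if pred[k] <= 0.0:
            continue
        m1 = float(theta @ joint[:, k]) / pred[k]
        m2 = float((theta * theta) @ joint[:, k]) / pred[k]
        epv += pred[k] * max(m2 - m1 * m1, 0.0)
    return epv


def _criterion_scores(
    state: PosteriorState,
    candidates: Sequence[ItemParameters],
    criterion: SelectionCriterion,
    probs_by_id: dict[str, np.ndarray] | None,
) -> np.ndarray:
    """Per-candidate score where LOWER is better (info negated)."""
    if criterion.kind == "mepv":
        return np.array(
            [
                expected_posterior_variance(
                    it, state, probs_by_id.get(it.item_id) if probs_by_id else None
                )
                for it in candidates
            ]
        )
    eap = state.mean
    return -np.array([float(item_information(eap, it)) for it in candidates])


def select_next_item(
    state: PosteriorState,
    remaining: Sequence[ItemParameters],
    criterion: SelectionCriterion,
    rng: Optional[np.random.Generator] = None,
    probs_by_id: dict[str, np.ndarray] | None = None,
) -> str:
    """Choose the next item id from ``remaining``.

    Ties break toward the earliest candidate in ``remaining`` (bank order);
    with ``randomesque_n`` > 1 the choice is uniform among the n best and
    requires ``rng``.
    """
    if len(remaining) == 0:
        raise SelectionError("no items remain to select from")
    scores = _criterion_scores(state, remaining, criterion, probs_by_id)
    order = np.argsort(scores, kind="stable")  # stable: ties -> lowest index
    n = min(criterion.randomesque_n, len(remaining))
    if n == 1:
        return remaining[int(order[0])].item_id
    if rng is None:
        raise ValueError("randomesque selection needs a seeded rng")
    return remaining[int(order[int(rng.integers(n))])].item_id


def should_stop(
    state: PosteriorState,
    n_administered: int,
    rule: StoppingRule,
    n_remaining: Optional[int] = None,
) -> tuple[bool, Optional[str]]:
    """Evaluate the stopping rule; returns (stop, reason).

    The SE criterion is only consulted once ``min_items`` items have been
    posed, so a tight carried-over prior can never yield a zero-item
    assessment.
    """
    if n_administered >= rule.min_items and state.sd < rule.se_threshold:
        return True, "se_met"
    if n_administered >= rule.max_items:
        return True, "max_items"
    if n_remaining is not None and n_remaining == 0:
        return True, "bank_exhausted"
    return False, None


def run_assessment(
    response_provider: Callable[[ItemParameters], int],
    bank: ItemBank,
    prior: NormalPrior,
    config: CATConfig,
    probs_by_id: dict[str, np.ndarray] | None = None,
    timestamp=None,
) -> AssessmentResult:
    """Administer one adaptive assessment.

    ``response_provider`` is called with each posed item and must return a
    category in 1..K; ``probs_by_id`` may carry precomputed per-item category
    probability matrices over the grid (as from
    :func:`promcat.grm.bank_category_probabilities`) to speed up batch
    simulation.
    """
    if probs_by_id is None:
        mats = bank_category_probabilities(bank, config.grid)
        probs_by_id = {it.item_id: m for it, m in zip(bank, mats)}
    state = PosteriorState(prior=prior, grid=config.grid)
    administered: list[tuple[str, int]] = []
    steps: list[ScoreSummary] = []
    remaining = list(bank.items)

    reason: Optional[str] = None
    while True:
        stop, reason = should_stop(state, len(administered), config.rule, len(remaining))
        if stop:
            break
        item_id = select_next_item(
            state, remaining, config.criterion, config.rng, probs_by_id
        )
        item = bank[item_id]
        remaining = [it for it in remaining if it.item_id != item_id]
        category = response_provider(item)
        if not isinstance(category, (int, np.integer)) or not 1 <= int(category) <= item.n_categories:
            raise AdministrationError(
                f"response provider returned invalid category {category!r} "
                f"for item {item.item_id!r} (valid: 1..{item.n_categories})"
            )
        state = state.update(item, int(category), probs_by_id[item_id])
        administered.append((item_id, int(category)))
        steps.append(state.summary())

    # recompute from the collected responses in one pass: the reported final
    # summary is, bitwise, the batch EAP score of what was administered
    from .scoring import eap_summary

    final = eap_summary(state.responses, prior, config.grid, timestamp=timestamp)
    assert reason is not None
    return AssessmentResult(
        administered=tuple(administered),
        step_summaries=tuple(steps),
        final=final,
        termination_reason=reason,  # type: ignore[arg-type]
    )
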