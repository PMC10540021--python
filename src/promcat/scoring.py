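"""Bayesian scoring of graded-response questionnaires.

Scores are expected a posteriori (EAP) estimates of the latent severity
``theta``: the mean of the posterior formed by the response likelihood and a
normal prior, computed by quadrature on a fixed grid.  The posterior SD is
reported as the SE of measurement, and 95% credible intervals use the normal
approximation ``eap ± 1.959964 · se``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .bank import ItemBank, ItemParameters
from .grm import QuadratureGrid, category_probabilities, response_loglikelihood

__all__ = [
    "Z_95",
    "PRIOR_SD_FLOOR",
    "NormalPrior",
    "ScoreSummary",
    "PosteriorState",
    "DegeneratePosteriorError",
    "eap_summary",
    "posterior_density",
    "score_full_length",
    "dynamic_prior",
    "marginal_reliability",
    "scale_mean_score",
    "EXCLUDED",
]

#: two-sided 95% normal quantile used for every credible interval
Z_95 = 1.959964

#: lower bound on any prior SD; prevents numerical collapse when posteriors
#: are chained across many assessments
PRIOR_SD_FLOOR = 0.1


class DegeneratePosteriorError(ValueError):
    """The posterior is numerically zero everywhere on the grid."""


@dataclass(frozen=True)
class NormalPrior:
    """Normal prior N(mean, sd^2) for the latent severity (z-score scale)."""

    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"prior sd must be positive, got {self.sd}")

    def log_density(self, theta: np.ndarray) -> np.ndarray:
        return norm.logpdf(theta, loc=self.mean, scale=self.sd)


@dataclass(frozen=True)
class ScoreSummary:
    """One assessment's score: EAP, SE of measurement, 95% credible bounds."""

    eap: float
    se: float
    ci_low: float
    ci_high: float
    n_items: int
    timestamp: Optional[object] = None

    @classmethod
    def from_moments(cls, eap: float, se: float, n_items: int, timestamp=None) -> "ScoreSummary":
        return cls(
            eap=float(eap),
            se=float(se),
            ci_low=float(eap - Z_95 * se),
            ci_high=float(eap + Z_95 * se),
            n_items=int(n_items),
            timestamp=timestamp,
        )

    def with_timestamp(self, timestamp) -> "ScoreSummary":
        return replace(self, timestamp=timestamp)


def _posterior_on_grid(
    responses: Sequence[tuple[ItemParameters, int]],
    prior: NormalPrior,
    grid: QuadratureGrid,
) -> np.ndarray:
    """Normalized posterior density values over the grid points."""
    logpost = response_loglikelihood(grid.points, responses) + prior.log_density(grid.points)
    finite = np.isfinite(logpost)
    if not finite.any():
        raise DegeneratePosteriorError("posterior is zero at every quadrature point")
    dens = np.zeros_like(logpost)
    dens[finite] = np.exp(logpost[finite] - logpost[finite].max())
    total = float(dens @ grid.weights)
    if not total > 0:
        raise DegeneratePosteriorError("posterior mass integrates to zero on the grid")
    return dens / total


def _moments(density: np.ndarray, grid: QuadratureGrid) -> tuple[float, float]:
    w = grid.weights * density
    mean = float(w @ grid.points)
    var = float(w @ (grid.points - mean) ** 2)
    return mean, max(var, 0.0)


def posterior_density(
    responses: Sequence[tuple[ItemParameters, int]],
    prior: NormalPrior,
    grid: QuadratureGrid,
) -> np.ndarray:
    """Normalized posterior density over the grid (quadrature sum = 1)."""
    return _posterior_on_grid(responses, prior, grid)


def eap_summary(
    responses: Sequence[tuple[ItemParameters, int]],
    prior: NormalPrior,
    grid: QuadratureGrid,
    timestamp=None,
) -> ScoreSummary:
    """EAP score and posterior-SD standard error by grid quadrature."""
    dens = _posterior_on_grid(responses, prior, grid)
    mean, var = _moments(dens, grid)
    return ScoreSummary.from_moments(mean, math.sqrt(var), n_items=len(responses), timestamp=timestamp)


@dataclass
class PosteriorState:
    """Running posterior during an adaptive assessment.

    Holds the prior, the responses accumulated so far, and the normalized
    gridded posterior density; ``update`` returns a new state with one more
    response folded in.
    """

    prior: NormalPrior
    grid: QuadratureGrid
    responses: tuple[tuple[ItemParameters, int], ...] = ()
    density: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.density is None:
            self.density = _posterior_on_grid(self.responses, self.prior, self.grid)

    @property
    def mean(self) -> float:
        return _moments(self.density, self.grid)[0]

    @property
    def variance(self) -> float:
        return _moments(self.density, self.grid)[1]

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)

    def administered_ids(self) -> set[str]:
        return {item.item_id for item, _ in self.responses}

    def update(self, item: ItemParameters, category: int, item_probs: np.ndarray | None = None) -> "PosteriorState":
        """Posterior after additionally observing ``category`` on ``item``.

        ``item_probs`` may carry the precomputed (M, K) category-probability
        matrix of the item over the grid.
        """
        if not 1 <= category <= item.n_categories:
            raise ValueError(
                f"category {category} out of range 1..{item.n_categories} for item {item.item_id!r}"
            )
        if item_probs is None:
            item_probs = category_probabilities(self.grid.points, item)
        dens = self.density * item_probs[:, category - 1]
        total = float(dens @ self.grid.weights)
        if not total > 0:
            raise DegeneratePosteriorError(
                f"updating with item {item.item_id!r} category {category} left no posterior mass"
            )
        return PosteriorState(
            prior=self.prior,
            grid=self.grid,
            responses=self.responses + ((item, category),),
            density=dens / total,
        )

    def summary(self, timestamp=None) -> ScoreSummary:
        mean, var = _moments(self.density, self.grid)
        return ScoreSummary.from_moments(
            mean, math.sqrt(var), n_items=len(self.responses), timestamp=timestamp
        )


def score_full_length(
    responses: Sequence[tuple[ItemParameters, int]],
    prior: NormalPrior,
    grid: QuadratureGrid,
    bank: ItemBank,
    timestamp=None,
) -> ScoreSummary:
    """EAP score of a complete (one response per bank item) administration."""
    answered = {item.item_id for item, _ in responses}
    missing = [iid for iid in bank.item_ids if iid not in answered]
    if missing:
        raise ValueError(f"incomplete full-length response set; missing items: {missing}")
    return eap_summary(responses, prior, grid, timestamp=timestamp)


def dynamic_prior(
    previous: ScoreSummary,
    inflation: float = 0.0,
    sd_floor: float = PRIOR_SD_FLOOR,
) -> NormalPrior:
    """Prior for the next assessment from the previous completed one.

    The normal approximation to the previous posterior — N(eap, se) — is
    carried forward; the SE is first clamped to ``sd_floor`` (so chained
    updates cannot collapse numerically), then optional between-assessment
    variance inflation is added: sd = sqrt(max(se, floor)^2 + inflation^2).
    """
    if inflation < 0:
        raise ValueError("inflation must be nonnegative")
    sd = math.sqrt(max(previous.se, sd_floor) ** 2 + inflation**2)
    return NormalPrior(mean=previous.eap, sd=sd)


def marginal_reliability(se: float) -> float:
    """Marginal reliability 1 - se^2 on the unit-variance latent scale.

    At the usual SE-of-measurement stopping threshold of 0.3 this is 0.91,
    i.e. approximately 90% reliability.
    """
    if se < 0:
        raise ValueError("se must be nonnegative")
    return 1.0 - se * se


#: marker returned when a classically scored response set has too many
#: missing items to be included
EXCLUDED = None


def scale_mean_score(item_scores: Sequence[Optional[float]], max_missing: int = 1) -> Optional[float]:
    """Classical mean-item scoring with a missingness inclusion rule.

    Returns the mean of the observed item scores if at most ``max_missing``
    responses are missing (None), else the excluded marker (None).  This is
    the standard rule for non-IRT scales scored by item means, e.g. a
    user-engagement questionnaire.
    """
    if len(item_scores) == 0:
        raise ValueError("empty item-score list")
    observed = [s for s in item_scores if s is not None]
    n_missing = len(item_scores) - len(observed)
    if n_missing > max_missing:
        return EXCLUDED
    return float(np.mean(observed))
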