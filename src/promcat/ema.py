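"""Ecological momentary assessment (EMA) simulation machinery.

Generates assessment schedules for the three study regimes (thrice weekly,
daily, thrice daily over 12 weeks), simulates respondents with clinically
motivated latent symptom trajectories and imperfect compliance, administers
adaptive assessments per schedule with dynamic priors chained across
occasions, and summarizes the resulting logs.

Two trajectory archetypes are modelled:

* ``recovery`` — severity decays exponentially from a baseline toward an
  asymptote, as after an uncomplicated fracture;
* ``fluctuating`` — a chronic condition whose burden varies by time of day
  (sinusoidal diurnal term) and stochastically (daily AR(1) noise), with an
  optional treatment effect: a transient dip in severity that returns to
  near-baseline over a rebound period, as after a steroid injection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .bank import ItemBank
from .cat import AssessmentResult, CATConfig, StoppingRule, run_assessment
from .grm import QuadratureGrid, bank_category_probabilities, category_probabilities
from .scoring import (
    NormalPrior,
    ScoreSummary,
    dynamic_prior,
    score_full_length,
)

__all__ = [
    "ScheduleRegime",
    "TrajectoryProfile",
    "Intervention",
    "SimulatedRespondent",
    "StudyResult",
    "StudySummary",
    "ErrorStats",
    "StudyConfigError",
    "generate_schedule",
    "latent_theta_at",
    "simulate_response",
    "run_study",
    "summarize_study",
    "compare_cat_full_length",
    "error_statistics",
    "simulate_cat_vs_full",
]

_REGIME_KINDS = ("thrice_weekly", "daily", "thrice_daily")

#: default notification clock times; plausible waking-hour defaults since no
#: canonical times exist for these regimes
_DEFAULT_TIMES = {
    "thrice_weekly": (time(9, 0),),
    "daily": (time(9, 0),),
    "thrice_daily": (time(9, 0), time(14, 0), time(20, 0)),
}
_MON_WED_FRI = (0, 2, 4)


class StudyConfigError(ValueError):
    """Inconsistent study configuration (e.g. regime without respondents)."""


@dataclass(frozen=True)
class ScheduleRegime:
    """One of the three assessment frequencies.

    thrice_weekly: 3 occasions/week (Mon/Wed/Fri by default); daily: 7/week;
    thrice_daily: 21/week.
    """

    kind: Literal["thrice_weekly", "daily", "thrice_daily"]
    start: datetime = datetime(2022, 7, 13)
    weeks: int = 12
    clock_times: Optional[tuple[time, ...]] = None
    weekdays: tuple[int, ...] = _MON_WED_FRI  # used by thrice_weekly only

    def __post_init__(self) -> None:
        if self.kind not in _REGIME_KINDS:
            raise ValueError(f"unknown regime kind {self.kind!r}")
        if self.weeks < 0:
            raise ValueError("weeks must be nonnegative")

    @property
    def occasions_per_week(self) -> int:
        return {"thrice_weekly": 3, "daily": 7, "thrice_daily": 21}[self.kind]


def generate_schedule(regime: ScheduleRegime) -> list[pd.Timestamp]:
    """Deterministic ordered occasion timestamps for a regime.

    Weeks are 7-day blocks anchored at the start date, so every weekday
    occurs exactly once per block and the occasion counts are exact:
    3, 7 or 21 per week.
    """
    times = regime.clock_times or _DEFAULT_TIMES[regime.kind]
    start_day = regime.start.date()
    out: list[pd.Timestamp] = []
    for day_offset in range(7 * regime.weeks):
        day = start_day + timedelta(days=day_offset)
        if regime.kind == "thrice_weekly" and day.weekday() not in regime.weekdays:
            continue
        for t in times:
            out.append(pd.Timestamp(datetime.combine(day, t)))
    return out


@dataclass(frozen=True)
class Intervention:
    """A transient treatment effect on a fluctuating trajectory.

    Severity dips by up to ``depth`` after ``at_day``, reaching its trough
    mid-way, and returns to baseline over ``rebound_days``.
    """

    at_day: float
    depth: float
    rebound_days: float

    def __post_init__(self) -> None:
        if not self.rebound_days > 0:
            raise ValueError("rebound_days must be positive")

    def effect(self, day: np.ndarray) -> np.ndarray:
        u = (np.asarray(day, dtype=float) - self.at_day) / self.rebound_days
        inside = (u >= 0.0) & (u <= 1.0)
        return np.where(inside, -self.depth * np.sin(np.pi * np.clip(u, 0.0, 1.0)), 0.0)


@dataclass
class TrajectoryProfile:
    """Latent severity trajectory of one simulated respondent.

    ``recovery``: theta(t) = asymptote + (baseline - asymptote) exp(-rate t).
    ``fluctuating``: baseline + diurnal sinusoid + daily AR(1) noise
    (+ optional intervention dip).  Time is measured in days from the study
    start; the noise path is precomputed from ``noise_seed`` so evaluation is
    deterministic and order-independent.
    """

    kind: Literal["recovery", "fluctuating"]
    baseline: float
    recovery_rate: float = 0.05  # per day
    asymptote: float = -1.0
    diurnal_amplitude: float = 0.3
    diurnal_peak_hour: float = 17.0  # severity peaks late afternoon
    ar_coefficient: float = 0.7
    noise_scale: float = 0.25  # stationary SD of the AR(1) daily noise
    intervention: Optional[Intervention] = None
    noise_seed: int = 0
    horizon_days: int = 120
    _noise_path: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in ("recovery", "fluctuating"):
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")
        if self._noise_path is None:
            self._noise_path = self._build_noise_path()

    def _build_noise_path(self) -> np.ndarray:
        n = self.horizon_days + 2
        if self.noise_scale == 0:
            return np.zeros(n)
        rng = np.random.default_rng(self.noise_seed)
        phi = self.ar_coefficient
        innov_sd = self.noise_scale * math.sqrt(max(1.0 - phi * phi, 0.0))
        path = np.empty(n)
        path[0] = rng.normal(0.0, self.noise_scale)
        eps = rng.normal(0.0, innov_sd, size=n - 1)
        for i in range(1, n):
            path[i] = phi * path[i - 1] + eps[i - 1]
        return path

    def theta_at_day(self, day) -> np.ndarray:
        """Latent severity at time ``day`` (float days since study start)."""
        day = np.asarray(day, dtype=float)
        if self.kind == "recovery":
            return self.asymptote + (self.baseline - self.asymptote) * np.exp(
                -self.recovery_rate * day
            )
        hour = (day % 1.0) * 24.0
        diurnal = self.diurnal_amplitude * np.cos(
            2.0 * np.pi * (hour - self.diurnal_peak_hour) / 24.0
        )
        idx = np.clip(np.floor(day).astype(int), 0, len(self._noise_path) - 1)
        out = self.baseline + diurnal + self._noise_path[idx]
        if self.intervention is not None:
            out = out + self.intervention.effect(day)
        return out


def latent_theta_at(
    profile: TrajectoryProfile,
    when: pd.Timestamp | datetime | float,
    start: Optional[datetime] = None,
) -> float:
    """Latent severity at a timestamp (or float days since start)."""
    if isinstance(when, (int, float)):
        day = float(when)
    else:
        if start is None:
            raise ValueError("timestamp evaluation needs the study start datetime")
        day = (pd.Timestamp(when) - pd.Timestamp(start)).total_seconds() / 86400.0
    return float(profile.theta_at_day(day))


@dataclass
class SimulatedRespondent:
    """One synthetic study participant."""

    respondent_id: str
    profile: TrajectoryProfile
    compliance: float = 0.9
    delay_median_minutes: float = 54.0
    delay_sigma: float = 1.0  # log-normal shape; affects timestamps only
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.compliance <= 1.0:
            raise ValueError("compliance must lie in [0, 1]")
        if self.delay_median_minutes < 0:
            raise ValueError("delays must be nonnegative")


def simulate_response(theta: float, item, rng: np.random.Generator) -> int:
    """Draw a response category 1..K from the graded model at ``theta``."""
    p = np.asarray(category_probabilities(theta, item), dtype=float)
    p = p / p.sum()
    return int(rng.choice(len(p), p=p)) + 1


@dataclass
class StudyResult:
    """Raw output of a simulated study."""

    response_log: pd.DataFrame  # one row per administered item
    assessments: pd.DataFrame  # one row per completed CAT assessment
    full_length: pd.DataFrame  # one row per full-length administration
    scheduled: dict[str, int]  # occasions scheduled per respondent
    start: datetime


@dataclass
class StudySummary:
    """Descriptive statistics of a study's logs."""

    response_rates: dict[str, float]
    items_median: float
    items_range: tuple[int, int]
    exposure_counts: dict[str, int]
    median_delay_minutes: float
    n_assessments: int


_LOG_COLUMNS = [
    "participant_id",
    "assessment_id",
    "scheduled_time",
    "response_time",
    "item_id",
    "category",
    "step_eap",
    "step_se",
]
_SUMMARY_COLUMNS = [
    "participant_id",
    "assessment_id",
    "timestamp",
    "eap",
    "se",
    "ci_low",
    "ci_high",
    "n_items",
    "termination_reason",
]


def _full_length_result(
    theta: float,
    bank: ItemBank,
    prior: NormalPrior,
    grid: QuadratureGrid,
    rng: np.random.Generator,
) -> ScoreSummary:
    responses = [(item, simulate_response(theta, item, rng)) for item in bank]
    return score_full_length(responses, prior, grid, bank)


def run_study(
    cohort: Sequence[SimulatedRespondent],
    bank: ItemBank,
    config: CATConfig,
    regimes: dict[str, ScheduleRegime],
    seed: int = 0,
    prior_policy: Literal["dynamic", "static"] = "dynamic",
    inflation: float = 0.0,
    full_length_weeks: tuple[int, ...] = (0, 6, 12),
) -> StudyResult:
    """Simulate a full EMA study.

    Each respondent follows their assigned schedule; occasions are skipped
    with probability 1 - compliance; completed occasions get a log-normal
    notification-to-response delay, the latent severity is evaluated at the
    response time, and an adaptive assessment is administered.  The first
    assessment uses a standard normal prior; later ones carry the previous
    posterior forward when ``prior_policy`` is "dynamic".  Full-length
    administrations are added on the first scheduled day of the listed weeks,
    on the same latent value as that day's adaptive assessment.
    """
    ids = {r.respondent_id for r in cohort}
    missing = set(regimes) - ids
    if missing:
        raise StudyConfigError(f"regimes assigned to unknown respondents: {sorted(missing)}")
    unassigned = ids - set(regimes)
    if unassigned:
        raise StudyConfigError(f"respondents without a regime: {sorted(unassigned)}")
    if not cohort:
        raise StudyConfigError("empty cohort")

    start = min(reg.start for reg in regimes.values())
    mats = bank_category_probabilities(bank, config.grid)
    probs_by_id = {it.item_id: m for it, m in zip(bank, mats)}

    log_rows: list[tuple] = []
    assess_rows: list[tuple] = []
    full_rows: list[tuple] = []
    scheduled: dict[str, int] = {}

    root = np.random.SeedSequence(seed)
    child_seeds = root.spawn(len(cohort))

    for resp, ss in zip(cohort, child_seeds):
        rng = np.random.default_rng([resp.seed, *ss.generate_state(2).tolist()])
        regime = regimes[resp.respondent_id]
        occasions = generate_schedule(regime)
        scheduled[resp.respondent_id] = len(occasions)
        # full-length targets clamped into the schedule: a "week 12" visit in
        # a 12-week study lands on the final scheduled day
        fl_pending = sorted(
            {min(7 * w, max(7 * regime.weeks - 1, 0)) for w in full_length_weeks}
        ) if regime.weeks > 0 else []
        prior = NormalPrior(0.0, 1.0)
        for occ_i, when in enumerate(occasions):
            if rng.random() >= resp.compliance:
                continue
            delay_min = math.exp(rng.normal(math.log(max(resp.delay_median_minutes, 1e-9)), resp.delay_sigma))
            response_time = (when + pd.Timedelta(minutes=delay_min)).round("s")
            theta = latent_theta_at(resp.profile, response_time, start=regime.start)
            result = run_assessment(
                lambda item: simulate_response(theta, item, rng),
                bank,
                prior,
                config,
                probs_by_id=probs_by_id,
                timestamp=response_time,
            )
            aid = f"{resp.respondent_id}-a{occ_i:04d}"
            for step, ((item_id, cat), summ) in enumerate(
                zip(result.administered, result.step_summaries)
            ):
                log_rows.append(
                    (resp.respondent_id, aid, when, response_time, item_id, cat, summ.eap, summ.se)
                )
            assess_rows.append(
                (
                    resp.respondent_id,
                    aid,
                    response_time,
                    result.final.eap,
                    result.final.se,
                    result.final.ci_low,
                    result.final.ci_high,
                    result.n_items,
                    result.termination_reason,
                )
            )
            day_index = (pd.Timestamp(when).normalize() - pd.Timestamp(regime.start).normalize()).days
            if fl_pending and day_index >= fl_pending[0]:
                fl_pending.pop(0)
                fl = _full_length_result(theta, bank, NormalPrior(0.0, 1.0), config.grid, rng)
                full_rows.append(
                    (
                        resp.respondent_id,
                        f"{resp.respondent_id}-f{day_index:03d}",
                        response_time,
                        fl.eap,
                        fl.se,
                        fl.ci_low,
                        fl.ci_high,
                        fl.n_items,
                        "full_length",
                    )
                )
            if prior_policy == "dynamic":
                prior = dynamic_prior(result.final, inflation=inflation)

    response_log = pd.DataFrame(log_rows, columns=_LOG_COLUMNS)
    assessments = pd.DataFrame(assess_rows, columns=_SUMMARY_COLUMNS)
    full_length = pd.DataFrame(full_rows, columns=_SUMMARY_COLUMNS)
    return StudyResult(
        response_log=response_log,
        assessments=assessments,
        full_length=full_length,
        scheduled=scheduled,
        start=start,
    )


def summarize_study(result: StudyResult) -> StudySummary:
    """Descriptive statistics: response rates, items per assessment, item
    exposure, and the median notification-to-response delay."""
    if len(result.assessments) == 0 and not result.scheduled:
        raise ValueError("empty study logs")
    completed = result.assessments.groupby("participant_id").size().to_dict()
    rates = {
        pid: completed.get(pid, 0) / n if n else 0.0 for pid, n in result.scheduled.items()
    }
    n_items = result.assessments["n_items"]
    exposure = result.response_log.groupby("item_id").size().to_dict()
    delays = (
        pd.to_datetime(result.response_log["response_time"])
        - pd.to_datetime(result.response_log["scheduled_time"])
    ).dt.total_seconds() / 60.0
    return StudySummary(
        response_rates=rates,
        items_median=float(n_items.median()) if len(n_items) else float("nan"),
        items_range=(int(n_items.min()), int(n_items.max())) if len(n_items) else (0, 0),
        exposure_counts={str(k): int(v) for k, v in exposure.items()},
        median_delay_minutes=float(delays.median()) if len(delays) else float("nan"),
        n_assessments=int(len(result.assessments)),
    )


@dataclass
class ErrorStats:
    """Agreement between paired adaptive and full-length scores."""

    n_pairs: int
    mean_error: float  # adaptive minus full-length, signed
    mae: float
    rmse: float
    correlation: float  # NaN when undefined (zero variance)


def error_statistics(cat_scores: np.ndarray, full_scores: np.ndarray) -> ErrorStats:
    cat_scores = np.asarray(cat_scores, dtype=float)
    full_scores = np.asarray(full_scores, dtype=float)
    if cat_scores.size == 0 or cat_scores.shape != full_scores.shape:
        raise ValueError("need at least one pair of equal-length score arrays")
    err = cat_scores - full_scores
    if cat_scores.size >= 2 and np.std(cat_scores) > 0 and np.std(full_scores) > 0:
        corr = float(np.corrcoef(cat_scores, full_scores)[0, 1])
    else:
        corr = float("nan")
    return ErrorStats(
        n_pairs=int(err.size),
        mean_error=float(err.mean()),
        mae=float(np.abs(err).mean()),
        rmse=float(np.sqrt((err**2).mean())),
        correlation=corr,
    )


def compare_cat_full_length(
    cat_summaries: pd.DataFrame, full_summaries: pd.DataFrame
) -> ErrorStats:
    """Pair same-respondent, same-day adaptive and full-length scores and
    compute their agreement statistics.

    When a respondent completed several adaptive assessments on a
    full-length day, the one closest in time is paired.
    """
    if len(full_summaries) == 0 or len(cat_summaries) == 0:
        raise ValueError("no records to pair")
    cat = cat_summaries.copy()
    full = full_summaries.copy()
    for df in (cat, full):
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        df["day"] = df["timestamp"].dt.normalize()
    pairs: list[tuple[float, float]] = []
    for (_, day), grp in full.groupby(["participant_id", "day"]):
        frow = grp.iloc[0]
        cands = cat[(cat["participant_id"] == frow["participant_id"]) & (cat["day"] == day)]
        if len(cands) == 0:
            continue
        nearest = cands.iloc[
            (cands["timestamp"] - frow["timestamp"]).abs().argsort().iloc[0]
        ]
        pairs.append((float(nearest["eap"]), float(frow["eap"])))
    if not pairs:
        raise ValueError("no same-day adaptive/full-length pairs found")
    arr = np.asarray(pairs)
    return error_statistics(arr[:, 0], arr[:, 1])


def simulate_cat_vs_full(
    bank: ItemBank,
    n_respondents: int,
    seed: int,
    config: Optional[CATConfig] = None,
    theta: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Paired adaptive-vs-full-length scoring experiment.

    Draws ``n_respondents`` latent severities theta ~ N(0, 1), simulates one
    complete response vector per respondent, scores it full-length by EAP,
    and replays an adaptive assessment against the *same* response vector.
    Returns one row per respondent with columns ``theta, full_eap, full_se,
    cat_eap, cat_se, n_items, termination_reason``.
    """
    config = config or CATConfig()
    rng = np.random.default_rng(seed)
    if theta is None:
        theta = rng.normal(0.0, 1.0, size=n_respondents)
    theta = np.asarray(theta, dtype=float)
    n = theta.size

    # draw full response vectors, one item at a time, vectorized over people
    responses = np.empty((n, len(bank)), dtype=int)
    for j, item in enumerate(bank):
        p = category_probabilities(theta, item)  # (n, K)
        u = rng.random(n)
        responses[:, j] = 1 + (p.cumsum(axis=1) < u[:, None]).sum(axis=1)

    grid = config.grid
    mats = bank_category_probabilities(bank, grid)
    probs_by_id = {it.item_id: m for it, m in zip(bank, mats)}

    # vectorized full-length EAP over all respondents at once
    prior = NormalPrior(0.0, 1.0)
    logpost = np.tile(prior.log_density(grid.points)[:, None], (1, n))
    for j, item in enumerate(bank):
        with np.errstate(divide="ignore"):
            logp = np.log(mats[j])  # (M, K)
        logpost += logp[:, responses[:, j] - 1]
    logpost -= logpost.max(axis=0, keepdims=True)
    dens = np.exp(logpost)
    w = dens * grid.weights[:, None]
    total = w.sum(axis=0)
    full_eap = (grid.points @ w) / total
    full_var = ((grid.points**2) @ w) / total - full_eap**2
    full_se = np.sqrt(np.maximum(full_var, 0.0))

    rows = []
    for i in range(n):
        lookup = {item.item_id: int(responses[i, j]) for j, item in enumerate(bank)}
        res = run_assessment(
            lambda item: lookup[item.item_id],
            bank,
            prior,
            config,
            probs_by_id=probs_by_id,
        )
        rows.append(
            (
                theta[i],
                full_eap[i],
                full_se[i],
                res.final.eap,
                res.final.se,
                res.n_items,
                res.termination_reason,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["theta", "full_eap", "full_se", "cat_eap", "cat_se", "n_items", "termination_reason"],
    )
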