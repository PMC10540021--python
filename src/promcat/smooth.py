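"""Individual-level trajectory analytics.

Three complementary displays of measurement uncertainty around a person's
latent-score time series: (a) 95% credible intervals from the normal
approximation to each score's posterior, (b) a time-by-theta posterior
density surface, and (c) LOESS smoothing — local tricube-weighted polynomial
least squares — with a t-based SE band, appropriate when the underlying
symptom trajectory is expected to be smooth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, t as t_dist

from .grm import QuadratureGrid

__all__ = [
    "ScoreSeries",
    "SmoothedSeries",
    "credible_band",
    "density_surface",
    "loess_smooth",
    "cohort_overlay",
    "plot_series",
]


@dataclass
class ScoreSeries:
    """Timestamped latent-score trajectory of one respondent."""

    respondent_id: str
    times: np.ndarray  # float days or datetime64
    eap: np.ndarray
    se: np.ndarray

    def __post_init__(self) -> None:
        self.eap = np.asarray(self.eap, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        t = np.asarray(self.times)
        if not (len(t) == len(self.eap) == len(self.se)):
            raise ValueError("times, eap, se must have equal length")
        tf = self.times_float
        if len(tf) > 1 and not np.all(np.diff(tf) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(self.se > 0):
            raise ValueError("all standard errors must be positive")

    @property
    def times_float(self) -> np.ndarray:
        arr = np.asarray(self.times)
        if np.issubdtype(arr.dtype, np.number):
            return arr.astype(float)
        ts = pd.to_datetime(pd.Series(arr))
        return ((ts - ts.iloc[0]).dt.total_seconds() / 86400.0).to_numpy()

    def __len__(self) -> int:
        return len(self.eap)

    @classmethod
    def from_summary_frame(cls, df: pd.DataFrame, respondent_id: Optional[str] = None) -> "ScoreSeries":
        """Build from a per-assessment summary table (as written by the
        engine: columns participant_id, timestamp, eap, se, ...)."""
        if respondent_id is not None:
            df = df[df["participant_id"] == respondent_id]
        elif "participant_id" in df.columns and df["participant_id"].nunique() == 1:
            respondent_id = str(df["participant_id"].iloc[0])
        df = df.sort_values("timestamp")
        return cls(
            respondent_id=respondent_id or "",
            times=pd.to_datetime(df["timestamp"]).to_numpy(),
            eap=df["eap"].to_numpy(dtype=float),
            se=df["se"].to_numpy(dtype=float),
        )


@dataclass
class SmoothedSeries:
    """LOESS fit of a score series with its SE band."""

    eval_times: np.ndarray
    fitted: np.ndarray
    band_half_width: np.ndarray
    span: float
    degree: int

    @property
    def band_low(self) -> np.ndarray:
        return self.fitted - self.band_half_width

    @property
    def band_high(self) -> np.ndarray:
        return self.fitted + self.band_half_width


def credible_band(series: ScoreSeries, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Per-point credible intervals eap_i +/- z_{(1+level)/2} * se_i."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    z = norm.ppf(0.5 * (1.0 + level))
    return series.eap - z * series.se, series.eap + z * series.se


def density_surface(
    times: Sequence,
    densities: Sequence[np.ndarray],
    grid: QuadratureGrid,
) -> np.ndarray:
    """Stack per-assessment posterior densities into a (time x theta) matrix.

    Every slice is renormalized to integrate to 1 over the shared grid, so a
    darker cell is a more probable true symptom level at that time.
    """
    if len(times) != len(densities):
        raise ValueError("times and densities must have equal length")
    mat = np.empty((len(densities), len(grid)))
    for i, d in enumerate(densities):
        d = np.asarray(d, dtype=float)
        if d.shape != grid.points.shape:
            raise ValueError(
                f"density {i} has {d.size} values but the grid has {len(grid)} points"
            )
        total = float(d @ grid.weights)
        if not total > 0:
            raise ValueError(f"density {i} has no mass")
        mat[i] = d / total
    return mat


def _loess_point(
    t0: float,
    x: np.ndarray,
    y: np.ndarray,
    q: int,
    degree: int,
    level: float,
) -> tuple[float, float]:
    """Local weighted polynomial fit at t0; returns (fit, t-based half-width)."""
    d = np.abs(x - t0)
    # bandwidth = distance to the q-th nearest neighbour
    h = np.sort(d)[q - 1]
    if h <= 0:
        h = np.finfo(float).eps
    u = np.minimum(d / h, 1.0)
    w = (1.0 - u**3) ** 3
    active = w > 0
    xw, yw, ww = x[active], y[active], w[active]
    p = degree + 1
    X = np.vander(xw - t0, N=p, increasing=True)  # column 0 -> intercept = fit
    WX = ww[:, None] * X
    XtWX = X.T @ WX
    beta, *_ = np.linalg.lstsq(XtWX, WX.T @ yw, rcond=None)
    fit = float(beta[0])
    # equivalent-kernel weights l such that fit = l @ y, Var(fit) = sigma^2 ||l||^2
    li = np.linalg.lstsq(XtWX, WX.T, rcond=None)[0][0]
    resid = yw - X @ beta
    nu = max(active.sum() - p, 1)
    sigma2 = float(ww @ resid**2) / max(float(ww.sum()) - p, 1e-12) if active.sum() > p else 0.0
    sigma2 = max(sigma2, 0.0)
    tq = t_dist.ppf(0.5 * (1.0 + level), df=nu)
    half = float(tq * np.sqrt(sigma2 * float(li @ li)))
    return fit, half


def loess_smooth(
    series: ScoreSeries,
    span: float = 0.75,
    degree: int = 1,
    eval_times: Optional[np.ndarray] = None,
    level: float = 0.95,
) -> SmoothedSeries:
    """LOESS: tricube-weighted local polynomial regression of the scores on
    time, with a t-based SE band.

    At each evaluation time the ``ceil(span * n)`` nearest observations are
    fit by weighted least squares (tricube weights on scaled distance); the
    band half-width is the two-sided ``level`` t quantile (local residual
    degrees of freedom) times the fitted value's standard error under
    homoscedastic noise.  The fit is invariant to affine rescaling of time.
    """
    x = series.times_float
    y = series.eap
    n = len(series)
    p = degree + 1
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} points for degree {degree}")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    q = int(np.ceil(span * n))
    if q < p:
        raise ValueError(f"span {span} gives {q} local points; need at least {p}")
    if eval_times is None:
        et = x.copy()
    else:
        et = np.asarray(eval_times, dtype=float)
        if et.size == 0:
            raise ValueError("empty evaluation grid")
    fits = np.empty(et.size)
    halves = np.empty(et.size)
    for i, t0 in enumerate(et):
        fits[i], halves[i] = _loess_point(float(t0), x, y, q, degree, level)
    return SmoothedSeries(
        eval_times=et, fitted=fits, band_half_width=halves, span=span, degree=degree
    )


def cohort_overlay(
    target: ScoreSeries,
    others: Sequence[ScoreSeries],
    time_grid: np.ndarray,
) -> dict[str, np.ndarray]:
    """Contextualize one trajectory against a cohort.

    Each comparison series is linearly interpolated onto the grid inside its
    own observed range (NaN outside — no extrapolation); the envelope is the
    pointwise min / median / max over series defined at each grid time.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.size == 0:
        raise ValueError("empty time grid")
    if len(others) == 0:
        raise ValueError("need at least one comparison series")
    vals = np.full((len(others), time_grid.size), np.nan)
    for i, s in enumerate(others):
        x = s.times_float
        inside = (time_grid >= x[0]) & (time_grid <= x[-1])
        vals[i, inside] = np.interp(time_grid[inside], x, s.eap)
    import warnings

    with warnings.catch_warnings():  # all-NaN grid columns are legitimate
        warnings.simplefilter("ignore", RuntimeWarning)
        env_min = np.nanmin(vals, axis=0)
        env_med = np.nanmedian(vals, axis=0)
        env_max = np.nanmax(vals, axis=0)
    tx = target.times_float
    t_inside = (time_grid >= tx[0]) & (time_grid <= tx[-1])
    t_vals = np.full(time_grid.size, np.nan)
    t_vals[t_inside] = np.interp(time_grid[t_inside], tx, target.eap)
    return {
        "time": time_grid,
        "target": t_vals,
        "min": env_min,
        "median": env_med,
        "max": env_max,
    }


def plot_series(
    series: ScoreSeries,
    out_path: str,
    smoothed: Optional[SmoothedSeries] = None,
    others: Optional[Sequence[ScoreSeries]] = None,
    level: float = 0.95,
) -> None:
    """Render a trajectory (points + credible bars, optional LOESS band and
    gray cohort lines) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    if others:
        for s in others:
            ax.plot(s.times_float, s.eap, color="0.75", lw=0.8, zorder=1)
    lo, hi = credible_band(series, level)
    x = series.times_float
    ax.errorbar(
        x, series.eap, yerr=[series.eap - lo, hi - series.eap],
        fmt="o", ms=3, color="crimson", ecolor="lightcoral", lw=0.8, zorder=3,
    )
    if smoothed is not None:
        ax.plot(smoothed.eval_times, smoothed.fitted, color="navy", lw=1.5, zorder=2)
        ax.fill_between(
            smoothed.eval_times, smoothed.band_low, smoothed.band_high,
            color="navy", alpha=0.15, zorder=2,
        )
    ax.set_xlabel("days since start")
    ax.set_ylabel("latent severity (z score)")
    ax.set_title(series.respondent_id)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
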