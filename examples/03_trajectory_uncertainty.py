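"""Displaying measurement uncertainty around a symptom trajectory.

Simulates one respondent's 12-week recovery monitored daily, then shows the
three uncertainty displays: per-point 95% credible intervals, a posterior
density surface over time, and a LOESS smooth with a t-based SE band.
Writes trajectory.png next to this script.
"""

from datetime import datetime
from pathlib import Path

import numpy as np

from promcat import (
    CATConfig,
    QuadratureGrid,
    ScheduleRegime,
    ScoreSeries,
    SimulatedRespondent,
    TrajectoryProfile,
    credible_band,
    density_surface,
    loess_smooth,
    make_synthetic_bank,
    plot_series,
    run_study,
)

start = datetime(2022, 7, 13)
bank = make_synthetic_bank()
patient = SimulatedRespondent(
    "p0",
    TrajectoryProfile(kind="recovery", baseline=1.4, recovery_rate=0.04, asymptote=-1.0),
    compliance=0.9,
    seed=1,
)
result = run_study([patient], bank, CATConfig(),
                   {"p0": ScheduleRegime(kind="daily", start=start, weeks=12)}, seed=7)

series = ScoreSeries.from_summary_frame(result.assessments)
lo, hi = credible_band(series, level=0.95)
print(f"{len(series)} assessments over 12 weeks")
print(f"first score {series.eap[0]:+.2f} (95% CI {lo[0]:+.2f}..{hi[0]:+.2f}), "
      f"last score {series.eap[-1]:+.2f} (95% CI {lo[-1]:+.2f}..{hi[-1]:+.2f})")

# posterior density surface: each row is a normalized density over theta
grid = QuadratureGrid.default()
from scipy.stats import norm
densities = [norm.pdf(grid.points, m, s) for m, s in zip(series.eap, series.se)]
surface = density_surface(series.times_float, densities, grid)
print(f"density surface: {surface.shape[0]} time slices x {surface.shape[1]} theta points, "
      f"each slice integrates to {float(surface[0] @ grid.weights):.6f}")

smoothed = loess_smooth(series, span=0.75, degree=1)
mid = len(smoothed.eval_times) // 2
print(f"LOESS at day {smoothed.eval_times[mid]:.0f}: fit {smoothed.fitted[mid]:+.3f} "
      f"± {smoothed.band_half_width[mid]:.3f} (t-based 95% band)")

out = Path(__file__).parent / "trajectory.png"
plot_series(series, str(out), smoothed=smoothed)
print(f"wrote {out}")
# The credible bars show per-measurement uncertainty; the LOESS band shows
# uncertainty about the smooth underlying trajectory — much tighter, because
# it pools information across neighbouring days.
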