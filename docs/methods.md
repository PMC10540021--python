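# Methods

## Measurement model

Items follow Samejima's graded response model (GRM) with a pure logistic
link. We use the slope–threshold parameterization
`P(X ≥ k+1 | θ) = logistic(a(θ − b_k))` and do **not** apply the 1.7
normal-ogive scaling constant; any bank calibrated with the scaling constant
folded into `a` is still usable unchanged, but mixing conventions within one
bank is not detectable and is the user's responsibility. Categories are
numbered 1..K externally and thresholds 1..K−1, with `b_k` separating
categories ≤ k from > k. The latent trait θ is a z score: 0 at the
calibration-sample mean, unit population SD, higher = more severe (the
orientation flag is carried on the bank).

Fisher information is computed as `Σ_k P'_k² / P_k`; the second-derivative
terms cancel because the category probabilities sum to one. For a
dichotomous item this reduces to the familiar `a² p(1−p)`.

## Scoring

EAP estimation integrates the posterior on a fixed quadrature grid:
161 equally spaced points on [−6, 6] with trapezoid weights. The wide
support matters because dynamic priors recentre posteriors away from 0; at
this density the EAP and posterior SD agree with a 10,001-point reference
quadrature to better than 1e−4 (tested). Likelihoods are accumulated in log
space and exponentiated after subtracting the running maximum, so long
response vectors cannot underflow; a posterior that is numerically zero at
every grid point (mutually contradictory near-deterministic responses)
raises a dedicated error rather than returning garbage.

The reported SE of measurement is the posterior SD, and all credible
intervals are the normal approximation `eap ± 1.959964 · se` at the fixed
95% level. Marginal reliability is `1 − se²` under the unit-variance latent
scale convention, so the default SE threshold of 0.3 corresponds to 0.91.

## Adaptive administration

Selection criteria:

- **MEPV** (default): for each candidate item, the expected posterior
  variance `Σ_k p̂_k · Var(θ | responses ∪ {k})`, with `p̂` the
  posterior-predictive category probabilities; the candidate minimizing this
  is posed. By the law of total variance the value never exceeds the current
  posterior variance (property-tested).
- **Maximum information** at the current EAP.
- **Randomesque exposure control**: with `randomesque_n = n > 1`, a uniform
  draw among the n best candidates under the active criterion (clamped to
  the number remaining). `n = 1` is fully deterministic.

Ties break toward the lowest bank index, making runs reproducible.

Stopping: stop once the posterior SD falls below `se_threshold`
(default 0.3) — but only after `min_items` (default 1) items, so a tight
carried-over prior can never produce a zero-item assessment — or when
`max_items` is reached, or when the bank is exhausted. The termination
reason (`se_met`, `max_items`, `bank_exhausted`) is recorded. The final
summary is recomputed in one batch pass over the collected responses, so a
bank-exhausting adaptive run is bitwise identical to full-length scoring of
the same answers.

## Dynamic priors

The prior for a respondent's next assessment is the normal approximation to
the previous posterior, `N(eap, se)`, optionally inflated:
`sd = sqrt(max(se, 0.1)² + inflation²)`. We carry the normal approximation
rather than the raw gridded density because it matches the credible-interval
convention used everywhere else, keeps priors closed-form, and makes the
carried state two numbers; raw-density carryover would be a straightforward
extension. The 0.1 SD floor prevents the prior from collapsing over many
chained assessments. Default inflation is 0; a positive value is the natural
way to encode expected between-occasion drift.

## Schedules and the study simulator

Three regimes: thrice weekly (Mon/Wed/Fri), daily, and thrice daily, at
09:00 (and 14:00/20:00 for thrice daily) by default — no canonical
notification times exist for these regimes, so these are configurable
waking-hours defaults. Weeks are 7-day blocks anchored at the start date,
which makes occasion counts exact (3/7/21 per week; 36/84/252 over 12 weeks)
regardless of the start weekday.

Simulated respondents combine a latent trajectory, a per-occasion compliance
probability, and a log-normal notification-to-response delay (median 54
minutes by default; delays shift timestamps only and never affect scores).
Two trajectory archetypes:

- **recovery**: `θ(t) = asymptote + (baseline − asymptote)·exp(−rate·t)` —
  monotone improvement, as after an uncomplicated fracture;
- **fluctuating**: baseline + a sinusoidal diurnal term (severity peaking
  late afternoon by default) + daily AR(1) noise (stationary SD
  `noise_scale`, coefficient 0.7) + an optional intervention dip of depth
  `d` shaped `−d·sin(π·(t−t₀)/rebound)`, which reaches its trough mid-way
  and returns exactly to baseline at `t₀ + rebound` — a steroid-injection-like
  transient.

The AR(1) noise path is precomputed per profile from its own seed, indexed
by study day, so trajectory evaluation is deterministic and independent of
the order or number of queries. Compliance is independent of latent
severity; informative missingness is a known omission, so simulated response
rates say nothing about whether sicker patients respond less.

The study runner chains assessments per respondent (standard normal prior
first, dynamic priors thereafter), adds full-length administrations on the
first completed scheduled day at/after weeks 0, 6 and 12 (the week-12 target
clamps to the final scheduled day) *on the same latent value* as that day's
adaptive assessment, and logs everything with timestamps. One master seed
drives the entire run through spawned per-respondent substreams;
whole-study reruns are frame-identical (tested).

## The synthetic item bank

The bank generator emulates an 11-item hand-function PROM scored with 7
response categories whose registry-derived GRM calibration is not publicly
printed: discriminations uniform on [1.5, 2.5], per-item thresholds equally
spaced 0.7 apart and centred on midpoints spread evenly over [−2, 2]
(interleaved so bank order does not follow severity), generation seed fixed
at 20220713. It reproduces the instrument's *structure*, not its
calibration. One visible consequence: these moderate slopes carry less
information per item than a well-calibrated clinical instrument, so
simulated assessments typically need around 8 items to reach SE < 0.3 from
a cold standard-normal prior (a strongly calibrated bank gets there in 2–3).
Agreement and stopping properties are unaffected, but absolute
items-per-assessment figures from this bank should not be read as what a
real calibrated instrument would achieve.

## Trajectory analytics

- **Credible bands**: `eap ± z_{(1+level)/2}·se` per assessment.
- **Density surface**: per-assessment posterior densities stacked over time,
  each slice renormalized to integrate to 1 on the shared grid.
- **LOESS**: local polynomial regression with tricube weights on the
  `ceil(span·n)` nearest neighbours, degree 1 and span 0.75 by default, no
  robustness iterations. Degree 1 avoids endpoint oscillation on short
  series; all three are configurable. The SE band is t-based: with
  equivalent-kernel weights `l` (so the fit is `lᵀy`), the half-width is
  `t_{0.975,ν} · sqrt(σ̂² · lᵀl)` with `σ̂² = Σwr²/(Σw − p)` from the local
  weighted residuals and `ν` the count of positively weighted points minus
  the number of local parameters. Exact on collinear data and affine-
  invariant in time (both tested, including against an independent per-point
  weighted-least-squares oracle and statsmodels' lowess).
- **Cohort overlay**: comparison series are linearly interpolated onto a
  grid strictly inside their observed ranges (no extrapolation) and
  summarized as a min/median/max envelope — honest for the ~20-patient
  cohorts this display is meant for, where estimated quantiles would be
  noise.

## Classical scoring

Non-IRT scales scored by item means (e.g. a 30-item user-engagement
questionnaire with four subscales) use `scale_mean_score`: the mean of
observed item scores, with the response set excluded outright when more
than one item (configurable) is missing.

## Numerical and design notes

- Every stochastic operation takes an explicit `numpy` Generator; there is
  no hidden global random state.
- Interchange formats are plain UTF-8 CSV with headers and ISO-8601
  timestamps; simulated response times are rounded to whole seconds so
  write→read round trips are exact.
- The per-assessment summary CSV includes a `timestamp` column so the
  trajectory tools can be driven directly from engine output.
- Item parameter estimation/calibration is out of scope: banks arrive
  already parameterized. Only the graded response model is supported.
- The paired adaptive-vs-full-length experiment
  (`simulate_cat_vs_full`) uses 5,000 respondents in the acceptance script
  and 2,000 in the recovery property test; both sizes give Monte-Carlo error
  an order of magnitude below the tolerances checked.

## Known limitations

- Maximum-likelihood / weighted-likelihood estimators, content balancing and
  decision-tree adaptive testing for non-IRT instruments are not
  implemented.
- The normal approximation in the dynamic prior discards posterior skewness;
  for respondents near the scale extremes the carried prior is slightly
  miscentred.
- Compliance is modelled independent of severity (see above), and the
  synthetic bank is a structural stand-in, not a clinical calibration.
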