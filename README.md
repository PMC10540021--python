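# promcat

Adaptive, low-burden scoring of patient-reported outcome measures (PROMs)
for high-frequency remote symptom monitoring.

Frequent in-situ assessment (ecological momentary assessment) gives much
richer symptom trajectories than occasional clinic questionnaires, but asking
a patient to complete a full-length PROM several times a day is not
sustainable. `promcat` implements the computational core that makes the
combination workable: item-response-theory **computerized adaptive testing**
(CAT), which poses only the most informative items for each respondent and
stops as soon as the score is precise enough, plus Bayesian **dynamic
priors** that carry each assessment's posterior into the next one, and
**trajectory analytics** that keep individual-level measurement uncertainty
visible.

The package is aimed at psychometricians and clinical researchers who want to
simulate, calibrate or run momentary CAT protocols from Python.

## The model

Items are ordinal (K response categories) and follow Samejima's graded
response model with a logistic link: for discrimination $a_j > 0$ and ordered
thresholds $b_{j1} < \dots < b_{j,K-1}$,

$$P(X_j \ge k + 1 \mid \theta) = \frac{1}{1 + e^{-a_j(\theta - b_{jk})}},$$

with category probabilities given by adjacent differences. The latent
severity $\theta$ lives on a z-score (logit) scale — 0 is the calibration
sample mean, higher is worse.

Scoring is **expected a posteriori** (EAP): the posterior mean of $\theta$
under a normal prior, computed on a 161-point quadrature grid; the posterior
SD is the SE of measurement, and 95% credible intervals use the normal
approximation $\hat\theta \pm 1.96\,\mathrm{SE}$. Item selection is
**minimum expected posterior variance** (MEPV): the next item minimizes the
posterior-predictive-weighted variance of the updated posterior (maximum
Fisher information and randomesque exposure control are also available).
The default stopping rule ends the assessment once SE $< 0.3$, which
corresponds to marginal reliability $1 - 0.3^2 = 0.91$. For repeated
assessments the prior of assessment $t+1$ is the normal approximation
$N(\hat\theta_t, \mathrm{SE}_t)$ to assessment $t$'s posterior (the *dynamic
prior*), so a stable patient's next assessment can stop after a single item.

## Worked example

`examples/01_adaptive_assessment.py` administers one adaptive assessment to
a simulated respondent with true severity $\theta = 0.2$:

```
step  item    cat   eap     se
   1  item11    5  -0.066  0.580
   2  item01    5  +0.504  0.512
   3  item04    5  +0.178  0.435
   4  item03    7  +0.353  0.402
   5  item07    2  +0.236  0.355
   6  item02    7  +0.307  0.338
   7  item09    6  +0.395  0.323
   8  item05    4  +0.347  0.302
   9  item08    2  +0.332  0.286

final: eap=+0.332 (z score; higher = more severe), se=0.286, 95% CI=(-0.229, +0.892)
terminated after 9/11 items (se_met)
```

Each response multiplies the likelihood into the posterior; the EAP estimate
homes in on the true severity while the SE of measurement falls, and the
assessment stops the moment it crosses 0.3. `examples/02_simulated_study.py`
runs a small multi-respondent study with the three scheduling regimes
(thrice weekly / daily / thrice daily) and `examples/03_trajectory_uncertainty.py`
shows the three uncertainty displays (credible bars, posterior density
surface, LOESS band).

A thin CLI wraps the same library calls:

```bash
promcat validate-bank --bank bank.csv
promcat administer --bank bank.csv --responses responses.csv --out-dir run/
promcat simulate-study --config study.yaml --seed 1 --out-dir study/
promcat smooth --summary study/assessment_summaries.csv --out smoothed.csv
promcat compare --cat study/assessment_summaries.csv --full study/full_length_summaries.csv
```

## Layout

- `src/promcat/bank.py` — item banks, CSV interchange, synthetic bank generator
- `src/promcat/grm.py` — graded-response probabilities, likelihoods, information
- `src/promcat/scoring.py` — EAP scoring, posteriors, dynamic priors, classical mean scoring
- `src/promcat/cat.py` — item selection, stopping rules, assessment loop
- `src/promcat/ema.py` — schedules, latent trajectories, study simulation, summaries
- `src/promcat/smooth.py` — credible bands, density surfaces, LOESS, cohort overlays
- `src/promcat/io.py`, `src/promcat/cli.py` — file formats, configuration, CLI

See `docs/methods.md` for modelling assumptions, defaults and limitations.
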