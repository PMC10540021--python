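"""Independent brute-force oracles used by the tests.

Everything here recomputes quantities from first principles — direct logistic
evaluation, dense-grid quadrature, exhaustive enumeration — deliberately not
sharing code paths with the package internals it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from scipy.stats import norm

#: dense independent quadrature grid (10,001 points)
FINE_N = 10_001
FINE_LO, FINE_HI = -8.0, 8.0


def fine_grid() -> tuple[np.ndarray, np.ndarray]:
    x = np.linspace(FINE_LO, FINE_HI, FINE_N)
    w = np.full(FINE_N, (FINE_HI - FINE_LO) / (FINE_N - 1))
    w[0] /= 2
    w[-1] /= 2
    return x, w


def grm_category_probs(theta, a: float, thresholds) -> np.ndarray:
    """Direct adjacent-difference evaluation of graded-model probabilities."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    b = np.asarray(thresholds, dtype=float)
    cum = expit(a * (theta[:, None] - b[None, :]))
    full = np.hstack([np.ones((theta.size, 1)), cum, np.zeros((theta.size, 1))])
    return full[:, :-1] - full[:, 1:]


def likelihood_on(x: np.ndarray, responses) -> np.ndarray:
    """Product of category probabilities at each x; responses are
    (a, thresholds, category) triples."""
    lik = np.ones_like(x)
    for a, thresholds, cat in responses:
        lik *= grm_category_probs(x, a, thresholds)[:, cat - 1]
    return lik


def eap_oracle(responses, prior_mean: float, prior_sd: float):
    """(eap, posterior sd) by dense quadrature."""
    x, w = fine_grid()
    post = likelihood_on(x, responses) * norm.pdf(x, prior_mean, prior_sd)
    total = post @ w
    mean = (x * post) @ w / total
    var = ((x - mean) ** 2 * post) @ w / total
    return float(mean), float(np.sqrt(var))


def posterior_variance_oracle(responses, prior_mean, prior_sd) -> float:
    return eap_oracle(responses, prior_mean, prior_sd)[1] ** 2


def predictive_probs_oracle(item_a, item_b, responses, prior_mean, prior_sd) -> np.ndarray:
    """Posterior-predictive category probabilities of a candidate item."""
    x, w = fine_grid()
    post = likelihood_on(x, responses) * norm.pdf(x, prior_mean, prior_sd)
    post = post / (post @ w)
    probs = grm_category_probs(x, item_a, item_b)
    return (post * w) @ probs


def epv_oracle(item_a, item_b, responses, prior_mean, prior_sd) -> float:
    """Expected posterior variance by exhaustive enumeration of categories."""
    pred = predictive_probs_oracle(item_a, item_b, responses, prior_mean, prior_sd)
    out = 0.0
    for k in range(len(item_b) + 1):
        if pred[k] <= 0:
            continue
        var_k = posterior_variance_oracle(
            list(responses) + [(item_a, item_b, k + 1)], prior_mean, prior_sd
        )
        out += pred[k] * var_k
    return float(out)


def fisher_information_fd(a, thresholds, theta0: float, h: float = 1e-3) -> float:
    """Finite-difference oracle: minus the second derivative (in theta) of
    the expected log-likelihood E_{theta0}[log P_X(theta)] at theta0."""
    p0 = grm_category_probs(theta0, a, thresholds)[0]

    def g(th):
        p = grm_category_probs(th, a, thresholds)[0]
        return float(p0 @ np.log(p))

    return -(g(theta0 + h) - 2.0 * g(theta0) + g(theta0 - h)) / (h * h)


def local_wls_fit(x, y, t0: float, span: float, degree: int) -> float:
    """Explicit single-point tricube weighted least squares (LOESS oracle)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    q = int(np.ceil(span * n))
    d = np.abs(x - t0)
    h = np.sort(d)[q - 1]
    h = max(h, np.finfo(float).eps)
    w = np.clip(1.0 - np.minimum(d / h, 1.0) ** 3, 0.0, None) ** 3
    X = np.column_stack([(x - t0) ** j for j in range(degree + 1)])
    W = np.diag(w)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    return float(beta[0])
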