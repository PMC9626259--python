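"""Small penalized logistic-regression core shared by the assay and demography fits.

Bootstrap refits of the pregnancy model routinely hit complete separation
(the reference concentrations have a wide gap between classes), so every fit
carries a tiny ridge penalty that keeps the Newton iteration bounded while
leaving well-identified fits essentially unchanged.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def _penalized_nll(beta: np.ndarray, X: np.ndarray, y: np.ndarray, ridge: float) -> float:
    eta = X @ beta
    # log(1 + e^eta) - y*eta, stable for large |eta|
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * ridge * beta @ beta)


def fit_logistic(
    x: np.ndarray,
    y: np.ndarray,
    ridge: float = 1e-4,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> np.ndarray:
    """Fit ``y ~ Bernoulli(expit(b0 + b1*x))`` by damped Newton iteration.

    Parameters
    ----------
    x, y
        Covariate and 0/1 response arrays of equal length.
    ridge
        L2 penalty on both coefficients; must be > 0 so separated data stay
        finite.

    Returns
    -------
    ndarray of shape (2,) — (intercept, slope).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if ridge <= 0:
        raise ValueError("ridge must be positive")
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    nll = _penalized_nll(beta, X, y, ridge)
    for _ in range(max_iter):
        p = expit(X @ beta)
        grad = X.T @ (p - y) + ridge * beta
        w = np.maximum(p * (1.0 - p), 1e-12)
        hess = (X * w[:, None]).T @ X + ridge * np.eye(2)
        step = np.linalg.solve(hess, grad)
        # backtracking line search on the penalized objective
        t = 1.0
        for _ in range(40):
            cand = beta - t * step
            cand_nll = _penalized_nll(cand, X, y, ridge)
            if cand_nll <= nll:
                break
            t *= 0.5
        if abs(nll - cand_nll) < tol and np.max(np.abs(t * step)) < 1e-8:
            beta = cand
            break
        beta, nll = cand, cand_nll
    return beta


def predict_logistic(beta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """expit(b0 + b1*x); ``beta`` may be (2,) or (B, 2) for replicate sets."""
    beta = np.asarray(beta, dtype=float)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if beta.ndim == 1:
        return expit(beta[0] + beta[1] * x)
    return expit(beta[:, [0]] + beta[:, [1]] * x[None, :])
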