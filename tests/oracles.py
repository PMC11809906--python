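"""Independent maximum-likelihood oracles for the count GLMs.

Hand-written log-likelihoods maximized by Newton / Fisher scoring (Poisson)
and profile likelihood over the dispersion (NB2). These never touch the
package's fitting path; tests compare the two routes.
"""

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln


def poisson_loglik(beta, y, X, offset):
    eta = X @ beta + offset
    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1)))


def fit_poisson_oracle(y, X, offset, tol=1e-12, maxiter=200):
    """Newton-Raphson on the written Poisson log-likelihood."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        mu = np.exp(X @ beta + offset)
        grad = X.T @ (y - mu)
        hess = X.T @ (mu[:, None] * X)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def nb2_loglik(beta, alpha, y, X, offset):
    mu = np.exp(X @ beta + offset)
    size = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + size)
            - gammaln(size)
            - gammaln(y + 1)
            + size * np.log(size / (size + mu))
            + y * np.log(mu / (size + mu))
        )
    )


def _nb2_beta_given_alpha(alpha, y, X, offset, tol=1e-12, maxiter=500):
    beta = fit_poisson_oracle(y, X, offset)  # start from the Poisson solution
    for _ in range(maxiter):
        mu = np.exp(X @ beta + offset)
        grad = X.T @ ((y - mu) / (1.0 + alpha * mu))
        w = mu / (1.0 + alpha * mu)  # Fisher scoring weights
        hess = X.T @ (w[:, None] * X)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def fit_nb2_oracle(y, X, offset, alpha_bounds=(1e-8, 50.0)):
    """Profile likelihood: Brent search over alpha, Fisher scoring for beta."""

    def neg_profile(log_alpha):
        a = np.exp(log_alpha)
        b = _nb2_beta_given_alpha(a, y, X, offset)
        return -nb2_loglik(b, a, y, X, offset)

    res = minimize_scalar(
        neg_profile,
        bounds=(np.log(alpha_bounds[0]), np.log(alpha_bounds[1])),
        method="bounded",
        options={"xatol": 1e-13},
    )
    alpha = float(np.exp(res.x))
    beta = _nb2_beta_given_alpha(alpha, y, X, offset)
    return beta, alpha
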