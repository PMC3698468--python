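"""Independent oracles used by the test suite.

Each oracle deliberately takes a different computational route from the
library code it checks: brute-force expansion instead of the quadratic
form for PSE, hand-rolled IRLS instead of the penalised Newton solver for
the GLM limit, and adaptive Gauss-Hermite quadrature instead of the
Laplace approximation for single-factor marginal likelihoods.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit, gammaln, logsumexp


def expansion_pse(C, abundances) -> float:
    """Phylogenetic species evenness by individual expansion.

    Each species i is replaced by ``m_i`` individuals attached by
    zero-length branches, so individuals of one species correlate
    perfectly and individuals of different species correlate like their
    species.  The numerator — the summed trait divergence
    ``1 - corr`` over ordered pairs of distinct individuals — is
    accumulated by explicit double loop; the standardisation is the
    index's maximum, attained on a star phylogeny with perfectly even
    abundances.
    """
    C = np.asarray(C, dtype=float)
    m = np.asarray(abundances)
    present = np.flatnonzero(m > 0)
    individuals = [i for i in present for _ in range(int(m[i]))]
    N = len(individuals)
    n = len(present)
    if n < 2:
        raise ValueError("need at least two present species")
    total = 0.0
    for a in range(N):
        for b in range(N):
            if a == b:
                continue
            ia, ib = individuals[a], individuals[b]
            corr = 1.0 if ia == ib else C[ia, ib]
            total += 1.0 - corr
    mbar = N / n
    return total / (N * N - N * mbar)


def irls_logistic(y, n, X, tol=1e-12, max_iter=200):
    """Binomial-logit GLM by plain iteratively reweighted least squares.

    Returns (beta, deviance).  Written from the textbook recursion
    ``beta <- (X' W X)^-1 X' W z`` with working response
    ``z = eta + (y - n mu) / W``.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    X = np.asarray(X, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        W = np.maximum(n * mu * (1 - mu), 1e-10)
        z = eta + (y - n * mu) / W
        beta_new = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    mu = expit(eta)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = 2.0 * np.sum(
            np.where(y > 0, y * np.log(y / (n * mu)), 0.0)
            + np.where(y < n, (n - y) * np.log((n - y) / (n - n * mu)), 0.0)
        )
    return beta, float(dev)


def agq_single_factor_loglik(y, n, eta_fixed, sigma, groups, n_points=25):
    """Marginal log-likelihood of a one-random-intercept binomial model.

    Adaptive Gauss-Hermite quadrature, centred and scaled at each group's
    conditional mode.  Includes the binomial coefficient terms so the
    value is directly comparable to a full log-likelihood.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    eta_fixed = np.broadcast_to(np.asarray(eta_fixed, dtype=float), y.shape)
    groups = np.asarray(groups)
    nodes, weights = hermgauss(n_points)
    total = float(np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)))
    for g in np.unique(groups):
        sel = groups == g
        yg, ng, fg = y[sel], n[sel], eta_fixed[sel]

        def h(u):
            eta = fg + sigma * u
            return float(np.sum(yg * eta - ng * np.logaddexp(0.0, eta)) - 0.5 * u * u)

        # scalar Newton for the conditional mode
        u = 0.0
        for _ in range(100):
            eta = fg + sigma * u
            mu = expit(eta)
            grad = float(sigma * np.sum(yg - ng * mu) - u)
            hess = -float(sigma * sigma * np.sum(ng * mu * (1 - mu)) + 1.0)
            step = grad / hess
            u_new = u - step
            if abs(u_new - u) < 1e-13:
                u = u_new
                break
            u = u_new
        eta = fg + sigma * u
        mu = expit(eta)
        tau = 1.0 / np.sqrt(sigma * sigma * np.sum(ng * mu * (1 - mu)) + 1.0)
        z = u + np.sqrt(2.0) * tau * nodes
        log_terms = np.array([h(zk) for zk in z]) + nodes**2 + np.log(weights)
        total += float(logsumexp(log_terms) + np.log(np.sqrt(2.0) * tau) - 0.5 * np.log(2 * np.pi))
    return total
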