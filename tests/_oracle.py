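"""Independent brute-force reference implementations used only by tests.

Deliberately written in plain, loop-heavy textbook style, with
scipy.stats densities, so they share no code path with the package.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def oracle_posteriors(y, mu, sigma2, pi):
    """Direct evaluation of p_ij = pi_j f_j(y_i) / sum_k pi_k f_k(y_i)."""
    y = np.asarray(y, dtype=float)
    out = np.zeros((len(y), 5))
    for i in range(len(y)):
        dens = np.array([pi[j] * norm.pdf(y[i], loc=mu[j],
                                          scale=np.sqrt(sigma2))
                         for j in range(5)])
        out[i] = dens / dens.sum()
    return out


def oracle_loglik(y, mu, sigma2, pi):
    total = 0.0
    for yi in np.asarray(y, dtype=float):
        dens = sum(pi[j] * norm.pdf(yi, loc=mu[j], scale=np.sqrt(sigma2))
                   for j in range(5))
        total += np.log(dens)
    return total


def oracle_gmm_em(y, mu0, sigma2_0, pi0, tol=1e-8, max_iter=2000):
    """Textbook 5-component common-variance Gaussian mixture EM.

    Free mixing proportions, free means, shared variance.  Returns
    (mu, sigma2, pi, loglik, trace).
    """
    y = np.asarray(y, dtype=float)
    mu = np.array(mu0, dtype=float)
    sigma2 = float(sigma2_0)
    pi = np.array(pi0, dtype=float)
    ll_old = oracle_loglik(y, mu, sigma2, pi)
    trace = [ll_old]
    for _ in range(max_iter):
        resp = oracle_posteriors(y, mu, sigma2, pi)
        nk = resp.sum(axis=0)
        pi = nk / len(y)
        for j in range(5):
            if nk[j] > 1e-12:
                mu[j] = (resp[:, j] * y).sum() / nk[j]
        sigma2 = sum((resp[:, j] * (y - mu[j]) ** 2).sum()
                     for j in range(5)) / len(y)
        ll = oracle_loglik(y, mu, sigma2, pi)
        trace.append(ll)
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    return mu, sigma2, pi, trace[-1], trace
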