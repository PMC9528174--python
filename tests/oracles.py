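"""Independent reference implementations used as oracles by the tests.

Kept free of bioagestack imports so the checks stay independent of the code
paths they verify.
"""

import numpy as np


def irls(X, y, family, n_iter=200, tol=1e-12):
    """Newton/IRLS for linear, Poisson (log link) and logistic models,
    written with plain numpy linear algebra."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if family == "linear":
        return np.linalg.solve(X.T @ X, X.T @ y)
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        if family == "poisson":
            mu = np.exp(eta)
            w = mu
        elif family == "logistic":
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
        else:
            raise ValueError(family)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta
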