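"""Independent epsilon-SVR oracle: direct solve of the dual program.

minimize_beta  1/2 beta' K beta - y' beta + eps * ||beta||_1
subject to     sum(beta) = 0,  -C <= beta_i <= C

solved smoothly via the split beta = p - q with p, q in [0, C], using
scipy SLSQP.  The bias is recovered from the KKT conditions at
in-tube support vectors.  This path shares nothing with the package's
fitting backend.
"""

import numpy as np
from scipy.optimize import minimize


def rbf_gram(X, gamma):
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    return np.exp(-gamma * np.maximum(d2, 0.0))


def solve_svr_dual(X, y, C, gamma, eps):
    """Return (beta, bias) of the epsilon-SVR dual."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    K = rbf_gram(X, gamma)

    def objective(v):
        p, q = v[:n], v[n:]
        beta = p - q
        return 0.5 * beta @ K @ beta - y @ beta + eps * np.sum(p + q)

    def grad(v):
        p, q = v[:n], v[n:]
        Kb = K @ (p - q)
        return np.concatenate([Kb - y + eps, -Kb + y + eps])

    cons = {"type": "eq", "fun": lambda v: np.sum(v[:n] - v[n:]),
            "jac": lambda v: np.concatenate([np.ones(n), -np.ones(n)])}
    res = minimize(
        objective,
        x0=np.zeros(2 * n),
        jac=grad,
        bounds=[(0.0, C)] * (2 * n),
        constraints=[cons],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    assert res.success, res.message
    beta = res.x[:n] - res.x[n:]
    # KKT: for 0 < p_i < C (upper tube) y_i - (K beta)_i - b = eps;
    # for 0 < q_i < C, y_i - (K beta)_i - b = -eps
    Kb = K @ beta
    tol = 1e-6 * C
    biases = []
    for i in range(n):
        p_i, q_i = res.x[i], res.x[n + i]
        if tol < p_i < C - tol:
            biases.append(y[i] - Kb[i] - eps)
        elif tol < q_i < C - tol:
            biases.append(y[i] - Kb[i] + eps)
    if not biases:  # all at bounds; fall back to midpoint estimate
        biases = [np.median(y - Kb)]
    return beta, float(np.mean(biases))


def predict_dual(X_train, beta, bias, gamma, X_new):
    X_train = np.asarray(X_train, float)
    X_new = np.atleast_2d(np.asarray(X_new, float))
    d2 = (
        np.sum(X_new**2, axis=1)[:, None]
        + np.sum(X_train**2, axis=1)[None, :]
        - 2.0 * X_new @ X_train.T
    )
    return np.exp(-gamma * np.maximum(d2, 0.0)) @ beta + bias
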