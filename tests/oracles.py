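"""Independent brute-force oracles used by the test suite.

Each oracle is written the transparent way (explicit loops, explicit
matrix inverses, risk sets built as Python sets) so it shares no code path
with the implementation it checks.
"""

import numpy as np


def ols_normal_equations(Y, X):
    """beta = (X'X)^{-1} X'Y by explicit inverse."""
    xtx = np.linalg.inv(X.T @ X)
    return xtx @ (X.T @ Y)


def log_odds_ratio_2x2(a, b, c, d):
    """Closed-form logistic slope for a 2x2 table: log(ad / bc)."""
    return np.log(a * d / (b * c))


def gls_dense(Y, X, weight):
    """GLS by explicit inversion: (X'WX)^{-1} X'WY."""
    xwx = np.linalg.inv(X.T @ weight @ X)
    return xwx @ (X.T @ weight @ Y)


def hc0_sandwich(X, resid):
    bread = np.linalg.inv(X.T @ X)
    meat = X.T @ np.diag(resid**2) @ X
    return bread @ meat @ bread


def cox_partial_loglik(beta, time, status, X):
    """Breslow/no-ties partial log-likelihood by risk-set enumeration."""
    beta = np.atleast_1d(np.asarray(beta, float))
    ll = 0.0
    for i in range(len(time)):
        if status[i] != 1:
            continue
        risk = [j for j in range(len(time)) if time[j] >= time[i]]
        denom = sum(np.exp(X[j] @ beta) for j in risk)
        ll += X[i] @ beta - np.log(denom)
    return float(ll)


def cox_newton_enumerated(time, status, X, n_iter=30):
    """Newton maximization with derivatives by risk-set enumeration."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(time):
        X = X.T
    p = X.shape[1]
    beta = np.zeros(p)
    for _ in range(n_iter):
        grad = np.zeros(p)
        info = np.zeros((p, p))
        for i in range(len(time)):
            if status[i] != 1:
                continue
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            w = np.array([np.exp(X[j] @ beta) for j in risk])
            s0 = w.sum()
            s1 = (w[:, None] * X[risk]).sum(axis=0)
            s2 = sum(w[k] * np.outer(X[risk][k], X[risk][k]) for k in range(len(risk)))
            grad += X[i] - s1 / s0
            info += s2 / s0 - np.outer(s1 / s0, s1 / s0)
        beta = beta + np.linalg.solve(info, grad)
    return beta, np.linalg.inv(info)
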