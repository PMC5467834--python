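"""Independent oracles used by the test suite.

These deliberately avoid the code paths they certify: the group elastic
net is re-solved by iteratively reweighted ridge regression (a
majorise-minimise scheme whose every step is a closed-form linear solve),
and AUC is recomputed by brute-force enumeration of all
positive/negative pairs.
"""

from __future__ import annotations

import numpy as np


def irls_group_elastic_net(X, Y, groups, gammas, lam, alpha,
                           eps: float = 1e-9, max_iter: int = 5000,
                           tol: float = 1e-13):
    """Majorise-minimise solution of the group elastic net.

    Uses the bound ||b_i|| <= ||b_i||^2/(2 w_i) + w_i/2 with weights
    w_i = max(||b_i||, eps), so each iteration solves a ridge system
    (X^t X + 2 alpha I + lam * diag(gamma_i / w_i)) b = X^t Y on centred
    data.  Converges to the eps-smoothed objective's minimiser; the gap
    to the exact optimum is at most lam * sum(gamma) * eps / 2.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    P = X.shape[1]
    G = Xc.T @ Xc
    XtY = Xc.T @ Yc
    beta = np.zeros((P, Y.shape[1]))
    prev = np.inf
    for _ in range(max_iter):
        w = np.empty(P)
        for i, g in enumerate(groups):
            w[g] = gammas[i] / max(np.linalg.norm(beta[g]), eps)
        A = G + 2.0 * alpha * np.eye(P) + lam * np.diag(w)
        beta = np.linalg.solve(A, XtY)
        obj = group_objective_value(Xc, Yc, beta, lam, alpha, gammas,
                                    groups)
        if abs(prev - obj) <= tol * max(1.0, abs(obj)):
            break
        prev = obj
    return beta


def group_objective_value(Xc, Yc, beta, lam, alpha, gammas, groups):
    R = Yc - Xc @ beta
    pen = sum(gammas[i] * np.linalg.norm(beta[g])
              for i, g in enumerate(groups))
    return (0.5 * float(np.sum(R ** 2)) + lam * pen
            + alpha * float(np.sum(beta ** 2)))


def pairwise_auc(scores, labels) -> float:
    """AUC by enumeration of all positive/negative pairs; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (pos.size * neg.size)


def random_grouped_problem(rng, n_rows=None, n_groups=None, d=None,
                           sparse_truth=True):
    """Small random grouped regression instance for solver checks."""
    n = n_rows or int(rng.integers(12, 31))
    q = n_groups or int(rng.integers(2, 6))
    d_ = d or int(rng.integers(1, 4))
    sizes = rng.integers(1, 5, size=q)
    X = rng.standard_normal((n, int(sizes.sum())))
    groups, start = [], 0
    for m in sizes:
        groups.append(np.arange(start, start + m))
        start += m
    gammas = np.sqrt(sizes.astype(float))
    beta = np.zeros((start, d_))
    for i, g in enumerate(groups):
        if not sparse_truth or rng.random() < 0.5:
            beta[g] = rng.standard_normal((g.size, d_))
    Y = X @ beta + 0.5 * rng.standard_normal((n, d_))
    return X, Y, groups, gammas
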