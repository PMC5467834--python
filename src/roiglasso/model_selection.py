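"""Generalised cross-validation, degrees of freedom, and lambda selection.

GCV scores a fit by its residual sum of squares inflated by the effective
degrees of freedom:

    GCV = (1/(NT)) ||Y - Yhat||_F^2 / (1 - df/NT)^2 .

For the ridge/minimum-norm inverse the df is the exact hat-matrix trace.
For the group elastic net no closed form exists; the estimator used here
counts, per active group, the d parameters that group entry costs plus a
shrinkage-ratio fraction of the remaining block dimensions:

    df = d + sum_{i active} [ d + (||b_i||_F / ||b_i^0||_F) (m_i d - d) ],

where m_i is the number of columns in group i and b^0 is a reference
(un-penalised) fit on the active columns, stabilised with a fixed ridge
constant because the raw least-squares reference on near-collinear
lead-field columns biases the estimate downward.  The leading d accounts
for the intercepts.

GCV for the group elastic net is evaluated in the reduced space the fit
was produced in ((N*S) x d); the minimum-norm GCV lives in the original
N x T space.  The two curves have different scales and are never compared
on a common axis.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "RIDGE_STABILIZER_DEFAULT",
    "gcv_error",
    "gcv_error_from_rss",
    "estimate_df_glasso",
    "select_lambda",
    "r_squared",
]

#: Ridge constant applied to the reference fit in the df approximation.
RIDGE_STABILIZER_DEFAULT = 1.0817e4


def gcv_error_from_rss(rss: float, df: float, n_rows: int,
                       n_cols: int) -> float:
    nt = n_rows * n_cols
    if df >= nt:
        raise ValueError("df must be smaller than the number of entries")
    return (rss / nt) / (1.0 - df / nt) ** 2


def gcv_error(Y_obs: np.ndarray, Y_fit: np.ndarray, df: float) -> float:
    """GCV error of a fit with the given effective degrees of freedom."""
    Y_obs = np.asarray(Y_obs, dtype=float)
    Y_fit = np.asarray(Y_fit, dtype=float)
    if Y_obs.shape != Y_fit.shape:
        raise ValueError("Y_obs and Y_fit must have the same shape")
    rss = float(np.sum((Y_obs - Y_fit) ** 2))
    return gcv_error_from_rss(rss, df, Y_obs.shape[0],
                              Y_obs.shape[1] if Y_obs.ndim > 1 else 1)


def estimate_df_glasso(beta: np.ndarray, X: np.ndarray, Y: np.ndarray,
                       groups, d: int | None = None,
                       ridge_stabilizer: float = RIDGE_STABILIZER_DEFAULT,
                       ) -> float:
    """Degrees-of-freedom estimate for a group-elastic-net solution.

    The shrinkage ratio per group compares the fitted block norm with the
    norm of a ridge-stabilised unpenalised reference fit on the active
    columns; the ratio is clipped to [0, 1] so the estimate respects
    d <= df <= (active parameters + d).  An empty active set costs d
    (the intercepts alone).
    """
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    groups = [np.asarray(g, dtype=int) for g in groups]
    if d is None:
        d = Y.shape[1]

    active = [i for i, g in enumerate(groups)
              if np.linalg.norm(beta[g]) > 0]
    if not active:
        return float(d)

    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    cols = np.concatenate([groups[i] for i in active])
    XA = Xc[:, cols]
    G = XA.T @ XA + ridge_stabilizer * np.eye(XA.shape[1])
    beta0 = np.linalg.solve(G, XA.T @ Yc)

    df = float(d)
    offset = 0
    for i in active:
        g = groups[i]
        m = g.size
        b0 = beta0[offset:offset + m]
        offset += m
        nb = float(np.linalg.norm(beta[g]))
        nb0 = float(np.linalg.norm(b0))
        ratio = min(nb / nb0, 1.0) if nb0 > 0 else 1.0
        df += d + ratio * (m * d - d)
    return df


def select_lambda(gcv: np.ndarray, lambdas: np.ndarray | None = None,
                  rtol: float = 1e-12) -> int:
    """Index of the GCV minimum; ties go to the larger lambda.

    The grid is decreasing, so among values within relative ``rtol`` of
    the minimum the smallest index (most regularisation) is returned.
    """
    gcv = np.asarray(gcv, dtype=float)
    if gcv.size == 0:
        raise ValueError("empty GCV curve")
    finite = np.isfinite(gcv)
    if not np.any(finite):
        raise ValueError("all GCV values are non-finite")
    if lambdas is not None:
        lambdas = np.asarray(lambdas, dtype=float)
        if np.any(np.diff(lambdas) >= 0):
            raise ValueError("lambda grid must be strictly decreasing")
    best = np.nanmin(np.where(finite, gcv, np.nan))
    tol = rtol * max(abs(best), 1e-300)
    return int(np.nonzero(finite & (gcv <= best + tol))[0][0])


def r_squared(Y: np.ndarray, Y_fit: np.ndarray) -> float:
    """Fraction of variance explained, against the column-mean matrix."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    Y_fit = np.atleast_2d(np.asarray(Y_fit, dtype=float))
    if Y.shape != Y_fit.shape:
        raise ValueError("Y and Y_fit must have the same shape")
    Yc = Y - Y.mean(axis=0)
    denom = float(np.sum(Yc ** 2))
    if denom == 0:
        raise ValueError("zero-variance Y")
    return 1.0 - float(np.sum((Y - Y_fit) ** 2)) / denom
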