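"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: dense multivariate-normal
restricted likelihoods built from explicit indicator/Kronecker matrices, and
a recursive kinship-coefficient pedigree oracle.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pandas as pd


def indicator(labels) -> np.ndarray:
    """n × g 0/1 design matrix for a grouping factor."""
    return pd.get_dummies(pd.Series(labels).astype(str)).to_numpy(dtype=float)


def dense_restricted_loglik(V: np.ndarray, y: np.ndarray, X: np.ndarray) -> float:
    """Restricted log-likelihood from the dense covariance matrix.

    l_R = -1/2 [ (n-p) log 2pi + log|V| + log|X'V^-1 X| + y'Py ]
    with P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1.
    """
    n, p = X.shape
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    _, logdetV = np.linalg.slogdet(V)
    _, logdetI = np.linalg.slogdet(XtViX)
    return -0.5 * ((n - p) * math.log(2 * math.pi) + logdetV + logdetI + float(y @ P @ y))


def dense_nested_V(V_sire, V_dam, V_resid, sire_ids, dam_ids) -> np.ndarray:
    Zs = indicator(sire_ids)
    combo = [f"{s}|{d}" for s, d in zip(sire_ids, dam_ids)]
    Zd = indicator(combo)
    n = Zs.shape[0]
    return V_sire * Zs @ Zs.T + V_dam * Zd @ Zd.T + V_resid * np.eye(n)


def dense_bivariate_V(G, R, A) -> np.ndarray:
    """Joint covariance G (x) A + R (x) I, trait-major row order."""
    n = A.shape[0]
    return np.kron(np.asarray(G, float), A) + np.kron(np.asarray(R, float), np.eye(n))


def kinship_A(parents: dict[str, tuple[str | None, str | None]]) -> dict[tuple[str, str], float]:
    """Additive relationships 2*phi via the recursive kinship coefficient.

    phi(i,i) = 1/2 (1 + phi(sire_i, dam_i)); phi(i,j) for i not an ancestor
    of j computed by recursing on the younger individual's parents.
    """
    depth: dict[str, int] = {}

    def get_depth(i: str) -> int:
        if i not in depth:
            s, d = parents.get(i, (None, None))
            depth[i] = 1 + max(
                get_depth(s) if s in parents else 0,
                get_depth(d) if d in parents else 0,
            )
        return depth[i]

    @lru_cache(maxsize=None)
    def phi(i: str | None, j: str | None) -> float:
        if i is None or j is None:
            return 0.0
        if i == j:
            s, d = parents.get(i, (None, None))
            return 0.5 * (1.0 + phi(s, d))
        # recurse on the individual with the deeper pedigree
        if get_depth(i) < get_depth(j):
            i, j = j, i
        s, d = parents.get(i, (None, None))
        return 0.5 * (phi(s, j) + phi(d, j))

    ids = list(parents)
    # A_ij = 2*phi(i,j); the diagonal 2*phi(i,i) = 1 + phi(sire, dam)
    return {(a, b): 2.0 * phi(a, b) for a in ids for b in ids}


def ols_restricted_loglik(y: np.ndarray, X: np.ndarray, sigma2: float) -> float:
    """Closed-form restricted loglik of the fixed-effects model with V = sigma2*I."""
    n, p = X.shape
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    rss = float(np.sum((y - X @ beta) ** 2))
    _, logdetXtX = np.linalg.slogdet(X.T @ X)
    return -0.5 * (
        (n - p) * math.log(2 * math.pi)
        + n * math.log(sigma2)
        + (logdetXtX - p * math.log(sigma2))
        + rss / sigma2
    )
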