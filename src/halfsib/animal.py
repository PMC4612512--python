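"""Pedigree-based animal models: relationship matrix, univariate and bivariate REML.

The animal model treats each individual's additive genetic merit as a
random effect whose covariance among relatives is V_A times the numerator
relationship matrix **A** (paternal half sibs 0.25, full sibs 0.5,
non-inbred individuals 1 on the diagonal).  **A** is built from a pedigree
by the tabular method.  Univariate fits estimate (V_A, V_resid) under
``V = V_A·A + V_resid·I``; bivariate fits estimate the full 2×2 additive
covariance G and residual covariance R under ``V = G⊗A + R⊗I`` and report
the genetic correlation r_g = cov_A/√(V_A1·V_A2) with a delta-method SE
from the inverse observed information.

Likelihoods are evaluated blockwise over the connected components of the
relatedness graph (a half-sib design decomposes into one small block per
sire family), so study-scale fits stay fast; on a fully connected pedigree
the evaluation degrades gracefully to a single dense block.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter
from typing import Sequence

import numpy as np
from scipy import optimize, sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.csgraph import connected_components

from .simulate import PedigreeTable

__all__ = [
    "RelationshipMatrix",
    "BivariateGeneticEstimate",
    "build_A_matrix",
    "fit_univariate_animal_model",
    "fit_bivariate_animal_model",
    "genetic_correlation",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class RelationshipMatrix:
    """Numerator relationship matrix with its individual ordering."""

    ids: tuple[str, ...]
    A: np.ndarray

    def submatrix(self, ids: Sequence[str]) -> "RelationshipMatrix":
        """Restrict to (and reorder by) the given individuals.

        Marginalising a multivariate-normal additive effect over
        unphenotyped relatives leaves exactly the submatrix of A, so animal
        models may be fit on phenotyped individuals only.
        """
        pos = {ind: i for i, ind in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        return RelationshipMatrix(tuple(ids), self.A[np.ix_(idx, idx)])


def build_A_matrix(pedigree: PedigreeTable) -> RelationshipMatrix:
    """Additive relationship matrix by the tabular (Henderson) recursion.

    Processing individuals in topological order,
    ``A_ij = ½(A_j,sire(i) + A_j,dam(i))`` for earlier j and
    ``A_ii = 1 + ½A_sire(i),dam(i)``; a missing parent contributes 0
    (unrelated founder).  A cyclic pedigree is rejected.
    """
    parents = {r.individual_id: (r.sire_id, r.dam_id) for r in pedigree.records}
    ts = TopologicalSorter(
        {ind: [p for p in prs if p is not None and p in parents] for ind, prs in parents.items()}
    )
    try:
        order = list(ts.static_order())
    except CycleError as exc:
        raise ValueError("pedigree contains a cycle") from exc

    n = len(order)
    pos = {ind: i for i, ind in enumerate(order)}
    A = np.zeros((n, n))
    for i, ind in enumerate(order):
        sire, dam = parents[ind]
        si = pos.get(sire, -1) if sire is not None else -1
        di = pos.get(dam, -1) if dam is not None else -1
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0)
    return RelationshipMatrix(tuple(order), A)


@dataclass
class BivariateGeneticEstimate:
    """Additive and residual (co)variances of two traits, and their genetic correlation."""

    V_A1: float
    V_A2: float
    cov_A: float
    V_R1: float
    V_R2: float
    cov_R: float
    r_g: float
    se_r_g: float
    reml_loglik: float
    converged: bool


# ---------------------------------------------------------------------------
# Blocked-likelihood machinery


def _as_matrix(A) -> np.ndarray:
    if isinstance(A, RelationshipMatrix):
        A = A.A
    A = np.asarray(A, dtype=float)
    w = np.linalg.eigvalsh((A + A.T) / 2.0)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError("relationship matrix is not positive semidefinite")
    return A


def _relatedness_blocks(A: np.ndarray, dam_codes: np.ndarray | None = None) -> list[np.ndarray]:
    """Connected components of the relatedness (plus shared-dam) graph."""
    n = A.shape[0]
    adj = sparse.csr_matrix((np.abs(A) > 1e-12).astype(np.int8))
    if dam_codes is not None:
        one = np.ones(n, dtype=np.int8)
        d = sparse.csr_matrix(
            (one, (np.arange(n), np.asarray(dam_codes))),
            shape=(n, int(np.max(dam_codes)) + 1),
        )
        adj = adj + (d @ d.T).astype(np.int8)
    ncomp, labels = connected_components(adj, directed=False)
    return [np.flatnonzero(labels == c) for c in range(ncomp)]


def _accumulate(cov_blocks, y, X):
    """Accumulate log|V|, X'V⁻¹X, X'V⁻¹y, y'V⁻¹y over dense covariance blocks."""
    p = X.shape[1]
    logdetV = 0.0
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    for idx, V in cov_blocks:
        c, low = cho_factor(V, lower=True, check_finite=False)
        logdetV += 2.0 * float(np.sum(np.log(np.diag(c))))
        rhs = np.column_stack([X[idx], y[idx]])
        sol = cho_solve((c, low), rhs, check_finite=False)
        XtViX += X[idx].T @ sol[:, :p]
        XtViy += X[idx].T @ sol[:, p]
        ytViy += float(y[idx] @ sol[:, p])
    return logdetV, XtViX, XtViy, ytViy


def _restricted_loglik_blocked(cov_blocks, y, X) -> tuple[float, np.ndarray, np.ndarray]:
    """(restricted loglik, β̂, (X'V⁻¹X)⁻¹) for a block-diagonal covariance."""
    n, p = X.shape
    logdetV, XtViX, XtViy, ytViy = _accumulate(cov_blocks, y, X)
    sign, logdet_info = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1 X singular")
    beta = np.linalg.solve(XtViX, XtViy)
    yPy = ytViy - XtViy @ beta
    ll = -0.5 * ((n - p) * _LOG2PI + logdetV + logdet_info + yPy)
    return ll, beta, np.linalg.inv(XtViX)


# ---------------------------------------------------------------------------
# Univariate animal model


def _eig_blockwise(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of A assembled from its connected components.

    Returns eigenvalues ``d`` and an orthogonal ``U`` (block diagonal up to
    the component permutation) with ``A = U diag(d) U'``.  For a half-sib
    design this costs one tiny symmetric eigenproblem per sire family.
    """
    n = A.shape[0]
    d = np.empty(n)
    U = np.zeros((n, n))
    for idx in _relatedness_blocks(A):
        w, v = np.linalg.eigh(A[np.ix_(idx, idx)])
        d[idx] = w
        U[np.ix_(idx, idx)] = v
    return d, U


def fit_univariate_animal_model(
    y, X, A: np.ndarray | RelationshipMatrix
) -> tuple[float, float, float]:
    """REML estimates (V_A, V_resid, restricted loglik) under V = V_A·A + V_resid·I.

    The ratio V_A/V_resid is profiled on the log scale with the residual
    variance solved in closed form; a solution at the lower bound is
    reported as V_A = 0.  Computed in the eigenbasis of A, where the
    covariance is diagonal.
    """
    A = _as_matrix(A)
    y = np.asarray(y, dtype=float)
    if X is None:
        X = np.ones((y.size, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    d, U = _eig_blockwise(A)
    yt = U.T @ y
    Xt = U.T @ X

    def profile(loglam: float):
        lam = math.exp(loglam)
        w = 1.0 + lam * d  # diagonal of W = I + lam*A in the eigenbasis
        logdetW = float(np.sum(np.log(w)))
        Xw = Xt / w[:, None]
        XtWiX = Xt.T @ Xw
        XtWiy = Xw.T @ yt
        ytWiy = float(yt @ (yt / w))
        sign, logdet_info = np.linalg.slogdet(XtWiX)
        if sign <= 0:
            return np.inf, np.nan, np.nan
        beta = np.linalg.solve(XtWiX, XtWiy)
        sigma2 = (ytWiy - XtWiy @ beta) / (n - p)
        if sigma2 <= 0:
            return np.inf, np.nan, np.nan
        neg2 = (n - p) * (_LOG2PI + math.log(sigma2) + 1.0) + logdetW + logdet_info
        return neg2, sigma2, logdetW + logdet_info

    res = optimize.minimize_scalar(
        lambda u: profile(u)[0], bounds=(-25.0, 8.0), method="bounded",
        options={"xatol": 1e-10},
    )
    neg2, sigma2, _ = profile(res.x)
    lam = math.exp(res.x)
    V_A, V_resid = lam * sigma2, float(sigma2)
    if V_A < 1e-8 * (V_A + V_resid):
        V_A = 0.0
    w = sigma2 * (1.0 + (V_A / sigma2) * d)
    Xw = Xt / w[:, None]
    XtWiX = Xt.T @ Xw
    beta = np.linalg.solve(XtWiX, Xw.T @ yt)
    yPy = float(yt @ (yt / w)) - float((Xw.T @ yt) @ beta)
    ll = -0.5 * (
        (n - p) * _LOG2PI + float(np.sum(np.log(w))) + np.linalg.slogdet(XtWiX)[1] + yPy
    )
    return float(V_A), V_resid, float(ll)


# ---------------------------------------------------------------------------
# Bivariate animal model


def _chol_from(t: np.ndarray) -> np.ndarray:
    """2×2 lower Cholesky factor from (log l11, l21, log l22)."""
    return np.array([[math.exp(t[0]), 0.0], [t[1], math.exp(t[2])]])


def _cov_from(t: np.ndarray) -> np.ndarray:
    L = _chol_from(t)
    return L @ L.T


def _stack_design(y1, y2, X1, X2):
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.size != y2.size:
        raise ValueError("both traits must be measured on the same individuals")
    n = y1.size
    if X1 is None:
        X1 = np.ones((n, 1))
    if X2 is None:
        X2 = np.ones((n, 1))
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[0] != n:
        X1 = X1.T
    if X2.shape[0] != n:
        X2 = X2.T
    p1, p2 = X1.shape[1], X2.shape[1]
    y = np.concatenate([y1, y2])
    X = np.zeros((2 * n, p1 + p2))
    X[:n, :p1] = X1
    X[n:, p1:] = X2
    return y, X, n, p1


def _bivariate_cov_blocks(G, R, sub, n, D=None, dam_codes=None):
    """Per-component joint covariance blocks for rows [trait1 idx, trait2 idx+n]."""
    for idx, Ab in sub:
        m = idx.size
        Im = np.eye(m)
        V = np.empty((2 * m, 2 * m))
        extra = 0.0
        if D is not None:
            dc = dam_codes[idx]
            M = (dc[:, None] == dc[None, :]).astype(float)
            extra = M
        for a in range(2):
            for b in range(2):
                Vab = G[a, b] * Ab + R[a, b] * Im
                if D is not None:
                    Vab = Vab + D[a, b] * extra
                V[a * m : (a + 1) * m, b * m : (b + 1) * m] = Vab
        yield np.concatenate([idx, idx + n]), V


def _bivariate_evaluator(d, y1t, y2t, X1t, X2t):
    """Fast −2·restricted-loglik evaluator in the eigenbasis of A.

    With A = U diag(d) U', transforming each trait by U' turns
    ``G⊗A + R⊗I`` into independent per-individual 2×2 covariances
    ``d_i·G + R``, inverted in closed form and accumulated by matrix
    products — no factorisation inside the optimisation loop.
    Returns (neg2(G, R), beta_and_cov(G, R)).
    """
    n = d.size
    p1, p2 = X1t.shape[1], X2t.shape[1]
    p = p1 + p2

    def core(G, R):
        v11 = G[0, 0] * d + R[0, 0]
        v12 = G[0, 1] * d + R[0, 1]
        v22 = G[1, 1] * d + R[1, 1]
        det = v11 * v22 - v12**2
        if np.any(det <= 0) or np.any(v11 <= 0):
            return None
        m11, m22, m12 = v22 / det, v11 / det, -v12 / det
        logdetV = float(np.sum(np.log(det)))
        A11 = X1t.T @ (m11[:, None] * X1t)
        A12 = X1t.T @ (m12[:, None] * X2t)
        A22 = X2t.T @ (m22[:, None] * X2t)
        XtViX = np.block([[A11, A12], [A12.T, A22]])
        XtViy = np.concatenate(
            [X1t.T @ (m11 * y1t + m12 * y2t), X2t.T @ (m12 * y1t + m22 * y2t)]
        )
        ytViy = float(np.sum(m11 * y1t**2 + 2 * m12 * y1t * y2t + m22 * y2t**2))
        sign, logdet_info = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return None
        beta = np.linalg.solve(XtViX, XtViy)
        yPy = ytViy - XtViy @ beta
        return logdetV, logdet_info, yPy, beta, XtViX

    def neg2(G, R):
        out = core(G, R)
        if out is None:
            return np.inf
        logdetV, logdet_info, yPy, _, _ = out
        return (2 * n - p) * _LOG2PI + logdetV + logdet_info + yPy

    return neg2


def fit_bivariate_animal_model(
    y1,
    y2,
    X1=None,
    X2=None,
    A: np.ndarray | RelationshipMatrix = None,
    *,
    dam_ids: Sequence | None = None,
    include_dam: bool = False,
) -> BivariateGeneticEstimate:
    """Bivariate animal model: REML for G (additive) and R (residual) 2×2 covariances.

    The joint covariance is ``G⊗A + R⊗I`` (optionally plus a 2×2 dam
    covariance ``D`` on a shared-dam indicator when ``include_dam=True``).
    Both covariance matrices are parameterised by their Cholesky factors,
    which keeps every iterate — and the reported G — positive semidefinite.
    The SE of r_g comes from the delta method applied to the inverse
    observed information of the (co)variance parameters.
    """
    if A is None:
        raise ValueError("a relationship matrix A is required")
    A = _as_matrix(A)
    y, X, n, p1 = _stack_design(y1, y2, X1, X2)
    if A.shape[0] != n:
        raise ValueError("A dimension does not match the number of individuals")

    if include_dam:
        if dam_ids is None:
            raise ValueError("include_dam=True requires dam_ids")
        import pandas as pd

        dam_codes = pd.factorize(np.asarray(dam_ids))[0]
        blocks = _relatedness_blocks(A, dam_codes)
        sub = [(idx, A[np.ix_(idx, idx)]) for idx in blocks]

        def neg2_GRD(G, R, D):
            try:
                ll, _, _ = _restricted_loglik_blocked(
                    _bivariate_cov_blocks(G, R, sub, n, D, dam_codes), y, X
                )
            except np.linalg.LinAlgError:
                return np.inf
            return -2.0 * ll

    else:
        d, U = _eig_blockwise(A)
        y1t, y2t = U.T @ y[:n], U.T @ y[n:]
        X1t, X2t = U.T @ X[:n, :p1], U.T @ X[n:, p1:]
        fast_neg2 = _bivariate_evaluator(d, y1t, y2t, X1t, X2t)

    def unpack(theta):
        G = _cov_from(theta[0:3])
        R = _cov_from(theta[3:6])
        D = _cov_from(theta[6:9]) if include_dam else None
        return G, R, D

    def neg2(theta):
        G, R, D = unpack(theta)
        if include_dam:
            return neg2_GRD(G, R, D)
        return fast_neg2(G, R)

    # starting values from univariate fits per trait
    va1, ve1, _ = fit_univariate_animal_model(y[:n], X[:n, :p1], A)
    va2, ve2, _ = fit_univariate_animal_model(y[n:], X[n:, p1:], A)
    va1 = max(va1, 0.05 * (va1 + ve1), 1e-8)
    va2 = max(va2, 0.05 * (va2 + ve2), 1e-8)

    def start(rho_g: float):
        tg = np.array(
            [0.5 * math.log(va1), rho_g * math.sqrt(va2), 0.5 * math.log(va2 * (1 - rho_g**2))]
        )
        tr = np.array([0.5 * math.log(ve1), 0.0, 0.5 * math.log(ve2)])
        th = [tg, tr]
        if include_dam:
            th.append(np.array([0.5 * math.log(ve1 / 10), 0.0, 0.5 * math.log(ve2 / 10)]))
        return np.concatenate(th)

    k = 9 if include_dam else 6
    bounds = [(-20.0, 20.0) if j % 3 != 1 else (-1e3, 1e3) for j in range(k)]

    best = None
    for rho in (0.0, -0.6, 0.6):
        res = optimize.minimize(
            neg2, start(rho), method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-13, "gtol": 1e-8, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("bivariate REML optimisation failed to find a finite optimum")

    G, R, D = unpack(best.x)
    ll = -0.5 * best.fun
    r_g = genetic_correlation(G[0, 1], max(G[0, 0], 1e-300), max(G[1, 1], 1e-300))

    def neg2_phi(phi):
        Gm = np.array([[phi[0], phi[1]], [phi[1], phi[2]]])
        Rm = np.array([[phi[3], phi[4]], [phi[4], phi[5]]])
        if include_dam:
            Dm = np.array([[phi[6], phi[7]], [phi[7], phi[8]]])
            return neg2_GRD(Gm, Rm, Dm)
        return fast_neg2(Gm, Rm)

    phi0 = [G[0, 0], G[0, 1], G[1, 1], R[0, 0], R[0, 1], R[1, 1]]
    if include_dam:
        phi0 += [D[0, 0], D[0, 1], D[1, 1]]
    se_r_g = _delta_se_rg(np.array(phi0), neg2_phi)
    return BivariateGeneticEstimate(
        V_A1=float(G[0, 0]), V_A2=float(G[1, 1]), cov_A=float(G[0, 1]),
        V_R1=float(R[0, 0]), V_R2=float(R[1, 1]), cov_R=float(R[0, 1]),
        r_g=r_g, se_r_g=se_r_g, reml_loglik=float(ll), converged=bool(best.success),
    )


def _delta_se_rg(phi0: np.ndarray, neg2_phi) -> float:
    """Delta-method SE of r_g from a numerical Hessian in (co)variance coordinates.

    ``phi0`` orders the parameters (g11, g12, g22, r11, r12, r22, ...); the
    REML estimator covariance is approximated by ``2·H⁻¹`` with H the
    central-difference Hessian of −2·loglik at the optimum.
    """
    k = phi0.size
    scale = np.array([max(abs(v), 1e-6 * max(np.abs(phi0).max(), 1.0)) for v in phi0])
    h = 1e-4 * scale
    H = np.full((k, k), np.nan)
    f0 = neg2_phi(phi0)
    try:
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h[i]
            H[i, i] = (neg2_phi(phi0 + ei) + neg2_phi(phi0 - ei) - 2 * f0) / h[i] ** 2
            for j in range(i):
                ej = np.zeros(k)
                ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    neg2_phi(phi0 + ei + ej)
                    - neg2_phi(phi0 + ei - ej)
                    - neg2_phi(phi0 - ei + ej)
                    + neg2_phi(phi0 - ei - ej)
                ) / (4 * h[i] * h[j])
        if not np.all(np.isfinite(H)):
            raise np.linalg.LinAlgError("non-finite Hessian")
        C = 2.0 * np.linalg.inv(H)
        g11, g12, g22 = phi0[0], phi0[1], phi0[2]
        r = g12 / math.sqrt(g11 * g22)
        grad = np.zeros(k)
        grad[0] = -r / (2 * g11)
        grad[1] = 1.0 / math.sqrt(g11 * g22)
        grad[2] = -r / (2 * g22)
        var = float(grad @ C @ grad)
        if var < 0:
            raise np.linalg.LinAlgError("negative delta-method variance")
        return math.sqrt(var)
    except np.linalg.LinAlgError as exc:
        warnings.warn(f"SE of r_g unavailable ({exc}); returning nan")
        return float("nan")


def genetic_correlation(cov_A: float, V_A1: float, V_A2: float) -> float:
    """r_g = cov_A / sqrt(V_A1·V_A2), clipped to [−1, 1] with a warning."""
    if V_A1 <= 0 or V_A2 <= 0:
        raise ValueError("additive variances must be positive for a genetic correlation")
    r = cov_A / math.sqrt(V_A1 * V_A2)
    if abs(r) > 1.0:
        warnings.warn(f"raw genetic correlation {r:.4f} outside [-1, 1]; clipped")
        r = math.copysign(1.0, r)
    return float(r)
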