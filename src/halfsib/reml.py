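"""REML for the nested sire / dam-within-sire linear mixed model.

The observational model for a paternal half-sib design is

    y = X beta + Z_s u_s + Z_d u_d + e,
    u_s ~ N(0, V_sire I),  u_d ~ N(0, V_dam I),  e ~ N(0, V_resid I),

with dams nested within sires, so the marginal covariance
``V = V_sire Z_s Z_s' + V_dam Z_d Z_d' + V_resid I`` is block diagonal by
sire family.  All likelihood work here exploits that block structure: the
restricted log-likelihood is accumulated family by family, which makes a
fit at study scale (≈70 families) a few milliseconds rather than a dense
n×n factorisation.

Estimation maximises the restricted likelihood profiled over the residual
variance, over log variance ratios (lambda_s = V_sire/V_resid,
lambda_d = V_dam/V_resid), with multiple starts so that boundary solutions
(a dam component estimated at exactly zero is common in these designs) are
found reliably.  Fixed effects are tested with Wald chi-square statistics
from the inverse expected information; random effects with likelihood-ratio
tests between nested fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from .prep import AnalysisRecord, analysis_frame, log1p_transform

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "TestResult",
    "reml_loglik",
    "fit_nested_lmm",
    "anova_oracle_balanced",
    "wald_test",
    "lrt_random_effect",
    "select_minimal_model",
]

_LOG2PI = math.log(2.0 * math.pi)
# Variance ratios are optimised on the log scale within these bounds; the
# lower bound is far below the zero-reporting threshold.
_LOG_RATIO_BOUNDS = (-25.0, 8.0)
_ZERO_TOL = 1e-8  # components below _ZERO_TOL * V_P are reported as exact 0


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, fixed covariates, random structure, transform."""

    response: str
    fixed_terms: tuple[str, ...] = ()
    random_structure: tuple[str, ...] = ("sire", "dam")
    transform: str = "none"  # none | log1p

    def __post_init__(self) -> None:
        if self.transform not in ("none", "log1p"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if not set(self.random_structure) <= {"sire", "dam"}:
            raise ValueError("random structure may contain only 'sire' and 'dam'")


@dataclass
class VarianceComponents:
    """REML variance components and fixed-effect estimates for one fit."""

    V_sire: float
    V_dam: float
    V_resid: float
    beta: np.ndarray
    beta_names: tuple[str, ...]
    beta_cov: np.ndarray
    reml_loglik: float
    n_obs: int
    n_sires: int
    n_dams: int
    converged: bool
    random_structure: tuple[str, ...] = ("sire", "dam")
    spec: ModelSpec | None = None

    @property
    def V_P(self) -> float:
        return self.V_sire + self.V_dam + self.V_resid


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    kind: str  # wald | lrt
    term: str | None = None


# ---------------------------------------------------------------------------
# Likelihood machinery


class _Layout:
    """Grouping structure of a nested sire/dam design.

    Stores dam codes, dam-family sizes, the dam-to-sire-family map, and an
    aggregation matrix used to collapse per-dam sums to per-sire-family
    sums in one small matrix product.
    """

    def __init__(self, sire_ids: np.ndarray, dam_ids: np.ndarray):
        sire = np.asarray(sire_ids).astype(str)
        dam = np.asarray(dam_ids).astype(str)
        combo = np.char.add(np.char.add(sire, "\x1f"), dam)
        self.dam_codes = pd.factorize(combo)[0]
        self.sire_codes = pd.factorize(sire)[0]
        self.n_dams = int(self.dam_codes.max()) + 1
        self.n_sires = int(self.sire_codes.max()) + 1
        self.dam_sizes = np.bincount(self.dam_codes).astype(float)
        # each dam belongs to exactly one sire family (nesting)
        fam_of_dam = np.empty(self.n_dams, dtype=int)
        fam_of_dam[self.dam_codes] = self.sire_codes
        self.fam_of_dam = fam_of_dam
        self.dam_to_fam = np.zeros((self.n_sires, self.n_dams))
        self.dam_to_fam[fam_of_dam, np.arange(self.n_dams)] = 1.0
        self.families = [np.flatnonzero(self.sire_codes == f) for f in range(self.n_sires)]


def _make_quadratics(y, X, layout: _Layout):
    """Closed-form likelihood quadratics for W = I + lam_s J + lam_d D per family.

    Within a sire family, W = B + lam_s·11' with B = I + lam_d·blockdiag(J);
    Sherman–Morrison at the dam level and again at the family level gives
    W⁻¹ and log|W| from per-dam and per-family sums alone, so each
    evaluation costs a few small matrix products.  Returns
    ``quad(lam_s, lam_d) -> (log|W|, X'W⁻¹X, X'W⁻¹y, y'W⁻¹y)``.
    """
    Xy = np.column_stack([X, y])
    q = Xy.shape[1]
    p = q - 1
    XtX = Xy.T @ Xy
    S = np.zeros((layout.n_dams, q))
    np.add.at(S, layout.dam_codes, Xy)
    k = layout.dam_sizes
    D2F = layout.dam_to_fam

    def quad(lam_s: float, lam_d: float):
        denom_d = 1.0 + lam_d * k
        c_d = lam_d / denom_d
        Q = XtX - S.T @ (c_d[:, None] * S)
        w = D2F @ (S / denom_d[:, None])  # per-family u'-weighted sums
        s_f = D2F @ (k / denom_d)  # per-family 1'B⁻¹1
        b_f = lam_s / (1.0 + lam_s * s_f)
        Q = Q - (w * b_f[:, None]).T @ w
        logdetW = float(np.sum(np.log(denom_d)) + np.sum(np.log1p(lam_s * s_f)))
        return logdetW, Q[:p, :p], Q[:p, p], float(Q[p, p])

    return quad


def _restricted_loglik_ratios(lam_s, lam_d, sigma2, quad, n, p):
    """Full restricted log-likelihood at V = sigma2 * (I + lam_s Zs Zs' + lam_d Zd Zd')."""
    logdetW, XtWiX, XtWiy, ytWiy = quad(lam_s, lam_d)
    sign, logdet_info = np.linalg.slogdet(XtWiX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1 X is singular; check design matrix rank")
    beta = np.linalg.solve(XtWiX, XtWiy)
    yPy = (ytWiy - XtWiy @ beta) / sigma2
    logdetV = n * math.log(sigma2) + logdetW
    logdet_XtViX = logdet_info - p * math.log(sigma2)
    return -0.5 * ((n - p) * _LOG2PI + logdetV + logdet_XtViX + yPy)


def reml_loglik(
    theta: tuple[float, float, float],
    y,
    X,
    sire_ids,
    dam_ids,
) -> float:
    """Restricted log-likelihood at components ``theta = (V_sire, V_dam, V_resid)``.

    Defined as ``-½[(n−p)·log 2π + log|V| + log|X'V⁻¹X| + y'Py]`` with
    ``P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹``; equals the dense multivariate-normal
    evaluation but is computed blockwise by sire family.
    """
    V_sire, V_dam, V_resid = (float(t) for t in theta)
    if min(V_sire, V_dam, V_resid) < 0:
        raise ValueError("variance components must be non-negative")
    if V_resid <= 0:
        raise ValueError("V_resid must be positive for a proper likelihood")
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    layout = _Layout(np.asarray(sire_ids), np.asarray(dam_ids))
    quad = _make_quadratics(y, X, layout)
    return _restricted_loglik_ratios(
        V_sire / V_resid, V_dam / V_resid, V_resid, quad, y.size, X.shape[1]
    )


def _neg2_profiled(u: np.ndarray, mask: np.ndarray, quad, n: int, p: int):
    """−2·(profiled restricted loglik) over log variance ratios ``u`` (masked)."""
    lam = np.zeros(2)
    lam[mask] = np.exp(u)
    logdetW, XtWiX, XtWiy, ytWiy = quad(lam[0], lam[1])
    sign, logdet_info = np.linalg.slogdet(XtWiX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtWiX, XtWiy)
    yPWy = ytWiy - XtWiy @ beta
    sigma2 = yPWy / (n - p)
    if sigma2 <= 0:
        return np.inf
    return (n - p) * (_LOG2PI + math.log(sigma2) + 1.0) + logdetW + logdet_info


def _build_design(
    data, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...], np.ndarray, np.ndarray]:
    if isinstance(data, (list, tuple)) and (not data or isinstance(data[0], AnalysisRecord)):
        data = analysis_frame(list(data))
    if not isinstance(data, pd.DataFrame):
        raise TypeError("data must be a DataFrame or a sequence of AnalysisRecord")
    y = data[spec.response].to_numpy(dtype=float)
    if spec.transform == "log1p":
        y = log1p_transform(y)
    cols = [np.ones(len(data))]
    names = ["(intercept)"]
    for term in spec.fixed_terms:
        cols.append(data[term].to_numpy(dtype=float))
        names.append(term)
    X = np.column_stack(cols)
    return y, X, tuple(names), data["sire_id"].to_numpy(), data["dam_id"].to_numpy()


def _moment_start(y, X, layout: _Layout) -> tuple[float, float]:
    """Crude method-of-moments variance ratios from OLS residuals, for starting values."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    ve = max(float(np.var(r)), 1e-12)
    fams = layout.families
    fam_means = np.array([r[idx].mean() for idx in fams])
    vs = max(float(np.var(fam_means)) - ve / max(np.mean([f.size for f in fams]), 1), 0.0)
    dam_means = pd.Series(r).groupby(layout.dam_codes).mean().to_numpy()
    vd = max(float(np.var(dam_means)) - ve / 3.0 - vs, 0.0)
    return max(vs / ve, 1e-6), max(vd / ve, 1e-6)


def fit_nested_lmm(
    spec: ModelSpec,
    data,
    *,
    mixture_lrt: bool = False,
) -> VarianceComponents:
    """Fit the nested sire/dam mixed model by REML.

    Maximises the restricted likelihood over non-negative variance
    components (log-ratio parameterisation, profiled residual variance,
    quasi-Newton with multiple starts).  Components estimated below
    ``1e-8 × V_P`` are reported as exactly 0.  Non-convergence raises.
    """
    y, X, names, sire_ids, dam_ids = _build_design(data, spec)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    layout = _Layout(sire_ids, dam_ids)
    n_sires = layout.n_sires
    n_dams = layout.n_dams
    if n_sires < 2 and "sire" in spec.random_structure:
        raise ValueError("need at least 2 sire families")

    mask = np.array(
        ["sire" in spec.random_structure, "dam" in spec.random_structure]
    )
    k = int(mask.sum())

    if k == 0:
        # pure fixed-effects model: closed-form OLS REML
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        sigma2 = rss / (n - p)
        quad0 = _make_quadratics(y, X, layout)
        ll = _restricted_loglik_ratios(0.0, 0.0, sigma2, quad0, n, p)
        return VarianceComponents(
            0.0, 0.0, sigma2, beta, names,
            sigma2 * np.linalg.inv(X.T @ X), ll, n, n_sires, n_dams, True,
            spec.random_structure, spec,
        )

    quad = _make_quadratics(y, X, layout)
    vs0, vd0 = _moment_start(y, X, layout)
    starts_full = [
        np.log([max(vs0, 1e-4), max(vd0, 1e-4)]),
        np.log([0.3, 0.3]),
        np.log([0.05, 1.0]),
    ]
    starts = [s[mask] for s in starts_full]

    best = None
    for u0 in starts:
        res = optimize.minimize(
            _neg2_profiled,
            np.clip(u0, *_LOG_RATIO_BOUNDS),
            args=(mask, quad, n, p),
            method="L-BFGS-B",
            bounds=[_LOG_RATIO_BOUNDS] * k,
            options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("REML optimisation failed: no finite objective found")
    # derivative-free polish: the quasi-Newton step relies on finite-difference
    # gradients and can stop a few 1e-9 in loglik short of the optimum
    polish = optimize.minimize(
        _neg2_profiled,
        best.x,
        args=(mask, quad, n, p),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    if polish.fun <= best.fun:
        best = polish

    lam = np.zeros(2)
    lam[mask] = np.exp(best.x)
    logdetW, XtWiX, XtWiy, ytWiy = quad(lam[0], lam[1])
    beta = np.linalg.solve(XtWiX, XtWiy)
    sigma2 = float((ytWiy - XtWiy @ beta) / (n - p))
    V_sire, V_dam, V_resid = lam[0] * sigma2, lam[1] * sigma2, sigma2
    V_P = V_sire + V_dam + V_resid
    if V_sire < _ZERO_TOL * V_P:
        V_sire = 0.0
    if V_dam < _ZERO_TOL * V_P:
        V_dam = 0.0
    ll = _restricted_loglik_ratios(
        V_sire / V_resid, V_dam / V_resid, V_resid, quad, n, p
    )
    beta_cov = sigma2 * np.linalg.inv(XtWiX)
    return VarianceComponents(
        V_sire, V_dam, V_resid, beta, names, beta_cov, ll,
        n, n_sires, n_dams, bool(best.success), spec.random_structure, spec,
    )


# ---------------------------------------------------------------------------
# Independent closed-form oracle for balanced designs


def anova_oracle_balanced(y, sire_ids, dam_ids) -> VarianceComponents:
    """Henderson method-of-moments components for a perfectly balanced design.

    With s sires × d dams × k daughters and no covariates, the expected
    mean squares give ``V_resid = MS_within``,
    ``V_dam = (MS_dam − MS_within)/k`` and
    ``V_sire = (MS_sire − MS_dam)/(k·d)``.  Unbalanced input is rejected.
    Intended as an independent check on :func:`fit_nested_lmm`.
    """
    df = pd.DataFrame(
        {"y": np.asarray(y, dtype=float), "sire": np.asarray(sire_ids), "dam": np.asarray(dam_ids)}
    )
    dam_sizes = df.groupby(["sire", "dam"]).size()
    sire_ndams = dam_sizes.groupby("sire").size()
    if dam_sizes.nunique() != 1 or sire_ndams.nunique() != 1:
        raise ValueError("anova_oracle_balanced requires a perfectly balanced design")
    k = int(dam_sizes.iloc[0])
    d = int(sire_ndams.iloc[0])
    s = int(sire_ndams.size)
    if k < 2 or d < 2 or s < 2:
        raise ValueError("balanced oracle needs >=2 sires, >=2 dams/sire, >=2 daughters/dam")

    grand = df["y"].mean()
    sire_means = df.groupby("sire")["y"].mean()
    dam_means = df.groupby(["sire", "dam"])["y"].mean()

    ss_sire = k * d * float(((sire_means - grand) ** 2).sum())
    ss_dam = k * float(
        ((dam_means - sire_means.reindex(dam_means.index.get_level_values(0)).to_numpy()) ** 2).sum()
    )
    fitted = dam_means.reindex(pd.MultiIndex.from_frame(df[["sire", "dam"]])).to_numpy()
    ss_within = float(((df["y"].to_numpy() - fitted) ** 2).sum())

    ms_sire = ss_sire / (s - 1)
    ms_dam = ss_dam / (s * (d - 1))
    ms_within = ss_within / (s * d * (k - 1))

    V_resid = ms_within
    V_dam = (ms_dam - ms_within) / k
    V_sire = (ms_sire - ms_dam) / (k * d)

    X = np.ones((len(df), 1))
    ll = np.nan
    if V_sire >= 0 and V_dam >= 0 and V_resid > 0:
        ll = reml_loglik((max(V_sire, 0), max(V_dam, 0), V_resid), df["y"], X,
                         df["sire"], df["dam"])
    return VarianceComponents(
        V_sire, V_dam, V_resid,
        np.array([grand]), ("(intercept)",),
        np.array([[ms_sire / (s * d * k)]]),
        ll, len(df), s, s * d, True, ("sire", "dam"), None,
    )


# ---------------------------------------------------------------------------
# Tests


def wald_test(fit: VarianceComponents, term: str) -> TestResult:
    """Wald chi-square test of a fixed-effect term: ``β̂ᵀ Cov(β̂)⁻¹ β̂``."""
    if term not in fit.beta_names:
        raise KeyError(f"term {term!r} not in fitted model {fit.beta_names}")
    j = [i for i, name in enumerate(fit.beta_names) if name == term]
    b = fit.beta[j]
    C = fit.beta_cov[np.ix_(j, j)]
    stat = float(b @ np.linalg.solve(C, b))
    df = len(j)
    return TestResult(stat, df, float(chi2.sf(stat, df)), "wald", term)


def lrt_random_effect(
    fit_full: VarianceComponents,
    fit_reduced: VarianceComponents,
    *,
    boundary_mixture: bool = False,
) -> TestResult:
    """Likelihood-ratio test of a random effect dropped from the full model.

    The statistic is ``2·(ℓ_full − ℓ_reduced)``, floored at 0, referred to
    χ²₁ by default.  Because the null pins the variance at the boundary of
    its space, the χ²₁ reference is conservative; a 50:50 mixture of χ²₀
    and χ²₁ is available via ``boundary_mixture=True``.
    """
    dropped = set(fit_full.random_structure) - set(fit_reduced.random_structure)
    if len(dropped) != 1 or not set(fit_reduced.random_structure) <= set(
        fit_full.random_structure
    ):
        raise ValueError(
            "reduced model must drop exactly one random term from the full model"
        )
    stat = max(0.0, 2.0 * (fit_full.reml_loglik - fit_reduced.reml_loglik))
    p = float(chi2.sf(stat, 1))
    if boundary_mixture:
        p = 0.5 * p + (0.5 if stat == 0.0 else 0.0)
    return TestResult(stat, 1, p, "lrt", dropped.pop())


def select_minimal_model(
    spec: ModelSpec, data, alpha: float = 0.05
) -> ModelSpec:
    """Single backward pass: keep only fixed terms with full-model Wald p < alpha.

    The intercept is always retained; the random structure is untouched.
    """
    if not spec.fixed_terms:
        return spec
    fit = fit_nested_lmm(spec, data)
    kept = tuple(
        term for term in spec.fixed_terms if wald_test(fit, term).p_value < alpha
    )
    return replace(spec, fixed_terms=kept)
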