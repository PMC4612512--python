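"""Quantitative-genetic parameters from half-sib variance components.

In a paternal half-sib design the sire variance component estimates one
quarter of the additive genetic variance, so V_A = 4·V_sire, and the
phenotypic variance is the sum of components, V_P = V_sire + V_dam +
V_resid.  From these come narrow-sense heritability h² = V_A/V_P and the
mean-standardized evolvability measures of Houle:

    CV_A = sqrt(V_A)/mean,   CV_P = sqrt(V_P)/mean,
    CV_R = sqrt(V_P − V_A)/mean,   I_A = V_A/mean²,

which satisfy CV_A² + CV_R² = CV_P² identically.  Standard errors for all
parameters are obtained by delete-one-sire-family jackknifing: the whole
REML pipeline is refit on each leave-one-family-out subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reml import ModelSpec, VarianceComponents, fit_nested_lmm

__all__ = [
    "GeneticParameterSet",
    "additive_variance",
    "phenotypic_variance",
    "heritability",
    "evolvability_stats",
    "jackknife_se",
    "parameters_from_fit",
    "estimate_genetic_parameters",
]

PARAM_NAMES = (
    "mean", "V_sire", "V_dam", "V_A", "V_P", "V_R", "h2",
    "CV_A", "CV_P", "CV_R", "I_A",
)


@dataclass
class GeneticParameterSet:
    """One trait's Table-style row: point estimates plus jackknife SEs."""

    trait: str
    n_obs: int
    n_sires: int
    n_dams: int
    estimates: dict[str, float]
    se: dict[str, float]
    n_sires_jackknifed: int = 0
    p_sire: float | None = None
    p_dam: float | None = None

    def __getitem__(self, key: str) -> float:
        return self.estimates[key]


def additive_variance(V_sire: float) -> float:
    """V_A = 4·V_sire (paternal half-sib covariance is ¼V_A)."""
    if V_sire < 0:
        raise ValueError("V_sire must be non-negative")
    return 4.0 * V_sire


def phenotypic_variance(vc: VarianceComponents | Sequence[float]) -> float:
    """V_P as the sum of the observational components."""
    if isinstance(vc, VarianceComponents):
        return vc.V_sire + vc.V_dam + vc.V_resid
    return float(sum(vc))


def heritability(V_A: float, V_P: float) -> float:
    """Narrow-sense heritability h² = V_A / V_P."""
    if V_P <= 0:
        raise ValueError("V_P must be positive")
    return V_A / V_P


def evolvability_stats(V_A: float, V_P: float, mean: float) -> dict[str, float]:
    """Mean-standardized evolvabilities (CV_A, CV_P, CV_R, I_A)."""
    if mean <= 0:
        raise ValueError("trait mean must be positive")
    if V_A < 0 or V_A > V_P:
        raise ValueError("require 0 <= V_A <= V_P (CV_R undefined otherwise)")
    return {
        "CV_A": math.sqrt(V_A) / mean,
        "CV_P": math.sqrt(V_P) / mean,
        "CV_R": math.sqrt(V_P - V_A) / mean,
        "I_A": V_A / mean**2,
    }


def parameters_from_fit(
    V_sire: float, V_dam: float, V_resid: float, mean: float
) -> dict[str, float]:
    """The full derived-parameter chain from raw components and the trait mean."""
    V_A = additive_variance(V_sire)
    V_P = phenotypic_variance((V_sire, V_dam, V_resid))
    out = {
        "mean": mean,
        "V_sire": V_sire,
        "V_dam": V_dam,
        "V_A": V_A,
        "V_P": V_P,
        "V_R": V_resid,
        "h2": heritability(V_A, V_P),
    }
    out.update(evolvability_stats(min(V_A, V_P), V_P, mean))
    return out


def jackknife_se(
    data: pd.DataFrame,
    estimator: Callable[[pd.DataFrame], Mapping[str, float]],
    group_key: str = "sire_id",
) -> dict[str, float]:
    """Delete-one-group jackknife standard errors.

    For n groups and leave-one-out estimates θ₋ᵢ,
    ``SE = sqrt((n−1)/n · Σᵢ (θ₋ᵢ − θ̄₋)²)``.  The estimator is rerun in
    full on every subset; a failure is re-raised naming the left-out group.
    """
    groups = pd.unique(data[group_key])
    n = len(groups)
    if n < 3:
        raise ValueError("jackknife needs at least 3 groups")
    rows = []
    for g in groups:
        subset = data[data[group_key] != g]
        try:
            rows.append(dict(estimator(subset)))
        except Exception as exc:  # noqa: BLE001 - reported with context
            raise RuntimeError(f"estimator failed with {group_key}={g!r} left out") from exc
    loo = pd.DataFrame(rows)
    dev = loo - loo.mean()
    return {k: float(np.sqrt((n - 1) / n * (dev[k] ** 2).sum())) for k in loo.columns}


def estimate_genetic_parameters(
    data: pd.DataFrame,
    spec: ModelSpec,
    *,
    jackknife: bool = True,
) -> GeneticParameterSet:
    """Fit the nested model and derive the genetic-parameter set for one trait.

    The response mean is taken on the analysis scale of ``spec`` (genetic
    parameters are normally extracted from untransformed fits).  With
    ``jackknife=True`` the entire fit is repeated with each sire family
    deleted to produce standard errors for every parameter.
    """
    fit = fit_nested_lmm(spec, data)
    mean = float(data[spec.response].mean())

    def estimator(subset: pd.DataFrame) -> dict[str, float]:
        f = fit_nested_lmm(spec, subset)
        return parameters_from_fit(f.V_sire, f.V_dam, f.V_resid, float(subset[spec.response].mean()))

    estimates = parameters_from_fit(fit.V_sire, fit.V_dam, fit.V_resid, mean)
    se: dict[str, float] = {}
    n_jack = 0
    if jackknife:
        se = jackknife_se(data, estimator, "sire_id")
        n_jack = data["sire_id"].nunique()
        # SE of the mean also by jackknife over sire families, for the table
        se["mean"] = jackknife_se(
            data, lambda d: {"mean": float(d[spec.response].mean())}, "sire_id"
        )["mean"]
    return GeneticParameterSet(
        trait=spec.response,
        n_obs=fit.n_obs,
        n_sires=fit.n_sires,
        n_dams=fit.n_dams,
        estimates=estimates,
        se=se,
        n_sires_jackknifed=n_jack,
    )
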