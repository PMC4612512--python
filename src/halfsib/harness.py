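"""Parameter-recovery and calibration harnesses at study-scale conditions.

These harnesses measure the estimators against simulated designs with known
truth: a 70-sire × 3-dam × 3-daughter breeding design with heritability 0.5
for longevity, an additive genetic correlation of −0.65 between longevity
and the mating-propensity liability, and a null covariate for Wald-test
calibration.

The recovery configurations deliberately switch off the phenotypic feedback
of lifetime matings on longevity and use a longevity intercept high enough
that essentially no female dies before her sixth mating opportunity: the
feedback makes the covariate-adjusted heritability truth ill-defined, and
early deaths act as phenotypic selection that shrinks between-family
covariance — a property of the subsetting rule, not of the estimators the
harness is probing (see docs/methods.md).
"""

from __future__ import annotations

import math

import numpy as np

from .animal import build_A_matrix, fit_bivariate_animal_model
from .params import parameters_from_fit
from .prep import analysis_frame, derive_traits, filter_analysis_subset
from .reml import ModelSpec, fit_nested_lmm, wald_test
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "h2_recovery_config",
    "rg_recovery_config",
    "run_h2_recovery",
    "run_rg_recovery",
    "run_wald_null_calibration",
]

_RECOVERY_DESIGN = dict(n_sires=70, n_dams_per_sire=3, n_daughters_per_dam=3)
_H2_TRUE = 0.5
_RG_TRUE = -0.65
# liability-scale components giving h2_longevity = 48/(48+4+44) = 0.5
_G11, _VDAM1, _VRES1 = 48.0, 4.0, 44.0
_G22 = 0.5


def _rep_seeds(seed: int, n: int) -> np.ndarray:
    """n child seeds below 2**31, reproducibly derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) & 0x7FFFFFFF


def h2_recovery_config(seed: int) -> SimulationConfig:
    """Study-scale design with true longevity heritability 0.5 and no feedback."""
    return SimulationConfig(
        **_RECOVERY_DESIGN,
        G=np.array([[_G11, 0.0], [0.0, _G22]]),
        V_dam=(_VDAM1, 0.02),
        V_resid=(_VRES1, 0.3),
        trait_means=(48.0, 2.085),
        beta_lifetime_matings=0.0,
        seed=int(seed),
    )


def rg_recovery_config(seed: int) -> SimulationConfig:
    """As :func:`h2_recovery_config` but with genetic correlation −0.65."""
    cov = _RG_TRUE * math.sqrt(_G11 * _G22)
    return SimulationConfig(
        **_RECOVERY_DESIGN,
        G=np.array([[_G11, cov], [cov, _G22]]),
        V_dam=(_VDAM1, 0.02),
        V_resid=(_VRES1, 0.3),
        trait_means=(48.0, 2.085),
        beta_lifetime_matings=0.0,
        seed=int(seed),
    )


def _prepared(cfg: SimulationConfig):
    pedigree, records, _ = simulate_dataset(cfg)
    return pedigree, analysis_frame(derive_traits(filter_analysis_subset(records)))


def run_h2_recovery(n_reps: int = 200, seed: int = 0) -> np.ndarray:
    """h² estimates (4·V̂_sire/V̂_P) over independent replicates; truth 0.5."""
    spec = ModelSpec("longevity", ("start_date",))
    out = np.empty(n_reps)
    for i, s in enumerate(_rep_seeds(seed, n_reps)):
        _, data = _prepared(h2_recovery_config(s))
        fit = fit_nested_lmm(spec, data)
        out[i] = parameters_from_fit(
            fit.V_sire, fit.V_dam, fit.V_resid, float(data["longevity"].mean())
        )["h2"]
    return out


def run_rg_recovery(n_reps: int = 100, seed: int = 0) -> np.ndarray:
    """Bivariate-animal-model r̂_g over independent replicates; truth −0.65."""
    out = np.empty(n_reps)
    for i, s in enumerate(_rep_seeds(seed, n_reps)):
        pedigree, data = _prepared(rg_recovery_config(s))
        rel = build_A_matrix(pedigree).submatrix(list(data["female_id"]))
        X = np.column_stack([np.ones(len(data)), data["start_date"].to_numpy(float)])
        est = fit_bivariate_animal_model(
            data["longevity"].to_numpy(float),
            data["early_life_matings"].to_numpy(float),
            X, X, rel.A,
        )
        out[i] = est.r_g
    return out


def run_wald_null_calibration(
    n_reps: int = 1000, seed: int = 0, alpha: float = 0.05
) -> float:
    """Type-I error of the Wald test for an individual-level null covariate.

    The study-mimicking default design is simulated, a standard-normal
    covariate with no true effect is appended, and the longevity model
    (lifetime matings + start date + null covariate) is fit; returns the
    fraction of replicates with p < alpha.
    """
    spec = ModelSpec("longevity", ("lifetime_matings", "start_date", "null_cov"))
    rejections = 0
    for s in _rep_seeds(seed, n_reps):
        cfg = SimulationConfig(seed=int(s))
        _, records, _ = simulate_dataset(cfg)
        data = analysis_frame(derive_traits(filter_analysis_subset(records)))
        rng = np.random.default_rng(int(s) + 1)
        data = data.assign(null_cov=rng.standard_normal(len(data)))
        fit = fit_nested_lmm(spec, data)
        if wald_test(fit, "null_cov").p_value < alpha:
            rejections += 1
    return rejections / n_reps
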