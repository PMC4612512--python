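"""Measure the genetic trade-off between early-life mating and longevity.

Fits a bivariate animal model — additive covariance G ⊗ A plus residual
covariance R ⊗ I, with A the pedigree relationship matrix — and reports the
genetic correlation r_g between early-life mating frequency and longevity.
A negative r_g means families that mate intensely early in life die
younger: a live-fast-die-young trade-off.
"""

import numpy as np

from halfsib import (
    SimulationConfig,
    analysis_frame,
    build_A_matrix,
    derive_traits,
    filter_analysis_subset,
    fit_bivariate_animal_model,
    simulate_dataset,
)

# default configuration simulates a true genetic correlation of -0.65
config = SimulationConfig(seed=4, beta_lifetime_matings=0.0)
pedigree, records, manifest = simulate_dataset(config)
data = analysis_frame(derive_traits(filter_analysis_subset(records)))

A = build_A_matrix(pedigree).submatrix(list(data["female_id"]))
X = np.column_stack([np.ones(len(data)), data["start_date"].to_numpy(float)])
est = fit_bivariate_animal_model(
    data["longevity"].to_numpy(float),
    data["early_life_matings"].to_numpy(float),
    X, X, A.A,
)

print(f"analysed n = {len(data)} females, A matrix {A.A.shape[0]}x{A.A.shape[0]}")
print(f"V_A(longevity)    = {est.V_A1:.2f}")
print(f"V_A(early mating) = {est.V_A2:.3f}")
print(f"cov_A             = {est.cov_A:.3f}")
print(f"r_g = {est.r_g:.3f} (SE {est.se_r_g:.3f})   [simulated truth {manifest.r_g:.3f}]")
# r_g = cov_A / sqrt(V_A1 * V_A2); a value near -0.65 with an SE around
# 0.15 shows the estimator resolving the simulated trade-off at study scale.
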