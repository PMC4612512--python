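import numpy as np
import pytest

import halfsib as hs
from halfsib.simulate import PedigreeRecord, PedigreeTable
from _oracles import dense_bivariate_V, dense_restricted_loglik, kinship_A


def pedigree_from(parents: dict[str, tuple[str | None, str | None]]) -> PedigreeTable:
    return PedigreeTable([PedigreeRecord(i, s, d) for i, (s, d) in parents.items()])


THREE_GEN_PEDIGREE = {
    # founders
    "f1": (None, None), "f2": (None, None), "f3": (None, None), "f4": (None, None),
    # second generation, including full sibs and half sibs
    "g1": ("f1", "f2"), "g2": ("f1", "f2"), "g3": ("f1", "f3"), "g4": ("f4", "f3"),
    # third generation, including one inbred individual (parents are full sibs)
    "h1": ("g1", "g2"), "h2": ("g1", "g4"), "h3": ("g3", "g4"), "h4": ("f1", "g4"),
}


class TestAMatrix:
    def test_unrelated_founders_give_identity(self):
        rel = hs.build_A_matrix(pedigree_from({"a": (None, None), "b": (None, None)}))
        np.testing.assert_array_equal(rel.A, np.eye(2))

    def test_half_sibs_quarter_full_sibs_half(self):
        ped = pedigree_from(
            {
                "s": (None, None), "d1": (None, None), "d2": (None, None),
                "x": ("s", "d1"), "y": ("s", "d2"), "z": ("s", "d1"),
            }
        )
        rel = hs.build_A_matrix(ped)
        i = {ind: k for k, ind in enumerate(rel.ids)}
        assert rel.A[i["x"], i["y"]] == 0.25  # paternal half sibs
        assert rel.A[i["x"], i["z"]] == 0.5  # full sibs
        assert rel.A[i["x"], i["x"]] == 1.0  # non-inbred diagonal

    def test_three_generation_fixture_matches_recursive_kinship_oracle(self):
        rel = hs.build_A_matrix(pedigree_from(THREE_GEN_PEDIGREE))
        oracle = kinship_A(THREE_GEN_PEDIGREE)
        i = {ind: k for k, ind in enumerate(rel.ids)}
        for a in THREE_GEN_PEDIGREE:
            for b in THREE_GEN_PEDIGREE:
                assert rel.A[i[a], i[b]] == pytest.approx(oracle[(a, b)], abs=1e-12), (a, b)
        # h1's parents are full sibs: diagonal shows inbreeding
        assert rel.A[i["h1"], i["h1"]] == pytest.approx(1.25)

    def test_cyclic_pedigree_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            hs.build_A_matrix(pedigree_from({"a": ("b", None), "b": ("a", None)}))

    def test_submatrix_reorders(self):
        rel = hs.build_A_matrix(pedigree_from(THREE_GEN_PEDIGREE))
        sub = rel.submatrix(["h3", "g1"])
        i = {ind: k for k, ind in enumerate(rel.ids)}
        assert sub.A[0, 1] == rel.A[i["h3"], i["g1"]]
        assert sub.A[0, 0] == rel.A[i["h3"], i["h3"]]

    def test_psd_and_symmetric(self, study_sim):
        rel = hs.build_A_matrix(study_sim["pedigree"])
        assert np.allclose(rel.A, rel.A.T)
        assert np.linalg.eigvalsh(rel.A).min() > -1e-10


def halfsib_design_A(n_sires, n_dams, n_kids, rng=None):
    """A over daughters of a balanced half-sib design, via the pedigree builder."""
    recs = {}
    for s in range(n_sires):
        recs[f"s{s}"] = (None, None)
        for d in range(n_dams):
            recs[f"s{s}d{d}"] = (None, None)
            for k in range(n_kids):
                recs[f"s{s}d{d}k{k}"] = (f"s{s}", f"s{s}d{d}")
    rel = hs.build_A_matrix(pedigree_from(recs))
    daughters = [i for i in rel.ids if "k" in i]
    return rel.submatrix(daughters)


class TestUnivariateAnimalModel:
    def test_matches_dense_likelihood_oracle(self):
        rel = halfsib_design_A(4, 2, 5)  # 40 individuals
        rng = np.random.default_rng(8)
        L = np.linalg.cholesky(2.0 * rel.A + 1.5 * np.eye(40))
        y = 5.0 + L @ rng.standard_normal(40)
        X = np.ones((40, 1))
        va, ve, ll = hs.fit_univariate_animal_model(y, X, rel)
        V = va * rel.A + ve * np.eye(40)
        assert ll == pytest.approx(dense_restricted_loglik(V, y, X), abs=1e-8)

    def test_no_genetic_signal_estimated_near_zero(self):
        rel = halfsib_design_A(10, 3, 3)
        rng = np.random.default_rng(9)
        y = rng.normal(0, 2, 90)  # iid: V_A truth is 0
        va, ve, _ = hs.fit_univariate_animal_model(y, None, rel)
        assert va / (va + ve) < 0.05

    def test_agrees_with_sire_model_at_large_n(self):
        """V_A from the animal model ~ 4*V_sire from the nested model."""
        cfg = hs.SimulationConfig(
            n_sires=300, n_daughters_per_dam=3,
            # high intercept so that no female dies before her sixth
            # opportunity: without truncation both estimators target V_A
            trait_means=(70.0, 2.085),
            beta_lifetime_matings=0.0, beta_start_date=0.0, attrition_prob=0.0,
            seed=21,
        )
        ped, recs, man = hs.simulate_dataset(cfg)
        data = hs.analysis_frame(hs.derive_traits(hs.filter_analysis_subset(recs)))
        rel = hs.build_A_matrix(ped).submatrix(list(data["female_id"]))
        va, ve, _ = hs.fit_univariate_animal_model(
            data["longevity"].to_numpy(float), None, rel
        )
        sire_fit = hs.fit_nested_lmm(hs.ModelSpec("longevity"), data)
        va_sire = 4 * sire_fit.V_sire
        # the two estimators weight half-sib and full-sib information
        # differently, so they agree only up to their joint sampling noise
        assert va == pytest.approx(va_sire, rel=0.25)
        assert va + ve == pytest.approx(sire_fit.V_P, rel=0.05)

    def test_non_psd_matrix_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semidefinite"):
            hs.fit_univariate_animal_model(np.zeros(2), None, bad)


class TestGeneticCorrelation:
    def test_identities(self):
        assert hs.genetic_correlation(0.0, 1.0, 1.0) == 0.0
        assert hs.genetic_correlation(-0.5, 1.0, 1.0) == -0.5
        for va1, va2 in [(3.0, 0.2), (50.0, 0.5)]:
            cov = -0.651 * np.sqrt(va1 * va2)
            assert hs.genetic_correlation(cov, va1, va2) == pytest.approx(-0.651)

    def test_out_of_range_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            assert hs.genetic_correlation(2.0, 1.0, 1.0) == 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            hs.genetic_correlation(0.1, 0.0, 1.0)


@pytest.fixture(scope="module")
def bivariate_sim():
    """Study-scale simulation with a strong negative genetic correlation."""
    cfg = hs.SimulationConfig(seed=31, beta_lifetime_matings=0.0)
    ped, recs, man = hs.simulate_dataset(cfg)
    data = hs.analysis_frame(hs.derive_traits(hs.filter_analysis_subset(recs)))
    rel = hs.build_A_matrix(ped).submatrix(list(data["female_id"]))
    return data, rel, man


class TestBivariateAnimalModel:
    def test_matches_dense_likelihood_oracle(self):
        rel = halfsib_design_A(4, 2, 3)  # 24 individuals
        rng = np.random.default_rng(14)
        G_true = np.array([[4.0, -1.0], [-1.0, 1.0]])
        R_true = np.array([[3.0, 0.5], [0.5, 2.0]])
        Vt = dense_bivariate_V(G_true, R_true, rel.A)
        yy = np.linalg.cholesky(Vt) @ rng.standard_normal(48)
        est = hs.fit_bivariate_animal_model(yy[:24], yy[24:], None, None, rel.A)
        G = np.array([[est.V_A1, est.cov_A], [est.cov_A, est.V_A2]])
        R = np.array([[est.V_R1, est.cov_R], [est.cov_R, est.V_R2]])
        V = dense_bivariate_V(G, R, rel.A)
        X = np.zeros((48, 2))
        X[:24, 0] = 1.0
        X[24:, 1] = 1.0
        assert est.reml_loglik == pytest.approx(
            dense_restricted_loglik(V, yy, X), abs=1e-8
        )

    def test_independent_traits_give_rg_near_zero(self):
        cfg = hs.SimulationConfig(
            seed=17, beta_lifetime_matings=0.0,
            G=np.array([[50.41, 0.0], [0.0, 0.5]]),
        )
        ped, recs, _ = hs.simulate_dataset(cfg)
        data = hs.analysis_frame(hs.derive_traits(hs.filter_analysis_subset(recs)))
        rel = hs.build_A_matrix(ped).submatrix(list(data["female_id"]))
        est = hs.fit_bivariate_animal_model(
            data["longevity"].to_numpy(float),
            data["early_life_matings"].to_numpy(float),
            None, None, rel.A,
        )
        assert abs(est.r_g) < 0.35  # ~2.5 SEs at this design size

    def test_recovers_negative_genetic_correlation(self, bivariate_sim):
        data, rel, man = bivariate_sim
        est = hs.fit_bivariate_animal_model(
            data["longevity"].to_numpy(float),
            data["early_life_matings"].to_numpy(float),
            None, None, rel.A,
        )
        assert est.converged
        assert est.r_g == pytest.approx(man.r_g, abs=0.35)
        assert est.r_g < 0
        assert 0 < est.se_r_g < 0.5

    def test_rg_invariant_to_affine_rescaling(self, bivariate_sim):
        data, rel, _ = bivariate_sim
        y1 = data["longevity"].to_numpy(float)
        y2 = data["early_life_matings"].to_numpy(float)
        base = hs.fit_bivariate_animal_model(y1, y2, None, None, rel.A)
        scaled = hs.fit_bivariate_animal_model(y1 / 24.0, 3.0 * y2 + 7.0, None, None, rel.A)
        assert scaled.r_g == pytest.approx(base.r_g, abs=1e-4)
        assert scaled.V_A1 == pytest.approx(base.V_A1 / 24.0**2, rel=1e-3)

    def test_optional_dam_effect_runs(self, bivariate_sim):
        data, rel, _ = bivariate_sim
        est = hs.fit_bivariate_animal_model(
            data["longevity"].to_numpy(float)[:200],
            data["early_life_matings"].to_numpy(float)[:200],
            None, None, rel.A[:200, :200],
            dam_ids=data["dam_id"].to_numpy()[:200], include_dam=True,
        )
        assert np.isfinite(est.reml_loglik)
        assert -1 <= est.r_g <= 1

    def test_mismatched_lengths_rejected(self, bivariate_sim):
        data, rel, _ = bivariate_sim
        with pytest.raises(ValueError):
            hs.fit_bivariate_animal_model(
                data["longevity"].to_numpy(float)[:-1],
                data["early_life_matings"].to_numpy(float),
                None, None, rel.A,
            )
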