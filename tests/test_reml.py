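import dataclasses
import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import halfsib as hs
from _oracles import dense_nested_V, dense_restricted_loglik, ols_restricted_loglik


def small_fixture(n=30, seed=1, p=2):
    rng = np.random.default_rng(seed)
    sire_ids = np.repeat([f"s{i}" for i in range(5)], n // 5)
    dam_ids = np.array([f"{s}_d{i % 2}" for i, s in enumerate(sire_ids)])
    X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(p - 1)])
    y = rng.normal(10, 3, size=n)
    return y, X, sire_ids, dam_ids


class TestRestrictedLoglik:
    def test_reduces_to_ols_when_variances_zero(self):
        y, X, sire_ids, dam_ids = small_fixture(n=10, p=2)
        sigma2 = 2.7
        ours = hs.reml_loglik((0.0, 0.0, sigma2), y, X, sire_ids, dam_ids)
        assert ours == pytest.approx(ols_restricted_loglik(y, X, sigma2), abs=1e-10)

    def test_matches_dense_multivariate_normal(self):
        y, X, sire_ids, dam_ids = small_fixture(n=30, p=3)
        for theta in [(1.0, 0.5, 2.0), (4.0, 0.0, 1.0), (0.3, 2.2, 0.7)]:
            V = dense_nested_V(*theta, sire_ids, dam_ids)
            assert hs.reml_loglik(theta, y, X, sire_ids, dam_ids) == pytest.approx(
                dense_restricted_loglik(V, y, X), abs=1e-8
            )

    def test_change_of_scale_identity(self):
        y, X, sire_ids, dam_ids = small_fixture(n=20)
        n, p = X.shape
        theta = (1.5, 0.4, 2.0)
        c = 3.7
        base = hs.reml_loglik(theta, y, X, sire_ids, dam_ids)
        scaled = hs.reml_loglik(
            tuple(c**2 * t for t in theta), c * y, X, sire_ids, dam_ids
        )
        assert scaled == pytest.approx(base - (n - p) * math.log(c), abs=1e-9)

    def test_negative_components_rejected(self):
        y, X, sire_ids, dam_ids = small_fixture(n=10)
        with pytest.raises(ValueError):
            hs.reml_loglik((-1.0, 0.0, 1.0), y, X, sire_ids, dam_ids)


class TestAnovaOracle:
    def test_hand_computed_two_by_two_fixture(self):
        # sires A,B; two dams each; two daughters per dam
        y = [4, 6, 8, 10, 1, 3, 3, 5]
        sires = ["A"] * 4 + ["B"] * 4
        dams = ["a1", "a1", "a2", "a2", "b1", "b1", "b2", "b2"]
        vc = hs.anova_oracle_balanced(y, sires, dams)
        # MS_sire=32, MS_dam=10, MS_within=2 from expected mean squares
        assert vc.V_resid == pytest.approx(2.0)
        assert vc.V_dam == pytest.approx((10 - 2) / 2)
        assert vc.V_sire == pytest.approx((32 - 10) / 4)

    def test_constant_data_gives_zero_components(self):
        y = [5.0] * 8
        sires = ["A"] * 4 + ["B"] * 4
        dams = ["a1", "a1", "a2", "a2", "b1", "b1", "b2", "b2"]
        vc = hs.anova_oracle_balanced(y, sires, dams)
        assert (vc.V_sire, vc.V_dam, vc.V_resid) == (0.0, 0.0, 0.0)

    def test_unbalanced_rejected(self):
        y = list(range(7))
        sires = ["A"] * 4 + ["B"] * 3
        dams = ["a1", "a1", "a2", "a2", "b1", "b1", "b2"]
        with pytest.raises(ValueError, match="balanced"):
            hs.anova_oracle_balanced(y, sires, dams)


def fit_intercept_model(y, sire_ids, dam_ids):
    df = pd.DataFrame(
        {"y": y, "sire_id": sire_ids, "dam_id": dam_ids, "female_id": range(len(y))}
    )
    return hs.fit_nested_lmm(hs.ModelSpec("y"), df)


class TestFitNestedLmm:
    def test_matches_anova_oracle_on_balanced_design(self, balanced_nested):
        y, sire_ids, dam_ids, _ = balanced_nested
        oracle = hs.anova_oracle_balanced(y, sire_ids, dam_ids)
        assert min(oracle.V_sire, oracle.V_dam, oracle.V_resid) > 0  # interior
        fit = fit_intercept_model(y, sire_ids, dam_ids)
        assert fit.V_sire == pytest.approx(oracle.V_sire, rel=1e-6)
        assert fit.V_dam == pytest.approx(oracle.V_dam, rel=1e-6)
        assert fit.V_resid == pytest.approx(oracle.V_resid, rel=1e-6)

    def test_invariant_to_record_order_and_labels(self, balanced_nested):
        y, sire_ids, dam_ids, _ = balanced_nested
        fit = fit_intercept_model(y, sire_ids, dam_ids)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        relabel = {s: f"zz{i}" for i, s in enumerate(dict.fromkeys(sire_ids))}
        fit2 = fit_intercept_model(
            y[perm], np.array([relabel[s] for s in sire_ids])[perm], dam_ids[perm]
        )
        assert fit2.V_sire == pytest.approx(fit.V_sire, rel=1e-5)
        assert fit2.V_dam == pytest.approx(fit.V_dam, rel=1e-5)
        assert fit2.reml_loglik == pytest.approx(fit.reml_loglik, abs=1e-8)

    def test_dam_variance_boundary_reported_as_exact_zero(self):
        rng = np.random.default_rng(3)
        s, d, k = 100, 3, 4
        y = np.repeat(rng.normal(0, 2.0, s), d * k) + rng.normal(0, 3.0, s * d * k)
        sire_ids = np.repeat([f"s{i}" for i in range(s)], d * k)
        dam_ids = np.repeat([f"d{i}" for i in range(s * d)], k)
        fit = fit_intercept_model(y, sire_ids, dam_ids)
        assert fit.V_dam == 0.0
        assert fit.converged

    def test_loglik_at_estimate_beats_neighbours(self, balanced_nested):
        y, sire_ids, dam_ids, _ = balanced_nested
        fit = fit_intercept_model(y, sire_ids, dam_ids)
        X = np.ones((len(y), 1))
        best = hs.reml_loglik(
            (fit.V_sire, fit.V_dam, fit.V_resid), y, X, sire_ids, dam_ids
        )
        for bump in (0.95, 1.05):
            other = hs.reml_loglik(
                (fit.V_sire * bump, fit.V_dam, fit.V_resid), y, X, sire_ids, dam_ids
            )
            assert other <= best + 1e-9

    def test_rank_deficient_design_rejected(self, balanced_nested):
        y, sire_ids, dam_ids, _ = balanced_nested
        df = pd.DataFrame(
            {"y": y, "x": 1.0, "sire_id": sire_ids, "dam_id": dam_ids}
        )
        with pytest.raises(np.linalg.LinAlgError):
            hs.fit_nested_lmm(hs.ModelSpec("y", ("x",)), df)

    def test_agrees_with_lme4(self, study_sim, tmp_path):
        """Independent cross-check of variance components against R's lmer."""
        data = study_sim["data"]
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                m <- lmer(longevity ~ lifetime_matings + (1|sire_id) + (1|sire_id:dam_id),
                          data = d, REML = TRUE)
                vc <- as.data.frame(VarCorr(m))
                out <- c(vc$vcov[vc$grp == "sire_id"], vc$vcov[vc$grp == "sire_id:dam_id"],
                         vc$vcov[vc$grp == "Residual"], fixef(m)["lifetime_matings"])
                cat(sprintf("%.10f\\n", out))
                """
            )
        )
        res = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
        assert res.returncode == 0, res.stderr
        r_vs, r_vd, r_ve, r_beta = map(float, res.stdout.split())
        fit = hs.fit_nested_lmm(hs.ModelSpec("longevity", ("lifetime_matings",)), data)
        vp = fit.V_P
        assert fit.V_sire == pytest.approx(r_vs, abs=2e-3 * vp)
        assert fit.V_dam == pytest.approx(r_vd, abs=2e-3 * vp)
        assert fit.V_resid == pytest.approx(r_ve, abs=2e-3 * vp)
        assert fit.beta[list(fit.beta_names).index("lifetime_matings")] == pytest.approx(
            r_beta, rel=1e-3
        )


class TestWald:
    def test_single_coefficient_equals_squared_z(self, study_sim):
        fit = hs.fit_nested_lmm(
            hs.ModelSpec("longevity", ("lifetime_matings", "body_size")), study_sim["data"]
        )
        j = list(fit.beta_names).index("lifetime_matings")
        z2 = fit.beta[j] ** 2 / fit.beta_cov[j, j]
        w = hs.wald_test(fit, "lifetime_matings")
        assert w.statistic == pytest.approx(z2)
        assert w.df == 1
        assert 0 <= w.p_value <= 1

    def test_zero_coefficient_gives_zero_statistic(self, study_sim):
        fit = hs.fit_nested_lmm(
            hs.ModelSpec("longevity", ("body_size",)), study_sim["data"]
        )
        fit.beta[list(fit.beta_names).index("body_size")] = 0.0
        w = hs.wald_test(fit, "body_size")
        assert w.statistic == 0.0
        assert w.p_value == 1.0

    def test_unknown_term_rejected(self, study_sim):
        fit = hs.fit_nested_lmm(hs.ModelSpec("longevity"), study_sim["data"])
        with pytest.raises(KeyError):
            hs.wald_test(fit, "nope")


class TestLrt:
    def test_identical_fits_give_zero_statistic(self, study_sim):
        fit = hs.fit_nested_lmm(hs.ModelSpec("longevity"), study_sim["data"])
        reduced = dataclasses.replace(fit, random_structure=("sire",))
        res = hs.lrt_random_effect(fit, reduced)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        res_mix = hs.lrt_random_effect(fit, reduced, boundary_mixture=True)
        assert res_mix.p_value == 1.0

    def test_strong_sire_variance_detected(self, balanced_nested):
        y, sire_ids, dam_ids, _ = balanced_nested
        df = pd.DataFrame({"y": y, "sire_id": sire_ids, "dam_id": dam_ids})
        full = hs.fit_nested_lmm(hs.ModelSpec("y"), df)
        no_sire = hs.fit_nested_lmm(
            hs.ModelSpec("y", random_structure=("dam",)), df
        )
        res = hs.lrt_random_effect(full, no_sire)
        assert res.statistic > 0
        assert res.p_value < 0.001

    def test_non_nested_pair_rejected(self, study_sim):
        fit = hs.fit_nested_lmm(hs.ModelSpec("longevity"), study_sim["data"])
        with pytest.raises(ValueError):
            hs.lrt_random_effect(fit, fit)


class TestModelSelection:
    def test_strong_effect_retained_null_dropped(self, study_sim):
        spec = hs.ModelSpec("longevity", ("lifetime_matings", "body_size"))
        minimal = hs.select_minimal_model(spec, study_sim["data"])
        assert "lifetime_matings" in minimal.fixed_terms
        assert "body_size" not in minimal.fixed_terms

    def test_no_candidates_is_noop(self, study_sim):
        spec = hs.ModelSpec("longevity")
        assert hs.select_minimal_model(spec, study_sim["data"]) == spec
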