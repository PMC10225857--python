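import numpy as np
import pandas as pd
import pytest

import avitrend as av
from avitrend.traits import brownian_covariance, enumerate_submodels


@pytest.fixture(scope="module")
def simple_spec():
    return av.ModelSpec(main_effects=("body_mass",), interactions=(), z_scored=False)


class TestZTransform:
    def test_closed_form(self):
        np.testing.assert_allclose(
            av.z_transform([1, 2, 3]), [-1.2247448, 0.0, 1.2247448], atol=1e-6
        )

    def test_idempotent_on_standardized(self):
        x = av.z_transform(np.random.default_rng(0).normal(3, 2, 100))
        np.testing.assert_allclose(av.z_transform(x), x, atol=1e-12)

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        x = rng.normal(5, 3, 50)
        z = av.z_transform(x)
        np.testing.assert_allclose(z * x.std(ddof=0) + x.mean(), x, atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            av.z_transform(np.ones(10))


class TestFitLM:
    def test_coefficient_recovery(self, simple_spec):
        rng = np.random.default_rng(2)
        n = 300
        mass = rng.normal(size=n)
        df = pd.DataFrame({"growth_rate": 0.5 * mass + rng.normal(0, 0.3, n), "body_mass": mass})
        fit = av.fit_lm(simple_spec, df)
        assert abs(fit.coef["body_mass"] - 0.5) < 2 * fit.se["body_mass"]

    def test_intercept_only_data(self):
        rng = np.random.default_rng(3)
        n = 200
        df = pd.DataFrame(
            {"growth_rate": 1.0 + rng.normal(0, 0.1, n), "body_mass": rng.normal(size=n)}
        )
        with_slope = av.fit_lm(
            av.ModelSpec(main_effects=("body_mass",), interactions=(), z_scored=False), df
        )
        intercept_only = av.fit_lm(
            av.ModelSpec(main_effects=(), interactions=(), z_scored=False), df
        )
        assert abs(with_slope.coef["body_mass"]) < 0.05
        assert intercept_only.aic < with_slope.aic

    def test_row_order_invariance(self, simple_spec):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {"growth_rate": rng.normal(size=50), "body_mass": rng.normal(size=50)}
        )
        a = av.fit_lm(simple_spec, df)
        b = av.fit_lm(simple_spec, df.sample(frac=1, random_state=0).reset_index(drop=True))
        np.testing.assert_allclose(a.coef, b.coef, atol=1e-10)

    def test_aliased_terms_reported(self):
        df = pd.DataFrame(
            {
                "growth_rate": np.random.default_rng(5).normal(size=30),
                "body_mass": np.arange(30.0),
                "cst": np.arange(30.0),  # perfectly collinear with body_mass
            }
        )
        spec = av.ModelSpec(main_effects=("body_mass", "cst"), interactions=(), z_scored=False)
        fit = av.fit_lm(spec, df)
        assert fit.aliased == ["cst"]


class TestPGLS:
    def test_lambda_zero_equals_ols(self, simple_spec, yule_50):
        rng = np.random.default_rng(6)
        ids = [t.label for t in yule_50.taxon_namespace]
        x = rng.normal(size=50)
        df = pd.DataFrame(
            {"species_id": ids, "growth_rate": 0.3 * x + rng.normal(0, 0.2, 50), "body_mass": x}
        )
        pgls = av.fit_pgls(simple_spec, df, yule_50)
        if pgls.lam == 0.0:
            ols = av.fit_lm(simple_spec, df)
            np.testing.assert_allclose(pgls.coef, ols.coef, atol=1e-8)

    def test_star_phylogeny_flagged_and_matches_ols(self, simple_spec):
        import dendropy

        n = 20
        newick = "(" + ",".join(f"t{i}:1.0" for i in range(n)) + ");"
        star = dendropy.Tree.get(data=newick, schema="newick")
        rng = np.random.default_rng(7)
        x = rng.normal(size=n)
        df = pd.DataFrame(
            {"species_id": [f"t{i}" for i in range(n)], "growth_rate": x + rng.normal(0, 0.5, n), "body_mass": x}
        )
        fit = av.fit_pgls(simple_spec, df, star)
        assert fit.star_tree
        ols = av.fit_lm(simple_spec, df)
        np.testing.assert_allclose(fit.coef, ols.coef, atol=1e-8)

    def test_brownian_residuals_recover_high_lambda(self, simple_spec, yule_50):
        rng = np.random.default_rng(8)
        ids = [t.label for t in yule_50.taxon_namespace]
        C = brownian_covariance(yule_50, ids)
        L = np.linalg.cholesky(C)
        hits = 0
        for _ in range(20):
            x = rng.normal(size=50)
            resid = 0.3 * (L @ rng.normal(size=50)) / np.sqrt(np.mean(np.diag(C)))
            df = pd.DataFrame({"species_id": ids, "growth_rate": 0.5 * x + resid, "body_mass": x})
            fit = av.fit_pgls(simple_spec, df, yule_50, cov=C)
            hits += fit.lam >= 0.8
        assert hits >= 16

    def test_independent_residuals_recover_low_lambda(self, simple_spec, yule_100):
        rng = np.random.default_rng(9)
        ids = [t.label for t in yule_100.taxon_namespace]
        C = brownian_covariance(yule_100, ids)
        hits = 0
        for _ in range(20):
            x = rng.normal(size=100)
            df = pd.DataFrame(
                {"species_id": ids, "growth_rate": 0.5 * x + rng.normal(0, 0.3, 100), "body_mass": x}
            )
            fit = av.fit_pgls(simple_spec, df, yule_100, cov=C)
            hits += fit.lam <= 0.1
        assert hits >= 16

    def test_species_missing_from_tree_dropped(self, simple_spec, yule_50):
        rng = np.random.default_rng(10)
        ids = [t.label for t in yule_50.taxon_namespace] + ["ghost"]
        x = rng.normal(size=51)
        df = pd.DataFrame({"species_id": ids, "growth_rate": x, "body_mass": x})
        fit = av.fit_pgls(simple_spec, df, yule_50)
        assert fit.n == 50

    def test_profile_maximum(self, simple_spec, yule_50):
        rng = np.random.default_rng(11)
        ids = [t.label for t in yule_50.taxon_namespace]
        x = rng.normal(size=50)
        df = pd.DataFrame({"species_id": ids, "growth_rate": x + rng.normal(size=50), "body_mass": x})
        fit = av.fit_pgls(simple_spec, df, yule_50)
        grid, lls = fit.profile
        assert fit.loglik >= lls.max() - 1e-6


class TestLRBoundary:
    def _fit(self, yule_50, brownian: bool, seed: int):
        rng = np.random.default_rng(seed)
        ids = [t.label for t in yule_50.taxon_namespace]
        C = brownian_covariance(yule_50, ids)
        if brownian:
            resid = np.linalg.cholesky(C) @ rng.normal(size=50)
        else:
            resid = rng.normal(size=50)
        x = rng.normal(size=50)
        df = pd.DataFrame({"species_id": ids, "growth_rate": 0.4 * x + 0.3 * resid, "body_mass": x})
        spec = av.ModelSpec(main_effects=("body_mass",), interactions=(), z_scored=False)
        return av.fit_pgls(spec, df, yule_50, cov=C)

    def test_statistic_nonnegative(self, yule_50):
        fit = self._fit(yule_50, brownian=True, seed=12)
        for null in (0.0, 1.0):
            stat, _ = av.lr_test_lambda(fit, null)
            assert stat >= 0

    def test_estimate_at_null_gives_high_p(self, yule_50):
        fit = self._fit(yule_50, brownian=False, seed=13)
        if fit.lam == 0.0:
            stat, p = av.lr_test_lambda(fit, 0.0)
            assert stat == 0.0 and p >= 0.5

    def test_independent_residual_pattern(self, yule_50):
        """λ indistinguishable from 0, distinguishable from 1."""
        fit = self._fit(yule_50, brownian=False, seed=14)
        _, p0 = av.lr_test_lambda(fit, 0.0)
        _, p1 = av.lr_test_lambda(fit, 1.0)
        assert p0 >= 0.05
        assert p1 < 0.05


class TestDredge:
    def test_two_predictor_enumeration(self):
        spec = av.ModelSpec(main_effects=("body_mass", "cst"), interactions=(), z_scored=False)
        models = enumerate_submodels(spec)
        formulas = {m.formula() for m in models}
        assert formulas == {
            "growth_rate ~ 1",
            "growth_rate ~ body_mass",
            "growth_rate ~ cst",
            "growth_rate ~ body_mass + cst",
        }

    def test_marginality_respected(self):
        spec = av.ModelSpec(
            main_effects=("migration", "body_mass"),
            interactions=(("migration", "body_mass"),),
            z_scored=False,
        )
        for m in enumerate_submodels(spec):
            for a, b in m.interactions:
                assert a in m.main_effects and b in m.main_effects

    def test_true_predictor_selected(self):
        rng = np.random.default_rng(15)
        hits = 0
        spec = av.ModelSpec(main_effects=("body_mass", "cst"), interactions=(), z_scored=False)
        for _ in range(20):
            n = 300
            mass = rng.normal(size=n)
            df = pd.DataFrame(
                {
                    "growth_rate": 1.0 * mass + rng.normal(0, 1.0, n),
                    "body_mass": mass,
                    "cst": rng.normal(size=n),
                }
            )
            sel = av.dredge(spec, df)
            terms = sel.best.spec.main_effects
            hits += ("body_mass" in terms) and ("cst" not in terms)
        assert hits >= 18

    def test_retained_within_six_aic_units(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame(
            {
                "growth_rate": rng.normal(size=100),
                "body_mass": rng.normal(size=100),
                "cst": rng.normal(size=100),
            }
        )
        spec = av.ModelSpec(main_effects=("body_mass", "cst"), interactions=(), z_scored=False)
        sel = av.dredge(spec, df)
        best_aic = sel.best.aic
        for f in sel.retained:
            assert f.aic - best_aic <= 6.0 + 1e-9

    def test_nested_removal(self):
        """Pure-noise predictors: more complex models nested in the null are dropped."""
        rng = np.random.default_rng(17)
        df = pd.DataFrame(
            {
                "growth_rate": rng.normal(size=200),
                "body_mass": rng.normal(size=200),
                "cst": rng.normal(size=200),
            }
        )
        spec = av.ModelSpec(main_effects=("body_mass", "cst"), interactions=(), z_scored=False)
        sel = av.dredge(spec, df)
        retained_terms = [set(f.spec.terms) for f in sel.retained]
        for i, a in enumerate(retained_terms):
            for j, b in enumerate(retained_terms):
                if i != j:
                    assert not (a < b and sel.retained[i].aic < sel.retained[j].aic)

    def test_prepare_trait_data_excludes_marine_and_missing_cst(self):
        df = pd.DataFrame(
            {
                "species_id": list("abcd"),
                "growth_rate": [0.1, 0.2, 0.3, 0.4],
                "habitat": ["marine", "forest", "grassland", "forest"],
                "cst": [0.1, np.nan, 0.2, 0.3],
                "body_mass": [1.0, 2.0, 3.0, 4.0],
            }
        )
        spec = av.ModelSpec(main_effects=("body_mass",), interactions=())
        out = av.prepare_trait_data(df, spec)
        assert set(out["species_id"]) == {"c", "d"}
        assert out["body_mass"].mean() == pytest.approx(0.0, abs=1e-12)
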