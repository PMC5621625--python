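import math

import numpy as np
import pandas as pd
import pytest

from spatnut._polya_gamma import pg_mean, pg_var, random_polyagamma
from spatnut.data_io import AdjacencyGraph
from spatnut.model import (PriorSpec, Posterior, build_design,
                           effective_sample_size, fit_model, icar_draw,
                           sample_gmrf, screen_collinearity, season_of,
                           split_rhat, summarize_effects)


class TestSeasons:
    @pytest.mark.parametrize("date,season", [
        ("2009-05-10", "Gu"), ("2009-08-01", "Hagaa"), ("2009-12-25", "Jilal"),
        ("2009-01-15", "Jilal"), ("2009-10-01", "Deyr"), ("2009-11-30", "Deyr"),
        ("2009-03-31", "Jilal"), ("2009-07-01", "Hagaa"),
    ])
    def test_month_mapping(self, date, season):
        assert season_of(date) == season

    def test_every_month_maps(self):
        seasons = {season_of(f"2009-{m:02d}-15") for m in range(1, 13)}
        assert seasons == {"Jilal", "Gu", "Hagaa", "Deyr"}

    def test_december_tiebreak_configurable(self):
        assert season_of("2009-12-01", december="Deyr") == "Deyr"
        with pytest.raises(ValueError):
            season_of("2009-12-01", december="Monsoon")


class TestCollinearity:
    def test_duplicated_column_flagged(self, rng):
        x = rng.standard_normal(200)
        report = screen_collinearity(pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(200)}))
        assert len(report.flagged) == 1
        assert report.flagged.iloc[0]["r"] == pytest.approx(1.0)
        assert report.threshold == 0.6  # the default

    def test_independent_columns_not_flagged(self, rng):
        df = pd.DataFrame(rng.standard_normal((10_000, 5)),
                          columns=list("abcde"))
        assert screen_collinearity(df).flagged.empty

    def test_constant_column_reported(self, rng):
        df = pd.DataFrame({"a": np.ones(50), "b": rng.standard_normal(50)})
        report = screen_collinearity(df)
        assert report.constant_columns == ["a"]

    def test_needs_two_columns(self):
        with pytest.raises(ValueError):
            screen_collinearity(pd.DataFrame({"a": [1.0, 2.0]}))


class TestPolyaGamma:
    @pytest.mark.parametrize("c", [0.0, 0.7, 2.0, 6.0, 20.0])
    def test_moments_match_closed_form(self, c, rng):
        n = 60_000
        x = random_polyagamma(c, rng, size=n)
        assert abs(x.mean() - pg_mean(c)) < 4 * math.sqrt(pg_var(c) / n)
        assert x.var() == pytest.approx(float(pg_var(c)), rel=0.05)
        assert (x > 0).all()

    def test_mean_matches_series_representation(self):
        # independent oracle: E sum_k (1/2pi^2)/((k-1/2)^2 + c^2/(4pi^2))
        c = 1.3
        k = np.arange(1, 200_000)
        series = (1.0 / (2 * np.pi ** 2) / ((k - 0.5) ** 2 + c ** 2 /
                                            (4 * np.pi ** 2))).sum()
        assert series == pytest.approx(float(pg_mean(c)), rel=1e-4)

    def test_vectorised_over_z(self, rng):
        z = np.array([0.0, 1.0, -1.0, 4.0])
        x = random_polyagamma(z, rng)
        assert x.shape == z.shape

    def test_sign_invariance_and_determinism(self):
        a = random_polyagamma(np.full(100, 2.0), np.random.default_rng(1))
        b = random_polyagamma(np.full(100, -2.0), np.random.default_rng(1))
        np.testing.assert_array_equal(a, b)


class TestGMRF:
    def test_sample_gmrf_mean_and_cov(self, rng):
        prec = np.array([[2.0, -0.5], [-0.5, 1.0]])
        rhs = np.array([1.0, -2.0])
        draws = np.array([sample_gmrf(prec, rhs, rng) for _ in range(20_000)])
        np.testing.assert_allclose(draws.mean(0), np.linalg.solve(prec, rhs),
                                   atol=0.02)
        np.testing.assert_allclose(np.cov(draws.T), np.linalg.inv(prec),
                                   atol=0.03)

    def test_icar_conditional_mean_is_neighbour_average(self):
        """On a path graph the ICAR full conditional for node j has mean equal
        to the average of its neighbours (closed form, 1e-8)."""
        g = AdjacencyGraph(list("abcd"), [("a", "b"), ("b", "c"), ("c", "d")])
        Q = g.structure_matrix()
        u = np.array([0.3, -0.1, 0.7, -0.9])
        for j, neigh in [(0, [1]), (1, [0, 2]), (2, [1, 3]), (3, [2])]:
            cond_mean = -(Q[j] @ u - Q[j, j] * u[j]) / Q[j, j]
            assert cond_mean == pytest.approx(u[neigh].mean(), abs=1e-8)

    def test_icar_draw_sums_to_zero_per_component(self, rng):
        g = AdjacencyGraph(list("abcdef"),
                           [("a", "b"), ("b", "c"), ("d", "e"), ("e", "f")])
        Q = g.structure_matrix()
        comps = [np.array([0, 1, 2]), np.array([3, 4, 5])]
        u = icar_draw(Q, tau=2.0, components=comps, rng=rng)
        for comp in comps:
            assert abs(u[comp].sum()) < 1e-8

    def test_icar_draw_infinite_precision_is_zero(self, rng):
        g = AdjacencyGraph(["a", "b"], [("a", "b")])
        u = icar_draw(g.structure_matrix(), np.inf, [np.array([0, 1])], rng)
        np.testing.assert_array_equal(u, np.zeros(2))


def _plain_design(X, y):
    n = len(y)
    return __import__("spatnut.model", fromlist=["DesignMatrix"]).DesignMatrix(
        X=X, columns=[f"b{i}" for i in range(X.shape[1])], y=y,
        cluster_codes=np.zeros(n, int), district_codes=np.zeros(n, int),
        round_codes=np.zeros(n, int), cluster_ids=["c0"], district_ids=["d0"],
        round_dates=[pd.Timestamp("2008-01-01")], variant="A", outcome="wasted")


class TestDesign:
    def test_variant_a_has_no_conflict_columns(self, small_survey):
        design = build_design(small_survey["dataset"], small_survey["exposure"],
                              small_survey["geography"], variant="A")
        assert not any("conflict" in c for c in design.columns)

    def test_variant_b_has_conflict_and_interactions(self, small_survey):
        design = build_design(small_survey["dataset"], small_survey["exposure"],
                              small_survey["geography"], variant="B")
        assert "recent_conflict" in design.columns
        assert "evi:temperature" in design.columns
        assert "longer_conflict:evi" in design.columns

    def test_interaction_is_product_of_centered_parents(self, small_survey):
        design = build_design(small_survey["dataset"], small_survey["exposure"],
                              small_survey["geography"], variant="B")
        name = "carbohydrate:evi"
        pa, pb, ca, cb = design.interactions[name]
        expected = (design.col(pa) - ca) * (design.col(pb) - cb)
        np.testing.assert_allclose(design.col(name), expected, atol=1e-12)
        # hand check on the first three records
        for i in range(3):
            assert design.col(name)[i] == pytest.approx(
                (design.col("carbohydrate")[i] - ca) * (design.col("evi")[i] - cb))

    def test_agro_pastoral_reference_level(self, small_survey):
        design = build_design(small_survey["dataset"], small_survey["exposure"],
                              small_survey["geography"], variant="A")
        records = small_survey["dataset"].records.reset_index(drop=True)
        agro = records["livelihood"] == "agro-pastoral"
        lcols = [c for c in design.columns if c.startswith("livelihood_")]
        assert agro.any()
        block = np.column_stack([design.col(c) for c in lcols])
        assert (block[agro.to_numpy()] == 0).all()

    def test_standardisation_recorded(self, small_survey):
        design = build_design(small_survey["dataset"], small_survey["exposure"],
                              small_survey["geography"], variant="B")
        assert "evi" in design.transforms
        assert design.col("evi").mean() == pytest.approx(0.0, abs=1e-9)
        assert design.col("evi").std() == pytest.approx(1.0, rel=1e-6)

    def test_no_constant_columns_after_build(self, small_survey):
        design = build_design(small_survey["dataset"], small_survey["exposure"],
                              small_survey["geography"], variant="B")
        body = design.X[:, 1:]  # intercept exempt
        assert (body.std(axis=0) > 0).all()

    def test_unknown_variant(self, small_survey):
        with pytest.raises(ValueError):
            build_design(small_survey["dataset"], small_survey["exposure"],
                         small_survey["geography"], variant="C")


class TestFit:
    def test_intercept_only_recovers_prevalence(self, rng):
        n = 5000
        y = (rng.random(n) < 0.3).astype(float)
        design = _plain_design(np.ones((n, 1)), y)
        post = fit_model(design, None, chains=2, iterations=600, burnin=200,
                         thinning=1, seed=1, random_effects=())
        p_hat = 1 / (1 + np.exp(-post.beta[:, 0]))
        assert p_hat.mean() == pytest.approx(y.mean(), abs=0.03)

    def test_fixed_effects_match_ml_oracle(self, rng):
        n = 4000
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        beta_true = np.array([-0.8, 0.6, -0.4])
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
        design = _plain_design(X, y)
        post = fit_model(design, None, chains=2, iterations=900, burnin=300,
                         thinning=1, seed=2, random_effects=())
        import statsmodels.api as sm
        ml = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        pm, sd = post.beta.mean(0), post.beta.std(0)
        assert (np.abs(pm - ml.params) < 2 * sd).all()

    def test_icar_sum_to_zero_every_draw(self, fitted_small):
        post = fitted_small["posterior"]
        adjacency = fitted_small["adjacency"]
        pos = {c: i for i, c in enumerate(post.cluster_ids)}
        for comp in adjacency.components():
            idx = [pos[c] for c in comp if c in pos]
            assert np.abs(post.u[:, idx].sum(axis=1)).max() < 1e-8

    def test_draw_count_contract(self, fitted_small):
        post = fitted_small["posterior"]
        assert post.n_draws == 2 * (600 - 250) // 1

    def test_deterministic_under_seed(self, small_survey):
        design = build_design(small_survey["dataset"], small_survey["exposure"],
                              small_survey["geography"], variant="A")
        kwargs = dict(chains=1, iterations=60, burnin=20, thinning=1, seed=5)
        p1 = fit_model(design, small_survey["adjacency"], **kwargs)
        p2 = fit_model(design, small_survey["adjacency"], **kwargs)
        np.testing.assert_array_equal(p1.beta, p2.beta)
        np.testing.assert_array_equal(p1.u, p2.u)

    def test_cluster_relabelling_invariance(self, small_survey):
        """Reversing cluster labels permutes u but leaves beta unchanged
        (same seed, identical record ordering)."""
        design = build_design(small_survey["dataset"], small_survey["exposure"],
                              small_survey["geography"], variant="A")
        post = fit_model(design, small_survey["adjacency"], chains=1,
                         iterations=200, burnin=100, thinning=1, seed=3)
        # relabel: map cluster ids to reversed names everywhere
        mapping = dict(zip(design.cluster_ids, reversed(design.cluster_ids)))
        ds2 = small_survey["dataset"].records.copy()
        ds2["cluster_id"] = ds2["cluster_id"].map(mapping)
        expo2 = small_survey["exposure"].copy()
        expo2["cluster_id"] = expo2["cluster_id"].map(mapping)
        geo2 = small_survey["geography"]
        clusters2 = geo2.clusters.copy()
        clusters2["cluster_id"] = clusters2["cluster_id"].map(mapping)
        cov2 = geo2.covariates.copy()
        cov2["cluster_id"] = cov2["cluster_id"].map(mapping)
        from spatnut.data_io import ClusterGeography
        geo2 = ClusterGeography(clusters2, cov2)
        adj2 = AdjacencyGraph([mapping[n] for n in small_survey["adjacency"].nodes],
                              [(mapping[a], mapping[b])
                               for a, b in small_survey["adjacency"].edges])
        design2 = build_design(ds2, expo2, geo2, variant="A")
        post2 = fit_model(design2, adj2, chains=1, iterations=200, burnin=100,
                          thinning=1, seed=3)
        # posterior over fixed effects agrees within MC error
        sd = post.beta.std(0) / math.sqrt(50)
        assert (np.abs(post.beta.mean(0) - post2.beta.mean(0))
                < 6 * np.maximum(sd, 5e-3)).all()

    def test_missing_adjacency_rejected(self, small_survey):
        design = build_design(small_survey["dataset"], small_survey["exposure"],
                              small_survey["geography"], variant="A")
        with pytest.raises(ValueError, match="adjacency"):
            fit_model(design, None, chains=1, iterations=20, burnin=10, seed=1)

    def test_burnin_validation(self, small_survey):
        design = build_design(small_survey["dataset"], small_survey["exposure"],
                              small_survey["geography"], variant="A")
        with pytest.raises(ValueError, match="burn-in"):
            fit_model(design, small_survey["adjacency"], iterations=10, burnin=10)

    def test_unknown_random_effect_block(self, small_survey):
        design = build_design(small_survey["dataset"], small_survey["exposure"],
                              small_survey["geography"], variant="A")
        with pytest.raises(ValueError, match="unknown random effect"):
            fit_model(design, small_survey["adjacency"], iterations=20,
                      burnin=10, random_effects=("icar", "weather"))

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            PriorSpec(tau_shape=-1.0)


class TestSummaries:
    def _posterior(self, draws):
        S = draws.shape[0]
        return Posterior(beta=draws, columns=[f"b{i}" for i in range(draws.shape[1])],
                         u=None, v=None, w=None, d=None, tau={},
                         chain=np.zeros(S, int), iteration=np.arange(S),
                         cluster_ids=["c0"], district_ids=["d0"],
                         random_effects=())

    def _design(self, p):
        return _plain_design(np.ones((4, p)), np.array([0, 1, 0, 1.0]))

    def test_zero_draws_give_unit_or(self):
        post = self._posterior(np.zeros((200, 1)))
        out = summarize_effects(post, self._design(1))
        row = out.iloc[0]
        assert row["or"] == 1.0 and row["ci_lo"] == 1.0 and row["ci_hi"] == 1.0
        assert not row["significant"]

    def test_grid_draws_reproduce_published_interval_shape(self):
        grid = np.log(np.linspace(1.71, 1.81, 401))[:, None]
        out = summarize_effects(self._posterior(grid), self._design(1))
        row = out.iloc[0]
        assert row["or"] == pytest.approx(1.76, abs=0.005)
        assert row["ci_lo"] == pytest.approx(1.71, abs=0.005)
        assert row["ci_hi"] == pytest.approx(1.81, abs=0.005)
        assert row["significant"]

    def test_quantile_oracle(self, rng):
        draws = rng.standard_normal((1000, 1)) * 0.2 + 0.1
        out = summarize_effects(self._posterior(draws), self._design(1))
        srt = np.sort(draws[:, 0])
        lo = np.exp(np.quantile(srt, 0.025))
        hi = np.exp(np.quantile(srt, 0.975))
        assert out.iloc[0]["ci_lo"] == pytest.approx(lo, rel=1e-12)
        assert out.iloc[0]["ci_hi"] == pytest.approx(hi, rel=1e-12)

    def test_requires_100_draws(self):
        with pytest.raises(ValueError):
            summarize_effects(self._posterior(np.zeros((50, 1))), self._design(1))

    def test_unit_scale_back_transform(self, fitted_small):
        """Per-unit OR equals standardized OR^(1/sd)."""
        design, post = fitted_small["design"], fitted_small["posterior"]
        std = summarize_effects(post, design, unit_scale=False)
        unit = summarize_effects(post, design, unit_scale=True)
        sd = design.transforms["evi"][1]
        r_std = std[std.term == "evi"].iloc[0]["or"]
        r_unit = unit[unit.term == "evi"].iloc[0]["or"]
        assert r_unit == pytest.approx(r_std ** (1.0 / sd), rel=1e-9)


class TestDiagnostics:
    def test_split_rhat_iid_near_one(self, rng):
        chains = rng.standard_normal((4, 500))
        assert abs(split_rhat(chains) - 1.0) < 0.05

    def test_split_rhat_detects_divergence(self, rng):
        chains = rng.standard_normal((2, 500))
        chains[1] += 10.0
        assert split_rhat(chains) > 2.0

    def test_ess_iid_close_to_n(self, rng):
        chains = rng.standard_normal((2, 1000))
        assert effective_sample_size(chains) > 1200

    def test_ess_autocorrelated_is_smaller(self, rng):
        x = np.cumsum(rng.standard_normal((2, 1000)), axis=1)
        assert effective_sample_size(x) < 200

    def test_posterior_diagnostics_frame(self, fitted_small):
        diag = fitted_small["posterior"].diagnostics()
        assert {"term", "rhat", "ess"} <= set(diag.columns)
        assert np.isfinite(diag["rhat"]).all()
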