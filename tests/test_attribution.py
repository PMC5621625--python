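import itertools
import math

import numpy as np
import pandas as pd
import pytest

from spatnut.attribution import (Factor, attributable_fraction,
                                 predict_counterfactual, resolve_factors,
                                 sequential_af)
from spatnut.model import DesignMatrix, Posterior


def _toy(X, y, columns, beta_draws, interactions=None):
    """A design plus a degenerate posterior with hand-fixed coefficients."""
    n = len(y)
    design = DesignMatrix(
        X=np.asarray(X, float), columns=list(columns), y=np.asarray(y, float),
        cluster_codes=np.zeros(n, int), district_codes=np.zeros(n, int),
        round_codes=np.zeros(n, int), cluster_ids=["c0"], district_ids=["d0"],
        round_dates=[pd.Timestamp("2008-01-01")], variant="B",
        outcome="wasted", interactions=interactions or {})
    draws = np.tile(np.asarray(beta_draws, float), (150, 1))
    post = Posterior(beta=draws, columns=list(columns), u=None, v=None, w=None,
                     d=None, tau={}, chain=np.zeros(150, int),
                     iteration=np.arange(150), cluster_ids=["c0"],
                     district_ids=["d0"], random_effects=())
    return design, post


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestAFArithmetic:
    def test_worked_example(self):
        assert attributable_fraction(100.0, 92.4) == pytest.approx(0.076)

    def test_equal_expected_gives_zero(self):
        assert attributable_fraction(50.0, 50.0) == 0.0

    def test_excess_expected_gives_negative(self):
        assert attributable_fraction(50.0, 60.0) == pytest.approx(-0.2)

    def test_zero_observed_rejected(self):
        with pytest.raises(ValueError):
            attributable_fraction(0.0, 10.0)


class TestCounterfactual:
    def _fixture(self):
        # 4 individuals, intercept + binary exposure + covariate
        X = np.array([[1, 1, 0.5], [1, 0, -0.5], [1, 1, 1.0], [1, 0, 0.0]])
        beta = [-1.0, 0.8, 0.3]
        y = np.array([1, 0, 1, 0.0])
        return _toy(X, y, ["intercept", "recent_conflict", "z"], beta)

    def test_empty_set_matches_fitted_sum(self):
        design, post = self._fixture()
        expected = _sigmoid(design.X @ post.beta[0]).sum()
        assert predict_counterfactual(post, design, []) == pytest.approx(expected)

    def test_hand_computed_sigmoid_sum(self):
        design, post = self._fixture()
        X0 = design.X.copy()
        X0[:, 1] = 0.0
        by_hand = _sigmoid(X0 @ post.beta[0]).sum()
        removed = resolve_factors(design, ["recent"])
        assert predict_counterfactual(post, design, removed) == \
            pytest.approx(by_hand, abs=1e-12)

    def test_null_factor_changes_nothing(self):
        X = np.array([[1, 1.0], [1, 0.0], [1, 1.0]])
        design, post = _toy(X, [1, 0, 1.0], ["intercept", "recent_conflict"],
                            [-0.3, 0.0])
        e0 = predict_counterfactual(post, design, [])
        e1 = predict_counterfactual(post, design,
                                    resolve_factors(design, ["recent"]))
        assert e1 == pytest.approx(e0, abs=1e-10)

    def test_interactions_rebuilt_from_modified_parents(self):
        # columns: intercept, f (exposure), z, f:z with centering recorded
        f = np.array([1.0, 0, 1, 0])
        z = np.array([0.2, -0.1, 0.4, 0.3])
        ca, cb = f.mean(), z.mean()
        X = np.column_stack([np.ones(4), f, z, (f - ca) * (z - cb)])
        design, post = _toy(X, [1, 0, 0, 1.0],
                            ["intercept", "recent_conflict", "z", "recent_conflict:z"],
                            [-0.5, 0.7, 0.2, 0.4],
                            interactions={"recent_conflict:z":
                                          ("recent_conflict", "z", ca, cb)})
        X0 = X.copy()
        X0[:, 1] = 0.0
        X0[:, 3] = (X0[:, 1] - ca) * (X0[:, 2] - cb)
        by_hand = _sigmoid(X0 @ post.beta[0]).sum()
        removed = resolve_factors(design, ["recent"])
        assert predict_counterfactual(post, design, removed) == \
            pytest.approx(by_hand, abs=1e-12)

    def test_evi_removed_to_upper_quantile(self):
        z = np.linspace(0, 1, 11)
        X = np.column_stack([np.ones(11), z])
        design, post = _toy(X, np.ones(11), ["intercept", "evi"], [0.0, -1.0])
        factors = resolve_factors(design, ["evi"], evi_reference_quantile=0.9)
        assert factors[0].reference == pytest.approx(np.quantile(z, 0.9))

    def test_unknown_factor_named_in_error(self):
        design, post = self._fixture()
        with pytest.raises(KeyError, match="degree_days"):
            resolve_factors(design, ["degree_days"])


def _brute_force_shapley(post, design, factors):
    """Independent enumeration: average AF increments over orderings."""
    O = design.y.sum()

    def af(subset):
        X = design.X.copy()
        idx = {c: i for i, c in enumerate(design.columns)}
        for f in subset:
            X[:, idx[f.column]] = f.reference
        for name, (pa, pb, ca, cb) in design.interactions.items():
            if any(f.column in (pa, pb) for f in subset):
                X[:, idx[name]] = (X[:, idx[pa]] - ca) * (X[:, idx[pb]] - cb)
        p = _sigmoid(post.linear_predictor(design, X=X)).mean(axis=0)
        return (O - p.sum()) / O

    out = {f.name: 0.0 for f in factors}
    perms = list(itertools.permutations(factors))
    for perm in perms:
        prev = 0.0
        for k in range(1, len(perm) + 1):
            cum = af(perm[:k])
            out[perm[k - 1].name] += cum - prev
            prev = cum
    return {k: v / len(perms) for k, v in out.items()}


class TestSequentialAF:
    def _instance(self, seed, n=60):
        rng = np.random.default_rng(seed)
        f1 = (rng.random(n) < 0.4).astype(float)
        f2 = (rng.random(n) < 0.3).astype(float)
        z = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), f1, f2, z])
        beta = [-0.5, 0.9, 0.6, 0.2]
        y = (rng.random(n) < _sigmoid(X @ np.array(beta))).astype(float)
        if y.sum() == 0:
            y[0] = 1.0
        cols = ["intercept", "recent_conflict", "longer_conflict", "z"]
        return _toy(X, y, cols, beta)

    def test_three_factors_give_six_orderings(self):
        rng = np.random.default_rng(0)
        n = 40
        X = np.column_stack([np.ones(n), (rng.random(n) < 0.5).astype(float),
                             (rng.random(n) < 0.5).astype(float),
                             rng.random(n)])
        design, post = _toy(X, np.ones(n),
                            ["intercept", "recent_conflict", "longer_conflict",
                             "evi"], [0.1, 0.2, 0.3, -0.4])
        report = sequential_af(post, design, ["recent", "longer", "evi"])
        assert report.per_permutation["permutation"].nunique() == 6
        assert len(report.per_permutation) == 18

    def test_zero_coefficients_give_zero_afs(self):
        # calibrated null model: p = 1/2 everywhere, half the outcomes are 1,
        # so E_S = O for every subset and every AF vanishes exactly
        n = 40
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(n), (rng.random(n) < 0.4).astype(float),
                             (rng.random(n) < 0.3).astype(float)])
        y = np.tile([0.0, 1.0], n // 2)
        design, post = _toy(X, y, ["intercept", "recent_conflict",
                                   "longer_conflict"], [0.0, 0.0, 0.0])
        report = sequential_af(post, design, ["recent", "longer"])
        for af in report.averaged.values():
            assert af == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_independent_brute_force(self, seed):
        design, post = self._instance(seed)
        factors = resolve_factors(design, ["recent", "longer"])
        expected = _brute_force_shapley(post, design, factors)
        report = sequential_af(post, design, ["recent", "longer"])
        for name in expected:
            assert report.averaged[name] == pytest.approx(expected[name], abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_shapley_efficiency(self, seed):
        design, post = self._instance(seed + 10)
        report = sequential_af(post, design, ["recent", "longer"])
        combined = report.combined[("recent", "longer")]
        assert sum(report.averaged.values()) == pytest.approx(combined, abs=1e-10)

    def test_per_permutation_telescopes_to_combined(self):
        design, post = self._instance(3)
        report = sequential_af(post, design, ["recent", "longer"])
        combined = report.combined[("recent", "longer")]
        for _, grp in report.per_permutation.groupby("permutation"):
            assert grp["sequential_af"].sum() == pytest.approx(combined, abs=1e-10)

    def test_symmetry_of_identical_factors(self):
        rng = np.random.default_rng(5)
        n = 50
        f = (rng.random(n) < 0.5).astype(float)
        X = np.column_stack([np.ones(n), f, f.copy()])
        design, post = _toy(X, np.ones(n), ["intercept", "fa", "fb"],
                            [-0.2, 0.5, 0.5])
        report = sequential_af(post, design,
                               [Factor("fa", "fa"), Factor("fb", "fb")])
        assert report.averaged["fa"] == pytest.approx(report.averaged["fb"],
                                                      abs=1e-12)

    def test_factor_list_order_only_permutes_labels(self):
        design, post = self._instance(7)
        r1 = sequential_af(post, design, ["recent", "longer"])
        r2 = sequential_af(post, design, ["longer", "recent"])
        for name in ("recent", "longer"):
            assert r1.averaged[name] == pytest.approx(r2.averaged[name], abs=1e-12)

    def test_too_many_factors_refused(self):
        design, post = self._instance(0)
        names = [Factor(f"f{i}", "z") for i in range(7)]
        with pytest.raises(ValueError, match="factorially"):
            sequential_af(post, design, names)

    def test_scaling_blend_preserves_null_calibration(self):
        """With scaling on, the empty-set expected count stays at O-scale:
        blending pulls predictions toward the observed mean, so E_empty is
        unchanged when the model is calibrated."""
        design, post = self._instance(2)
        report = sequential_af(post, design, ["recent"], scaling="blend")
        assert report.r2 is not None and 0 <= report.r2 <= 1
        e_empty = predict_counterfactual(post, design, [], scaling="blend",
                                         r2=report.r2)
        p = _sigmoid(post.linear_predictor(design)).mean(axis=0)
        ybar = design.y.mean()
        blended = ybar + report.r2 * (p - ybar)
        assert e_empty == pytest.approx(blended.sum(), abs=1e-9)

    def test_report_table_layout(self):
        design, post = self._instance(4)
        report = sequential_af(post, design, ["recent", "longer"])
        table = report.table()
        assert set(table["kind"]) == {"combined", "averaged"}
        assert "recent + longer" in set(table["predictors"])
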