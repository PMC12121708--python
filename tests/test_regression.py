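"""Run-pair regression, noise ceiling, and commonality analysis."""

import numpy as np
import pytest

from mvpattern.core import PatternDataset, VolumeGrid
from mvpattern.patterns import ContrastSpec
from mvpattern.regression import (
    RegressionDesign,
    explainable_variance_pct,
    fit_noise_ceiling,
    fit_runpair_regressions,
    run_pairs,
    variance_partition,
)


def _dataset_from_condition_vectors(cond_vectors):
    """cond_vectors: condition -> run -> vector."""
    v = len(next(iter(next(iter(cond_vectors.values())).values())))
    grid = VolumeGrid((v, 1, 1))
    pats = {}
    for cond, by_run in cond_vectors.items():
        for r, vec in by_run.items():
            pats[(r, cond)] = np.asarray(vec, float)
    return PatternDataset(grid, np.ones(grid.dims, bool), pats)


def _design(n_pred=3):
    names = ["O", "I", "M"][:n_pred]
    return RegressionDesign(
        dependent=ContrastSpec("dep", "self", "rest"),
        predictors=tuple(ContrastSpec(n, n, "rest") for n in names),
    )


def _random_dataset(seed, v=60, n_runs=5, conds=("self", "O", "I", "M")):
    rng = np.random.default_rng(seed)
    return _dataset_from_condition_vectors(
        {c: {r: rng.standard_normal(v) for r in range(n_runs)} for c in conds}
    )


class TestRunPairRegression:
    def test_five_runs_give_twenty_ordered_pairs(self):
        ds = _random_dataset(0)
        res = fit_runpair_regressions(_design(), ds)
        assert len(res.per_pair) == 20
        assert set(res.per_pair) == set(run_pairs(range(5)))
        assert all(a != b for a, b in res.per_pair)

    def test_exact_linear_dependence_recovered(self):
        rng = np.random.default_rng(1)
        o = rng.standard_normal(200)
        ds = _dataset_from_condition_vectors(
            {
                "self": {r: o for r in range(3)},
                "O": {r: o for r in range(3)},
                "I": {r: rng.standard_normal(200) for r in range(3)},
                "M": {r: rng.standard_normal(200) for r in range(3)},
            }
        )
        res = fit_runpair_regressions(_design(), ds)
        assert res.mean_betas[0] == pytest.approx(1.0, abs=1e-10)
        assert abs(res.mean_betas[1]) < 1e-10
        assert res.mean_adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_betas_match_normal_equations_oracle(self):
        # tiny 2-run toy solved independently via (X'X)^-1 X'y
        y0 = np.array([1.0, 2.0, 0.5, -1.0])
        x1 = np.array([0.5, 1.0, -0.5, 0.0])
        ds = _dataset_from_condition_vectors(
            {"self": {0: y0, 1: y0[::-1]}, "O": {0: x1, 1: 2 * x1}}
        )
        design = RegressionDesign(
            dependent=ContrastSpec("dep", "self", "rest"),
            predictors=(ContrastSpec("O", "O", "rest"),),
        )
        res = fit_runpair_regressions(design, ds)
        for (a, b), fit in res.per_pair.items():
            y = ds.get(a, "self")
            x = np.column_stack([np.ones(4), ds.get(b, "O")])
            beta = np.linalg.solve(x.T @ x, x.T @ y)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
            assert fit.betas[0] == pytest.approx(beta[1], abs=1e-10)

    def test_matches_statsmodels_cross_check(self):
        sm = pytest.importorskip("statsmodels.api")
        ds = _random_dataset(2, v=80, n_runs=2)
        res = fit_runpair_regressions(_design(), ds)
        for (a, b), fit in res.per_pair.items():
            x = np.column_stack([ds.get(b, c) for c in ("O", "I", "M")])
            m = sm.OLS(ds.get(a, "self"), sm.add_constant(x)).fit()
            np.testing.assert_allclose(fit.betas, m.params[1:], atol=1e-8)
            assert fit.r2 == pytest.approx(m.rsquared, abs=1e-10)
            assert fit.adj_r2 == pytest.approx(m.rsquared_adj, abs=1e-10)

    def test_rank_deficient_predictors_named(self):
        rng = np.random.default_rng(3)
        o = rng.standard_normal(50)
        ds = _dataset_from_condition_vectors(
            {
                "self": {r: rng.standard_normal(50) for r in range(2)},
                "O": {r: o for r in range(2)},
                "I": {r: 2 * o for r in range(2)},  # exactly collinear
                "M": {r: rng.standard_normal(50) for r in range(2)},
            }
        )
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_runpair_regressions(_design(), ds)

    def test_roi_too_small_rejected(self):
        ds = _random_dataset(4, v=4)
        with pytest.raises(ValueError, match="too small"):
            fit_runpair_regressions(_design(), ds)


class TestNoiseCeiling:
    def test_noiseless_dependent_reaches_ceiling_one(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(100)
        ds = _dataset_from_condition_vectors(
            {
                "self": {r: y for r in range(3)},
                "O": {r: rng.standard_normal(100) for r in range(3)},
                "I": {r: rng.standard_normal(100) for r in range(3)},
                "M": {r: rng.standard_normal(100) for r in range(3)},
            }
        )
        res = fit_noise_ceiling(_design(), ds)
        assert res.mean_adj_r2 == pytest.approx(1.0, abs=1e-10)
        assert len(res.predictor_names) == 4

    def test_ceiling_bounds_full_model(self):
        # nested models: the ceiling adds a predictor, so raw R2 never drops
        for seed in range(20):
            ds = _random_dataset(100 + seed, v=80)
            full = fit_runpair_regressions(_design(), ds)
            ceil = fit_noise_ceiling(_design(), ds)
            for pair in full.per_pair:
                assert ceil.per_pair[pair].r2 >= full.per_pair[pair].r2 - 1e-12

    def test_pure_noise_ceiling_near_zero(self):
        ds = _random_dataset(6, v=5000, n_runs=3)
        res = fit_noise_ceiling(_design(), ds)
        assert abs(res.mean_adj_r2) < 0.05


class TestVariancePartition:
    def test_orthogonal_design_isolates_unique_portion(self):
        rng = np.random.default_rng(7)
        o, i_, m = (rng.standard_normal(3000) for _ in range(3))
        y = 0.8 * o + 0.6 * rng.standard_normal(3000)
        ds = _dataset_from_condition_vectors(
            {
                "self": {r: y for r in range(2)},
                "O": {r: o for r in range(2)},
                "I": {r: i_ for r in range(2)},
                "M": {r: m for r in range(2)},
            }
        )
        vpa = variance_partition(_design(), ds)
        assert vpa.unique_O == pytest.approx(vpa.full_r2, abs=0.01)
        for k in ("unique_I", "unique_M", "common_OI", "common_OM", "common_IM",
                  "common_OIM"):
            assert abs(vpa.portions[k]) < 0.01

    def test_near_duplicated_predictors_share_common_portion(self):
        rng = np.random.default_rng(8)
        shared = rng.standard_normal(3000)
        i_ = shared + 0.05 * rng.standard_normal(3000)
        m = shared + 0.05 * rng.standard_normal(3000)
        y = 0.8 * shared + 0.6 * rng.standard_normal(3000)
        ds = _dataset_from_condition_vectors(
            {
                "self": {r: y for r in range(2)},
                "O": {r: rng.standard_normal(3000) for r in range(2)},
                "I": {r: i_ for r in range(2)},
                "M": {r: m for r in range(2)},
            }
        )
        vpa = variance_partition(_design(), ds)
        assert abs(vpa.unique_I) < 0.02
        assert abs(vpa.unique_M) < 0.02
        assert vpa.common_IM > 0.5 * vpa.full_r2

    def test_seven_portions_sum_to_full_r2(self):
        for seed in range(10):
            ds = _random_dataset(200 + seed, v=40)
            vpa = variance_partition(_design(), ds)
            assert sum(vpa.portions.values()) == pytest.approx(
                vpa.full_r2, abs=1e-10
            )
            assert len(vpa.submodel_r2) == 7

    def test_nesting_monotonicity(self):
        ds = _random_dataset(9, v=60)
        vpa = variance_partition(_design(), ds)
        r2 = vpa.submodel_r2
        assert r2["OIM"] >= max(r2["OI"], r2["OM"], r2["IM"]) - 1e-12
        assert min(r2["OI"], r2["OM"], r2["IM"]) >= min(r2["O"], r2["I"], r2["M"]) - 1e-12

    def test_requires_three_predictors(self):
        ds = _random_dataset(10)
        with pytest.raises(ValueError, match="3 predictors"):
            variance_partition(_design(n_pred=2), ds)


class TestExplainableVariance:
    def _result_with_adj(self, adj):
        from mvpattern.regression import RunPairRegressionResult

        return RunPairRegressionResult(
            predictor_names=("O",), per_pair={}, mean_betas=np.zeros(1),
            mean_r2=adj, mean_adj_r2=adj, n_voxels=100,
        )

    def test_full_equals_ceiling_gives_100(self):
        r = self._result_with_adj(0.5)
        assert explainable_variance_pct([r], [r]) == pytest.approx(100.0)

    def test_ratio_definition(self):
        full, ceil = self._result_with_adj(0.4), self._result_with_adj(0.5)
        assert explainable_variance_pct([full], [ceil]) == pytest.approx(80.0)

    def test_nonpositive_ceiling_excluded_with_warning(self):
        full = [self._result_with_adj(0.4), self._result_with_adj(0.3)]
        ceil = [self._result_with_adj(0.5), self._result_with_adj(-0.1)]
        with pytest.warns(UserWarning, match="excluded"):
            pct = explainable_variance_pct(full, ceil)
        assert pct == pytest.approx(80.0)
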