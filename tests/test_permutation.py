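"""Moran's I, smoothing-SD calibration, and the voxel-shuffle null."""

import numpy as np
import pytest

from mvpattern.core import PatternDataset, VolumeGrid, volume_to_vector
from mvpattern.patterns import ContrastSpec
from mvpattern.permutation import (
    MoransIWeights,
    calibrate_smoothing_sd,
    morans_i,
    permuted_statistic_null,
    regression_statistic,
)
from mvpattern.regression import RegressionDesign
from mvpattern.synth import GeneratorSpec, generate_pattern_dataset, smooth_volume


def _line_weights(n):
    coords = np.column_stack([np.arange(n), np.zeros(n), np.zeros(n)])
    return MoransIWeights.from_coords(coords.astype(float))


def _cube_dataset(n, patterns):
    grid = VolumeGrid((n, n, n))
    return PatternDataset(grid, np.ones(grid.dims, bool), patterns)


@pytest.fixture(scope="module")
def cube_weights():
    grid = VolumeGrid((8, 8, 8))
    coords = grid.voxel_to_mm(
        np.argwhere(np.ones(grid.dims, bool))
    )
    return MoransIWeights.from_coords(coords)


class TestMoransI:
    def test_alternating_series_is_negative(self):
        x = np.resize([1.0, -1.0], 20)
        assert morans_i(x, _line_weights(20)) < 0

    def test_smooth_gradient_is_positive(self):
        assert morans_i(np.arange(20.0), _line_weights(20)) > 0

    def test_iid_null_expectation(self, cube_weights):
        n = 512
        rng = np.random.default_rng(0)
        vals = [morans_i(rng.standard_normal(n), cube_weights) for _ in range(200)]
        expected = -1.0 / (n - 1)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * se

    def test_smoothing_increases_i(self, cube_weights):
        rng = np.random.default_rng(1)
        higher = 0
        for _ in range(100):
            vol = rng.standard_normal((8, 8, 8))
            sm = smooth_volume(vol, sd_voxels=1.0)
            if morans_i(sm.ravel(order="F"), cube_weights) > morans_i(
                vol.ravel(order="F"), cube_weights
            ):
                higher += 1
        assert higher == 100

    def test_affine_invariance(self, cube_weights):
        x = np.random.default_rng(2).standard_normal(512)
        i1 = morans_i(x, cube_weights)
        i2 = morans_i(5.0 * x - 3.0, cube_weights)
        assert i1 == pytest.approx(i2, abs=1e-12)

    def test_constant_input_rejected(self, cube_weights):
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(512), cube_weights)

    def test_weights_symmetric_nonneg_zero_diag(self, cube_weights):
        w = cube_weights.weights
        assert np.array_equal(w, w.T)
        assert w.min() >= 0
        assert np.all(np.diag(w) == 0)


class TestCalibration:
    def test_single_candidate_grid(self):
        ds = _cube_dataset(6, {(0, "self"): np.arange(216.0)})
        cal = calibrate_smoothing_sd(
            ds.get(0, "self"), ds, sd_grid=np.array([0.0]), n_rep=5, seed=0
        )
        assert cal.best_sd == 0.0

    def test_iid_map_calibrates_to_zero(self):
        """Shuffling an i.i.d. map already matches its smoothness, so no
        smoothing is needed. Smoothing can only push Moran's I upward, so
        whenever the observed I does not exceed the shuffled-map mean the
        chosen SD must be exactly 0; across draws the SD stays near 0."""
        ds0 = _cube_dataset(12, {(0, "x"): np.arange(1728.0)})
        weights = MoransIWeights.for_dataset(ds0)
        grid = np.round(np.arange(0.0, 0.41, 0.02), 2)
        i_null_mean = -1.0 / (1728 - 1)
        best, zero_expected = [], []
        for rep in range(10):
            obs = np.random.default_rng(50 + rep).standard_normal(1728)
            cal = calibrate_smoothing_sd(
                obs, ds0, weights=weights, sd_grid=grid, n_rep=20, seed=rep
            )
            best.append(cal.best_sd)
            if cal.observed_i <= i_null_mean:
                zero_expected.append(cal.best_sd)
        assert zero_expected and all(sd == 0.0 for sd in zero_expected)
        assert max(best) <= 0.4

    def test_recovers_known_smoothness_against_fine_grid_oracle(self):
        """Coarse-grid calibration agrees with a finer-grid rerun to 0.1 and
        both land near the smoothing actually applied to the map."""
        ds0 = _cube_dataset(12, {(0, "x"): np.arange(1728.0)})
        weights = MoransIWeights.for_dataset(ds0)
        vol = smooth_volume(
            np.random.default_rng(5).standard_normal((12, 12, 12)), sd_voxels=0.8
        )
        obs = volume_to_vector(vol, ds0.mask)
        coarse = calibrate_smoothing_sd(
            obs, ds0, weights=weights,
            sd_grid=np.round(np.arange(0, 1.61, 0.08), 2), n_rep=25, seed=1,
        )
        fine = calibrate_smoothing_sd(
            obs, ds0, weights=weights,
            sd_grid=np.round(np.arange(0, 1.61, 0.02), 2), n_rep=50, seed=2,
        )
        assert abs(coarse.best_sd - fine.best_sd) <= 0.1
        assert abs(fine.best_sd - 0.8) <= 0.25

    def test_constant_map_rejected(self):
        ds = _cube_dataset(6, {(0, "self"): np.arange(216.0)})
        with pytest.raises(ValueError, match="constant"):
            calibrate_smoothing_sd(
                np.ones(216), ds, sd_grid=np.array([0.0, 0.5]), n_rep=5, seed=0
            )


def _regression_setup(seed, n=6, load_self_on_o=0.0):
    conds = ("self", "other", "introspection", "memory")
    loading = np.zeros((4, 1))
    loading[1, 0] = 1.0
    loading[0, 0] = load_self_on_o
    grid = VolumeGrid((n, n, n))
    spec = GeneratorSpec(
        grid=grid, mask=np.ones(grid.dims, bool), n_runs=5,
        condition_labels=conds, loading_matrix=loading,
        obs_noise_sd=1.0, seed=seed,
    )
    ds = generate_pattern_dataset(spec)
    design = RegressionDesign(
        dependent=ContrastSpec("dep", "self", "rest"),
        predictors=(
            ContrastSpec("O", "other", "rest"),
            ContrastSpec("I", "introspection", "rest"),
            ContrastSpec("M", "memory", "rest"),
        ),
    )
    return ds, design


class TestPermutedNull:
    def _calibration(self, ds, seed=0):
        return calibrate_smoothing_sd(
            ds.get(0, "self"), ds,
            sd_grid=np.round(np.arange(0, 1.01, 0.1), 1), n_rep=10, seed=seed,
        )

    def test_constant_statistic_gives_p_one(self):
        ds, design = self._setup_or_cache(0)
        cal = self._calibration(ds)
        null = permuted_statistic_null(
            ds, lambda d: {"c": 1.0}, cal, n_perm=50, seed=1
        )
        assert null.p_values["c"] == 1.0

    def _setup_or_cache(self, seed, **kw):
        return _regression_setup(seed, **kw)

    def test_shuffle_preserves_value_multiset(self):
        ds, design = self._setup_or_cache(1)
        cal = self._calibration(ds)
        cal.best_sd = 0.0  # no smoothing: shuffles must preserve the multiset
        ref = {r: np.sort(ds.get(r, "self")) for r in ds.runs}

        def stat(d):
            for r in d.runs:
                np.testing.assert_allclose(np.sort(d.get(r, "self")), ref[r])
            return {"ok": 1.0}

        permuted_statistic_null(ds, stat, cal, n_perm=10, seed=2)

    def test_same_seed_bit_identical(self):
        ds, design = self._setup_or_cache(2)
        cal = self._calibration(ds)
        stat = regression_statistic(design)
        n1 = permuted_statistic_null(ds, stat, cal, n_perm=30, seed=3)
        n2 = permuted_statistic_null(ds, stat, cal, n_perm=30, seed=3)
        for k in n1.null_samples:
            np.testing.assert_array_equal(n1.null_samples[k], n2.null_samples[k])

    def test_p_never_zero_and_monotone(self):
        ds, design = self._setup_or_cache(3, load_self_on_o=2.0)
        cal = self._calibration(ds)
        null = permuted_statistic_null(
            ds, regression_statistic(design), cal, n_perm=100, seed=4
        )
        assert all(p > 0 for p in null.p_values.values())
        # strong planted dependence on O: its beta should be extreme
        assert null.p_values["beta_O"] <= null.p_values["beta_M"]

    def test_planted_signal_detected(self):
        hits = 0
        for rep in range(10):
            ds, design = _regression_setup(100 + rep, n=7, load_self_on_o=0.8)
            cal = self._calibration(ds, seed=rep)
            null = permuted_statistic_null(
                ds, regression_statistic(design), cal, n_perm=100, seed=rep
            )
            if null.p_values["beta_O"] < 0.05:
                hits += 1
        assert hits >= 8

    def test_failing_statistic_resampled_with_cap(self):
        ds, design = self._setup_or_cache(4)
        cal = self._calibration(ds)

        def always_fail(d):
            raise RuntimeError("nope")

        first = {"done": False}

        def fail_on_perms(d):
            if not first["done"]:
                first["done"] = True  # observed call succeeds
                return {"x": 0.0}
            raise RuntimeError("nope")

        with pytest.raises(RuntimeError):
            permuted_statistic_null(ds, fail_on_perms, cal, n_perm=100, seed=5)
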