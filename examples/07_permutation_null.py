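"""Smoothness-matched voxel-shuffle permutation test for regression betas.

The self pattern loads on the other condition's component, so beta_O should
be significant while beta_I and beta_M are not. The null shuffles the self
pattern (same permutation in every run), then smooths at the Gaussian SD
whose Moran's I best matches the observed map's smoothness (grid 0-2,
step 0.02).
"""

import numpy as np

from mvpattern import (
    MoransIWeights,
    RegressionDesign,
    calibrate_smoothing_sd,
    morans_i,
    permuted_statistic_null,
)
from mvpattern.core import VolumeGrid
from mvpattern.patterns import ContrastSpec
from mvpattern.permutation import regression_statistic
from mvpattern.synth import GeneratorSpec, generate_pattern_dataset

conds = ("self", "other", "introspection", "memory")
loading = np.zeros((4, 2))
loading[1, 0] = 1.0   # other's component
loading[0, 0] = 0.6   # self loads on it
loading[:, 1] = 0.0
grid = VolumeGrid((8, 8, 8))
ds = generate_pattern_dataset(
    GeneratorSpec(
        grid=grid, mask=np.ones(grid.dims, bool), n_runs=5,
        condition_labels=conds, loading_matrix=loading,
        component_smoothness_fwhm_mm=6.0, obs_noise_sd=1.0, seed=3,
    )
)
design = RegressionDesign(
    dependent=ContrastSpec("self", "self", "rest"),
    predictors=(
        ContrastSpec("O", "other", "rest"),
        ContrastSpec("I", "introspection", "rest"),
        ContrastSpec("M", "memory", "rest"),
    ),
)

weights = MoransIWeights.for_dataset(ds)
observed_map = ds.get(0, "self")
print(f"observed Moran's I of the self map: {morans_i(observed_map, weights):.4f}")
cal = calibrate_smoothing_sd(
    observed_map, ds, weights=weights,
    sd_grid=np.round(np.arange(0.0, 2.001, 0.02), 2), n_rep=40, seed=1,
)
print(f"calibrated post-shuffle smoothing SD: {cal.best_sd:.2f} voxels")

null = permuted_statistic_null(
    ds, regression_statistic(design), cal, n_perm=1000, seed=2
)
for key in ("beta_O", "beta_I", "beta_M", "adj_r2"):
    print(f"  {key:8s} observed={null.observed[key]:+.4f}  p={null.p_values[key]:.4f}")
print("-> only the planted dependence (beta_O) beats its smoothness-matched "
      "null; smoothing the shuffled maps keeps the test from mistaking "
      "spatial autocorrelation for signal.")
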