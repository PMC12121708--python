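import numpy as np
import pytest

from mvpattern.core import PatternDataset, VolumeGrid
from mvpattern.patterns import ContrastPatterns, ContrastSpec
from mvpattern.synth import DEFAULT_CONDITIONS, GeneratorSpec, generate_pattern_dataset


@pytest.fixture
def small_grid() -> VolumeGrid:
    return VolumeGrid(dims=(6, 6, 6), voxel_size_mm=(3.0, 3.0, 3.0))


@pytest.fixture
def full_mask(small_grid):
    return np.ones(small_grid.dims, bool)


def make_noise_dataset(
    n_runs=5,
    conditions=DEFAULT_CONDITIONS,
    grid_n=6,
    seed=0,
    obs_noise_sd=1.0,
    run_noise_sd=0.0,
    loading=None,
    smoothness=0.0,
) -> PatternDataset:
    grid = VolumeGrid((grid_n,) * 3)
    mask = np.ones(grid.dims, bool)
    if loading is None:
        loading = np.zeros((len(conditions), 1))
    spec = GeneratorSpec(
        grid=grid,
        mask=mask,
        n_runs=n_runs,
        condition_labels=tuple(conditions),
        loading_matrix=np.asarray(loading, float),
        component_smoothness_fwhm_mm=smoothness,
        run_noise_sd=run_noise_sd,
        obs_noise_sd=obs_noise_sd,
        seed=seed,
    )
    return generate_pattern_dataset(spec)


def make_contrast_patterns(name, vectors_by_run) -> ContrastPatterns:
    return ContrastPatterns(
        contrast=ContrastSpec(name, name, "rest"),
        per_run={r: np.asarray(v, float) for r, v in vectors_by_run.items()},
    )


@pytest.fixture
def seven_condition_dataset() -> PatternDataset:
    """7 conditions x 5 runs, weak independent signal per condition."""
    return make_noise_dataset(
        seed=11, loading=np.eye(7), obs_noise_sd=1.0, run_noise_sd=0.3
    )
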