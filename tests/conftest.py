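import dataclasses

import numpy as np
import pytest

from catring.geometry import Boundary, StimulusRing
from catring.synthetic import ROIDataset, SyntheticConfig, default_rois


@pytest.fixture(scope="session")
def ring() -> StimulusRing:
    return StimulusRing()


@pytest.fixture(scope="session")
def boundary() -> Boundary:
    return Boundary(45.0)


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """5 runs x (8 task + 8 fixation) trials, 30-voxel ROIs: one task trial
    per position per run, enough runs for nested cross-validation."""
    rois = tuple(dataclasses.replace(r, n_voxels=30) for r in default_rois())
    kwargs = dict(
        n_subjects=1, n_runs=5, task_trials_per_run=8, fixation_trials_per_run=8,
        rois=rois, seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture
def small_cfg() -> SyntheticConfig:
    return small_config()


def separable_dataset(
    n_runs: int = 4,
    trials_per_pos_per_run: int = 1,
    n_voxels: int = 24,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_positions: int = 8,
    n_timepoints: int = 7,
) -> ROIDataset:
    """Dataset whose position patterns are orthogonal indicator blocks —
    perfectly linearly separable when noiseless."""
    rng = np.random.default_rng(seed)
    block = n_voxels // n_positions
    assert block >= 1
    protos = np.zeros((n_positions, n_voxels))
    for k in range(n_positions):
        protos[k, k * block : (k + 1) * block] = 1.0
    n_trials = n_runs * n_positions * trials_per_pos_per_run
    pos = np.tile(np.arange(n_positions), n_trials // n_positions)
    runs = np.repeat(np.arange(n_runs), n_positions * trials_per_pos_per_run)
    data = protos[pos][:, None, :] * np.ones((1, n_timepoints, 1))
    data = data + rng.normal(0.0, noise_sd, data.shape)
    return ROIDataset(
        roi_name="toy",
        data=data,
        run_labels=runs,
        position_labels=pos,
        correct=np.ones(n_trials, bool),
        time_labels=np.arange(n_timepoints) * 2.0,
    )
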