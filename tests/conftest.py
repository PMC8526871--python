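"""Shared fixtures: small simulated populations and fitted toy states."""

from __future__ import annotations

import numpy as np
import pytest

import spfm
from spfm import model as M


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small population with clear structure: 5 modes, 8 subjects, 2 runs."""
    cfg = spfm.SimConfig(
        n_subjects=8,
        n_modes=5,
        n_voxels=300,
        n_timepoints=80,
        n_runs=2,
        mean_mode_size=0.08,
        target_misalignment=0.1,
        noise_snr=1.0,
        seed=7,
    )
    return spfm.simulate(cfg)


def normalise_rows(d):
    d = d - d.mean(axis=1, keepdims=True)
    sd = d.std(axis=1, keepdims=True)
    return d / np.where(sd > 0, sd, 1.0)


@pytest.fixture(scope="session")
def tiny_data(tiny_bundle):
    """Preprocessed per-subject run matrices for the tiny population."""
    b = tiny_bundle
    s, r = b.config.n_subjects, b.config.n_runs
    return [[normalise_rows(b.data[i, j]) for j in range(r)] for i in range(s)]


@pytest.fixture(scope="session")
def tiny_init(tiny_bundle):
    """ICA-free initial maps: noisy unit-variance copies of the truth."""
    rng = np.random.default_rng(3)
    maps = tiny_bundle.group_maps / tiny_bundle.group_maps.std(axis=0, keepdims=True)
    maps = maps + 0.3 * rng.standard_normal(maps.shape)
    return spfm.InitialMaps(maps=maps, mixing=np.eye(maps.shape[1]), seed=3)


@pytest.fixture(scope="session")
def fitted_toy(tiny_bundle, tiny_data, tiny_init):
    """Fully-converged full-batch VB state on the tiny population."""
    b = tiny_bundle
    cfg = M.ModelConfig(n_modes=b.config.n_modes, tr=b.config.tr)
    kernel = M.TemporalKernel.get(b.config.n_timepoints, cfg.tr, cfg.temporal_noise_floor)
    group = M.init_group_model(cfg, b.config.n_voxels, tiny_init.maps)
    subjects = [
        M.init_subject(group, tiny_init.maps, b.config.n_runs, b.config.n_timepoints)
        for _ in range(b.config.n_subjects)
    ]
    for _ in range(15):
        for s, subj in enumerate(subjects):
            M.update_subject(tiny_data[s], group, subj, kernel)
        group = M.accumulate_and_update_group(subjects, group, scale=1.0)
    return {"group": group, "subjects": subjects, "kernel": kernel, "config": cfg}
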