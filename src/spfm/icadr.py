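"""Group spatial ICA plus dual regression: the comparison pipeline.

Group maps come from the same spatial ICA (and the same PCA basis) that
initialises the hierarchical model, so differences between the two
pipelines are not attributable to the initial decomposition. Dual
regression then maps the group decomposition onto each subject: stage 1
regresses the group maps against a subject's data to obtain timecourses,
stage 2 regresses the variance-normalised timecourses against the data to
obtain subject maps. Mode amplitudes are the stage-1 timecourse standard
deviations, and between-mode connectivity is summarised with
Tikhonov-regularised partial correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import MaskedDataset, SpatialBasis
from .initialization import InitialMaps, spatial_ica_init

__all__ = [
    "DualRegressionResult",
    "group_spatial_ica",
    "dual_regression",
    "partial_netmat",
]


@dataclass
class DualRegressionResult:
    """Subject-level output of the two-stage regression for one run."""

    stage1_timecourses: np.ndarray  # (K, T)
    stage2_maps: np.ndarray  # (V, K)
    amplitudes: np.ndarray  # (K,) std of the stage-1 timecourses


def group_spatial_ica(basis: SpatialBasis, n_modes: int, seed: int = 0) -> InitialMaps:
    """Group IC maps from the PCA basis (shared estimator with the initialiser)."""
    return spatial_ica_init(basis, n_modes, seed=seed)


def dual_regression(group_maps: np.ndarray, ds: MaskedDataset | np.ndarray) -> DualRegressionResult:
    """Two-stage least squares from group maps to one subject-run.

    Raises a ``ValueError`` naming the collinear modes if the group-map
    design is rank deficient.
    """
    data = ds.data if isinstance(ds, MaskedDataset) else np.asarray(ds, dtype=float)
    v, k = group_maps.shape
    if data.shape[0] != v:
        raise ValueError("data and group maps must share the voxel grid")

    gram = group_maps.T @ group_maps
    rank = np.linalg.matrix_rank(gram)
    if rank < k:
        sd = group_maps.std(axis=0)
        bad = [int(i) for i in np.flatnonzero(sd < 1e-12)]
        if not bad:
            # identify modes involved in exact collinearity via the null space
            _, _, vt = np.linalg.svd(gram)
            bad = [int(i) for i in np.flatnonzero(np.abs(vt[-1]) > 1e-6)]
        raise ValueError(f"group maps are rank deficient; collinear modes: {bad}")

    # stage 1: timecourses
    tcs, *_ = np.linalg.lstsq(group_maps, data, rcond=None)  # (K, T)
    amplitudes = tcs.std(axis=1)
    # stage 2: subject maps from variance-normalised timecourses
    norm_tcs = tcs / np.where(amplitudes > 0, amplitudes, 1.0)[:, None]
    maps_t, *_ = np.linalg.lstsq(norm_tcs.T, data.T, rcond=None)  # (K, V)
    return DualRegressionResult(
        stage1_timecourses=tcs, stage2_maps=maps_t.T, amplitudes=amplitudes
    )


def partial_netmat(timecourses: np.ndarray, rho: float = 0.01) -> np.ndarray:
    """Tikhonov-regularised partial correlations between mode timecourses.

    The covariance is regularised as ``cov + rho * mean(diag(cov)) * I``
    (scale-invariant ridge), inverted, and converted to partial
    correlations with unit diagonal. Constant rows raise a ``ValueError``.
    """
    tcs = np.asarray(timecourses, dtype=float)
    if tcs.shape[1] < 2:
        raise ValueError("need more than one timepoint")
    sd = tcs.std(axis=1)
    if np.any(sd < 1e-12):
        raise ValueError(f"constant timecourse rows: {list(np.flatnonzero(sd < 1e-12))}")
    cov = np.cov(tcs)
    cov = np.atleast_2d(cov)
    prec = np.linalg.inv(cov + rho * np.mean(np.diag(cov)) * np.eye(cov.shape[0]))
    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc
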