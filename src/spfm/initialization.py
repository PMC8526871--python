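"""Spatial ICA on the group PCA basis, used to initialise the group model.

The hierarchical inference only needs a starting point in a realistic
ballpark: a deterministic fixed-point ICA (FastICA) of the spatial basis,
with fixed sign and ordering conventions, provides it. The same estimator
doubles as the group-level spatial ICA of the baseline pipeline so that
both models start from an identical PCA stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats
from sklearn.decomposition import FastICA

from .data_io import SpatialBasis

__all__ = ["InitialMaps", "spatial_ica_init"]


@dataclass
class InitialMaps:
    """Initial group mode maps (voxels x modes) and their mixing matrix."""

    maps: np.ndarray
    mixing: np.ndarray  # (n_components, n_modes)
    seed: int

    @property
    def n_modes(self) -> int:
        return self.maps.shape[1]

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("maps", data=self.maps)
            f.create_dataset("mixing", data=self.mixing)
            f.attrs["seed"] = self.seed

    @classmethod
    def load(cls, path) -> "InitialMaps":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(maps=f["maps"][()], mixing=f["mixing"][()], seed=int(f.attrs["seed"]))


def spatial_ica_init(
    basis: SpatialBasis,
    n_modes: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> InitialMaps:
    """Decompose a spatial basis into maximally non-Gaussian spatial maps.

    The singular-value-weighted basis is fed to fixed-point ICA; recovered
    maps are variance-normalised per column, signed so each map's skewness
    is nonnegative, and ordered by descending explained variance (measured
    through the mixing-column norms).

    Raises a ``RuntimeError`` carrying the iteration count if the
    fixed-point iteration does not converge.
    """
    if n_modes > basis.n_components:
        raise ValueError("n_modes cannot exceed the number of basis components")
    # weight by singular values so ICA sees the PCA-reduced data, not an
    # isotropic subspace
    x = basis.basis * basis.singular_values[None, :]
    ica = FastICA(
        n_components=n_modes,
        random_state=np.random.RandomState(seed),
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
    )
    import warnings

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sources = ica.fit_transform(x)  # (V, n_modes), unit variance
    for w in caught:
        if "did not converge" in str(w.message):
            raise RuntimeError(
                f"spatial ICA did not converge after {ica.n_iter_} iterations"
            )

    mixing = ica.mixing_  # (n_components_in, n_modes) scaled by singular values
    # sign convention: nonnegative skewness per map
    signs = np.where(sp_stats.skew(sources, axis=0) < 0, -1.0, 1.0)
    sources = sources * signs
    mixing = mixing * signs
    # order: descending explained variance (mixing column energy)
    order = np.argsort(-np.linalg.norm(mixing, axis=0))
    sources = sources[:, order]
    mixing = mixing[:, order]
    # unit variance per column (FastICA already gives it; enforce exactly)
    sd = sources.std(axis=0)
    sources = sources / np.where(sd > 0, sd, 1.0)
    return InitialMaps(maps=sources, mixing=mixing, seed=seed)
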