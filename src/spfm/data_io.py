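"""Masked fMRI data containers, preprocessing, and incremental group PCA.

A :class:`MaskedDataset` holds one subject-run's voxels-by-timepoints
matrix together with the mask geometry that maps rows back onto the 3D
grid. Voxel ordering is fixed as C-order over the (x, y, z) coordinates of
the mask, so decompositions are reproducible across runs and tools.

:func:`migp` implements incremental group PCA: subjects are visited one at
a time and a running, time-reduced matrix of fixed height is maintained,
so the spatial basis of an arbitrarily large population can be computed in
memory proportional to one subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "MaskedDataset",
    "SpatialBasis",
    "load_masked",
    "save_masked",
    "preprocess",
    "migp",
]


@dataclass
class MaskedDataset:
    """One subject-run's masked data matrix (voxels x timepoints)."""

    data: np.ndarray
    tr: float
    subject_id: str = ""
    run_id: str = ""
    mask_coords: Optional[np.ndarray] = None  # (V, 3) int voxel coordinates
    grid_shape: Optional[tuple] = None
    flagged_voxels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (voxels x timepoints)")
        if self.mask_coords is not None and len(self.mask_coords) != self.data.shape[0]:
            raise ValueError("mask_coords must have one row per data row")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class SpatialBasis:
    """Orthonormal spatial basis (voxels x components) with singular values."""

    basis: np.ndarray
    singular_values: np.ndarray

    def __post_init__(self) -> None:
        g = self.basis.T @ self.basis
        if not np.allclose(g, np.eye(self.basis.shape[1]), atol=1e-8):
            raise ValueError("basis columns must be orthonormal")
        if np.any(self.singular_values < 0):
            raise ValueError("singular values must be nonnegative")

    @property
    def n_components(self) -> int:
        return self.basis.shape[1]

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("basis", data=self.basis)
            f.create_dataset("singular_values", data=self.singular_values)

    @classmethod
    def load(cls, path) -> "SpatialBasis":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(basis=f["basis"][()], singular_values=f["singular_values"][()])


def _mask_index(mask: np.ndarray):
    """C-ordered (x, y, z) coordinates of true mask voxels."""
    coords = np.argwhere(mask)  # argwhere is C-ordered by construction
    return coords


def load_masked(nifti_path, mask_path, subject_id: str = "", run_id: str = "") -> MaskedDataset:
    """Read a 4D NIfTI image and a 3D binary mask into a masked matrix.

    Rows are ordered C-style over the (x, y, z) mask coordinates; the TR is
    taken from the image header.
    """
    import nibabel as nib

    img = nib.load(str(nifti_path))
    mask_img = nib.load(str(mask_path))
    if img.shape[:3] != mask_img.shape[:3]:
        raise ValueError(f"image grid {img.shape[:3]} != mask grid {mask_img.shape[:3]}")
    mask = np.asarray(mask_img.dataobj) > 0
    if not mask.any():
        raise ValueError("mask is empty")
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim == 3:
        vol = vol[..., None]
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    coords = _mask_index(mask)
    data = vol[coords[:, 0], coords[:, 1], coords[:, 2], :]
    return MaskedDataset(
        data=data,
        tr=tr,
        subject_id=subject_id,
        run_id=run_id,
        mask_coords=coords,
        grid_shape=tuple(mask.shape),
    )


def save_masked(ds: MaskedDataset, nifti_path, mask_path=None) -> None:
    """Write a masked dataset back onto its 3D grid as a 4D NIfTI image."""
    import nibabel as nib

    if ds.mask_coords is None or ds.grid_shape is None:
        raise ValueError("dataset has no mask geometry")
    vol = np.zeros(tuple(ds.grid_shape) + (ds.n_timepoints,))
    c = ds.mask_coords
    vol[c[:, 0], c[:, 1], c[:, 2], :] = ds.data
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, ds.tr))
    nib.save(img, str(nifti_path))
    if mask_path is not None:
        mask = np.zeros(ds.grid_shape, dtype=np.uint8)
        mask[c[:, 0], c[:, 1], c[:, 2]] = 1
        nib.save(nib.Nifti1Image(mask, affine=np.eye(4)), str(mask_path))


def preprocess(
    ds: MaskedDataset,
    smooth_fwhm: Optional[float] = None,
    variance_floor: float = 1e-8,
) -> MaskedDataset:
    """Demean and variance-normalise every voxel timecourse.

    Rows whose variance falls below ``variance_floor`` are zeroed and
    recorded in ``flagged_voxels``. Optional Gaussian smoothing of
    ``smooth_fwhm`` (in voxel units) is applied on the 3D grid first, when
    the mask geometry is available. Idempotent.
    """
    data = np.array(ds.data, dtype=float)
    if smooth_fwhm:
        if ds.mask_coords is None or ds.grid_shape is None:
            raise ValueError("smoothing requires mask geometry")
        from scipy.ndimage import gaussian_filter

        sigma = smooth_fwhm / 2.3548
        c = ds.mask_coords
        vol = np.zeros(tuple(ds.grid_shape) + (ds.n_timepoints,))
        vol[c[:, 0], c[:, 1], c[:, 2], :] = data
        vol = gaussian_filter(vol, sigma=(sigma, sigma, sigma, 0))
        data = vol[c[:, 0], c[:, 1], c[:, 2], :]
    data = data - data.mean(axis=1, keepdims=True)
    var = data.var(axis=1)
    good = var > variance_floor
    if not good.any():
        raise ValueError("degenerate input: every voxel timecourse is constant")
    data[good] /= np.sqrt(var[good])[:, None]
    data[~good] = 0.0
    flagged = np.flatnonzero(~good)
    return replace(ds, data=data, flagged_voxels=flagged)


def migp(
    datasets: Iterable[MaskedDataset | np.ndarray],
    n_components: int,
    seed: int = 0,
) -> SpatialBasis:
    """Incremental group PCA over a stream of subject-run datasets.

    Maintains a running time-reduced matrix ``W`` of at most
    ``n_components`` rows; each new dataset is concatenated in the time
    dimension and the stack is reduced back to its top left singular
    directions. Never holds more than one subject plus ``W`` in memory.
    The ``seed`` argument is accepted for interface symmetry (the
    deterministic dense SVD is used; no randomised projection).
    """
    from scipy.linalg import svd

    w: Optional[np.ndarray] = None
    sv: Optional[np.ndarray] = None
    n_voxels = None
    for ds in datasets:
        x = ds.data if isinstance(ds, MaskedDataset) else np.asarray(ds, dtype=float)
        if n_voxels is None:
            n_voxels = x.shape[0]
            if n_components > n_voxels:
                raise ValueError("n_components cannot exceed the number of voxels")
        elif x.shape[0] != n_voxels:
            raise ValueError("all datasets must share the same mask")
        stack = x.T if w is None else np.vstack([w, x.T])
        _, s, vt = svd(stack, full_matrices=False, lapack_driver="gesdd")
        keep = min(n_components, len(s))
        w = s[:keep, None] * vt[:keep]
        sv = s[:keep]
    if w is None:
        raise ValueError("no datasets provided")
    basis = w.T / sv[None, :]
    return SpatialBasis(basis=basis, singular_values=np.asarray(sv))
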