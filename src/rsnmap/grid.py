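"""Volume I/O and vectorization on a fixed analysis grid.

Every stage of the pipeline operates on volumes that live on one
:class:`AnalysisGrid`: a voxel lattice with a binary brain mask and a fixed
raster convention (first axis fastest-varying, i.e. Fortran order).  Grid
mismatches are hard errors everywhere -- nothing is ever resampled silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger("rsnmap")


class GridMismatchError(ValueError):
    """A volume does not live on the expected analysis grid."""


@dataclass(frozen=True)
class AnalysisGrid:
    """Shared voxel lattice for one analysis.

    Parameters
    ----------
    shape
        Three positive integers, the volume dimensions in voxels.
    mask
        Boolean brain mask of shape ``shape``.  All statistics are computed
        over mask voxels only.
    voxel_size
        Voxel edge lengths in mm (isotropic phantoms use ``(1, 1, 1)``).
    affine
        Voxel-to-world affine used when writing NIfTI.
    """

    shape: tuple[int, int, int]
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != tuple(self.shape):
            raise GridMismatchError(
                f"mask shape {mask.shape} != grid shape {tuple(self.shape)}"
            )
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "mask", mask)
        if self.affine is None:
            aff = np.diag(list(self.voxel_size) + [1.0])
            object.__setattr__(self, "affine", aff)

    @property
    def n_voxels(self) -> int:
        """Number of voxels inside the brain mask."""
        return int(self.mask.sum())

    # Raster convention: first axis fastest-varying == Fortran ravel order.
    @property
    def _mask_flat(self) -> np.ndarray:
        return self.mask.ravel(order="F")

    def validate(self, volume: np.ndarray, name: str = "volume") -> np.ndarray:
        """Check that ``volume`` lives on this grid (3D or 4D)."""
        volume = np.asarray(volume)
        if volume.shape[:3] != self.shape:
            raise GridMismatchError(
                f"{name} has shape {volume.shape[:3]}, grid is {self.shape}"
            )
        return volume

    def vectorize(self, volume: np.ndarray) -> np.ndarray:
        """Extract mask voxels of a 3D (or 4D) volume in raster order.

        Returns a 1D vector for 3D input, or an ``n_voxels x T`` matrix for
        4D input.
        """
        volume = self.validate(volume)
        if volume.ndim == 3:
            return volume.ravel(order="F")[self._mask_flat]
        if volume.ndim == 4:
            flat = volume.reshape(-1, volume.shape[3], order="F")
            return flat[self._mask_flat, :]
        raise ValueError(f"expected 3D or 4D volume, got ndim={volume.ndim}")

    def devectorize(self, vector: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Inverse of :meth:`vectorize`: mask voxels filled, 0 elsewhere."""
        vector = np.asarray(vector)
        if vector.shape[0] != self.n_voxels:
            raise ValueError(
                f"vector length {vector.shape[0]} != mask size {self.n_voxels}"
            )
        if vector.ndim == 1:
            flat = np.full(int(np.prod(self.shape)), fill, dtype=float)
            flat[self._mask_flat] = vector
            return flat.reshape(self.shape, order="F")
        flat = np.full((int(np.prod(self.shape)), vector.shape[1]), fill)
        flat[self._mask_flat, :] = vector
        return flat.reshape(self.shape + (vector.shape[1],), order="F")


def write_volume(path, data: np.ndarray, grid: AnalysisGrid) -> None:
    """Write a volume on ``grid`` as NIfTI-1.

    Integer/bool arrays are stored as uint8 (masks round-trip bit-exactly);
    floats as float64.
    """
    data = grid.validate(data)
    if data.dtype == bool or np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float64)
    img = nib.Nifti1Image(data, grid.affine)
    nib.save(img, str(path))


def read_volume(path, grid: AnalysisGrid | None = None) -> np.ndarray:
    """Read a NIfTI volume, optionally validating it against ``grid``."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if grid is not None:
        grid.validate(data, name=str(path))
        if not np.allclose(img.affine, grid.affine, atol=1e-4):
            raise GridMismatchError(
                f"{path}: affine mismatch with analysis grid "
                f"({img.affine.tolist()} vs {grid.affine.tolist()})"
            )
    return data
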