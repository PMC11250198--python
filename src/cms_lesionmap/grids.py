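"""Common spatial containers: volumes, binary masks and weight maps.

Every spatial object in the package lives on a single common grid — a 3-D
lattice plus a 4x4 voxel-to-world affine in RAS millimetres (x: left->right,
y: posterior->anterior, z: inferior->superior; voxel indices 0-based).  No
silent resampling is ever performed: grids either match or an error is
raised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: elementwise affine agreement tolerance, in mm
AFFINE_TOL_MM = 1e-4


@dataclass
class VolumeGrid:
    """A 3-D scalar lattice with a voxel-index -> world-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"not a 3-D volume: data has {self.data.ndim} dimensions")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel, |det| of the 3x3 affine block."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (n, 3) to world mm coordinates (n, 3)."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class BinaryMask(VolumeGrid):
    """A lesion or ROI indicator volume with values restricted to {0, 1}."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.dtype != bool and not ((self.data == 0) | (self.data == 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        self.data = self.data.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3

    def voxel_indices(self) -> np.ndarray:
        """(n, 3) array of the voxel indices of all foreground voxels."""
        return np.argwhere(self.data > 0)


@dataclass
class WeightMap(VolumeGrid):
    """Continuous [0, 1] lesion-symptom weight volume with a scalar eigenvalue.

    The eigenvalue is the scale factor attached to the normalized weight map;
    predicted scores are ``lesion . (eigenvalue * weights)``.
    """

    eigenvalue: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(float)
        if self.data.min() < -1e-12 or self.data.max() > 1 + 1e-12:
            raise ValueError("weight map values must lie in [0, 1]")
        if not self.eigenvalue > 0:
            raise ValueError("eigenvalue must be positive")

    @property
    def weight_sum(self) -> float:
        return float(self.data.sum())


def grids_match(a: VolumeGrid, b: VolumeGrid, tol: float = AFFINE_TOL_MM) -> bool:
    """True when shapes match exactly and affines agree within ``tol`` mm."""
    return a.shape == b.shape and bool(np.allclose(a.affine, b.affine, atol=tol, rtol=0))


def check_same_grid(a: VolumeGrid, b: VolumeGrid, what: str = "volumes") -> None:
    if not grids_match(a, b):
        raise ValueError(f"{what} must live on the template grid (shape/affine mismatch)")


def binarize_mask(grid: VolumeGrid, threshold: float = 0.5,
                  reference: VolumeGrid | None = None) -> BinaryMask:
    """Threshold a volume to {0, 1}.

    Voxels with value >= ``threshold`` map to 1, everything below (including
    negative interpolation ringing) to 0.  When ``reference`` is given, the
    grid must match it exactly in shape and within tolerance in affine.
    """
    if reference is not None:
        check_same_grid(grid, reference, "masks")
    data = (np.asarray(grid.data, dtype=float) >= threshold).astype(np.uint8)
    if data.sum() == 0:
        logger.warning("binarize_mask produced an all-zero mask")
    return BinaryMask(data=data, affine=grid.affine.copy())
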