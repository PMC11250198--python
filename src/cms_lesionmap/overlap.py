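"""Descriptive lesion maps: overlap counts, proportional subtraction, peaks.

These are the standard exploratory maps of lesion studies: the voxelwise
count of masks covering each voxel, the difference of per-group lesion
proportions (symptomatic minus asymptomatic), peak localization in world
coordinates, and a midline-crossing descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grids import BinaryMask, VolumeGrid, check_same_grid


@dataclass
class CountMap(VolumeGrid):
    """Voxelwise number of lesion masks overlapping; values in [0, n_masks]."""

    n_masks: int = 0


@dataclass
class SubtractionMap(VolumeGrid):
    """Voxelwise p+ - p- difference of group lesion proportions, in [-1, 1]."""


@dataclass(frozen=True)
class PeakResult:
    world_mm: tuple[float, float, float]
    value: float
    tie_count: int
    voxel_index: tuple[int, int, int]


def _check_stack(masks: Sequence[BinaryMask], what: str) -> None:
    if len(masks) == 0:
        raise ValueError(f"{what}: empty mask list")
    for m in masks[1:]:
        check_same_grid(m, masks[0], what)


def overlap_count(masks: Sequence[BinaryMask]) -> CountMap:
    """Voxelwise sum of binary masks."""
    _check_stack(masks, "overlap_count")
    total = np.zeros(masks[0].shape, dtype=np.int32)
    for m in masks:
        total += m.data
    return CountMap(data=total, affine=masks[0].affine.copy(), n_masks=len(masks))


def proportional_subtraction(pos: Sequence[BinaryMask],
                             neg: Sequence[BinaryMask]) -> SubtractionMap:
    """Plain difference of group lesion proportions, count(pos)/|pos| - count(neg)/|neg|."""
    _check_stack(pos, "positive group")
    _check_stack(neg, "negative group")
    check_same_grid(pos[0], neg[0], "groups")
    p_pos = overlap_count(pos).data / len(pos)
    p_neg = overlap_count(neg).data / len(neg)
    return SubtractionMap(data=p_pos - p_neg, affine=pos[0].affine.copy())


def peak_voxel(volume: VolumeGrid) -> PeakResult:
    """World coordinate of the maximum voxel.

    Ties are counted; the lexicographically smallest voxel index is reported
    as the canonical peak rather than silently dropping the others.
    """
    data = np.asarray(volume.data, dtype=float)
    if np.ptp(data) == 0:
        raise ValueError("constant map has no peak")
    peak = data.max()
    tied = np.argwhere(data == peak)
    canonical = tied[np.lexsort(tied.T[::-1])][0]
    world = volume.world_coords(canonical)[0]
    return PeakResult(tuple(float(c) for c in world), float(peak),
                      int(len(tied)), tuple(int(i) for i in canonical))


def crosses_midline(mask: BinaryMask, epsilon: float | None = None) -> bool:
    """True when the mask has voxels strictly on both sides of world x = 0.

    A band of half a voxel width around the midline is excluded so that
    exactly-midline voxels do not count as bilateral.
    """
    ijk = mask.voxel_indices()
    if len(ijk) == 0:
        raise ValueError("empty mask")
    if epsilon is None:
        epsilon = 0.5 * float(np.abs(mask.affine[0, :3]).max())
    x = mask.world_coords(ijk)[:, 0]
    return bool((x < -epsilon).any() and (x > epsilon).any())
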