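"""Cerebellar-outflow-pathway lesion load by oblique coronal slicing.

The outflow ROI is cut into 1 mm oblique coronal slices tilted 17 degrees
from true coronal about the left-right axis, so the planes lie roughly
perpendicular to the superior cerebellar peduncles.  For each slice the
percentage of ROI voxels intersected by the lesion mask is computed; the
maximum percentage over slices is the subject's "lesion load": 100% means
some slice of the pathway is fully transected, 0% means the pathway is
entirely spared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import BinaryMask, check_same_grid


@dataclass(frozen=True)
class SlicingSpec:
    """Geometry of the oblique slicing.

    ``angle_deg`` tilts the slice planes from true coronal about the x
    (left-right) axis; a point's slice coordinate is
    ``u = y*cos(theta) - tilt_sign*z*sin(theta)`` and slices are the
    half-open intervals ``[k*thickness, (k+1)*thickness)``.  ``tilt_sign``
    selects which way the normal tips (the default tips anterior-posterior
    toward superior); results are invariant to it for symmetric ROIs.
    """

    angle_deg: float = 17.0
    thickness_mm: float = 1.0
    min_roi_voxels: int = 1
    tilt_sign: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.angle_deg < 90:
            raise ValueError("angle_deg must be in [0, 90)")
        if not self.thickness_mm > 0:
            raise ValueError("thickness_mm must be positive")
        if self.min_roi_voxels < 0:
            raise ValueError("min_roi_voxels must be non-negative")
        if self.tilt_sign not in (-1, 1):
            raise ValueError("tilt_sign must be +1 or -1")

    def slice_coordinate(self, points: np.ndarray) -> np.ndarray:
        """Oblique coordinate u for world points of shape (n, 3)."""
        theta = math.radians(self.angle_deg)
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts[:, 1] * math.cos(theta) - self.tilt_sign * pts[:, 2] * math.sin(theta)


def slice_index(world_point, spec: SlicingSpec = SlicingSpec()) -> int:
    """Index of the oblique slice containing a world point (voxel center)."""
    pt = np.asarray(world_point, dtype=float)
    if not np.isfinite(pt).all():
        raise ValueError("coordinates must be finite")
    u = spec.slice_coordinate(pt)[0]
    return int(math.floor(u / spec.thickness_mm))


@dataclass
class SliceProfile:
    """Per-slice ROI voxel counts and lesion overlap, in slice-index order.

    ``percent`` is 100*overlap/roi per eligible slice and NaN where the slice
    has fewer than ``min_roi_voxels`` ROI voxels.
    """

    slice_indices: np.ndarray
    roi_counts: np.ndarray
    overlap_counts: np.ndarray
    min_roi_voxels: int = 1

    @property
    def eligible(self) -> np.ndarray:
        return self.roi_counts >= max(self.min_roi_voxels, 1)

    @property
    def percents(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.overlap_counts / self.roi_counts
        return np.where(self.eligible, pct, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "slice_index": self.slice_indices,
            "roi_count": self.roi_counts,
            "overlap_count": self.overlap_counts,
            "percent": self.percents,
        })


@dataclass(frozen=True)
class LesionLoadResult:
    subject_id: str
    load_percent: float
    argmax_slice: int


class OutflowLoadScorer:
    """Scores lesion masks against a fixed outflow ROI (fit once, score many).

    fit() assigns every ROI voxel, by its voxel-center world coordinate, to
    exactly one oblique slice; transform() then only needs to look the lesion
    values up at the ROI voxels, which makes scoring whole cohorts cheap.
    """

    def __init__(self, spec: SlicingSpec = SlicingSpec()):
        self.spec = spec

    def get_params(self, deep: bool = True) -> dict:
        return {"spec": self.spec}

    def set_params(self, **params) -> "OutflowLoadScorer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, roi: BinaryMask) -> "OutflowLoadScorer":
        if roi.n_voxels == 0:
            raise ValueError("ROI is empty")
        self.roi_ = roi
        ijk = roi.voxel_indices()
        u = self.spec.slice_coordinate(roi.world_coords(ijk))
        idx = np.floor(u / self.spec.thickness_mm).astype(int)
        order = np.argsort(idx, kind="stable")
        self._roi_ijk = ijk[order]
        idx = idx[order]
        self.slice_indices_, self._inverse, self.roi_counts_ = np.unique(
            idx, return_inverse=True, return_counts=True)
        self._flat = np.ravel_multi_index(self._roi_ijk.T, roi.shape)
        return self

    def profile(self, lesion: BinaryMask) -> SliceProfile:
        check_same_grid(lesion, self.roi_, "ROI and lesion")
        hit = lesion.data.reshape(-1)[self._flat]
        overlap = np.bincount(self._inverse, weights=hit,
                              minlength=len(self.slice_indices_)).astype(int)
        return SliceProfile(self.slice_indices_.copy(), self.roi_counts_.copy(),
                            overlap, self.spec.min_roi_voxels)

    def score(self, lesion: BinaryMask, subject_id: str = "") -> LesionLoadResult:
        return outflow_lesion_load(self.profile(lesion), subject_id)

    def transform(self, cohort) -> pd.DataFrame:
        """Loads for a whole cohort; columns subject_id, load_percent, argmax_slice."""
        rows = [self.score(cohort.masks[s], s) for s in cohort.subject_ids]
        return pd.DataFrame({
            "subject_id": [r.subject_id for r in rows],
            "load_percent": [r.load_percent for r in rows],
            "argmax_slice": [r.argmax_slice for r in rows],
        })


def slice_profile(roi: BinaryMask, lesion: BinaryMask,
                  spec: SlicingSpec = SlicingSpec()) -> SliceProfile:
    """Per-oblique-slice ROI and lesion-overlap counts."""
    return OutflowLoadScorer(spec).fit(roi).profile(lesion)


def outflow_lesion_load(profile: SliceProfile, subject_id: str = "") -> LesionLoadResult:
    """Max-slice lesion load; ties broken toward the smallest slice index."""
    pct = profile.percents
    ok = ~np.isnan(pct)
    if not ok.any():
        raise ValueError("no eligible slices")
    best = np.nanmax(pct)
    # slice_indices are sorted ascending, so the first attaining index wins
    arg = int(profile.slice_indices[ok][np.argmax(pct[ok] >= best - 1e-12)])
    return LesionLoadResult(subject_id, float(best), arg)


def cohort_outflow_loads(roi: BinaryMask, cohort,
                         spec: SlicingSpec = SlicingSpec()) -> pd.DataFrame:
    return OutflowLoadScorer(spec).fit(roi).transform(cohort)
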