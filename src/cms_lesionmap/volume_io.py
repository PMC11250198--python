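"""NIfTI volume and cohort-manifest I/O.

All volumes are NIfTI-1 (.nii / .nii.gz) read through nibabel; manifests are
UTF-8 CSV with a header row.  Masks referenced by a manifest are loaded,
binarized and checked against a common reference grid — the analyses assume
every mask is already registered to one template grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import BinaryMask, VolumeGrid, WeightMap, binarize_mask, check_same_grid

REQUIRED_MANIFEST_COLUMNS = ("subject_id", "mask_path", "cms_status")
OPTIONAL_MANIFEST_COLUMNS = ("age_years", "sex", "site", "tumour_type")


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a 3-D NIfTI volume.

    Singleton trailing dimensions are squeezed; genuinely 4-D files (time
    series) are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"not a 3-D volume: {path} has shape {data.shape}")
    return VolumeGrid(data=data, affine=np.asarray(img.affine))


def write_volume(grid: VolumeGrid, path: str | Path) -> Path:
    """Write a grid to NIfTI-1. Integer data is stored losslessly."""
    path = Path(path)
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, grid.affine)
    nib.save(img, str(path))
    return path


def read_weight_map(path: str | Path, eigenvalue: float = 1.0) -> WeightMap:
    """Read a continuous [0, 1] weight volume and attach its eigenvalue."""
    grid = read_volume(path)
    return WeightMap(data=grid.data, affine=grid.affine, eigenvalue=eigenvalue)


@dataclass
class CohortTable:
    """Per-subject manifest rows plus the loaded, binarized lesion masks.

    ``table`` columns: subject_id, mask_path, cms_status (0/1), age_years,
    sex, site, tumour_type, lesion_volume_mm3; ``masks`` maps subject_id to
    its BinaryMask on the common grid.
    """

    table: pd.DataFrame
    masks: dict[str, BinaryMask] = field(repr=False)

    def __post_init__(self) -> None:
        ids = self.table["subject_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate subject_id: {dupes}")
        cms = self.table["cms_status"]
        if cms.isna().any() or not cms.isin([0, 1]).all():
            raise ValueError("cms_status must be 0 or 1 for every subject")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    @property
    def labels(self) -> np.ndarray:
        return self.table["cms_status"].to_numpy(dtype=int)

    def mask_list(self) -> list[BinaryMask]:
        return [self.masks[s] for s in self.subject_ids]

    def split_by_label(self) -> tuple[list[BinaryMask], list[BinaryMask]]:
        """(CMS+ masks, CMS- masks) in manifest order."""
        pos = [self.masks[s] for s, y in zip(self.subject_ids, self.labels) if y == 1]
        neg = [self.masks[s] for s, y in zip(self.subject_ids, self.labels) if y == 0]
        return pos, neg


def cohort_from_masks(masks: dict[str, BinaryMask], cms_status: dict[str, int],
                      extra: pd.DataFrame | None = None) -> CohortTable:
    """Assemble a CohortTable from in-memory masks and labels."""
    ids = list(masks)
    rows = pd.DataFrame({
        "subject_id": ids,
        "mask_path": ["<memory>"] * len(ids),
        "cms_status": [int(cms_status[s]) for s in ids],
        "lesion_volume_mm3": [masks[s].volume_mm3 for s in ids],
    })
    if extra is not None:
        rows = rows.merge(extra, on="subject_id", how="left")
    ref = masks[ids[0]]
    for s in ids[1:]:
        check_same_grid(masks[s], ref, "masks")
    return CohortTable(table=rows, masks=masks)


def read_manifest(path: str | Path, mask_root: str | Path | None = None,
                  reference: VolumeGrid | None = None) -> CohortTable:
    """Read a cohort manifest CSV and load every subject's lesion mask.

    Parameters
    ----------
    path : CSV with at least subject_id, mask_path, cms_status columns.
    mask_root : directory that relative mask paths are resolved against
        (defaults to the manifest's own directory).
    reference : optional grid every mask must match; defaults to the first
        mask's grid.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required column(s): {missing}")
    for col in OPTIONAL_MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col == "age_years" else "unknown"
    if df["subject_id"].astype(str).duplicated().any():
        raise ValueError("duplicate subject_id in manifest")
    if not df["cms_status"].isin([0, 1]).all():
        raise ValueError("cms_status outside {0, 1}")
    if (pd.to_numeric(df["age_years"], errors="coerce").dropna() < 0).any():
        raise ValueError("age_years must be non-negative")

    root = Path(mask_root) if mask_root is not None else path.parent
    masks: dict[str, BinaryMask] = {}
    volumes = []
    for _, row in df.iterrows():
        mp = Path(row["mask_path"])
        if not mp.is_absolute():
            mp = root / mp
        grid = read_volume(mp)
        if reference is None:
            reference = grid
        masks[str(row["subject_id"])] = binarize_mask(grid, reference=reference)
        volumes.append(masks[str(row["subject_id"])].volume_mm3)
    df = df.assign(subject_id=df["subject_id"].astype(str),
                   lesion_volume_mm3=volumes)
    return CohortTable(table=df, masks=masks)
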