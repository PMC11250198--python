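"""End-to-end study orchestration: loads -> statistics -> maps -> report.

run_study ties the stages together exactly as the analyses are meant to be
read: outflow-pathway lesion loads and weight-map loads per subject, the
pre-registered one-tailed CMS+ > CMS- comparisons of both loads, two-sided
comparisons of age and lesion volume, the site chi-square, the
rate-by-load curve, descriptive overlap/subtraction maps, and optionally
the sparse lesion-symptom map.  Identical config + inputs + seed produce a
byte-identical JSON report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from importlib.metadata import version as _dist_version

from .grids import BinaryMask
from .map_load import WeightMapLoadScorer
from .overlap import crosses_midline, overlap_count, peak_voxel, \
    proportional_subtraction
from .sccan import build_lesion_matrix, fit_sparse_map, DEFAULT_SPARSENESS_GRID
from .slicing import OutflowLoadScorer, SlicingSpec
from .stats import (DEFAULT_BIN_EDGES, GroupSummary, chi_square_2x2, cohens_d,
                    rate_by_load_bins, welch_t)
from .volume_io import CohortTable, read_manifest, read_volume, \
    read_weight_map, write_volume
from .grids import binarize_mask

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one full study run."""

    manifest: str
    roi: str
    out_dir: str
    weight_map: str | None = None
    eigenvalue: float = 1.0
    slicing: SlicingSpec = field(default_factory=SlicingSpec)
    normalization: str = "weight_sum"
    bin_edges: tuple = DEFAULT_BIN_EDGES
    isolate_zero_bin: bool = False
    run_lsm: bool = False
    sparseness_grid: tuple = DEFAULT_SPARSENESS_GRID
    min_subjects: int | None = None
    seed: int = 0

    def config_hash(self) -> str:
        """Hash of the analysis-relevant parameters (output location excluded)."""
        payload = asdict(self)
        payload.pop("out_dir")
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    loads: pd.DataFrame
    map_loads: pd.DataFrame | None
    stats: dict
    outputs: dict

    def to_json(self) -> str:
        return json.dumps({"stats": self.stats, "outputs": self.outputs},
                          indent=2, sort_keys=True)


def _comparison_dict(values: np.ndarray, labels: np.ndarray,
                     alternative: str) -> dict:
    pos = GroupSummary.from_values(values[labels == 1])
    neg = GroupSummary.from_values(values[labels == 0])
    cmp_ = welch_t(pos, neg, alternative)
    return {
        "mean_pos": pos.mean, "sd_pos": pos.sd, "n_pos": pos.n,
        "mean_neg": neg.mean, "sd_neg": neg.sd, "n_neg": neg.n,
        "t": cmp_.t, "df": cmp_.df, "df_floor": cmp_.df_floor,
        "p": cmp_.p, "alternative": alternative,
        "cohens_d_pooled": cohens_d(pos, neg, "pooled"),
        "cohens_d_from_t": cohens_d(pos, neg, "from_t", t=cmp_.t),
    }


def run_study(config: RunConfig, cohort: CohortTable | None = None,
              roi: BinaryMask | None = None, weight_map=None) -> StudyReport:
    """Execute the full analysis; in-memory objects may replace file inputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        if roi is None:
            roi = binarize_mask(read_volume(config.roi))
        if cohort is None:
            cohort = read_manifest(config.manifest, reference=roi)
        if weight_map is None and config.weight_map is not None:
            weight_map = read_weight_map(config.weight_map, config.eigenvalue)
    except FileNotFoundError as err:
        raise FileNotFoundError(f"[inputs] {err}") from err

    labels = cohort.labels
    if labels.sum() < 2 or (1 - labels).sum() < 2:
        raise ValueError("[group_stats] need >= 2 subjects per CMS group")

    # stage: lesion loads
    loads = OutflowLoadScorer(config.slicing).fit(roi).transform(cohort)
    loads.to_csv(out / "outflow_loads.csv", index=False)

    stats: dict = {
        "outflow_load": _comparison_dict(
            loads["load_percent"].to_numpy(), labels, "greater"),
        "age": _comparison_dict(
            cohort.table["age_years"].to_numpy(float), labels, "two_sided"),
        "lesion_volume": _comparison_dict(
            cohort.table["lesion_volume_mm3"].to_numpy(float), labels,
            "two_sided"),
    }

    map_loads = None
    if weight_map is not None:
        map_loads = WeightMapLoadScorer(config.normalization)\
            .fit(weight_map).transform(cohort)
        map_loads.to_csv(out / "map_loads.csv", index=False)
        stats["map_load"] = _comparison_dict(
            map_loads["map_load"].to_numpy(), labels, "greater")
        stats["map_load"]["normalization"] = config.normalization

    # stage: site comparison (2x2 site x CMS), only with exactly two sites
    sites = cohort.table["site"].astype(str)
    site_names = sorted(sites.unique())
    if len(site_names) == 2:
        tab = [[int(((sites == s) & (labels == y)).sum()) for y in (0, 1)]
               for s in site_names]
        chi2, p = chi_square_2x2(tab, correction=False)
        stats["site_cms_rate"] = {"sites": site_names, "table": tab,
                                  "chi2": chi2, "p": p, "correction": False}

    curve = rate_by_load_bins(loads["load_percent"], labels,
                              config.bin_edges, config.isolate_zero_bin)
    stats["rate_by_load"] = json.loads(curve.to_frame().to_json(orient="records"))

    pos_masks, neg_masks = cohort.split_by_label()
    stats["midline_crossing"] = {
        "rate_pos": float(np.mean([crosses_midline(m) for m in pos_masks])),
        "rate_neg": float(np.mean([crosses_midline(m) for m in neg_masks])),
    }

    # stage: descriptive maps
    outputs: dict = {}
    peaks = {}
    for name, group in (("overlap_all", cohort.mask_list()),
                        ("overlap_pos", pos_masks),
                        ("overlap_neg", neg_masks)):
        cmap = overlap_count(group)
        write_volume(cmap, out / f"{name}.nii.gz")
        pk = peak_voxel(cmap)
        peaks[name] = {"world_mm": pk.world_mm, "value": pk.value,
                       "tie_count": pk.tie_count}
        outputs[name] = f"{name}.nii.gz"
    sub = proportional_subtraction(pos_masks, neg_masks)
    write_volume(sub, out / "subtraction.nii.gz")
    outputs["subtraction"] = "subtraction.nii.gz"
    pk = peak_voxel(sub)
    peaks["subtraction"] = {"world_mm": pk.world_mm, "value": pk.value,
                            "tie_count": pk.tie_count}
    (out / "peaks.json").write_text(json.dumps(peaks, indent=2, sort_keys=True))
    stats["peaks"] = peaks

    # stage: sparse lesion-symptom map (optional)
    if config.run_lsm:
        lm = build_lesion_matrix(cohort, config.min_subjects)
        res = fit_sparse_map(lm, labels, sparseness_grid=config.sparseness_grid,
                             seed=config.seed)
        write_volume(res.weight_map, out / "lsm_weights.nii.gz")
        outputs["lsm_weights"] = "lsm_weights.nii.gz"
        stats["lsm"] = {
            "eigenvalue": res.eigenvalue,
            "optimal_sparseness": res.optimal_sparseness,
            "cv_r": res.cv_r, "in_sample_r": res.in_sample_r,
            "n_voxels": lm.n_voxels, "min_subjects": lm.min_subjects,
        }

    stats["provenance"] = {
        "config_hash": config.config_hash(), "seed": config.seed,
        "package_version": _dist_version("cms-lesionmap"),
        "n_subjects": len(cohort), "n_cms": int(labels.sum()),
        "cms_rate_percent": round(100.0 * labels.mean(), 1),
    }
    report = StudyReport(loads, map_loads, stats, outputs)
    (out / "report.json").write_text(report.to_json())
    return report
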