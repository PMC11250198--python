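"""Lesion-symptom-map lesion load: scoring lesions against a weight map.

The raw score is the eigenvalue-scaled inner product of the continuous
weight map with the binary lesion: ``raw = gamma * sum_v W_v * L_v``.  What
"standardized" means is ambiguous for this statistic, so three normalizations
are offered and the choice is recorded in every score:

- ``none``       standardized = raw
- ``weight_sum`` standardized = raw / sum_v W_v  (bounded, cohort-independent;
                 the default)
- ``cohort_z``   z-score of raw across the cohort (mean 0, sample SD 1)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import BinaryMask, WeightMap, check_same_grid

NORMALIZATIONS = ("none", "weight_sum", "cohort_z")


@dataclass(frozen=True)
class MapLoadScore:
    subject_id: str
    raw: float
    standardized: float
    normalization: str


class WeightMapLoadScorer:
    """Scores lesions against a fixed weight map (fit once, score many)."""

    def __init__(self, normalization: str = "weight_sum"):
        if normalization not in NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
        self.normalization = normalization

    def get_params(self, deep: bool = True) -> dict:
        return {"normalization": self.normalization}

    def set_params(self, **params) -> "WeightMapLoadScorer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, weight_map: WeightMap) -> "WeightMapLoadScorer":
        self.weight_map_ = weight_map
        self.weight_sum_ = weight_map.weight_sum
        if self.normalization == "weight_sum" and self.weight_sum_ == 0:
            raise ValueError("weight map sums to zero; weight_sum normalization undefined")
        return self

    def raw_score(self, lesion: BinaryMask) -> float:
        check_same_grid(lesion, self.weight_map_, "weight map and lesion")
        w = self.weight_map_
        return float(w.eigenvalue * (w.data * lesion.data).sum())

    def score(self, lesion: BinaryMask, subject_id: str = "") -> MapLoadScore:
        raw = self.raw_score(lesion)
        if self.normalization == "weight_sum":
            std = raw / self.weight_sum_
        elif self.normalization == "none":
            std = raw
        else:
            raise ValueError("cohort_z requires transform() over a cohort")
        return MapLoadScore(subject_id, raw, std, self.normalization)

    def transform(self, cohort) -> pd.DataFrame:
        """Scores for a whole cohort; cohort_z is applied across its rows."""
        ids = cohort.subject_ids
        raws = np.array([self.raw_score(cohort.masks[s]) for s in ids])
        if self.normalization == "cohort_z":
            if len(ids) < 2:
                raise ValueError("cohort_z needs at least 2 subjects")
            sd = raws.std(ddof=1)
            if sd == 0:
                raise ValueError("zero variance across cohort under cohort_z")
            std = (raws - raws.mean()) / sd
        elif self.normalization == "weight_sum":
            std = raws / self.weight_sum_
        else:
            std = raws
        return pd.DataFrame({
            "subject_id": ids,
            "raw": raws,
            "map_load": std,
            "normalization": self.normalization,
        })


def map_lesion_load(weight_map: WeightMap, lesion: BinaryMask,
                    normalization: str = "weight_sum",
                    subject_id: str = "") -> MapLoadScore:
    """Score one lesion; see module docstring for the normalization variants."""
    return WeightMapLoadScorer(normalization).fit(weight_map).score(lesion, subject_id)


def cohort_map_loads(weight_map: WeightMap, cohort,
                     normalization: str = "weight_sum") -> pd.DataFrame:
    return WeightMapLoadScorer(normalization).fit(weight_map).transform(cohort)
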