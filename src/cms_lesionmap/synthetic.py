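"""Synthetic lesion cohorts with a planted anatomical effect.

The generator builds a toy template space — an ellipsoidal "cerebellum", a
narrow midline tube tilted 17 degrees from the anterior-posterior axis
standing in for the cerebellar outflow pathway, and a weight map
concentrated on that tube — then samples ellipsoidal resection cavities
with lognormal volumes and a midline placement bias, and assigns CMS
labels from a logistic model on the outflow lesion load:

    P(CMS) = sigmoid(alpha + beta * load / 100)

The intercept alpha is calibrated by bisection so the marginal CMS rate
matches the target rate; the slope beta plants the lesion-location effect.
Defaults emulate the study conditions this package analyses: cohorts of 56
with an 18% CMS rate, cavity volumes with median ~7000 mm^3, and a planted
effect producing a group lesion-load difference of roughly d ~ 0.7.

The logistic label model is a simulation harness choice — convenient,
monotone and easy to calibrate — not a claim about how real CMS risk is
generated.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import BinaryMask, WeightMap
from .slicing import OutflowLoadScorer, SlicingSpec
from .volume_io import CohortTable, cohort_from_masks, write_volume

_TUBE_HALF_WIDTH_MM = 12.0   # left-right half extent of the pathway cross-section
_TUBE_HALF_THICK_MM = 3.0    # thickness of the cross-section along the slab
_TUBE_HALF_LENGTH_MM = 15.0
_TUBE_CENTER = (0.0, -4.0, -6.0)
_WEIGHT_SIGMA_MM = 4.0
_CALIBRATION_SEED = 321987
_CALIBRATION_N = 1500


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of one synthetic cohort.

    volume_lognormal is (mu, sigma) of log cavity volume in mm^3 (the
    default gives median 7000 mm^3); midline_bias is the probability that a
    cavity is centred near the midline; beta_load is the planted logistic
    slope on load/100 and alpha, when None, is calibrated to target_rate.
    """

    n_subjects: int = 56
    target_rate: float = 0.179
    beta_load: float = 4.0
    alpha: float | None = None
    volume_lognormal: tuple[float, float] = (math.log(7000.0), 0.5)
    midline_bias: float = 0.8
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_rate < 1:
            raise ValueError("target_rate must be in (0, 1)")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if min(self.grid_shape) < 32:
            raise ValueError("grid too small to contain geometry (need >= 32^3)")

    def spec_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _affine(grid_shape) -> np.ndarray:
    """1 mm isotropic RAS affine with the world origin mid-grid."""
    aff = np.eye(4)
    aff[:3, 3] = -(np.asarray(grid_shape) // 2).astype(float)
    return aff


def _world_axes(grid_shape, affine):
    idx = [np.arange(n) for n in grid_shape]
    return [idx[i] * affine[i, i] + affine[i, 3] for i in range(3)]


def make_toy_space(grid_shape=(64, 64, 64), seed: int = 0
                   ) -> tuple[BinaryMask, BinaryMask, WeightMap]:
    """Deterministic toy template, outflow-like ROI and weight map.

    The template is an ellipsoid centred at the world origin; the ROI is a
    midline slab-like tube — elliptical cross-section 24 mm wide (left-right)
    by 6 mm thick, 30 mm long — whose axis runs along
    (0, cos 17deg, -sin 17deg), i.e. perpendicular to the default oblique
    slicing planes, so every slice cuts the tube transversally (mimicking the
    deep-nuclei + peduncle pathway, which is wide across the midline and thin
    along its course); the weight map decays as a Gaussian with the
    elliptical distance from the tube axis.  The geometry is deterministic;
    ``seed`` is accepted for interface symmetry.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if min(grid_shape) < 32:
        raise ValueError("grid too small to contain geometry (need >= 32^3)")
    aff = _affine(grid_shape)
    xs, ys, zs = _world_axes(grid_shape, aff)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    semi = (np.array(grid_shape) / 64.0) * np.array([29.0, 25.0, 21.0])
    template = ((X / semi[0]) ** 2 + (Y / semi[1]) ** 2 + (Z / semi[2]) ** 2) <= 1.0

    theta = math.radians(17.0)
    d = np.array([0.0, math.cos(theta), -math.sin(theta)])
    c0 = np.array(_TUBE_CENTER)
    rel = np.stack([X - c0[0], Y - c0[1], Z - c0[2]], axis=-1)
    t = rel @ d
    perp = rel - t[..., None] * d
    # elliptical cross-section: wide along x, thin along the remaining axis
    q = np.linalg.norm(perp - perp[..., 0:1] * np.array([1.0, 0, 0]), axis=-1)
    r_ell = np.sqrt((perp[..., 0] / _TUBE_HALF_WIDTH_MM) ** 2
                    + (q / _TUBE_HALF_THICK_MM) ** 2)
    tube = (r_ell <= 1.0) & (np.abs(t) <= _TUBE_HALF_LENGTH_MM) & template

    taper = np.exp(-np.maximum(np.abs(t) - _TUBE_HALF_LENGTH_MM, 0) ** 2
                   / (2 * _WEIGHT_SIGMA_MM ** 2))
    sigma_ell = _WEIGHT_SIGMA_MM / _TUBE_HALF_THICK_MM  # in cross-section units
    weights = np.exp(-r_ell ** 2 / (2 * sigma_ell ** 2)) * taper * template

    return (BinaryMask(data=template, affine=aff.copy()),
            BinaryMask(data=tube, affine=aff.copy()),
            WeightMap(data=weights, affine=aff.copy(), eigenvalue=1.0))


def sample_lesion(spec: SyntheticCohortSpec, rng: np.random.Generator,
                  template: BinaryMask | None = None) -> BinaryMask:
    """One ellipsoidal resection cavity clipped to the template.

    Volume is lognormal; semi-axes get mild random anisotropy at constant
    volume; the centre sits near the midline with probability
    ``midline_bias``.  Cavities that end up empty after clipping are
    resampled.
    """
    if template is None:
        template = make_toy_space(spec.grid_shape)[0]
    aff = template.affine
    shape = template.shape
    mu, sigma = spec.volume_lognormal
    for _ in range(50):
        volume = rng.lognormal(mu, sigma)
        r0 = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
        f = np.exp(rng.normal(0.0, 0.22, size=3))
        f /= f.prod() ** (1.0 / 3.0)
        semi = np.maximum(r0 * f, 1.0)
        if rng.random() < spec.midline_bias:
            # clip so the cavity always reaches the midline column
            cx = float(np.clip(rng.normal(0.0, 4.0), -0.75 * semi[0], 0.75 * semi[0]))
        else:
            cx = rng.uniform(-17.0, 17.0)
        center = np.array([cx, rng.normal(-3.0, 9.0), rng.normal(-4.0, 7.5)])
        # voxel-index bounding box of the ellipsoid (1 mm grid, diagonal affine)
        lo = np.maximum(np.floor(center - semi - aff[:3, 3]).astype(int), 0)
        hi = np.minimum(np.ceil(center + semi - aff[:3, 3]).astype(int) + 1, shape)
        if (hi <= lo).any():
            continue
        axes = [np.arange(lo[i], hi[i]) * aff[i, i] + aff[i, 3] - center[i]
                for i in range(3)]
        bx, by, bz = np.meshgrid(*axes, indexing="ij")
        ell = ((bx / semi[0]) ** 2 + (by / semi[1]) ** 2
               + (bz / semi[2]) ** 2) <= 1.0
        box = template.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        cavity = ell & (box > 0)
        if cavity.any():
            data = np.zeros(shape, dtype=np.uint8)
            data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = cavity
            return BinaryMask(data=data, affine=aff.copy())
    raise RuntimeError("failed to sample a non-degenerate cavity")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


_alpha_cache: dict = {}
_space_cache: dict = {}


def _toy_space_cached(grid_shape):
    key = tuple(grid_shape)
    if key not in _space_cache:
        template, roi, wmap = make_toy_space(key)
        scorer = OutflowLoadScorer(SlicingSpec()).fit(roi)
        _space_cache[key] = (template, roi, wmap, scorer)
    return _space_cache[key]


def calibrate_alpha(spec: SyntheticCohortSpec) -> float:
    """Logistic intercept hitting the target marginal CMS rate.

    Bisection on alpha against the mean of sigmoid(alpha + beta*load/100)
    over a fixed-seed calibration draw of lesion loads.  Alpha depends only
    on the generator's scientific parameters, not the cohort seed, so
    replicate cohorts share one intercept.
    """
    key = (tuple(spec.grid_shape), spec.beta_load, spec.target_rate,
           spec.volume_lognormal, spec.midline_bias)
    if key in _alpha_cache:
        return _alpha_cache[key]
    template, _, _, scorer = _toy_space_cached(spec.grid_shape)
    rng = np.random.default_rng(_CALIBRATION_SEED)
    loads = np.array([
        scorer.score(sample_lesion(spec, rng, template)).load_percent
        for _ in range(_CALIBRATION_N)]) / 100.0

    def marginal(alpha: float) -> float:
        return float(_sigmoid(alpha + spec.beta_load * loads).mean())

    lo, hi = -20.0, 10.0
    if not (marginal(lo) < spec.target_rate < marginal(hi)):
        raise RuntimeError("alpha calibration failed to bracket the target rate")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if marginal(mid) < spec.target_rate:
            lo = mid
        else:
            hi = mid
    alpha = 0.5 * (lo + hi)
    _alpha_cache[key] = alpha
    return alpha


_TUMOUR_TYPES = ("pilocytic astrocytoma", "medulloblastoma",
                 "ATRT", "ganglioma", "ependymoma",
                 "haemangioblastoma", "high-grade glioma")
_TUMOUR_P = np.array([24, 24, 3, 2, 1, 1, 1]) / 56.0


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    cohort: CohortTable
    true_load: np.ndarray
    probability: np.ndarray
    alpha: float
    spec: SyntheticCohortSpec
    template: BinaryMask = field(repr=False, default=None)
    roi: BinaryMask = field(repr=False, default=None)
    weight_map: WeightMap = field(repr=False, default=None)


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Sample a full cohort: cavities, loads, labels and covariates."""
    template, roi, wmap, scorer = _toy_space_cached(spec.grid_shape)
    alpha = spec.alpha if spec.alpha is not None else calibrate_alpha(spec)
    rng = np.random.default_rng(spec.seed)
    masks: dict[str, BinaryMask] = {}
    loads = np.empty(spec.n_subjects)
    for i in range(spec.n_subjects):
        sid = f"sub-{i + 1:03d}"
        masks[sid] = sample_lesion(spec, rng, template)
        loads[i] = scorer.score(masks[sid]).load_percent
    prob = _sigmoid(alpha + spec.beta_load * loads / 100.0)
    labels = (rng.random(spec.n_subjects) < prob).astype(int)
    ids = list(masks)
    extra = pd.DataFrame({
        "subject_id": ids,
        "age_years": np.clip(rng.normal(6.2, 3.7, spec.n_subjects), 0.4, 14.0),
        "sex": rng.choice(["F", "M"], spec.n_subjects, p=[0.446, 0.554]),
        "site": rng.choice(["IA", "GOSH"], spec.n_subjects, p=[9 / 56, 47 / 56]),
        "tumour_type": rng.choice(_TUMOUR_TYPES, spec.n_subjects, p=_TUMOUR_P),
    })
    cohort = cohort_from_masks(masks, dict(zip(ids, labels)), extra)
    return SyntheticCohort(cohort, loads, prob, alpha, spec,
                           template, roi, wmap)


def write_cohort(syn: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write masks, ROI, weight map, manifest and ground truth to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    rows = syn.cohort.table.copy()
    paths = []
    for sid in syn.cohort.subject_ids:
        rel = f"masks/{sid}.nii.gz"
        write_volume(syn.cohort.masks[sid], out / rel)
        paths.append(rel)
    rows["mask_path"] = paths
    rows.to_csv(out / "manifest.csv", index=False)
    write_volume(syn.template, out / "template.nii.gz")
    write_volume(syn.roi, out / "outflow_roi.nii.gz")
    write_volume(syn.weight_map, out / "weight_map.nii.gz")
    truth = {
        "spec": asdict(syn.spec), "spec_hash": syn.spec.spec_hash(),
        "alpha": syn.alpha, "eigenvalue": syn.weight_map.eigenvalue,
        "true_load": syn.true_load.tolist(),
        "probability": syn.probability.tolist(),
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return out


def planted_signal_matrix(n_subjects: int = 80, n_voxels: int = 600,
                          n_signal: int = 20, slope: float = 2.0,
                          base_prob: float = 0.15, hit_prob: float = 0.35,
                          p_in: float = 0.7, p_out: float = 0.05,
                          seed: int = 0
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Abstract planted-signal benchmark for the sparse mapper.

    Signal voxels are spatially coherent the way real cavities are: a latent
    per-subject indicator (probability ``hit_prob``) decides whether the
    cavity involves the critical region, and signal voxels are then lesioned
    with probability ``p_in`` (hit) or ``p_out`` (spared); background voxels
    are independent Bernoulli(``base_prob``).  The outcome is
    Bernoulli(sigmoid(slope * z)) where z is the z-scored count of lesioned
    signal voxels.  Returns (X, y, signal_column_indices).
    """
    rng = np.random.default_rng(seed)
    X = (rng.random((n_subjects, n_voxels)) < base_prob).astype(float)
    signal = np.arange(n_signal)
    hit = rng.random(n_subjects) < hit_prob
    p_sig = np.where(hit, p_in, p_out)[:, None]
    X[:, signal] = (rng.random((n_subjects, n_signal)) < p_sig).astype(float)
    count = X[:, signal].sum(axis=1)
    z = (count - count.mean()) / count.std()
    y = (rng.random(n_subjects) < _sigmoid(slope * z)).astype(int)
    if y.min() == y.max():  # resample degenerate outcomes deterministically
        return planted_signal_matrix(n_subjects, n_voxels, n_signal, slope,
                                     base_prob, hit_prob, p_in, p_out, seed + 1)
    return X, y, signal
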