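"""Simplified sparse canonical correlation lesion-symptom mapping.

With a single binary outcome, canonical correlation between the lesion
matrix X (subjects x voxels) and the outcome y reduces to finding one sparse
voxel weight vector w maximizing corr(X w, y).  The solver is a penalized
alternating scheme: the outcome-side variate is the centred, unit-norm y;
the voxel side is w = X_c' v hard-thresholded to keep the top fraction s of
weights by magnitude (with soft shrinkage at the cut), renormalized, and
iterated to convergence.  Sparseness s is selected by repeated 75/25
train/test splits, scoring each candidate by the mean Pearson correlation
between held-out predicted scores and held-out outcomes; ties go to the
sparser model.  This is an intentional simplification of multi-component
SCCAN optimizers, not a reimplementation of one.

Reported weight maps follow the 0-to-1 convention of lesion-symptom maps:
negative weights are rectified to zero by default (a signed map is kept for
diagnostics) and weights are normalized by their maximum absolute value.
The retained scale, the "eigenvalue", is the L2 norm of the unnormalized
solution; predicted scores are ``X . (eigenvalue * normalized weights)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedShuffleSplit

from .grids import BinaryMask, WeightMap, check_same_grid

DEFAULT_SPARSENESS_GRID = (0.005, 0.01, 0.02, 0.05, 0.1)


@dataclass
class LesionMatrix:
    """Subjects x included-voxels binary matrix with voxel bookkeeping.

    Columns are restricted to voxels lesioned in at least ``min_subjects``
    subjects; ``voxel_ijk`` maps each column back to its voxel index on the
    grid given by ``grid_shape``/``affine``.
    """

    X: np.ndarray
    voxel_ijk: np.ndarray
    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    min_subjects: int

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def column_to_volume(self, values: np.ndarray) -> np.ndarray:
        """Scatter a per-column vector back into a dense volume."""
        vol = np.zeros(self.grid_shape, dtype=float)
        vol[tuple(self.voxel_ijk.T)] = values
        return vol


def build_lesion_matrix(cohort, min_subjects: int | None = None) -> LesionMatrix:
    """Stack cohort masks into a lesion matrix, dropping rare voxels.

    ``min_subjects`` defaults to max(3, 10% of the cohort).
    """
    masks = cohort.mask_list()
    ref = masks[0]
    for m in masks[1:]:
        check_same_grid(m, ref, "masks")
    if min_subjects is None:
        min_subjects = max(3, int(round(0.10 * len(masks))))
    stack = np.stack([m.data.reshape(-1) for m in masks])
    counts = stack.sum(axis=0)
    keep = np.flatnonzero(counts >= max(min_subjects, 1))
    if keep.size == 0:
        raise ValueError("no voxel is lesioned in enough subjects")
    ijk = np.array(np.unravel_index(keep, ref.shape)).T
    return LesionMatrix(stack[:, keep].astype(np.float64), ijk, ref.shape,
                        ref.affine.copy(), int(min_subjects))


def _threshold(w: np.ndarray, sparseness: float) -> np.ndarray:
    """Keep the top fraction ``sparseness`` of weights by magnitude.

    Soft-shrinks the survivors by the cut magnitude so the solution varies
    continuously with the data.
    """
    p = w.size
    k = max(1, int(np.floor(sparseness * p)))
    if k >= p:
        return w.copy()
    mags = np.abs(w)
    cut = np.partition(mags, p - k - 1)[p - k - 1]
    out = np.sign(w) * np.maximum(mags - cut, 0.0)
    if not out.any():  # all magnitudes tied at the cut: keep the top-k as-is
        idx = np.argsort(-mags, kind="stable")[:k]
        out = np.zeros_like(w)
        out[idx] = w[idx]
    return out


def _fit_direction(X: np.ndarray, y: np.ndarray, sparseness: float,
                   max_iter: int, tol: float) -> np.ndarray:
    """One sparse canonical direction for X against a single outcome y.

    Returns the unnormalized sparse weight vector (thresholded X_c' v at
    convergence), oriented so that corr(X w, y) >= 0.
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)
    if ynorm == 0:
        raise ValueError("no outcome variance")
    v = yc / ynorm
    w_raw = _threshold(Xc.T @ v, sparseness)
    w_unit = w_raw / np.linalg.norm(w_raw)
    for _ in range(max_iter):
        u = Xc @ w_unit
        unorm = np.linalg.norm(u)
        if unorm == 0:
            raise ValueError("degenerate lesion matrix (all rows identical)")
        # outcome side: best multiple of y_c, only its sign matters
        sgn = 1.0 if yc @ u >= 0 else -1.0
        w_raw = _threshold(Xc.T @ (sgn * yc / ynorm), sparseness)
        w_next = w_raw / np.linalg.norm(w_raw)
        if np.linalg.norm(w_next - w_unit) < tol:
            w_unit = w_next
            break
        w_unit = w_next
    if (Xc @ w_raw) @ yc < 0:
        w_raw = -w_raw
    return w_raw


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


class SparseCCAMapper(BaseEstimator):
    """Sparse canonical-correlation lesion-symptom mapper for a binary outcome.

    Parameters
    ----------
    sparseness_grid : candidate fractions of voxels allowed nonzero weight.
    cv_fraction : training fraction of each cross-validation split (0.75:
        map in 75% of patients, predict the held-out 25%).
    cv_repeats : number of distinct seeded splits per candidate.
    max_iter, tol : alternating-scheme stopping rule.
    rectify : clamp negative weights to zero in the reported map.
    random_state : seed for the CV splits; fixed seed gives bit-identical fits.

    Attributes (after ``fit``)
    ----------
    weights_ : normalized voxel weights in [0, 1] (max = 1 when any nonzero).
    signed_weights_ : diagnostic weights before rectification, max-abs 1.
    eigenvalue_ : L2 norm of the unnormalized solution.
    optimal_sparseness_ : selected sparseness fraction.
    cv_r_ : mean held-out Pearson r of the selected candidate.
    in_sample_r_ : Pearson r of the full-fit scores against y.
    cv_table_ : mean held-out r per candidate sparseness.
    """

    def __init__(self, sparseness_grid=DEFAULT_SPARSENESS_GRID,
                 cv_fraction: float = 0.75, cv_repeats: int = 4,
                 max_iter: int = 50, tol: float = 1e-8,
                 rectify: bool = True, random_state: int = 0):
        self.sparseness_grid = sparseness_grid
        self.cv_fraction = cv_fraction
        self.cv_repeats = cv_repeats
        self.max_iter = max_iter
        self.tol = tol
        self.rectify = rectify
        self.random_state = random_state

    def _validate(self, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X rows must align with y")
        if np.unique(y).size < 2:
            raise ValueError("no outcome variance: y must contain both classes")
        grid = tuple(self.sparseness_grid)
        if not grid or not all(0 < s <= 1 for s in grid):
            raise ValueError("sparseness_grid must be fractions in (0, 1]")
        if not 0 < self.cv_fraction < 1:
            raise ValueError("cv_fraction must be in (0, 1)")
        return X, y

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SparseCCAMapper":
        X, y = self._validate(X, y)
        grid = sorted(set(float(s) for s in self.sparseness_grid))
        splitter = StratifiedShuffleSplit(
            n_splits=self.cv_repeats, train_size=self.cv_fraction,
            random_state=self.random_state)
        splits = list(splitter.split(X, y))
        cv_means: dict[float, float] = {}
        for s in grid:
            rs = []
            for tr, te in splits:
                try:
                    w = _fit_direction(X[tr], y[tr], s, self.max_iter, self.tol)
                except ValueError:
                    rs.append(0.0)
                    continue
                rs.append(_safe_pearson(X[te] @ w, y[te]))
            cv_means[s] = float(np.mean(rs))
        # best mean held-out r; ties broken toward the sparser model
        best = min(grid, key=lambda s: (-round(cv_means[s], 12), s))
        w_raw = _fit_direction(X, y, best, self.max_iter, self.tol)

        self.eigenvalue_ = float(np.linalg.norm(w_raw))
        signed = w_raw / np.max(np.abs(w_raw))
        self.signed_weights_ = signed
        w = np.maximum(signed, 0.0) if self.rectify else signed
        if w.max() > 0:
            w = w / np.max(np.abs(w))
        self.weights_ = w
        self.optimal_sparseness_ = float(best)
        self.cv_r_ = cv_means[best]
        self.cv_table_ = cv_means
        self.in_sample_r_ = _safe_pearson(self.decision_function(X), y)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Predicted scores X . (eigenvalue * normalized weights)."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.weights_.size:
            raise ValueError("X columns do not match the fitted voxel index")
        return X @ (self.eigenvalue_ * self.weights_)

    predict = decision_function


@dataclass
class LSMResult:
    """Fitted lesion-symptom map plus its selection diagnostics."""

    weight_map: WeightMap
    voxel_ijk: np.ndarray
    weights: np.ndarray
    eigenvalue: float
    optimal_sparseness: float
    cv_r: float
    in_sample_r: float
    cv_table: dict[float, float] = field(default_factory=dict)


def fit_sparse_map(lesion_matrix: LesionMatrix, y,
                   sparseness_grid=DEFAULT_SPARSENESS_GRID,
                   cv_fraction: float = 0.75, cv_repeats: int = 4,
                   max_iter: int = 50, tol: float = 1e-8,
                   rectify: bool = True, seed: int = 0) -> LSMResult:
    """Fit the sparse map on a lesion matrix and return it as a WeightMap."""
    mapper = SparseCCAMapper(sparseness_grid, cv_fraction, cv_repeats,
                             max_iter, tol, rectify, seed)
    mapper.fit(lesion_matrix.X, np.asarray(y))
    vol = lesion_matrix.column_to_volume(np.clip(mapper.weights_, 0.0, 1.0))
    wmap = WeightMap(data=vol, affine=lesion_matrix.affine.copy(),
                     eigenvalue=mapper.eigenvalue_)
    return LSMResult(wmap, lesion_matrix.voxel_ijk, mapper.weights_,
                     mapper.eigenvalue_, mapper.optimal_sparseness_,
                     mapper.cv_r_, mapper.in_sample_r_, mapper.cv_table_)


def predict_scores(result: LSMResult, lesion_matrix: LesionMatrix) -> np.ndarray:
    """Scores X . (eigenvalue * normalized weights) for a lesion matrix."""
    if lesion_matrix.X.shape[1] != result.weights.size or \
            not np.array_equal(lesion_matrix.voxel_ijk, result.voxel_ijk):
        raise ValueError("lesion matrix voxel index does not match the fitted map")
    return lesion_matrix.X @ (result.eigenvalue * result.weights)
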