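"""Sparse canonical-correlation mapper: planted-signal recovery and nulls."""

import numpy as np
import pytest

from cms_lesionmap import (SparseCCAMapper, build_lesion_matrix,
                           cohort_from_masks, fit_sparse_map,
                           planted_signal_matrix, predict_scores)
from conftest import make_mask


@pytest.fixture(scope="module")
def planted():
    return planted_signal_matrix(n_subjects=80, n_voxels=600, n_signal=20,
                                 seed=7)


class TestLesionMatrix:
    def _cohort(self):
        masks = {
            "s1": make_mask((4, 4, 4), [(0, 0, 0), (1, 0, 0)]),
            "s2": make_mask((4, 4, 4), [(0, 0, 0), (2, 0, 0)]),
            "s3": make_mask((4, 4, 4), [(0, 0, 0), (1, 0, 0), (3, 3, 3)]),
        }
        return cohort_from_masks(masks, {"s1": 1, "s2": 0, "s3": 1})

    def test_rare_voxels_excluded(self):
        lm = build_lesion_matrix(self._cohort(), min_subjects=2)
        assert lm.n_voxels == 2  # (0,0,0) in all three, (1,0,0) in two
        assert lm.X.shape == (3, 2)

    def test_min_subjects_zero_keeps_all_ever_lesioned(self):
        lm = build_lesion_matrix(self._cohort(), min_subjects=0)
        assert lm.n_voxels == 4

    def test_column_to_volume_round_trip(self):
        cohort = self._cohort()
        lm = build_lesion_matrix(cohort, min_subjects=1)
        vol = lm.column_to_volume(lm.X[0])
        mask = cohort.masks["s1"]
        assert np.array_equal(vol[tuple(lm.voxel_ijk.T)] > 0,
                              mask.data[tuple(lm.voxel_ijk.T)] > 0)

    def test_no_voxel_passes_threshold_rejected(self):
        with pytest.raises(ValueError, match="no voxel"):
            build_lesion_matrix(self._cohort(), min_subjects=4)


class TestFit:
    def test_constant_outcome_rejected(self, planted):
        X, _, _ = planted
        with pytest.raises(ValueError, match="outcome"):
            SparseCCAMapper().fit(X, np.ones(X.shape[0]))

    def test_planted_signal_recovered(self, planted):
        X, y, signal = planted
        mapper = SparseCCAMapper(random_state=7).fit(X, y)
        top20 = np.argsort(-np.abs(mapper.weights_))[:20]
        recovered = np.isin(top20, signal).mean()
        assert recovered >= 0.7
        assert mapper.cv_r_ > 0.3

    def test_permuted_outcome_gives_null_cv(self, planted):
        X, y, _ = planted
        y_perm = np.random.default_rng(11).permutation(y)
        mapper = SparseCCAMapper(random_state=7).fit(X, y_perm)
        assert abs(mapper.cv_r_) < 0.2

    def test_null_cv_centred_near_zero_over_many_permutations(self, planted):
        X, y, _ = planted
        rng = np.random.default_rng(3)
        rs = [SparseCCAMapper(sparseness_grid=(0.05,), cv_repeats=2,
                              random_state=k).fit(X, rng.permutation(y)).cv_r_
              for k in range(40)]
        assert abs(np.mean(rs)) < 0.1

    def test_sparseness_honored_and_weights_normalized(self, planted):
        X, y, _ = planted
        mapper = SparseCCAMapper(random_state=0).fit(X, y)
        w = mapper.weights_
        frac = np.count_nonzero(w) / w.size
        assert frac <= mapper.optimal_sparseness_ + 1e-12
        assert w.min() >= 0.0 and w.max() == pytest.approx(1.0)

    def test_seeded_determinism_bit_for_bit(self, planted):
        X, y, _ = planted
        a = SparseCCAMapper(random_state=5).fit(X, y)
        b = SparseCCAMapper(random_state=5).fit(X, y)
        assert np.array_equal(a.weights_, b.weights_)
        assert a.eigenvalue_ == b.eigenvalue_ and a.cv_r_ == b.cv_r_

    def test_signed_weights_available_without_rectification(self, planted):
        X, y, _ = planted
        mapper = SparseCCAMapper(rectify=False, random_state=0).fit(X, y)
        assert np.max(np.abs(mapper.weights_)) == pytest.approx(1.0)

    def test_sklearn_get_set_params_round_trip(self):
        mapper = SparseCCAMapper(cv_repeats=6)
        params = mapper.get_params()
        assert params["cv_repeats"] == 6
        mapper.set_params(cv_repeats=3)
        assert mapper.cv_repeats == 3


class TestPredictScores:
    def _fitted(self):
        masks = {}
        rng = np.random.default_rng(0)
        for i in range(12):
            vox = rng.integers(0, 5, (rng.integers(3, 15), 3))
            masks[f"s{i}"] = make_mask((5, 5, 5), vox)
        masks["empty"] = make_mask((5, 5, 5), [])
        labels = {k: int(i % 3 == 0) for i, k in enumerate(masks)}
        cohort = cohort_from_masks(masks, labels)
        lm = build_lesion_matrix(cohort, min_subjects=1)
        res = fit_sparse_map(lm, cohort.labels, sparseness_grid=(0.2, 0.5),
                             cv_repeats=2, seed=0)
        return lm, res, cohort

    def test_empty_lesion_scores_zero(self):
        lm, res, cohort = self._fitted()
        scores = predict_scores(res, lm)
        empty_row = cohort.subject_ids.index("empty")
        assert scores[empty_row] == 0.0

    def test_uniform_weights_reduce_to_scaled_lesion_size(self, planted):
        X, _, _ = planted
        lm_scores = X @ (2.0 * np.ones(X.shape[1]))
        assert np.allclose(lm_scores, 2.0 * X.sum(axis=1))

    def test_in_sample_r_consistent_with_recomputation(self):
        lm, res, cohort = self._fitted()
        scores = predict_scores(res, lm)
        r = np.corrcoef(scores, cohort.labels)[0, 1]
        assert r == pytest.approx(res.in_sample_r, abs=1e-9)

    def test_weight_map_volume_on_unit_interval_with_max_one(self):
        _, res, _ = self._fitted()
        data = res.weight_map.data
        assert data.min() >= 0.0 and data.max() == pytest.approx(1.0)
        assert res.weight_map.eigenvalue == pytest.approx(res.eigenvalue)

    def test_voxel_index_mismatch_rejected(self):
        import copy
        lm, res, _ = self._fitted()
        shifted = copy.copy(lm)
        shifted.voxel_ijk = lm.voxel_ijk + 1
        with pytest.raises(ValueError, match="voxel index"):
            predict_scores(res, shifted)
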