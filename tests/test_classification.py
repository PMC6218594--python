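"""Feature assembly, modality combination, LOSO SVM, permutation test, ROC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats
from sklearn.svm import SVC

from rsmvpa.alff import VoxelMap
from rsmvpa.classification import (
    FeatureMatrix,
    assemble_features,
    combine_modalities,
    fold_training_means,
    loocv,
    mask_scan_order,
    permutation_test,
    roc,
)
from rsmvpa.outcome_labels import PERSISTENT, REMITTED, OutcomeLabel


def make_labels(assignment: dict[str, str]) -> list[OutcomeLabel]:
    return [
        OutcomeLabel(sid, lab, 0.6 if lab == REMITTED else 0.2)
        for sid, lab in assignment.items()
    ]


def matrix_from_values(values, subject_ids, modality="alff") -> FeatureMatrix:
    values = np.asarray(values, dtype=float)
    vi = pd.DataFrame(
        {"modality": modality, "x": np.arange(values.shape[1]), "y": 0, "z": 0}
    )
    return FeatureMatrix(values=values, subject_ids=list(subject_ids),
                         voxel_index=vi, modality_tag=modality)


def toy_separable(n_pos=3, n_neg=3):
    """1-D toy: remitted at +1..+n, persistent at -1..-n."""
    ids = [f"s{i}" for i in range(n_pos + n_neg)]
    values = np.r_[np.arange(1, n_pos + 1), -np.arange(1, n_neg + 1)].reshape(-1, 1)
    assignment = {
        sid: (REMITTED if i < n_pos else PERSISTENT) for i, sid in enumerate(ids)
    }
    return matrix_from_values(values, ids), make_labels(assignment)


class TestAssembleFeatures:
    def _maps(self, rng, mask, subjects):
        return {
            sid: VoxelMap(
                values=np.where(mask, rng.uniform(0.5, 1.5, mask.shape), 0.0),
                mask=mask, modality="alff",
            )
            for sid in subjects
        }

    def test_shape_contract(self, rng):
        mask = np.zeros((3, 2, 2), dtype=bool)
        mask.ravel()[:5] = True
        maps = self._maps(rng, mask, ["a", "b", "c"])
        mat = assemble_features(maps, mask)
        assert mat.values.shape == (3, int(mask.sum()))

    def test_scan_order_x_fastest(self):
        mask = np.ones((2, 2, 1), dtype=bool)
        coords = mask_scan_order(mask)
        np.testing.assert_array_equal(
            coords, [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]
        )

    def test_rows_follow_supplied_subject_order(self, rng):
        mask = np.ones((2, 2, 1), dtype=bool)
        maps = self._maps(rng, mask, ["a", "b", "c"])
        forward = assemble_features(maps, mask, ["a", "b", "c"])
        shuffled = assemble_features(maps, mask, ["c", "a", "b"])
        assert shuffled.subject_ids == ["c", "a", "b"]
        np.testing.assert_array_equal(shuffled.values[1], forward.values[0])

    def test_values_track_voxel_index(self, rng):
        mask = np.zeros((3, 3, 1), dtype=bool)
        mask[0, 0, 0] = mask[2, 1, 0] = True
        maps = self._maps(rng, mask, ["a"])
        mat = assemble_features(maps, mask)
        for col, (_, row) in enumerate(mat.voxel_index.iterrows()):
            assert mat.values[0, col] == maps["a"].values[row.x, row.y, row.z]

    def test_missing_subject_rejected(self, rng):
        mask = np.ones((2, 1, 1), dtype=bool)
        maps = self._maps(rng, mask, ["a"])
        with pytest.raises(ValueError, match="missing"):
            assemble_features(maps, mask, ["a", "b"])


class TestCombineModalities:
    def test_single_matrix_identity(self, rng):
        mat = matrix_from_values(rng.normal(size=(4, 6)), list("abcd"))
        assert combine_modalities([mat], "concatenate") is mat
        assert combine_modalities([mat], "stack_samples") is mat

    def test_duplicate_modality_kernel_doubles(self, rng):
        x = rng.normal(size=(5, 8))
        m1 = matrix_from_values(x, list("abcde"), "alff")
        m2 = matrix_from_values(x, list("abcde"), "dc")
        combined = combine_modalities([m1, m2], "concatenate")
        xc = x - x.mean(axis=0)
        k_norm = (xc @ xc.T) / (np.einsum("ij,ij->i", xc, xc).mean())
        cc = combined.values - combined.values.mean(axis=0)
        np.testing.assert_allclose(cc @ cc.T, 2 * k_norm, atol=1e-10)

    def test_duplicate_modality_predictions_match_normalized_single(self, rng):
        x = rng.normal(size=(8, 10))
        ids = [f"s{i}" for i in range(8)]
        assignment = {sid: (REMITTED if i < 4 else PERSISTENT) for i, sid in enumerate(ids)}
        labels = make_labels(assignment)
        m1 = matrix_from_values(x, ids, "alff")
        m2 = matrix_from_values(x, ids, "dc")
        combined = combine_modalities([m1, m2], "concatenate")
        single = loocv(m1, labels)
        dup = loocv(combined, labels)
        assert list(dup.folds.predicted_label) == list(single.folds.predicted_label)

    def test_stack_samples_layout(self, rng):
        ids = [f"s{i}" for i in range(20)]
        m1 = matrix_from_values(rng.normal(size=(20, 5)), ids, "alff")
        m2 = matrix_from_values(rng.normal(size=(20, 5)), ids, "dc")
        stacked = combine_modalities([m1, m2], "stack_samples")
        assert stacked.values.shape == (40, 5)
        assert len(stacked.unique_subjects) == 20
        assert stacked.row_modality.count("alff") == 20

    def test_subject_mismatch_rejected(self, rng):
        m1 = matrix_from_values(rng.normal(size=(3, 4)), list("abc"))
        m2 = matrix_from_values(rng.normal(size=(3, 4)), list("abd"), "dc")
        with pytest.raises(ValueError, match="different subjects"):
            combine_modalities([m1, m2], "concatenate")

    def test_subject_reorder_aligned(self, rng):
        x = rng.normal(size=(4, 5))
        m1 = matrix_from_values(x, list("abcd"), "alff")
        m2 = matrix_from_values(x[::-1], list("dcba"), "dc")
        combined = combine_modalities([m1, m2], "concatenate")
        n = combined.values.shape[1] // 2
        np.testing.assert_allclose(
            combined.values[:, :n] * np.linalg.norm(combined.values[:, n:]),
            combined.values[:, n:] * np.linalg.norm(combined.values[:, :n]),
        )


class TestLoocv:
    def test_separable_toy_perfect(self):
        mat, labels = toy_separable()
        cv = loocv(mat, labels)
        assert cv.total_accuracy == 1.0
        assert cv.sensitivity == 1.0 and cv.specificity == 1.0

    def test_identical_labels_rejected(self):
        mat, _ = toy_separable()
        labels = make_labels({sid: REMITTED for sid in mat.subject_ids})
        with pytest.raises(ValueError, match="2 subjects per class"):
            loocv(mat, labels)

    def test_uninformative_features_near_chance(self):
        # identical rows: centered features vanish, constant decision values
        ids = [f"s{i}" for i in range(8)]
        mat = matrix_from_values(np.ones((8, 3)), ids)
        labels = make_labels(
            {sid: (REMITTED if i < 4 else PERSISTENT) for i, sid in enumerate(ids)}
        )
        cv = loocv(mat, labels)
        assert cv.total_accuracy <= 0.5 + 1.0 / 8

    def test_kernel_engine_matches_explicit_svc(self, rng):
        # oracle: per-fold feature centering + public SVC on raw features
        x = rng.normal(size=(10, 15))
        ids = [f"s{i}" for i in range(10)]
        labels = make_labels(
            {sid: (REMITTED if i % 2 == 0 else PERSISTENT) for i, sid in enumerate(ids)}
        )
        cv = loocv(mat := matrix_from_values(x, ids), labels)
        y = np.array([1 if i % 2 == 0 else -1 for i in range(10)])
        for held in range(10):
            train = np.arange(10) != held
            mu = x[train].mean(axis=0)
            svc = SVC(kernel="linear", C=1.0).fit(x[train] - mu, y[train])
            expected = svc.decision_function((x[held] - mu)[None, :])[0]
            got = cv.folds.decision_value.iloc[held]
            np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_cohort_centering_matches_precentered_features(self, rng):
        # whole-dataset centering: shifting all features by a constant
        # vector must not change anything (unlike raw uncentered fits)
        x = rng.normal(size=(8, 6))
        ids = [f"s{i}" for i in range(8)]
        labels = make_labels(
            {sid: (REMITTED if i < 4 else PERSISTENT) for i, sid in enumerate(ids)}
        )
        cv1 = loocv(matrix_from_values(x, ids), labels, centering="cohort")
        cv2 = loocv(matrix_from_values(x + 7.5, ids), labels, centering="cohort")
        np.testing.assert_allclose(
            cv1.folds.decision_value, cv2.folds.decision_value, atol=1e-8
        )
        with pytest.raises(ValueError, match="centering"):
            loocv(matrix_from_values(x, ids), labels, centering="nope")

    def test_no_leakage_training_means_ignore_held_out(self, rng):
        x = rng.normal(size=(6, 4))
        ids = [f"s{i}" for i in range(6)]
        mat1 = matrix_from_values(x, ids)
        x2 = x.copy()
        x2[2] += 100.0  # perturb one subject
        mat2 = matrix_from_values(x2, ids)
        means1 = fold_training_means(mat1)
        means2 = fold_training_means(mat2)
        np.testing.assert_array_equal(means1["s2"], means2["s2"])

    def test_accuracy_identity(self, rng):
        ids = [f"s{i}" for i in range(9)]
        mat = matrix_from_values(rng.normal(size=(9, 5)), ids)
        labels = make_labels(
            {sid: (REMITTED if i < 4 else PERSISTENT) for i, sid in enumerate(ids)}
        )
        cv = loocv(mat, labels)
        n, n_r, n_p = 9, 4, 5
        total_correct = cv.total_accuracy * n
        np.testing.assert_allclose(
            total_correct, cv.sensitivity * n_r + cv.specificity * n_p, atol=1e-10
        )

    def test_stacked_rows_share_fold_with_subject(self, rng):
        ids = [f"s{i}" for i in range(6)]
        m1 = matrix_from_values(rng.normal(size=(6, 4)), ids, "alff")
        m2 = matrix_from_values(rng.normal(size=(6, 4)), ids, "dc")
        stacked = combine_modalities([m1, m2], "stack_samples")
        labels = make_labels(
            {sid: (REMITTED if i < 3 else PERSISTENT) for i, sid in enumerate(ids)}
        )
        cv = loocv(stacked, labels)
        assert cv.n_samples == 12
        # every subject appears exactly twice (once per modality)
        assert cv.folds.groupby("subject_id").size().eq(2).all()


class TestPermutationTest:
    def test_counting_formula_on_separable_toy(self):
        mat, labels = toy_separable(4, 4)
        perm = permutation_test(mat, labels, n_permutations=199, seed=123)
        assert perm.observed_accuracy == 1.0
        if not np.any(perm.null_accuracies >= 1.0):
            assert perm.p_value == pytest.approx(1.0 / 200.0)
        else:  # a null permutation can re-create the true labeling
            expected = (1 + np.sum(perm.null_accuracies >= 1.0)) / 200.0
            assert perm.p_value == pytest.approx(expected)

    def test_p_value_formula_upper_bound(self, rng):
        ids = [f"s{i}" for i in range(8)]
        mat = matrix_from_values(rng.normal(size=(8, 3)), ids)
        labels = make_labels(
            {sid: (REMITTED if i < 4 else PERSISTENT) for i, sid in enumerate(ids)}
        )
        perm = permutation_test(mat, labels, n_permutations=50, seed=9)
        assert 0.0 < perm.p_value <= 1.0
        expected = (1 + np.sum(perm.null_accuracies >= perm.observed_accuracy)) / 51.0
        assert perm.p_value == pytest.approx(expected)

    def test_same_seed_identical_nulls(self):
        mat, labels = toy_separable(3, 4)
        p1 = permutation_test(mat, labels, n_permutations=30, seed=42)
        p2 = permutation_test(mat, labels, n_permutations=30, seed=42)
        np.testing.assert_array_equal(p1.null_accuracies, p2.null_accuracies)

    def test_seed_required(self):
        mat, labels = toy_separable()
        with pytest.raises(ValueError, match="seed"):
            permutation_test(mat, labels, n_permutations=10)


def cv_from_decisions(decisions, true_labels):
    folds = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(len(decisions))],
            "row_modality": "alff",
            "true_label": true_labels,
            "predicted_label": [REMITTED if d >= 0 else PERSISTENT for d in decisions],
            "decision_value": decisions,
        }
    )
    from rsmvpa.classification import CvResult

    return CvResult(folds=folds, total_accuracy=0.0, sensitivity=0.0, specificity=0.0)


class TestRoc:
    def test_perfect_ranking(self):
        cv = cv_from_decisions([2, 1, -1, -2], [REMITTED, REMITTED, PERSISTENT, PERSISTENT])
        assert roc(cv).auc == pytest.approx(1.0)

    def test_inverted_ranking(self):
        cv = cv_from_decisions([-1, 1], [REMITTED, PERSISTENT])
        assert roc(cv).auc == pytest.approx(0.0)

    def test_all_ties_give_half(self):
        cv = cv_from_decisions([0.5] * 6, [REMITTED] * 3 + [PERSISTENT] * 3)
        assert roc(cv).auc == pytest.approx(0.5)

    def test_auc_equals_normalized_mann_whitney(self, rng):
        decisions = rng.normal(size=12)
        labels = [REMITTED] * 5 + [PERSISTENT] * 7
        auc = roc(cv_from_decisions(decisions, labels)).auc
        u = spstats.mannwhitneyu(decisions[:5], decisions[5:]).statistic
        assert auc == pytest.approx(u / (5 * 7))

    def test_single_class_rejected(self):
        cv = cv_from_decisions([1, 2], [REMITTED, REMITTED])
        with pytest.raises(ValueError, match="per class"):
            roc(cv)

    def test_curve_monotone(self, rng):
        decisions = rng.normal(size=20)
        labels = [REMITTED if rng.random() < 0.5 else PERSISTENT for _ in range(19)]
        labels.append(REMITTED if labels.count(REMITTED) == 0 else PERSISTENT)
        curve = roc(cv_from_decisions(decisions, labels))
        pts = np.array(curve.points)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)
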