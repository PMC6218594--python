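"""Leave-one-subject-out SVM classification of outcome from voxel features.

Feature vectors are the in-mask voxels of each subject's standardized
ALFF and/or DC map ("input space is voxel space").  Modalities can be
combined either by column concatenation after per-modality kernel trace
normalization (equivalently: summing normalized linear kernels) or by
stacking each modality as a separate sample that shares the subject's
label and cross-validation fold.

Cross-validation centers features on the training rows of each fold only
(leakage-safe), trains a soft-margin linear SVM (default C = 1), and
records the held-out decision values.  Significance of the observed
total accuracy is assessed by rerunning the full cross-validation under
random label permutations.

Implementation note: because the SVM is linear, every fold can be
expressed through the subjects' Gram matrix; fold-wise training-mean
centering becomes a rank-one kernel correction, so the permutation test
reuses one set of per-fold centered kernels for all permutations.  The
kernel route is exactly equivalent to explicit feature-space centering
and is cross-checked against scikit-learn's ``SVC`` in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.svm import SVC

from .alff import VoxelMap
from .outcome_labels import PERSISTENT, REMITTED, OutcomeLabel

try:  # fast path: low-level libsvm binding (same solver SVC wraps)
    from sklearn.svm import _libsvm as _libsvm_mod

    _libsvm_mod.set_verbosity_wrap(0)
except Exception:  # pragma: no cover - fallback for unexpected sklearn layouts
    _libsvm_mod = None

__all__ = [
    "FeatureMatrix",
    "CvResult",
    "PermutationResult",
    "RocCurve",
    "assemble_features",
    "combine_modalities",
    "loocv",
    "permutation_test",
    "roc",
    "fold_training_means",
]


@dataclass
class FeatureMatrix:
    """Rows of per-sample voxel features with bookkeeping.

    ``subject_ids`` has one entry per row (duplicated under the
    ``stack_samples`` scheme); ``voxel_index`` maps each column to its
    modality and grid coordinate; ``row_modality`` tags rows when
    modalities are stacked as separate samples.
    """

    values: np.ndarray
    subject_ids: list[str]
    voxel_index: pd.DataFrame
    modality_tag: str
    row_modality: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2D")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("one subject_id per row required")
        if len(self.voxel_index) != self.values.shape[1]:
            raise ValueError("voxel_index must describe every column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def unique_subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subject_ids:
            seen.setdefault(s)
        return list(seen)


@dataclass
class CvResult:
    """Leave-one-subject-out predictions and summary accuracies."""

    folds: pd.DataFrame  # subject_id, row_modality, true_label, predicted_label, decision_value
    total_accuracy: float
    sensitivity: float
    specificity: float

    @property
    def n_samples(self) -> int:
        return len(self.folds)


@dataclass
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float
    n_permutations: int
    seed: int


@dataclass
class RocCurve:
    points: list[tuple[float, float]]  # (false positive rate, true positive rate)
    auc: float


def mask_scan_order(mask: np.ndarray) -> np.ndarray:
    """In-mask voxel coordinates in scan order, x varying fastest.

    Returns an ``(n_voxels, 3)`` integer array; this order defines the
    feature-column layout and is used to scatter weights back to grid.
    """
    mask = np.asarray(mask, dtype=bool)
    flat = np.flatnonzero(mask.ravel(order="F"))
    return np.column_stack(np.unravel_index(flat, mask.shape, order="F"))


def assemble_features(
    maps: Mapping[str, VoxelMap],
    mask: np.ndarray,
    subject_order: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Stack per-subject voxel maps into a subjects-by-voxels matrix.

    Row order follows ``subject_order`` (default: mapping order); column
    order is mask scan order with x fastest.
    """
    mask = np.asarray(mask, dtype=bool)
    subjects = list(subject_order) if subject_order is not None else list(maps)
    missing = [s for s in subjects if s not in maps]
    if missing:
        raise ValueError(f"missing maps for subjects: {missing}")
    coords = mask_scan_order(mask)
    modality = None
    rows = []
    for sid in subjects:
        vmap = maps[sid]
        if vmap.values.shape != mask.shape or not np.array_equal(vmap.mask, mask):
            raise ValueError(f"map for {sid} is not on the shared grid/mask")
        modality = modality or vmap.modality
        rows.append(vmap.values[coords[:, 0], coords[:, 1], coords[:, 2]])
    voxel_index = pd.DataFrame(coords, columns=["x", "y", "z"])
    voxel_index.insert(0, "modality", modality or "unknown")
    return FeatureMatrix(
        values=np.vstack(rows),
        subject_ids=subjects,
        voxel_index=voxel_index,
        modality_tag=modality or "unknown",
    )


def _trace_normalize(values: np.ndarray) -> np.ndarray:
    """Scale features so the centered linear kernel has unit mean diagonal.

    Puts modalities with different raw scales (ALFF amplitudes vs DC
    counts) on a common kernel scale before combination.
    """
    centered = values - values.mean(axis=0, keepdims=True)
    mean_diag = float(np.einsum("ij,ij->i", centered, centered).mean())
    if mean_diag <= 0:
        raise ValueError("cannot normalize a modality with identical rows")
    return values / np.sqrt(mean_diag)


def combine_modalities(
    mats: Sequence[FeatureMatrix], scheme: str = "concatenate"
) -> FeatureMatrix:
    """Merge single-modality feature matrices for joint classification.

    ``concatenate``: trace-normalize each modality and column-concatenate,
    so the combined linear kernel is the sum of normalized per-modality
    kernels.  ``stack_samples``: trace-normalize and stack each modality's
    rows as separate samples carrying the subject's label; leave-one-
    subject-out then holds out all of a subject's rows together.
    A single input matrix is returned unchanged under either scheme.
    """
    if len(mats) == 0:
        raise ValueError("no feature matrices supplied")
    if len(mats) == 1:
        return mats[0]
    ref = mats[0].unique_subjects
    aligned = []
    for m in mats:
        if m.row_modality is not None:
            raise ValueError("cannot combine an already-stacked matrix")
        if m.unique_subjects != ref:
            if set(m.unique_subjects) != set(ref):
                raise ValueError("feature matrices cover different subjects")
            order = [m.subject_ids.index(s) for s in ref]
            m = FeatureMatrix(
                values=m.values[order],
                subject_ids=ref.copy(),
                voxel_index=m.voxel_index,
                modality_tag=m.modality_tag,
            )
        aligned.append(m)

    if scheme == "concatenate":
        blocks = [_trace_normalize(m.values) for m in aligned]
        return FeatureMatrix(
            values=np.hstack(blocks),
            subject_ids=ref.copy(),
            voxel_index=pd.concat([m.voxel_index for m in aligned], ignore_index=True),
            modality_tag="combined",
        )
    if scheme == "stack_samples":
        widths = {m.values.shape[1] for m in aligned}
        if len(widths) != 1:
            raise ValueError("stack_samples needs equal feature counts per modality")
        values = np.vstack([_trace_normalize(m.values) for m in aligned])
        subject_ids = sum(([s for s in ref] for _ in aligned), [])
        row_modality = sum(([m.modality_tag] * len(ref) for m in aligned), [])
        voxel_index = aligned[0].voxel_index.assign(modality="shared")
        return FeatureMatrix(
            values=values,
            subject_ids=subject_ids,
            voxel_index=voxel_index,
            modality_tag="combined",
            row_modality=row_modality,
        )
    raise ValueError(f"unknown combination scheme {scheme!r}")


def _labels_by_subject(
    features: FeatureMatrix, labels: Sequence[OutcomeLabel]
) -> dict[str, int]:
    lab = {l.subject_id: l.label for l in labels}
    missing = [s for s in features.unique_subjects if s not in lab]
    if missing:
        raise ValueError(f"labels missing for subjects: {missing}")
    y = {}
    for s in features.unique_subjects:
        if lab[s] not in (REMITTED, PERSISTENT):
            raise ValueError(f"unknown label {lab[s]!r}")
        y[s] = 1 if lab[s] == REMITTED else -1
    return y


class _KernelLoocv:
    """Precomputed per-fold centered kernels for leave-one-subject-out CV.

    Fold centering uses training rows only; because centering is label
    independent, the same kernels serve the observed run and every label
    permutation.  ``centering='cohort'`` instead centers on all rows once
    (closer to some toolbox defaults, but not leakage-safe; off by
    default everywhere).
    """

    def __init__(
        self, features: FeatureMatrix, c_param: float = 1.0, centering: str = "fold"
    ):
        if centering not in ("fold", "cohort"):
            raise ValueError(f"unknown centering {centering!r}")
        x = features.values
        if centering == "cohort":
            x = x - x.mean(axis=0, keepdims=True)
        self.c_param = float(c_param)
        self.subjects = features.unique_subjects
        self.row_subject = np.array(features.subject_ids)
        gram = x @ x.T
        self.folds = []
        n = x.shape[0]
        all_rows = np.arange(n)
        for held in self.subjects:
            test = all_rows[self.row_subject == held]
            train = all_rows[self.row_subject != held]
            if centering == "fold":
                m_t = gram[:, train].mean(axis=1)  # row means over training columns
                mtt = m_t[train].mean()
                k_centered = gram - m_t[:, None] - m_t[None, :] + mtt
            else:
                k_centered = gram
            k_train = np.ascontiguousarray(k_centered[np.ix_(train, train)])
            k_test = np.ascontiguousarray(k_centered[np.ix_(test, train)])
            self.folds.append((held, train, test, k_train, k_test))

    def decisions(self, y_rows: np.ndarray) -> np.ndarray:
        """Held-out decision values per row for the given +/-1 row labels."""
        out = np.empty(len(y_rows))
        for _, train, test, k_train, k_test in self.folds:
            y_train = np.ascontiguousarray(y_rows[train], dtype=np.float64)
            if len(np.unique(y_train)) < 2:
                raise ValueError("a class is absent from a training fold")
            out[test] = _svm_decision(k_train, y_train, k_test, self.c_param)
        return out


def _svm_decision(
    k_train: np.ndarray, y_train: np.ndarray, k_test: np.ndarray, c_param: float
) -> np.ndarray:
    """Train C-SVC on a precomputed kernel; signed decision values for test rows.

    Positive decision value means the positive (+1, remitted) class.
    """
    if _libsvm_mod is not None:
        support, _, _, coef, intercept, *_ = _libsvm_mod.fit(
            k_train, y_train, svm_type=0, kernel="precomputed", C=c_param
        )
        return -(k_test[:, support] @ coef.ravel() + intercept[0])
    svc = SVC(kernel="precomputed", C=c_param)  # pragma: no cover - fallback
    svc.fit(k_train, y_train)
    return svc.decision_function(k_test)


def _summarize(features: FeatureMatrix, y_rows: np.ndarray, decisions: np.ndarray) -> CvResult:
    predicted = np.where(decisions >= 0, 1, -1)  # tie at 0 predicts remitted
    correct = predicted == y_rows
    pos = y_rows == 1
    table = pd.DataFrame(
        {
            "subject_id": features.subject_ids,
            "row_modality": features.row_modality
            if features.row_modality is not None
            else [features.modality_tag] * len(y_rows),
            "true_label": np.where(pos, REMITTED, PERSISTENT),
            "predicted_label": np.where(predicted == 1, REMITTED, PERSISTENT),
            "decision_value": decisions,
        }
    )
    return CvResult(
        folds=table,
        total_accuracy=float(correct.mean()),
        sensitivity=float(correct[pos].mean()),
        specificity=float(correct[~pos].mean()),
    )


def _row_labels(features: FeatureMatrix, y_subject: dict[str, int]) -> np.ndarray:
    return np.array([y_subject[s] for s in features.subject_ids], dtype=np.float64)


def _check_class_sizes(y_subject: dict[str, int]) -> None:
    counts = {1: 0, -1: 0}
    for v in y_subject.values():
        counts[v] += 1
    if min(counts.values()) < 2:
        raise ValueError(
            "need at least 2 subjects per class for leave-one-subject-out CV "
            f"(got {counts[1]} remitted / {counts[-1]} persistent)"
        )


def loocv(
    features: FeatureMatrix,
    labels: Sequence[OutcomeLabel],
    c_param: float = 1.0,
    centering: str = "fold",
) -> CvResult:
    """Leave-one-subject-out linear SVM with per-fold training-mean centering.

    ``centering='cohort'`` centers on the whole dataset instead (not
    leakage-safe; provided for comparison with toolbox defaults).
    """
    y_subject = _labels_by_subject(features, labels)
    _check_class_sizes(y_subject)
    engine = _KernelLoocv(features, c_param, centering)
    y_rows = _row_labels(features, y_subject)
    return _summarize(features, y_rows, engine.decisions(y_rows))


def permutation_test(
    features: FeatureMatrix,
    labels: Sequence[OutcomeLabel],
    n_permutations: int = 1000,
    seed: int | None = None,
    c_param: float = 1.0,
    centering: str = "fold",
) -> PermutationResult:
    """Permutation test of the observed LOOCV total accuracy.

    Subject labels are randomly re-paired with the data ``n_permutations``
    times; each permutation reruns the full cross-validation (per-fold
    centering included).  The p-value uses the add-one estimator
    ``(1 + #{null >= observed}) / (1 + B)`` and therefore never reaches 0.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for the permutation test")
    y_subject = _labels_by_subject(features, labels)
    _check_class_sizes(y_subject)
    engine = _KernelLoocv(features, c_param, centering)
    subjects = features.unique_subjects
    y_vec = np.array([y_subject[s] for s in subjects], dtype=np.float64)
    row_pos = np.array([subjects.index(s) for s in features.subject_ids])

    observed = _summarize(features, y_vec[row_pos], engine.decisions(y_vec[row_pos]))
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        y_perm = rng.permutation(y_vec)
        y_rows = y_perm[row_pos]
        dec = engine.decisions(y_rows)
        null[b] = float((np.where(dec >= 0, 1, -1) == y_rows).mean())
    p = (1.0 + int(np.sum(null >= observed.total_accuracy))) / (1.0 + n_permutations)
    return PermutationResult(
        observed_accuracy=observed.total_accuracy,
        null_accuracies=null,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )


def roc(cv: CvResult) -> RocCurve:
    """ROC over all decision-value thresholds; remitted is the positive class.

    Tied decision values contribute diagonal segments, so the trapezoidal
    AUC counts ties with half weight (equivalently, AUC equals the
    normalized Mann-Whitney U of the decision values).
    """
    y = (cv.folds["true_label"] == REMITTED).to_numpy().astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("ROC needs at least one sample per class")
    fpr, tpr, _ = skmetrics.roc_curve(y, cv.folds["decision_value"].to_numpy(),
                                      drop_intermediate=False)
    return RocCurve(points=list(zip(fpr.tolist(), tpr.tolist())),
                    auc=float(skmetrics.auc(fpr, tpr)))


def fold_training_means(features: FeatureMatrix) -> dict[str, np.ndarray]:
    """Per-fold training-row feature means (introspection/diagnostics).

    Keyed by the held-out subject; these are the centering vectors the
    cross-validation applies, computed from training rows only.
    """
    x = features.values
    row_subject = np.array(features.subject_ids)
    return {
        held: x[row_subject != held].mean(axis=0) for held in features.unique_subjects
    }
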