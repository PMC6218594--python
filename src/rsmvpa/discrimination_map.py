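"""Discriminative weight maps from the full-cohort linear SVM.

After cross-validated performance is established, the linear SVM is
refit on all subjects (features centered on the full cohort — there is
no held-out subject for the final map) and its primal weight vector is
scattered back to voxel space, one signed volume per modality.  Positive
weight is evidence for the remitted class.  For display and reporting,
weights are thresholded at a fraction of the maximum absolute weight
(default 30%) and maximal same-sign connected components are tabulated.

Because the classifier is multivariate, a voxel's weight reflects its
contribution to the whole-brain discriminating pattern; no local
inference should be made from individual weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.svm import SVC

from .classification import FeatureMatrix, _labels_by_subject, _check_class_sizes
from .outcome_labels import PERSISTENT, REMITTED, OutcomeLabel

__all__ = ["WeightMap", "fit_weight_map", "threshold_weight_map", "cluster_table"]

SIGN_POSITIVE = f"{REMITTED}>{PERSISTENT}"
SIGN_NEGATIVE = f"{PERSISTENT}>{REMITTED}"


@dataclass
class WeightMap:
    """Signed voxelwise SVM weights, per modality.

    ``volumes`` maps modality name to a 3D signed weight array (zero
    outside the mask).  ``weight_vector``/``intercept``/``feature_means``
    retain the flat primal solution so predictions can be reproduced from
    the map.  Weight magnitudes are on the raw primal (solver) scale;
    only ratios of weights are meaningful.
    """

    volumes: dict[str, np.ndarray]
    mask: np.ndarray
    threshold_fraction: float | None = None
    thresholded: bool = False
    weight_vector: np.ndarray | None = None
    intercept: float | None = None
    feature_means: np.ndarray | None = None
    affine: np.ndarray | None = None


def fit_weight_map(
    features: FeatureMatrix,
    labels: Sequence[OutcomeLabel],
    mask: np.ndarray,
    c_param: float = 1.0,
    affine: np.ndarray | None = None,
) -> WeightMap:
    """Train the linear SVM on all subjects and back-project its weights.

    Features are mean-centered on the full cohort; the fitted primal
    vector is scattered to grid coordinates via the feature matrix's
    voxel index, one volume per modality.
    """
    mask = np.asarray(mask, dtype=bool)
    y_subject = _labels_by_subject(features, labels)
    _check_class_sizes(y_subject)
    y = np.array([y_subject[s] for s in features.subject_ids], dtype=float)
    means = features.values.mean(axis=0)
    x = features.values - means
    svc = SVC(kernel="linear", C=c_param)
    svc.fit(x, y)
    w = svc.coef_.ravel().astype(np.float64)
    # sklearn orders classes ascending: classes_=[-1, +1], so positive
    # decision (x @ w + b > 0) already means the remitted (+1) class.
    volumes: dict[str, np.ndarray] = {}
    vi = features.voxel_index
    for modality in vi["modality"].unique():
        sel = (vi["modality"] == modality).to_numpy()
        vol = np.zeros(mask.shape, dtype=np.float64)
        coords = vi.loc[sel, ["x", "y", "z"]].to_numpy()
        vol[coords[:, 0], coords[:, 1], coords[:, 2]] = w[sel]
        volumes[str(modality)] = vol
    return WeightMap(
        volumes=volumes,
        mask=mask,
        weight_vector=w,
        intercept=float(svc.intercept_[0]),
        feature_means=means,
        affine=affine,
    )


def threshold_weight_map(wm: WeightMap, fraction: float = 0.30) -> WeightMap:
    """Retain voxels with ``|w| >= fraction * max|w|`` (per modality), zero others.

    The cutoff is a fraction of the maximum absolute weight within each
    modality's volume, so the retained set is invariant to positive
    rescaling of the weights.  Idempotent at a fixed fraction.
    """
    if wm.thresholded:
        raise ValueError("weight map is already thresholded")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    volumes = {}
    for modality, vol in wm.volumes.items():
        peak = float(np.abs(vol).max())
        if peak == 0:
            raise ValueError(f"all-zero weight map for modality {modality!r}")
        cutoff = fraction * peak
        volumes[modality] = np.where(np.abs(vol) >= cutoff, vol, 0.0)
    return replace(wm, volumes=volumes, threshold_fraction=fraction, thresholded=True)


_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=int)


def cluster_table(
    wm: WeightMap,
    min_cluster_size: int = 20,
    label_image: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tabulate signed clusters of a thresholded weight map.

    Connected components (26-connectivity) are computed separately for
    positive and negative retained voxels, so adjacent blobs of opposite
    sign stay distinct.  Components smaller than ``min_cluster_size`` are
    dropped.  Each row reports the modality, sign, voxel count, peak-|w|
    grid coordinate (and world mm coordinate when an affine is present),
    and the peak signed weight; an optional integer label image annotates
    each cluster with its modal label.
    """
    if not wm.thresholded:
        raise ValueError("cluster_table requires a thresholded weight map")
    rows = []
    for modality, vol in wm.volumes.items():
        for sign_name, signed in ((SIGN_POSITIVE, vol > 0), (SIGN_NEGATIVE, vol < 0)):
            labeled, n_comp = ndimage.label(signed, structure=_CONNECTIVITY_26)
            for comp in range(1, n_comp + 1):
                coords = np.argwhere(labeled == comp)
                if len(coords) < min_cluster_size:
                    continue
                weights = vol[coords[:, 0], coords[:, 1], coords[:, 2]]
                peak_idx = int(np.argmax(np.abs(weights)))
                peak = coords[peak_idx]
                row = {
                    "modality": modality,
                    "sign": sign_name,
                    "n_voxels": int(len(coords)),
                    "peak_x": int(peak[0]),
                    "peak_y": int(peak[1]),
                    "peak_z": int(peak[2]),
                    "peak_weight": float(weights[peak_idx]),
                }
                if wm.affine is not None:
                    world = wm.affine @ np.array([*peak, 1.0])
                    row.update(
                        peak_x_mm=float(world[0]),
                        peak_y_mm=float(world[1]),
                        peak_z_mm=float(world[2]),
                    )
                if label_image is not None:
                    region_labels = label_image[coords[:, 0], coords[:, 1], coords[:, 2]]
                    values, counts = np.unique(region_labels, return_counts=True)
                    row["modal_label"] = int(values[np.argmax(counts)])
                rows.append(row)
    columns = ["modality", "sign", "n_voxels", "peak_x", "peak_y", "peak_z", "peak_weight"]
    if wm.affine is not None:
        columns += ["peak_x_mm", "peak_y_mm", "peak_z_mm"]
    if label_image is not None:
        columns += ["modal_label"]
    df = pd.DataFrame(rows, columns=columns)
    return df.sort_values(
        ["modality", "sign", "n_voxels"], ascending=[True, True, False]
    ).reset_index(drop=True)
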