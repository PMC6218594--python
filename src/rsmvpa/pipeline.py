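"""End-to-end orchestration: preprocessing -> features -> labels -> SVM.

Two entry points:

* :func:`analyze_cohort` runs the full analysis on an in-memory
  :class:`~rsmvpa.synthetic_cohort.CohortBundle` (or equivalent loaded
  data) and returns results as objects — the workhorse for simulation
  studies.
* :func:`run_pipeline` is the file-level driver: it reads a cohort from
  disk (optionally generating it first), writes feature maps, labels,
  classification results, weight maps and a cluster table, and emits a
  manifest JSON with per-stage parameters and output hashes.

Feature paths follow the fixed stage order: the ALFF path smooths the
residual series *before* spectral analysis; the DC path computes degree
on unsmoothed lowpass-filtered residuals and smooths the *map* last, so
smoothing can never inflate the voxel-pair correlations that define
degree.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alff import VoxelMap, compute_alff, standardize_map
from .classification import (
    FeatureMatrix,
    assemble_features,
    combine_modalities,
    loocv,
    permutation_test,
    roc,
)
from .degree_centrality import DEFAULT_SWEEP, DcParams, compute_dc, dc_threshold_sweep
from .discrimination_map import cluster_table, fit_weight_map, threshold_weight_map
from .outcome_labels import label_cohort, read_clinical_csv, write_labels_tsv
from .preprocess import (
    BoldRun,
    FilterSpec,
    NuisanceSet,
    discard_initial,
    gaussian_smooth,
    motion_screen,
    regress_nuisance,
)
from .synthetic_cohort import (
    CohortBundle,
    generate_cohort,
    synthetic_config_from_dict,
    write_cohort,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "preprocess_run",
    "extract_feature_maps",
    "analyze_cohort",
    "run_pipeline",
    "load_cohort",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters, with study defaults.

    Defaults: 5 discarded volumes, joint nuisance regression with linear
    detrend, 6 mm FWHM smoothing, 0.01-0.08 Hz ALFF band, 0.08 Hz DC
    lowpass, r = 0.25 degree threshold (sweep 0.15-0.35), C = 1 linear
    SVM with 1,000 label permutations, 30% of max |w| weight threshold,
    20-voxel minimum cluster size, and 1.5 mm / 1.5 deg motion screening.
    """

    # paths (file mode; unused by analyze_cohort)
    data_dir: str | None = None
    output_dir: str | None = None
    simulate: bool = False
    synthetic: dict = field(default_factory=dict)
    # preprocessing
    n_discard: int = 5
    detrend: bool = True
    sequential_regression: bool = False
    fwhm_mm: float = 6.0
    smooth_before_dc: bool = False  # must stay False: DC smooths the map, never the series
    motion_screen_mm: float = 1.5
    motion_screen_deg: float = 1.5
    # ALFF band
    alff_low_hz: float = 0.01
    alff_high_hz: float = 0.08
    # degree centrality
    dc_lowpass_hz: float = 0.08
    r_threshold: float = 0.25
    dc_sweep: tuple[float, ...] = DEFAULT_SWEEP
    block_size: int = 2048
    # classifier
    c_param: float = 1.0
    scheme: str = "concatenate"
    n_permutations: int = 1000
    seed: int = 0
    whole_cohort_centering: bool = False  # CV centering stays per training fold by default
    # weight maps
    weight_fraction: float = 0.30
    min_cluster_size: int = 20
    session: str = "pre"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")
        if self.smooth_before_dc:
            raise ValueError(
                "smoothing the DC input series is not allowed: degree centrality "
                "is computed on unsmoothed series and the map is smoothed afterwards"
            )
        if not 0 < self.weight_fraction <= 1:
            raise ValueError("weight_fraction must be in (0, 1]")
        if self.scheme not in ("concatenate", "stack_samples"):
            raise ValueError(f"unknown combination scheme {self.scheme!r}")
        FilterSpec(self.alff_low_hz, self.alff_high_hz, "bandpass")
        DcParams(self.r_threshold, tuple(self.dc_sweep), self.block_size)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["dc_sweep"] = list(d["dc_sweep"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "dc_sweep" in d:
            d["dc_sweep"] = tuple(d["dc_sweep"])
        return cls(**d)


def preprocess_run(
    run: BoldRun, nuisance: NuisanceSet, mask: np.ndarray, cfg: PipelineConfig
) -> tuple[BoldRun, NuisanceSet]:
    """Discard initial volumes and regress nuisance signals.

    ``nuisance`` covers the acquired volumes and is truncated in step
    with the discarded volumes, so regressor rows always match the
    retained series.
    """
    run = discard_initial(run, cfg.n_discard)
    nuisance = nuisance.truncated(cfg.n_discard) if cfg.n_discard else nuisance
    resid = regress_nuisance(
        run, nuisance, mask, detrend=cfg.detrend, sequential=cfg.sequential_regression
    )
    return resid, nuisance


def extract_feature_maps(
    resid: BoldRun, mask: np.ndarray, cfg: PipelineConfig, want_sweep: bool = False
) -> dict:
    """Standardized ALFF and DC maps from a nuisance-regressed run.

    ALFF path: smooth the 4D residuals, band amplitude, standardize.
    DC path: lowpass the residuals, degree at ``r_threshold``,
    standardize, then smooth the standardized map.
    """
    from .preprocess import ideal_filter  # local import to keep module top light

    band = FilterSpec(cfg.alff_low_hz, cfg.alff_high_hz, "bandpass")
    smoothed = dataclasses.replace(
        resid, data=gaussian_smooth(resid.data, cfg.fwhm_mm, resid.voxel_size_mm)
    )
    alff_raw = compute_alff(smoothed, mask, band)
    alff_std = standardize_map(alff_raw)

    lp = FilterSpec(0.0, cfg.dc_lowpass_hz, "lowpass")
    filtered = dataclasses.replace(
        resid, data=ideal_filter(resid.data, resid.tr_s, lp).astype(resid.data.dtype)
    )
    params = DcParams(cfg.r_threshold, tuple(cfg.dc_sweep), cfg.block_size)
    out: dict = {}
    if want_sweep:
        sweep_maps = dc_threshold_sweep(filtered, mask, params)
        by_thr = {m.params["r_threshold"]: m for m in sweep_maps}
        if cfg.r_threshold in by_thr:
            dc_raw = by_thr[cfg.r_threshold]
        else:
            dc_raw = compute_dc(filtered, mask, params)
        out["dc_sweep_raw"] = sweep_maps
    else:
        dc_raw = compute_dc(filtered, mask, params)
    dc_std = standardize_map(dc_raw)
    dc_smoothed = dataclasses.replace(
        dc_std,
        values=gaussian_smooth(dc_std.values, cfg.fwhm_mm, resid.voxel_size_mm),
    )
    dc_smoothed.values[~mask] = 0.0

    out.update(
        alff_raw=alff_raw,
        alff=alff_std,
        dc_raw=dc_raw,
        dc=dc_smoothed,
    )
    return out


def analyze_cohort(
    bundle: CohortBundle,
    cfg: PipelineConfig | None = None,
    modalities: Sequence[str] = ("alff", "dc", "combined"),
    compute_weights: bool = True,
    n_permutations: int | None = None,
) -> dict:
    """Run the full prognosis analysis on one cohort, in memory.

    Returns a dict with per-modality feature matrices, cross-validation
    results, permutation results, ROC curves, and (for the combined
    features) the thresholded weight map and cluster table.
    """
    cfg = cfg or PipelineConfig()
    session = cfg.session
    mask = bundle.mask
    subjects = bundle.subject_ids()
    labels = label_cohort(bundle.clinical)

    alff_maps: dict[str, VoxelMap] = {}
    dc_maps: dict[str, VoxelMap] = {}
    screens = {}
    for sid in subjects:
        run = bundle.runs[(sid, session)]
        nuis = bundle.nuisance[(sid, session)]
        resid, nuis_t = preprocess_run(run, nuis, mask, cfg)
        screens[sid] = motion_screen(
            nuis_t.motion6, cfg.motion_screen_mm, cfg.motion_screen_deg
        )
        maps = extract_feature_maps(resid, mask, cfg)
        alff_maps[sid] = maps["alff"]
        dc_maps[sid] = maps["dc"]

    mat_alff = assemble_features(alff_maps, mask, subjects)
    mat_dc = assemble_features(dc_maps, mask, subjects)
    feature_sets: dict[str, FeatureMatrix] = {}
    if "alff" in modalities:
        feature_sets["alff"] = mat_alff
    if "dc" in modalities:
        feature_sets["dc"] = mat_dc
    if "combined" in modalities:
        feature_sets["combined"] = combine_modalities([mat_alff, mat_dc], cfg.scheme)

    n_perm = cfg.n_permutations if n_permutations is None else n_permutations
    results: dict = {
        "labels": labels,
        "motion_screens": screens,
        "features": feature_sets,
        "cv": {},
        "permutation": {},
        "roc": {},
    }
    centering = "cohort" if cfg.whole_cohort_centering else "fold"
    for name, mat in feature_sets.items():
        cv = loocv(mat, labels, cfg.c_param, centering)
        results["cv"][name] = cv
        results["roc"][name] = roc(cv)
        if n_perm > 0:
            results["permutation"][name] = permutation_test(
                mat, labels, n_permutations=n_perm, seed=cfg.seed,
                c_param=cfg.c_param, centering=centering,
            )

    if compute_weights and "combined" in feature_sets and cfg.scheme == "concatenate":
        wm = fit_weight_map(feature_sets["combined"], labels, mask, cfg.c_param)
        wm_thr = threshold_weight_map(wm, cfg.weight_fraction)
        results["weight_map"] = wm
        results["weight_map_thresholded"] = wm_thr
        results["clusters"] = cluster_table(wm_thr, cfg.min_cluster_size)
    return results


# ---------------------------------------------------------------------------
# file-level driver


def load_cohort(data_dir: str | Path) -> CohortBundle:
    """Load a cohort from the on-disk layout produced by ``write_cohort``."""
    import nibabel as nib

    data_dir = Path(data_dir)
    mask_img = nib.load(data_dir / "mask.nii.gz")
    mask = np.asarray(mask_img.dataobj).astype(bool)
    clinical = read_clinical_csv(data_dir / "clinical.csv")

    runs: dict[tuple[str, str], BoldRun] = {}
    nuisance: dict[tuple[str, str], NuisanceSet] = {}
    for bold_path in sorted(data_dir.glob("*_bold.nii.gz")):
        stem = bold_path.name.replace("_bold.nii.gz", "")
        sid, _, session = stem.rpartition("_ses-")
        img = nib.load(bold_path)
        if img.shape[:3] != mask.shape or not np.allclose(img.affine, mask_img.affine):
            raise ValueError(f"grid/affine mismatch between {bold_path.name} and mask")
        zooms = img.header.get_zooms()
        runs[(sid, session)] = BoldRun(
            data=np.asarray(img.dataobj, dtype=np.float32),
            tr_s=float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0,
            voxel_size_mm=tuple(float(z) for z in zooms[:3]),
            subject_id=sid,
            session=session,
        )
        motion = np.loadtxt(data_dir / f"{stem}_motion.txt")
        signals = np.loadtxt(data_dir / f"{stem}_nuisance_signals.txt")
        nuisance[(sid, session)] = NuisanceSet(
            motion6=motion, wm_signal=signals[:, 0], csf_signal=signals[:, 1]
        )
    if not runs:
        raise ValueError(f"no *_bold.nii.gz runs found in {data_dir}")
    return CohortBundle(
        runs=runs, mask=mask, nuisance=nuisance, clinical=clinical, truth={},
        affine=np.asarray(mask_img.affine),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _save_map(vmap: VoxelMap, affine: np.ndarray, path: Path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(vmap.values.astype(np.float32), affine), path)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full file-level pipeline and write a manifest.

    Stages: (optional) simulate -> preprocess+features -> labels ->
    classification (ALFF, DC, combined) -> weight maps.  Any stage error
    aborts with the failing stage named and leaves a ``FAILED`` marker in
    the output directory; on success the manifest JSON records config,
    software version, per-stage parameters, elapsed time, and SHA-256
    hashes of every output file.
    """
    if cfg.output_dir is None:
        raise ValueError("output_dir is required")
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {**dataclasses.asdict(cfg), "dc_sweep": list(cfg.dc_sweep)},
        "coordinate_convention": "0-based voxel indices; world mm via NIfTI affine",
        "stages": [],
    }
    stage = "setup"
    try:
        if cfg.simulate:
            stage = "simulate"
            t0 = time.perf_counter()
            syn = synthetic_config_from_dict({"seed": cfg.seed, **cfg.synthetic})
            bundle = generate_cohort(syn)
            sim_dir = Path(cfg.data_dir) if cfg.data_dir else outdir / "cohort"
            write_cohort(bundle, sim_dir, syn)
            manifest["stages"].append(
                {"stage": stage, "elapsed_s": round(time.perf_counter() - t0, 3),
                 "n_subjects": syn.n_subjects, "seed": syn.seed}
            )
        else:
            if cfg.data_dir is None:
                raise ValueError("data_dir is required when simulate is false")
            sim_dir = Path(cfg.data_dir)

        stage = "load"
        bundle = load_cohort(sim_dir)
        affine = bundle.grid_affine()

        stage = "features"
        import nibabel as nib

        t0 = time.perf_counter()
        results = analyze_cohort(bundle, cfg, compute_weights=(cfg.scheme == "concatenate"))
        maps_dir = outdir / "maps"
        maps_dir.mkdir(exist_ok=True)
        outputs: dict[str, str] = {}
        # per-subject standardized maps, re-scattered from the feature rows
        for name in ("alff", "dc"):
            if name not in results["features"]:
                continue
            mat = results["features"][name]
            coords = mat.voxel_index[["x", "y", "z"]].to_numpy()
            for row, sid in zip(mat.values, mat.subject_ids):
                vol = np.zeros(bundle.mask.shape, dtype=np.float32)
                vol[coords[:, 0], coords[:, 1], coords[:, 2]] = row
                path = maps_dir / f"{sid}_{name}_std.nii"
                nib.save(nib.Nifti1Image(vol, affine), path)
                outputs[str(path.relative_to(outdir))] = _sha256(path)
        manifest["stages"].append(
            {"stage": stage, "elapsed_s": round(time.perf_counter() - t0, 3),
             "outputs": outputs}
        )

        stage = "labels"
        labels_path = outdir / "labels.tsv"
        write_labels_tsv(results["labels"], labels_path)
        manifest["stages"].append(
            {"stage": stage, "outputs": {"labels.tsv": _sha256(labels_path)}}
        )

        stage = "classify"
        t0 = time.perf_counter()
        summary = {}
        for name, cv in results["cv"].items():
            perm = results["permutation"].get(name)
            curve = results["roc"][name]
            summary[name] = {
                "total_accuracy": cv.total_accuracy,
                "sensitivity": cv.sensitivity,
                "specificity": cv.specificity,
                "auc": curve.auc,
                "p_value": perm.p_value if perm else None,
                "n_permutations": perm.n_permutations if perm else 0,
            }
            roc_path = outdir / f"roc_{name}.tsv"
            pd.DataFrame(curve.points, columns=["fpr", "tpr"]).to_csv(
                roc_path, sep="\t", index=False
            )
            folds_path = outdir / f"folds_{name}.tsv"
            cv.folds.to_csv(folds_path, sep="\t", index=False)
        results_path = outdir / "classification.json"
        results_path.write_text(json.dumps(summary, indent=2))
        manifest["stages"].append(
            {"stage": stage, "elapsed_s": round(time.perf_counter() - t0, 3),
             "outputs": {"classification.json": _sha256(results_path)}}
        )

        if "weight_map_thresholded" in results:
            stage = "weights"
            import nibabel as nib

            wm_outputs = {}
            for modality, vol in results["weight_map"].volumes.items():
                p = outdir / f"weights_{modality}.nii"
                nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), p)
                wm_outputs[p.name] = _sha256(p)
            for modality, vol in results["weight_map_thresholded"].volumes.items():
                p = outdir / f"weights_{modality}_thresholded.nii"
                nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), p)
                wm_outputs[p.name] = _sha256(p)
            clusters_path = outdir / "clusters.tsv"
            results["clusters"].to_csv(clusters_path, sep="\t", index=False)
            wm_outputs["clusters.tsv"] = _sha256(clusters_path)
            manifest["stages"].append({"stage": stage, "outputs": wm_outputs})

        stage = "manifest"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
    results["manifest"] = manifest
    return results
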