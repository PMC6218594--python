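"""Synthetic BOLD cohort generator.

Emulates a small longitudinal PTSD treatment cohort: per subject one or
two resting-state BOLD runs (TR 2 s, 205 acquired volumes) on a common
voxel grid with an ellipsoidal brain mask, motion and WM/CSF nuisance
traces, and a CAPS trajectory (baseline, post-treatment, 2-year
follow-up) whose follow-up improvement defines the remitted/persistent
outcome.

Generative model, per voxel time series::

    x_v(t) = sum_l A[v, l] * s_l(t)  +  AR(1) noise

where the latents ``s_l`` are band-limited (0.01-0.08 Hz) Gaussian
processes sampled at TR and the noise has lag-1 autocorrelation
``ar_coef`` and marginal SD ``noise_sd``.  Baseline voxels load on a
single latent chosen by spatial slab; two kinds of group effects can be
injected:

* *ALFF effect regions* scale the voxel's whole latent (band-limited)
  component by a group-specific amplitude multiplier, raising
  low-frequency amplitude without targeting connectivity.
* *Hub effect regions* replace the loading row with a group-specific
  loading on ALL latents, raising pairwise correlation with every slab
  and hence binarized degree.

Setting all multipliers to 1 and identical hub loadings in both groups
yields a null cohort in which the outcome label is independent of every
time series.  Everything is reproducible from ``seed``.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, signal, stats

from .outcome_labels import REMITTED, PERSISTENT, ClinicalRecord, classify_outcome
from .preprocess import BoldRun, FilterSpec, NuisanceSet, ideal_filter

__all__ = [
    "RegionSpec",
    "SyntheticConfig",
    "CohortBundle",
    "ellipsoid_mask",
    "generate_cohort",
    "generate_clinical",
    "write_cohort",
]


class ConfigurationError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass(frozen=True)
class RegionSpec:
    """A spherical effect region with one value per outcome group.

    For ALFF regions the values are amplitude multipliers; for hub
    regions they are shared-latent loadings.
    """

    center: tuple[int, int, int]
    radius: float
    remitted: float
    persistent: float

    def voxel_mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.ogrid[: grid_shape[0], : grid_shape[1], : grid_shape[2]]
        d2 = sum((g - c) ** 2 for g, c in zip(grids, self.center))
        return d2 <= self.radius**2

    def value(self, group: str) -> float:
        return self.remitted if group == REMITTED else self.persistent


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level generator settings.

    Defaults mirror the emulated study: 20 followed-up subjects with a
    9 remitted / 11 persistent split, TR 2 s, 205 acquired volumes, and a
    baseline CAPS distribution with mean 67.3 and SD 14.5 truncated to
    the instrument-plausible range for a diagnosed cohort.
    """

    n_subjects: int = 20
    n_remitted: int = 9
    grid_shape: tuple[int, int, int] = (18, 18, 18)
    voxel_size_mm: tuple[float, float, float] = (5.0, 5.0, 5.0)
    n_volumes: int = 205
    tr_s: float = 2.0
    alff_effect_regions: tuple[RegionSpec, ...] = (
        RegionSpec(center=(5, 9, 9), radius=3.0, remitted=2.0, persistent=1.0),
    )
    hub_effect_regions: tuple[RegionSpec, ...] = (
        RegionSpec(center=(12, 9, 9), radius=3.0, remitted=1.2, persistent=0.2),
    )
    n_latents: int = 3
    noise_sd: float = 1.0
    ar_coef: float = 0.3
    baseline_loading: float = 0.6
    signal_low_hz: float = 0.01
    signal_high_hz: float = 0.08
    sessions: tuple[str, ...] = ("pre",)
    post_attenuation: float = 0.5
    randomize_assignment: bool = False
    caps_mean: float = 67.3
    caps_sd: float = 14.5
    caps_floor: float = 45.0
    caps_ceiling: float = 136.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_remitted <= self.n_subjects:
            raise ConfigurationError(
                f"n_remitted={self.n_remitted} must lie in [0, n_subjects={self.n_subjects}]"
            )
        if self.tr_s <= 0 or self.noise_sd <= 0:
            raise ConfigurationError("tr_s and noise_sd must be positive")
        if not 0 <= self.ar_coef < 1:
            raise ConfigurationError("ar_coef must be in [0, 1)")
        if self.n_latents < 1:
            raise ConfigurationError("need at least one latent signal")
        for region in (*self.alff_effect_regions, *self.hub_effect_regions):
            if region.radius < 1:
                raise ConfigurationError("region radius must be >= 1 voxel")
            for axis, (c, n) in enumerate(zip(region.center, self.grid_shape)):
                if c - region.radius < 0 or c + region.radius > n - 1:
                    raise ConfigurationError(
                        f"region at {region.center} (radius {region.radius}) leaves the "
                        f"grid along axis {axis} (size {n})"
                    )
        for s in self.sessions:
            if s not in ("pre", "post"):
                raise ConfigurationError(f"unknown session {s!r}")

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """A no-effect cohort: group label independent of every time series."""
        base = cls(seed=seed, **overrides)
        return SyntheticConfig(
            **{
                **asdict_shallow(base),
                "alff_effect_regions": tuple(
                    RegionSpec(r.center, r.radius, 1.0, 1.0) for r in base.alff_effect_regions
                ),
                "hub_effect_regions": tuple(
                    RegionSpec(r.center, r.radius, base.baseline_loading, base.baseline_loading)
                    for r in base.hub_effect_regions
                ),
            }
        )

    def signal_band(self) -> FilterSpec:
        return FilterSpec(self.signal_low_hz, self.signal_high_hz, "bandpass")


def asdict_shallow(cfg: SyntheticConfig) -> dict:
    """Dataclass fields without recursing into RegionSpec tuples."""
    return {f: getattr(cfg, f) for f in cfg.__dataclass_fields__}


def synthetic_config_from_dict(d: dict) -> SyntheticConfig:
    """Build a config from plain (YAML/JSON) values; region dicts accepted."""
    d = dict(d)
    for key in ("alff_effect_regions", "hub_effect_regions"):
        if key in d:
            d[key] = tuple(
                r if isinstance(r, RegionSpec)
                else RegionSpec(center=tuple(r["center"]), radius=float(r["radius"]),
                                remitted=float(r["remitted"]), persistent=float(r["persistent"]))
                for r in d[key]
            )
    for key in ("grid_shape", "voxel_size_mm", "sessions"):
        if key in d:
            d[key] = tuple(d[key])
    return SyntheticConfig(**d)


@dataclass
class CohortBundle:
    """Everything the pipeline needs for one synthetic cohort.

    ``runs`` and ``nuisance`` are keyed by ``(subject_id, session)``;
    nuisance traces cover all *acquired* volumes and are truncated
    alongside volume discarding.  ``truth`` records the injected effects
    and group assignment.
    """

    runs: dict[tuple[str, str], BoldRun]
    mask: np.ndarray
    nuisance: dict[tuple[str, str], NuisanceSet]
    clinical: list[ClinicalRecord]
    truth: dict
    affine: np.ndarray | None = None

    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.clinical]

    def grid_affine(self) -> np.ndarray:
        """Voxel-to-world affine; falls back to a diagonal from voxel size."""
        if self.affine is not None:
            return self.affine
        voxel = self.runs[next(iter(self.runs))].voxel_size_mm
        return np.diag([*voxel, 1.0])


def ellipsoid_mask(grid_shape: Sequence[int]) -> np.ndarray:
    """Ellipsoidal 'brain' mask centered in the grid, one voxel of margin."""
    grid_shape = tuple(grid_shape)
    grids = np.ogrid[[slice(0, n) for n in grid_shape]]
    centers = [(n - 1) / 2.0 for n in grid_shape]
    semi = [max(n / 2.0 - 1.0, 1.0) for n in grid_shape]
    d2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, centers, semi))
    return d2 <= 1.0


def group_assignment(cfg: SyntheticConfig) -> list[str]:
    """Outcome group per subject index.

    Deterministic by default (first ``n_remitted`` indices remitted) so
    truth bookkeeping stays trivial; ``randomize_assignment`` permutes
    the assignment reproducibly from the seed.
    """
    groups = [REMITTED] * cfg.n_remitted + [PERSISTENT] * (cfg.n_subjects - cfg.n_remitted)
    if cfg.randomize_assignment:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(3,)))
        groups = [groups[i] for i in rng.permutation(cfg.n_subjects)]
    return groups


def subject_ids(cfg: SyntheticConfig) -> list[str]:
    width = max(2, len(str(cfg.n_subjects)))
    return [f"sub-{i + 1:0{width}d}" for i in range(cfg.n_subjects)]


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...], sd: float, a: float) -> np.ndarray:
    """AR(1) series along the last axis with marginal SD ``sd``."""
    innov = rng.standard_normal(shape) * (sd * np.sqrt(1.0 - a * a))
    if a == 0:
        return innov
    return signal.lfilter([1.0], [1.0, -a], innov, axis=-1)


def _band_limited_latents(
    rng: np.random.Generator, n_latents: int, t: int, tr_s: float, band: FilterSpec
) -> np.ndarray:
    """Unit-SD latents confined to the signal band (zero mean by construction)."""
    raw = rng.standard_normal((n_latents, t))
    filtered = ideal_filter(raw, tr_s, band)
    sd = filtered.std(axis=-1, keepdims=True)
    return filtered / np.where(sd > 0, sd, 1.0)


def _loading_matrix(
    cfg: SyntheticConfig, mask: np.ndarray, group: str, session: str
) -> np.ndarray:
    """Per-voxel latent loadings for one subject's group and session.

    The 'post' session attenuates injected group contrasts toward the
    across-group mean by ``post_attenuation``, mimicking effects washed
    out by treatment.
    """
    coords = np.nonzero(mask)
    n_vox = coords[0].size
    nx = cfg.grid_shape[0]
    slab = np.minimum((coords[0] * cfg.n_latents) // nx, cfg.n_latents - 1)
    a = np.zeros((n_vox, cfg.n_latents))
    a[np.arange(n_vox), slab] = cfg.baseline_loading

    def effective(region: RegionSpec) -> float:
        v = region.value(group)
        if session == "post":
            mid = 0.5 * (region.remitted + region.persistent)
            v = mid + cfg.post_attenuation * (v - mid)
        return v

    for region in cfg.hub_effect_regions:
        inside = region.voxel_mask(cfg.grid_shape)[mask]
        a[inside, :] = effective(region)
    for region in cfg.alff_effect_regions:
        inside = region.voxel_mask(cfg.grid_shape)[mask]
        a[inside, :] *= effective(region)
    return a


def _run_seed(cfg: SyntheticConfig, subject_idx: int, session: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(cfg.seed, spawn_key=(subject_idx, cfg.sessions.index(session)))


def generate_cohort(cfg: SyntheticConfig) -> CohortBundle:
    """Generate BOLD runs, nuisance traces, and clinical records for a cohort."""
    mask = ellipsoid_mask(cfg.grid_shape)
    groups = group_assignment(cfg)
    ids = subject_ids(cfg)
    band = cfg.signal_band()
    t = cfg.n_volumes

    runs: dict[tuple[str, str], BoldRun] = {}
    nuisance: dict[tuple[str, str], NuisanceSet] = {}
    for idx, (sid, group) in enumerate(zip(ids, groups)):
        for session in cfg.sessions:
            rng = np.random.default_rng(_run_seed(cfg, idx, session))
            latents = _band_limited_latents(rng, cfg.n_latents, t, cfg.tr_s, band)
            loadings = _loading_matrix(cfg, mask, group, session)
            series = loadings @ latents + _ar1_noise(
                rng, (int(mask.sum()), t), cfg.noise_sd, cfg.ar_coef
            )
            data = np.zeros((*cfg.grid_shape, t), dtype=np.float32)
            data[mask] = series.astype(np.float32)
            runs[(sid, session)] = BoldRun(
                data=data,
                tr_s=cfg.tr_s,
                voxel_size_mm=cfg.voxel_size_mm,
                subject_id=sid,
                session=session,
            )
            motion = np.cumsum(
                rng.normal(scale=[0.02, 0.02, 0.02, 5e-4, 5e-4, 5e-4], size=(t, 6)), axis=0
            )
            nuisance[(sid, session)] = NuisanceSet(
                motion6=motion,
                wm_signal=_ar1_noise(rng, (t,), 1.0, cfg.ar_coef),
                csf_signal=_ar1_noise(rng, (t,), 1.0, cfg.ar_coef),
            )

    clinical = generate_clinical(cfg)
    labels = [classify_outcome(r).label for r in clinical]
    if labels != groups:  # pragma: no cover - construction guarantees agreement
        raise RuntimeError("clinical records disagree with truth assignment")

    truth = {
        "groups": dict(zip(ids, groups)),
        "alff_effect_regions": [asdict(r) for r in cfg.alff_effect_regions],
        "hub_effect_regions": [asdict(r) for r in cfg.hub_effect_regions],
        "seed": cfg.seed,
    }
    return CohortBundle(runs=runs, mask=mask, nuisance=nuisance, clinical=clinical, truth=truth)


@functools.lru_cache(maxsize=8)
def _truncnorm_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Location/scale of the parent normal so the truncated law has the
    requested mean and SD.

    Truncating a normal at the instrument floor shifts its mean upward,
    so the parent parameters are solved for numerically rather than set
    to the target moments.
    """

    def moments(p):
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        dist = stats.truncnorm(a, b, loc=mu, scale=sigma)
        return [dist.mean() - mean, dist.std() - sd]

    (mu, log_sigma), info, ok, msg = optimize.fsolve(
        moments, x0=[mean, np.log(sd)], full_output=True
    )
    if ok != 1:  # pragma: no cover
        raise RuntimeError(f"truncated-normal moment matching failed: {msg}")
    return float(mu), float(np.exp(log_sigma))


def generate_clinical(cfg: SyntheticConfig) -> list[ClinicalRecord]:
    """CAPS trajectories consistent with the configured outcome split.

    Baseline scores follow a truncated normal whose truncated mean/SD
    match ``caps_mean``/``caps_sd`` on ``[caps_floor, caps_ceiling]``.
    Acute (post-treatment) improvement is at least 50% for everyone;
    follow-up improvement is drawn >= 0.5 for designated remitted
    subjects and < 0.5 otherwise, so outcome labeling recovers the truth
    assignment exactly.
    """
    groups = group_assignment(cfg)
    ids = subject_ids(cfg)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1_000_003,)))

    mu, sigma = _truncnorm_params(cfg.caps_mean, cfg.caps_sd, cfg.caps_floor, cfg.caps_ceiling)
    a, b = (cfg.caps_floor - mu) / sigma, (cfg.caps_ceiling - mu) / sigma
    caps_pre = stats.truncnorm(a, b, loc=mu, scale=sigma).rvs(cfg.n_subjects, random_state=rng)

    records = []
    for sid, group, pre in zip(ids, groups, caps_pre):
        acute_imp = rng.uniform(0.52, 0.90)
        follow_imp = (
            rng.uniform(0.50, 0.95) if group == REMITTED else rng.uniform(-0.20, 0.45)
        )
        records.append(
            ClinicalRecord(
                subject_id=sid,
                caps_pre=float(pre),
                caps_post=float(pre * (1.0 - acute_imp)),
                caps_followup=float(np.clip(pre * (1.0 - follow_imp), 0.0, cfg.caps_ceiling)),
            )
        )
    return records


def write_cohort(bundle: CohortBundle, outdir: str | Path, cfg: SyntheticConfig | None = None) -> dict:
    """Write a cohort to disk in the pipeline's on-disk layout.

    NIfTI-1 runs and mask, SPM-style whitespace 6-column motion text
    files plus WM/CSF trace files, a clinical CSV, and a truth JSON.
    Returns a manifest of the written paths.
    """
    import nibabel as nib
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    voxel = bundle.runs[next(iter(bundle.runs))].voxel_size_mm
    affine = bundle.grid_affine()

    paths: dict[str, str] = {}
    mask_path = outdir / "mask.nii.gz"
    nib.save(nib.Nifti1Image(bundle.mask.astype(np.uint8), affine), mask_path)
    paths["mask"] = str(mask_path)

    for (sid, session), run in bundle.runs.items():
        stem = f"{sid}_ses-{session}"
        img = nib.Nifti1Image(run.data.astype(np.float32), affine)
        img.header.set_zooms((*voxel, run.tr_s))
        nib.save(img, outdir / f"{stem}_bold.nii.gz")
        nuis = bundle.nuisance[(sid, session)]
        np.savetxt(outdir / f"{stem}_motion.txt", nuis.motion6, fmt="%.8f")
        np.savetxt(
            outdir / f"{stem}_nuisance_signals.txt",
            np.column_stack([nuis.wm_signal, nuis.csf_signal]),
            fmt="%.8f",
            header="wm csf",
        )
        paths[stem] = str(outdir / f"{stem}_bold.nii.gz")

    clinical_path = outdir / "clinical.csv"
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "caps_pre": r.caps_pre,
                "caps_post": r.caps_post,
                "caps_followup": r.caps_followup,
            }
            for r in bundle.clinical
        ]
    ).to_csv(clinical_path, index=False)
    paths["clinical"] = str(clinical_path)

    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(bundle.truth, indent=2))
    paths["truth"] = str(truth_path)
    if cfg is not None:
        cfg_path = outdir / "synthetic_config.json"
        cfg_path.write_text(json.dumps(asdict(cfg), indent=2, default=list))
        paths["config"] = str(cfg_path)
    return paths
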