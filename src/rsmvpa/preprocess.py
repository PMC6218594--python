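"""Post-alignment BOLD preprocessing.

The functions here implement the denoising steps that sit between a
spatially aligned 4D BOLD run and feature extraction: discarding initial
volumes (magnetization saturation), nuisance regression against white
matter / CSF signals and the Friston 24-parameter motion expansion,
rectangular (ideal) frequency filtering, and Gaussian spatial smoothing.

Global signal regression is deliberately not offered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "BoldRun",
    "NuisanceSet",
    "FilterSpec",
    "MotionScreen",
    "discard_initial",
    "friston24",
    "regress_nuisance",
    "ideal_filter",
    "gaussian_smooth",
    "motion_screen",
]


@dataclass
class BoldRun:
    """One subject-session 4D time series on a fixed voxel grid.

    ``data`` is indexed ``(x, y, z, t)``; units are arbitrary BOLD signal.
    """

    data: np.ndarray
    tr_s: float
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    subject_id: str = ""
    session: str = "pre"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D (x, y, z, t), got ndim={self.data.ndim}")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD run needs at least 2 volumes")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)


@dataclass
class NuisanceSet:
    """Per-run nuisance signals: 6 motion parameters, WM and CSF means.

    Motion columns are three translations (mm) followed by three rotations
    (radians).  Row count must equal the run's post-discard volume count.
    """

    motion6: np.ndarray
    wm_signal: np.ndarray
    csf_signal: np.ndarray

    def __post_init__(self) -> None:
        self.motion6 = np.atleast_2d(np.asarray(self.motion6, dtype=float))
        self.wm_signal = np.asarray(self.wm_signal, dtype=float).ravel()
        self.csf_signal = np.asarray(self.csf_signal, dtype=float).ravel()
        if self.motion6.shape[1] != 6:
            raise ValueError(f"motion6 must have 6 columns, got {self.motion6.shape[1]}")
        t = self.motion6.shape[0]
        if self.wm_signal.shape[0] != t or self.csf_signal.shape[0] != t:
            raise ValueError("wm/csf signal length must match motion row count")

    @property
    def n_timepoints(self) -> int:
        return self.motion6.shape[0]

    def truncated(self, n_discard: int) -> "NuisanceSet":
        """Drop the first ``n_discard`` rows (mirrors volume discarding)."""
        return NuisanceSet(
            motion6=self.motion6[n_discard:],
            wm_signal=self.wm_signal[n_discard:],
            csf_signal=self.csf_signal[n_discard:],
        )


@dataclass(frozen=True)
class FilterSpec:
    """Rectangular frequency band, inclusive at both edges.

    ``mode='lowpass'`` keeps everything from DC up to ``high_hz``;
    ``mode='bandpass'`` keeps ``low_hz <= f <= high_hz``.
    """

    low_hz: float
    high_hz: float
    mode: Literal["bandpass", "lowpass"] = "bandpass"

    def __post_init__(self) -> None:
        if self.low_hz < 0:
            raise ValueError("low_hz must be >= 0")
        if self.high_hz <= self.low_hz:
            raise ValueError("high_hz must exceed low_hz")
        if self.mode not in ("bandpass", "lowpass"):
            raise ValueError(f"unknown filter mode {self.mode!r}")


@dataclass(frozen=True)
class MotionScreen:
    """Head-motion report for one run (no automatic exclusion)."""

    max_translation_mm: float
    max_rotation_deg: float
    exceeded: bool


def discard_initial(run: BoldRun, n_discard: int) -> BoldRun:
    """Remove the first ``n_discard`` volumes of a run.

    The leading volumes of an EPI acquisition are contaminated by
    magnetization saturation and subject habituation, so they are dropped
    before any statistic is computed.
    """
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= run.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {run.n_volumes} volumes: nothing would remain"
        )
    if n_discard == 0:
        return run
    return replace(run, data=run.data[..., n_discard:])


def friston24(motion6: np.ndarray) -> np.ndarray:
    """Expand 6 rigid-body motion parameters to the 24-regressor set.

    Column blocks, in order: the 6 parameters ``p_t``, their one-volume
    lags ``p_{t-1}`` (first row zero-padded), the squares ``p_t**2``, and
    the squared lags ``p_{t-1}**2``.
    """
    motion6 = np.atleast_2d(np.asarray(motion6, dtype=float))
    if motion6.shape[1] != 6:
        raise ValueError(f"expected 6 motion columns, got {motion6.shape[1]}")
    if motion6.shape[0] < 2:
        raise ValueError("need at least 2 timepoints")
    lagged = np.vstack([np.zeros((1, 6)), motion6[:-1]])
    return np.hstack([motion6, lagged, motion6**2, lagged**2])


def _nuisance_design(nuisance: NuisanceSet, detrend: bool = True) -> np.ndarray:
    t = nuisance.n_timepoints
    cols = [np.ones(t)]
    if detrend:
        cols.append(np.linspace(-1.0, 1.0, t))
    cols.append(nuisance.wm_signal)
    cols.append(nuisance.csf_signal)
    design = np.column_stack(cols + [friston24(nuisance.motion6)])
    return design


def regress_nuisance(
    run: BoldRun,
    nuisance: NuisanceSet,
    mask: np.ndarray,
    detrend: bool = True,
    sequential: bool = False,
) -> BoldRun:
    """Residualize every in-mask voxel time series against nuisance signals.

    The design holds an intercept, an optional linear trend, the WM and CSF
    signals, and the Friston-24 motion expansion.  By default all regressors
    are fit jointly in one least-squares problem (pseudoinverse, so
    rank-deficient designs are handled); ``sequential=True`` instead
    residualizes stagewise (trend, then WM, then CSF, then motion) for
    comparison with toolchains that regress covariates one at a time.
    Out-of-mask voxels are zeroed.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != run.grid_shape:
        raise ValueError(f"mask shape {mask.shape} does not match run grid {run.grid_shape}")
    t = run.n_volumes
    if nuisance.n_timepoints != t:
        raise ValueError(
            f"nuisance rows ({nuisance.n_timepoints}) must match run volumes ({t})"
        )

    y = run.data[mask].astype(np.float64, copy=False).T  # t x n_vox

    if sequential:
        first = [np.ones(t)] + ([np.linspace(-1.0, 1.0, t)] if detrend else [])
        stages = [
            np.column_stack(first),
            np.column_stack([np.ones(t), nuisance.wm_signal]),
            np.column_stack([np.ones(t), nuisance.csf_signal]),
            np.column_stack([np.ones(t), friston24(nuisance.motion6)]),
        ]
        resid = y
        for x in stages:
            resid = resid - x @ (np.linalg.pinv(x) @ resid)
    else:
        x = _nuisance_design(nuisance, detrend=detrend)
        resid = y - x @ (np.linalg.pinv(x) @ y)

    out = np.zeros(run.data.shape, dtype=np.float64)
    out[mask] = resid.T
    return replace(run, data=out)


def ideal_filter(series: np.ndarray, tr_s: float, spec: FilterSpec) -> np.ndarray:
    """Rectangular DFT-domain filter applied along the last axis.

    Frequency bins with ``low_hz <= f_k <= high_hz`` (inclusive; lowpass
    additionally keeps the DC bin) are retained, all others zeroed, and the
    series inverse-transformed.  Being a projection, the filter is
    idempotent.
    """
    series = np.asarray(series, dtype=np.float64)
    t = series.shape[-1]
    if t < 4:
        raise ValueError("need at least 4 timepoints to filter")
    nyq = 1.0 / (2.0 * tr_s)
    if spec.high_hz > nyq * (1.0 + 1e-9):
        raise ValueError(f"high_hz={spec.high_hz} exceeds Nyquist {nyq} for TR={tr_s}")
    freqs = np.fft.rfftfreq(t, d=tr_s)
    tol = 1e-9
    if spec.mode == "lowpass":
        keep = freqs <= spec.high_hz * (1.0 + tol)
    else:
        keep = (freqs >= spec.low_hz * (1.0 - tol)) & (freqs <= spec.high_hz * (1.0 + tol))
    spec_f = np.fft.rfft(series, axis=-1)
    spec_f[..., ~keep] = 0.0
    return np.fft.irfft(spec_f, n=t, axis=-1)


def gaussian_smooth(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: tuple[float, float, float],
) -> np.ndarray:
    """Separable spatial Gaussian smoothing of a 3D volume or 4D series.

    ``fwhm_mm`` is converted to a per-axis sigma in voxels via
    ``sigma = FWHM / (2 sqrt(2 ln 2)) / voxel_size``.  Boundaries are
    zero-padded; a 4D input is smoothed volume-by-volume (no temporal
    blurring).  ``fwhm_mm == 0`` is the identity.
    """
    volume = np.asarray(volume)
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if volume.ndim not in (3, 4):
        raise ValueError("expected a 3D volume or 4D series")
    if fwhm_mm == 0:
        return volume.copy()
    sigmas = [fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / v for v in voxel_size_mm]
    if volume.ndim == 4:
        sigmas = sigmas + [0.0]
    return ndimage.gaussian_filter(volume.astype(np.float64, copy=False), sigma=sigmas, mode="constant", cval=0.0)


def motion_screen(
    motion6: np.ndarray,
    translation_thresh_mm: float = 1.5,
    rotation_thresh_deg: float = 1.5,
) -> MotionScreen:
    """Report whether a run's motion exceeds the screening thresholds.

    This is a report, not an exclusion: the caller decides what to do with
    flagged runs.
    """
    motion6 = np.atleast_2d(np.asarray(motion6, dtype=float))
    if motion6.shape[1] != 6:
        raise ValueError("expected 6 motion columns")
    max_trans = float(np.max(np.abs(motion6[:, :3])))
    max_rot = float(np.degrees(np.max(np.abs(motion6[:, 3:]))))
    return MotionScreen(
        max_translation_mm=max_trans,
        max_rotation_deg=max_rot,
        exceeded=(max_trans > translation_thresh_mm or max_rot > rotation_thresh_deg),
    )
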