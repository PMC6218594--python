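"""Amplitude of low-frequency fluctuations (ALFF).

ALFF indexes regional spontaneous activity as the mean one-sided DFT
amplitude of a voxel's time series inside a low-frequency band
(conventionally 0.01-0.08 Hz).  Maps are made comparable across subjects
by dividing by the within-mask global mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .preprocess import BoldRun, FilterSpec

__all__ = ["VoxelMap", "alff_band_bins", "compute_alff", "standardize_map"]


@dataclass
class VoxelMap:
    """One scalar per in-mask voxel on a 3D grid (ALFF or DC).

    ``values`` is zero outside ``mask``.  ``standardized`` records whether
    the map has been divided by its in-mask mean.
    """

    values: np.ndarray
    mask: np.ndarray
    modality: str
    standardized: bool = False
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("VoxelMap values must be 3D")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite in-mask values")

    @property
    def in_mask_values(self) -> np.ndarray:
        return self.values[self.mask]


def alff_band_bins(n_timepoints: int, tr_s: float, band: FilterSpec) -> np.ndarray:
    """Indices of DFT bins inside the ALFF band (inclusive endpoints).

    Bin ``k`` sits at ``f_k = k / (t * TR)`` Hz; the DC bin is never part
    of the band because ``low_hz`` must be positive.
    """
    if band.low_hz <= 0:
        raise ValueError("ALFF band must have low_hz > 0 (DC bin excluded)")
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_s)
    tol = 1e-9
    keep = (freqs >= band.low_hz * (1.0 - tol)) & (freqs <= band.high_hz * (1.0 + tol))
    bins = np.nonzero(keep)[0]
    if bins.size == 0:
        raise ValueError(
            f"band [{band.low_hz}, {band.high_hz}] Hz contains no DFT bins for "
            f"t={n_timepoints}, TR={tr_s}s (bin spacing {1.0 / (n_timepoints * tr_s):.6g} Hz)"
        )
    return bins


def compute_alff(run: BoldRun, mask: np.ndarray, band: FilterSpec) -> VoxelMap:
    """Raw ALFF map of a (nuisance-regressed, smoothed) run.

    Per in-mask voxel the series is transformed with an un-tapered,
    un-padded DFT (transform length = series length); the one-sided
    amplitude at bin ``k`` is ``2 |X_k| / t``, so an on-bin unit-amplitude
    sinusoid reads out amplitude 1.  ALFF is the mean amplitude over the
    band's bins.  Any fixed amplitude convention cancels under global-mean
    standardization; this one is chosen for its interpretability.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != run.grid_shape:
        raise ValueError("mask does not match run grid")
    t = run.n_volumes
    bins = alff_band_bins(t, run.tr_s, band)
    series = run.data[mask].astype(np.float64, copy=False)
    spectrum = np.fft.rfft(series, axis=-1)[:, bins]
    amplitude = 2.0 * np.abs(spectrum) / t
    values = np.zeros(mask.shape, dtype=np.float64)
    values[mask] = amplitude.mean(axis=-1)
    return VoxelMap(
        values=values,
        mask=mask,
        modality="alff",
        standardized=False,
        params={"low_hz": band.low_hz, "high_hz": band.high_hz,
                "bins": (int(bins[0]), int(bins[-1])), "tr_s": run.tr_s},
    )


def standardize_map(vmap: VoxelMap) -> VoxelMap:
    """Divide a map by its in-mask mean (global-mean standardization).

    Standardized maps have in-mask mean exactly 1, making them comparable
    across subjects regardless of raw signal scale.  Idempotent.
    """
    mean = float(vmap.in_mask_values.mean())
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError(f"in-mask mean must be positive and finite, got {mean}")
    values = vmap.values / mean
    values[~vmap.mask] = 0.0
    return replace(vmap, values=values, standardized=True)
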