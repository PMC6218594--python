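"""Binarized voxelwise degree centrality (DC).

For every in-mask voxel, DC counts how many other in-mask voxels its
time series correlates with above a Pearson threshold (positive
correlations only, strict inequality).  The count is a graph degree on
the binarized whole-mask connectivity matrix and indexes functional
integration ("hubness").

The implementation is blocked: time series are z-scored once, then
pairwise correlation blocks of at most ``block_size`` rows are formed and
reduced to per-voxel counts, so peak memory is bounded by
``block_size * n_voxels`` regardless of mask size.  The blocked result is
identical to a dense all-pairs computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alff import VoxelMap
from .preprocess import BoldRun

__all__ = ["DcParams", "compute_dc", "dc_threshold_sweep"]

DEFAULT_SWEEP = (0.15, 0.2, 0.25, 0.3, 0.35)


@dataclass(frozen=True)
class DcParams:
    """Degree-centrality parameters.

    ``r_threshold`` is the Pearson cutoff defining an edge (default 0.25,
    high enough to exclude noise-level correlations); ``sweep`` lists the
    thresholds examined in the robustness sweep; ``block_size`` bounds the
    correlation block held in memory.
    """

    r_threshold: float = 0.25
    sweep: tuple[float, ...] = DEFAULT_SWEEP
    block_size: int = 2048

    def __post_init__(self) -> None:
        for thr in (self.r_threshold, *self.sweep):
            if not 0.0 < thr < 1.0:
                raise ValueError(f"correlation threshold must be in (0, 1), got {thr}")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


def _zscore_rows(series: np.ndarray) -> np.ndarray:
    """Scale rows to zero mean and unit norm; constant rows become zero.

    With rows scaled this way, ``z_i @ z_j`` is exactly the Pearson
    correlation, and a zero-variance voxel has r = 0 with everything
    (it can never be a neighbor).
    """
    centered = series - series.mean(axis=-1, keepdims=True)
    norm = np.sqrt(np.einsum("ij,ij->i", centered, centered))
    nonconst = norm > 0
    out = np.zeros_like(centered)
    out[nonconst] = centered[nonconst] / norm[nonconst, None]
    return out


def _dc_counts(z: np.ndarray, thresholds: np.ndarray, block_size: int) -> np.ndarray:
    """Per-threshold degree counts from z-scored rows, blocked.

    Returns an array of shape ``(len(thresholds), n_voxels)``.  The
    diagonal (self-correlation, r = 1 for non-constant voxels) is removed
    analytically, so ties at the threshold never involve the self edge.
    """
    n = z.shape[0]
    nonconst = np.einsum("ij,ij->i", z, z) > 0.5  # unit rows have norm 1, constant rows 0
    counts = np.zeros((len(thresholds), n), dtype=np.int64)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        r_block = z[start:stop] @ z.T  # (block, n)
        for k, thr in enumerate(thresholds):
            over = r_block > thr
            counts[k, start:stop] += over.sum(axis=1)
    # every non-constant voxel counted its own r=1 self edge at any thr < 1
    counts[:, nonconst] -= 1
    return counts


def compute_dc(run: BoldRun, mask: np.ndarray, params: DcParams | None = None) -> VoxelMap:
    """Raw binarized degree-centrality map at ``params.r_threshold``.

    The run must already be nuisance-regressed and lowpass-filtered but
    NOT spatially smoothed: smoothing before the correlation step would
    inflate local correlations, so on the DC path smoothing is applied to
    the finished map, never to the input series.
    """
    params = params or DcParams()
    maps = _dc_maps(run, mask, np.array([params.r_threshold]), params.block_size)
    return maps[0]


def dc_threshold_sweep(
    run: BoldRun, mask: np.ndarray, params: DcParams | None = None
) -> list[VoxelMap]:
    """Raw DC maps for every threshold in ``params.sweep``, one data pass.

    Maps are pointwise non-increasing in the threshold.
    """
    params = params or DcParams()
    return _dc_maps(run, mask, np.asarray(params.sweep, dtype=float), params.block_size)


def _dc_maps(
    run: BoldRun, mask: np.ndarray, thresholds: np.ndarray, block_size: int
) -> list[VoxelMap]:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != run.grid_shape:
        raise ValueError("mask does not match run grid")
    if mask.sum() < 2:
        raise ValueError("degree centrality needs at least 2 in-mask voxels")
    if run.n_volumes < 3:
        raise ValueError("degree centrality needs at least 3 timepoints")
    series = run.data[mask]
    if series.dtype not in (np.float32, np.float64):
        series = series.astype(np.float64)
    z = _zscore_rows(series)
    counts = _dc_counts(z, thresholds, block_size)
    out = []
    for thr, row in zip(thresholds, counts):
        values = np.zeros(mask.shape, dtype=np.float64)
        values[mask] = row
        out.append(
            VoxelMap(values=values, mask=mask, modality="dc", standardized=False,
                     params={"r_threshold": float(thr)})
        )
    return out
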