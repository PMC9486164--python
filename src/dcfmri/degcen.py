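"""Voxelwise degree centrality (DC) of the functional connectome.

For each in-mask voxel, DC is the number (binary mode) or summed strength
(weighted mode) of positive Pearson correlations above a threshold
(default r > 0.25) between that voxel's time series and every other in-mask
series. Maps are then z-scored across the mask and Gaussian-smoothed
(default 6 mm FWHM), in that order.

The pairwise-correlation pass is chunked so peak memory stays
O(chunk_size * n_voxels); results do not depend on the chunk size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import BoldScan, smooth_masked, voxel_sizes_mm

__all__ = ["DCMap", "degree_centrality", "zscore_map", "smooth_map", "dc_pipeline"]


@dataclass
class DCMap:
    """A 3-D degree-centrality field on a scan grid.

    ``kind`` tracks the processing stage: ``raw_binary`` / ``raw_weighted``
    -> ``zscored`` -> ``zscored_smoothed``.
    """

    values: np.ndarray
    mask: np.ndarray
    kind: str
    r_threshold: float
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite DC values inside mask")


def _standardised_series(scan: BoldScan, mask: np.ndarray) -> np.ndarray:
    """In-mask series, demeaned and scaled to unit L2 norm (rows), so that
    row dot products are Pearson correlations."""
    Y = scan.data[mask]  # (V, t)
    # constant series have no defined correlation; detect exactly
    bad = np.ptp(Y, axis=1) == 0
    Y = Y - Y.mean(axis=1, keepdims=True)
    norms = np.sqrt((Y ** 2).sum(axis=1))
    if bad.any():
        coords = np.argwhere(mask)[bad]
        raise ValueError(
            "zero-variance series inside mask at voxel coordinates "
            f"{coords.tolist()[:10]}{'...' if bad.sum() > 10 else ''}; "
            "mask them out before computing degree centrality")
    return Y / norms[:, None]


def degree_centrality(scan: BoldScan, mask: np.ndarray, r_threshold: float = 0.25,
                      mode: str = "binary", chunk_size: int = 2048) -> DCMap:
    """Voxel degree over the mask at a positive-correlation threshold.

    Binary mode counts in-mask voxels u != v with r(v, u) > r_threshold
    (strict); weighted mode sums those correlations. Negative correlations
    never contribute.
    """
    if mode not in ("binary", "weighted"):
        raise ValueError(f"unknown mode {mode!r}")
    if chunk_size < 1:
        raise ValueError("chunk_size must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if scan.n_volumes < 3:
        raise ValueError("need at least 3 volumes")
    Z = _standardised_series(scan, mask)
    n_vox = Z.shape[0]
    dc = np.zeros(n_vox)
    for start in range(0, n_vox, chunk_size):
        stop = min(start + chunk_size, n_vox)
        R = Z[start:stop] @ Z.T  # (chunk, V) correlations
        R[np.arange(stop - start), np.arange(start, stop)] = -np.inf  # self
        above = R > r_threshold
        if mode == "binary":
            dc[start:stop] = above.sum(axis=1)
        else:
            dc[start:stop] = np.where(above, R, 0.0).sum(axis=1)
    values = np.zeros(mask.shape)
    values[mask] = dc
    return DCMap(values=values, mask=mask, kind=f"raw_{mode}",
                 r_threshold=r_threshold, affine=scan.affine,
                 subject_id=scan.subject_id)


def zscore_map(dc: DCMap) -> DCMap:
    """Standardise to mean 0, sd 1 over the mask (population sd, divisor n)."""
    if dc.mask.sum() < 2:
        raise ValueError("need at least 2 in-mask voxels")
    vals = dc.values[dc.mask]
    sd = vals.std()  # population sd
    if sd == 0:
        raise ValueError("constant DC map: zero sd over mask")
    out = np.zeros(dc.values.shape)
    out[dc.mask] = (vals - vals.mean()) / sd
    return replace(dc, values=out, kind="zscored")


def smooth_map(dc: DCMap, fwhm_mm: float = 6.0) -> DCMap:
    """Mask-renormalised Gaussian smoothing (per-axis sigma from the affine)."""
    vs = voxel_sizes_mm(dc.affine)
    out = smooth_masked(dc.values, dc.mask, fwhm_mm, vs)
    return replace(dc, values=out, kind="zscored_smoothed")


def dc_pipeline(scan: BoldScan, mask: np.ndarray, r_threshold: float = 0.25,
                mode: str = "binary", fwhm_mm: float = 6.0,
                chunk_size: int = 2048) -> DCMap:
    """degree -> z-score -> smooth, the standard per-subject DC map."""
    return smooth_map(zscore_map(
        degree_centrality(scan, mask, r_threshold, mode, chunk_size)), fwhm_mm)
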