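"""Shared primitives: the 4-D scan container, the ideal band-pass filter, and
mask-aware Gaussian smoothing.

These live in one place because the simulator and the preprocessing /
degree-centrality stages must use bit-identical routines: the synthetic
network signals are band-limited with the same ideal FFT filter that the
preprocessing stage applies, and the simulator's spatial noise smoothing is
the same kernel routine used to smooth degree maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "BoldScan",
    "voxel_sizes_mm",
    "ideal_bandpass",
    "fwhm_to_sigma",
    "smooth_masked",
]

#: FWHM = sigma * sqrt(8 ln 2); 6 mm FWHM <-> sigma ~ 2.548 mm.
_FWHM_PER_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))


@dataclass
class BoldScan:
    """One subject's 4-D BOLD time series on a voxel grid.

    Parameters
    ----------
    data
        Array of shape (x, y, z, t), finite everywhere.
    affine
        4x4 voxel-to-world transform (mm); must be invertible.
    tr_s
        Repetition time in seconds.
    subject_id
        Free-text identifier.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BoldScan data must be 4-D, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("BoldScan needs at least 2 time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BoldScan data contains NaN or Inf")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")
        if not (self.tr_s > 0):
            raise ValueError("tr_s must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray) -> "BoldScan":
        """Copy of this scan with new time-series data on the same grid."""
        return BoldScan(data=data, affine=self.affine, tr_s=self.tr_s,
                        subject_id=self.subject_id)


def voxel_sizes_mm(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths (mm) from an affine (column norms)."""
    affine = np.asarray(affine, dtype=float)
    sizes = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    if np.any(sizes <= 0):
        raise ValueError("affine implies a zero voxel size")
    return sizes


def ideal_bandpass(x: np.ndarray, tr_s: float, low_hz: float, high_hz: float,
                   axis: int = -1) -> np.ndarray:
    """Ideal (brick-wall) frequency-domain band-pass along ``axis``.

    All FFT bins with frequency outside [low_hz, high_hz] are zeroed; the DC
    bin is zeroed unconditionally. The bound check is inclusive on both band
    edges, so an on-bin sinusoid at either edge passes unchanged.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[axis]
    nyquist = 0.5 / tr_s
    if not (0.0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyquist:.4g} Hz"
        )
    freqs = np.fft.rfftfreq(n, d=tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    keep[0] = False  # DC always removed
    spec = np.fft.rfft(x, axis=axis)
    shape = [1] * x.ndim
    shape[axis] = keep.size
    spec *= keep.reshape(shape)
    return np.fft.irfft(spec, n=n, axis=axis)


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma corresponding to a full width at half maximum."""
    return float(fwhm) / _FWHM_PER_SIGMA


def smooth_masked(field: np.ndarray, mask: np.ndarray, fwhm_mm: float,
                  voxel_sizes: np.ndarray) -> np.ndarray:
    """Gaussian-smooth a 3-D field within a mask, renormalising by the
    smoothed mask so values outside the mask do not bleed in and constants
    are preserved.

    Anisotropic voxels are handled with a per-axis sigma. Out-of-mask voxels
    of the result are zero.
    """
    field = np.asarray(field, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if field.shape != mask.shape:
        raise ValueError("field and mask shapes differ")
    voxel_sizes = np.asarray(voxel_sizes, dtype=float)
    if np.any(voxel_sizes <= 0):
        raise ValueError("voxel sizes must be positive")
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    sigma_vox = fwhm_to_sigma(fwhm_mm) / voxel_sizes
    out = np.zeros_like(field)
    if np.all(sigma_vox < 1e-3):  # effectively a delta kernel
        out[mask] = field[mask]
        return out
    m = mask.astype(np.float64)
    num = ndimage.gaussian_filter(field * m, sigma=sigma_vox, truncate=6.0)
    den = ndimage.gaussian_filter(m, sigma=sigma_vox, truncate=6.0)
    out[mask] = num[mask] / den[mask]
    return out
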