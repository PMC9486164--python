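"""Temporal preprocessing of pre-aligned 4-D BOLD data.

The chain is: discard initial volumes -> motion QC gate -> linear detrend ->
ideal band-pass (0.01-0.08 Hz) -> nuisance regression (six motion
parameters, white-matter and CSF signals) -> optional final re-detrend.
Spatial steps (realignment, slice timing, normalisation) are out of scope:
inputs are assumed to sit on a common grid with motion parameters given.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import BoldScan, ideal_bandpass
from .synthdata import CONFOUND_COLUMNS

__all__ = [
    "ConfoundSet",
    "QCReport",
    "discard_initial",
    "motion_qc",
    "detrend_linear",
    "bandpass",
    "nuisance_regress",
    "preprocess_scan",
]


@dataclass
class ConfoundSet:
    """Per-subject nuisance series: t x 6 motion (mm / deg), WM and CSF."""

    motion: np.ndarray
    wm: np.ndarray
    csf: np.ndarray

    def __post_init__(self) -> None:
        self.motion = np.atleast_2d(np.asarray(self.motion, dtype=float))
        self.wm = np.asarray(self.wm, dtype=float).ravel()
        self.csf = np.asarray(self.csf, dtype=float).ravel()
        if self.motion.shape[1] != 6:
            raise ValueError("motion must have 6 columns")
        if not (len(self.wm) == len(self.csf) == self.motion.shape[0]):
            raise ValueError("confound series lengths differ")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ConfoundSet":
        missing = [c for c in CONFOUND_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"confound table missing columns: {missing}")
        return cls(motion=df[CONFOUND_COLUMNS[:6]].to_numpy(),
                   wm=df["wm"].to_numpy(), csf=df["csf"].to_numpy())

    def discard_initial(self, n_discard: int) -> "ConfoundSet":
        if n_discard >= self.motion.shape[0]:
            raise ValueError("discarding all confound rows")
        return ConfoundSet(motion=self.motion[n_discard:],
                           wm=self.wm[n_discard:], csf=self.csf[n_discard:])

    @property
    def n_frames(self) -> int:
        return self.motion.shape[0]


@dataclass
class QCReport:
    """Head-motion quality control outcome for one subject."""

    subject_id: str
    max_abs_translation_mm: float
    max_abs_rotation_deg: float
    passed: bool


def discard_initial(scan: BoldScan, n_discard: int = 5) -> BoldScan:
    """Drop the first ``n_discard`` volumes (scanner equilibration)."""
    if n_discard < 0:
        raise ValueError("n_discard must be nonnegative")
    if scan.n_volumes <= n_discard:
        raise ValueError(
            f"scan has {scan.n_volumes} volumes, cannot discard {n_discard}")
    if n_discard == 0:
        return scan.with_data(scan.data.copy())
    return scan.with_data(scan.data[..., n_discard:])


def motion_qc(confounds: ConfoundSet, subject_id: str = "",
              translation_limit_mm: float = 2.0,
              rotation_limit_deg: float = 2.0) -> QCReport:
    """Check peak absolute head motion against the +/-2 mm / +/-2 deg limits.

    Bounds are inclusive: a subject at exactly the limit passes.
    """
    if confounds.motion.size == 0:
        raise ValueError("empty motion matrix")
    if np.isnan(confounds.motion).any():
        raise ValueError("NaN in motion parameters")
    max_t = float(np.abs(confounds.motion[:, :3]).max())
    max_r = float(np.abs(confounds.motion[:, 3:]).max())
    passed = (max_t <= translation_limit_mm) and (max_r <= rotation_limit_deg)
    return QCReport(subject_id=subject_id, max_abs_translation_mm=max_t,
                    max_abs_rotation_deg=max_r, passed=passed)


def detrend_linear(scan: BoldScan) -> BoldScan:
    """Remove, per voxel, the least-squares line (intercept + slope * frame)."""
    if scan.n_volumes < 3:
        raise ValueError("need at least 3 volumes to detrend")
    return scan.with_data(signal.detrend(scan.data, axis=-1, type="linear"))


def bandpass(scan: BoldScan, low_hz: float = 0.01, high_hz: float = 0.08) -> BoldScan:
    """Ideal FFT band-pass of every voxel series (DC removed)."""
    return scan.with_data(ideal_bandpass(scan.data, scan.tr_s, low_hz, high_hz,
                                         axis=-1))


def _design_matrix(confounds: ConfoundSet) -> tuple[np.ndarray, list[str]]:
    names = ["intercept"] + CONFOUND_COLUMNS
    X = np.column_stack([np.ones(confounds.n_frames), confounds.motion,
                         confounds.wm, confounds.csf])
    # all-zero confound columns carry no signal; drop them so a motionless
    # subject degrades to intercept-only demeaning instead of a rank error
    keep = [j for j in range(X.shape[1]) if j == 0 or np.any(X[:, j] != 0)]
    return X[:, keep], [names[j] for j in keep]


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns involved in rank deficiency (adding them gains no rank)."""
    flagged, rank = [], 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, :j + 1])
        if r == rank:
            flagged.append(names[j])
        rank = r
    return flagged


def nuisance_regress(scan: BoldScan, confounds: ConfoundSet) -> BoldScan:
    """Residualise every voxel series on intercept + 6 motion + WM + CSF."""
    if confounds.n_frames != scan.n_volumes:
        raise ValueError(
            f"confound rows ({confounds.n_frames}) != scan volumes "
            f"({scan.n_volumes}); align the discard step first")
    X, names = _design_matrix(confounds)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "nuisance design is rank deficient; collinear columns: "
            f"{_collinear_columns(X, names)}")
    flat = scan.data.reshape(-1, scan.n_volumes).T  # (t, V)
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    return scan.with_data(resid.T.reshape(scan.data.shape))


@dataclass
class PreprocessParams:
    n_discard: int = 5
    low_hz: float = 0.01
    high_hz: float = 0.08
    translation_limit_mm: float = 2.0
    rotation_limit_deg: float = 2.0
    final_redetrend: bool = True


def preprocess_scan(scan: BoldScan, confounds: ConfoundSet | pd.DataFrame,
                    params: PreprocessParams | None = None) -> tuple[BoldScan, QCReport]:
    """Full temporal chain for one subject; returns the cleaned scan and the
    QC report. The caller decides whether to exclude QC failures.

    The confound table is expected at the scan's original length and is
    discard-aligned here.
    """
    params = params or PreprocessParams()
    if isinstance(confounds, pd.DataFrame):
        confounds = ConfoundSet.from_dataframe(confounds)
    scan = discard_initial(scan, params.n_discard)
    confounds = confounds.discard_initial(params.n_discard)
    qc = motion_qc(confounds, scan.subject_id,
                   params.translation_limit_mm, params.rotation_limit_deg)
    scan = detrend_linear(scan)
    scan = bandpass(scan, params.low_hz, params.high_hz)
    scan = nuisance_regress(scan, confounds)
    if params.final_redetrend:
        scan = detrend_linear(scan)
    return scan, qc
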