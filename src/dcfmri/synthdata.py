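"""Synthetic resting-state BOLD cohort with planted degree-centrality effects.

The generator emulates, at desk scale, a two-group rs-fMRI study: each
subject is a 4-D scan in which voxels belonging to a "network" ROI share a
band-limited (0.01-0.08 Hz) Gaussian signal with a group-specific loading
lambda, on top of temporally autocorrelated (AR(1)) spatially smoothed
noise. Two voxels inside the same ROI with loading lambda and noise sd sigma
then have expected Pearson correlation lambda^2 / (lambda^2 + sigma^2)
(before any extra correlation contributed by spatial noise smoothing), so
choosing the patient and control loadings on either side of the r = 0.25
degree threshold plants a known group difference in voxel degree.

Alongside the scans the generator emits per-subject confound series (six
rigid-body motion parameters as bounded random walks, plus white-matter and
CSF signals), a phenotype table modelled on a depression case-control cohort
(ages ~28 y, HRSD-17 severity scores ~24 for patients), a brain mask, and a
ground-truth manifest naming each planted ROI and the designed direction of
its group degree difference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BoldScan, ideal_bandpass, smooth_masked

__all__ = [
    "NetworkSpec",
    "SimConfig",
    "default_networks",
    "brain_mask",
    "roi_mask",
    "generate_phenotypes",
    "simulate_subject",
    "simulate_cohort",
    "generate_cohort",
]

MISSING = "NA"

CONFOUND_COLUMNS = [
    "trans_x_mm", "trans_y_mm", "trans_z_mm",
    "rot_x_deg", "rot_y_deg", "rot_z_deg",
    "wm", "csf",
]


@dataclass
class NetworkSpec:
    """A planted network: spherical ROIs sharing one latent signal.

    ``loading_patients`` / ``loading_controls`` are the signal loadings
    (lambda) applied to in-ROI voxels per group; unequal loadings plant a
    group difference in within-ROI correlation and hence in voxel degree.
    """

    name: str
    roi_centers: list[tuple[int, int, int]]
    roi_radius_mm: float = 6.0
    loading_patients: float = 0.9
    loading_controls: float = 0.2

    def __post_init__(self) -> None:
        if not np.isfinite([self.loading_patients, self.loading_controls]).all():
            raise ValueError(f"network {self.name!r}: loadings must be finite")
        if self.loading_patients < 0 or self.loading_controls < 0:
            raise ValueError(f"network {self.name!r}: loadings must be nonnegative")
        if self.roi_radius_mm <= 0:
            raise ValueError(f"network {self.name!r}: roi_radius_mm must be positive")

    @property
    def direction(self) -> str:
        """Designed direction of the patients-minus-controls degree contrast."""
        if self.loading_patients > self.loading_controls:
            return "patients_higher"
        if self.loading_patients < self.loading_controls:
            return "patients_lower"
        return "null"


def default_networks(grid_dims: tuple[int, int, int]) -> list[NetworkSpec]:
    """Two hub networks, one elevated and one depreciated in patients,
    placed in opposite halves of the grid (scaled with grid size)."""
    gx, gy, gz = grid_dims
    up = (int(gx * 0.30), int(gy * 0.35), int(gz * 0.5))
    down = (int(gx * 0.68), int(gy * 0.62), int(gz * 0.5))
    return [
        NetworkSpec("hub_up", [up], 6.0, loading_patients=0.9, loading_controls=0.2),
        NetworkSpec("hub_down", [down], 6.0, loading_patients=0.2, loading_controls=0.9),
    ]


@dataclass
class SimConfig:
    """Cohort simulation parameters (desk-scale defaults).

    The default grid (24 x 24 x 18 voxels at 3 mm), 150 volumes at TR 2 s and
    20 subjects per group reproduce the *structure* of a full-size study
    (which would use a ~64^3 MNI grid and hundreds of subjects) at a size a
    laptop handles; every dimension is configurable.
    """

    grid_dims: tuple[int, int, int] = (24, 24, 18)
    voxel_size_mm: float = 3.0
    tr_s: float = 2.0
    n_volumes: int = 150
    n_patients: int = 20
    n_controls: int = 20
    networks: list[NetworkSpec] | None = None
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    noise_smooth_fwhm_mm: float = 3.0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    n_motion_violators: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        if self.networks is None:
            self.networks = default_networks(self.grid_dims)
        if any(d <= 0 for d in self.grid_dims):
            raise ValueError("grid_dims must be positive")
        if self.networks and any(d < 8 for d in self.grid_dims):
            raise ValueError("grid_dims must all be >= 8 when networks are present")
        if self.voxel_size_mm <= 0 or self.tr_s <= 0:
            raise ValueError("voxel_size_mm and tr_s must be positive")
        if self.n_volumes <= 5:
            raise ValueError("n_volumes must exceed the 5 discarded frames")
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ValueError("group sizes must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ValueError("ar1_rho must lie in [0, 1)")
        if self.noise_smooth_fwhm_mm < 0:
            raise ValueError("noise_smooth_fwhm_mm must be nonnegative")
        nyquist = 0.5 / self.tr_s
        if self.band_high_hz >= nyquist:
            raise ValueError(
                f"band_high_hz={self.band_high_hz} Hz not below Nyquist "
                f"{nyquist:.4g} Hz at TR={self.tr_s}s"
            )

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-world transform: isotropic spacing, origin at grid centre
        (so world coordinates look MNI-like, spanning +/- mm)."""
        vs = self.voxel_size_mm
        aff = np.diag([vs, vs, vs, 1.0])
        aff[:3, 3] = -(np.array(self.grid_dims) - 1) / 2.0 * vs
        return aff


def brain_mask(config: SimConfig) -> np.ndarray:
    """Ellipsoidal "brain" inscribed in the grid (semi-axes 0.45 x dims)."""
    dims = np.array(config.grid_dims)
    centre = (dims - 1) / 2.0
    semi = 0.45 * dims
    idx = np.indices(config.grid_dims)
    d2 = sum(((idx[a] - centre[a]) / semi[a]) ** 2 for a in range(3))
    return d2 <= 1.0


def roi_mask(config: SimConfig, net: NetworkSpec) -> np.ndarray:
    """Boolean mask of the union of a network's spherical ROIs (mm radius)."""
    out = np.zeros(config.grid_dims, dtype=bool)
    idx = np.indices(config.grid_dims)
    vs = config.voxel_size_mm
    for c in net.roi_centers:
        d2 = sum(((idx[a] - c[a]) * vs) ** 2 for a in range(3))
        out |= d2 <= net.roi_radius_mm ** 2
    return out


def _validate_rois(config: SimConfig, mask: np.ndarray) -> dict[str, np.ndarray]:
    rois: dict[str, np.ndarray] = {}
    for net in config.networks:
        m = roi_mask(config, net)
        if not m.any():
            raise ValueError(f"ROI of network {net.name!r} contains no voxels")
        if np.any(m & ~mask):
            raise ValueError(
                f"ROI of network {net.name!r} extends outside the brain mask"
            )
        rois[net.name] = m
    return rois


# ---------------------------------------------------------------------------
# phenotypes

# Group summary statistics the phenotype generator targets (case-control
# depression cohort: mean +/- sd as commonly tabulated).
PHENOTYPE_DEFAULTS = {
    "age": {"patient": (28.01, 7.442), "control": (27.87, 6.492), "bounds": (18.0, 65.0)},
    "education": {"patient": (12.05, 3.325), "control": (12.55, 2.931), "bounds": (0.0, 22.0)},
    "hrsd17": {"patient": (23.63, 2.547), "bounds": (17.0, 52.0)},
    "male_fraction": {"patient": 102 / 198, "control": 130 / 234},
}


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    if sd <= 0:
        raise ValueError("sd must be positive")
    out = np.empty(size)
    n = 0
    while n < size:
        draw = rng.normal(mean, sd, size=size)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(size - n, draw.size)
        out[n:n + take] = draw[:take]
        n += take
    return out


def generate_phenotypes(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Phenotype table: id, group, age, sex, education, hrsd17, duration_months.

    Ages and education are truncated normals matched to the group summary
    statistics; sex is Bernoulli with per-group male fractions; HRSD-17 is a
    rounded truncated normal for patients only (controls are missing-coded);
    illness duration is log-normal (median ~20 months), patients only.
    """
    if config.n_patients < 2 or config.n_controls < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    counts = {"patient": config.n_patients, "control": config.n_controls}
    sid = 0
    for group in ("patient", "control"):
        n = counts[group]
        a_mu, a_sd = PHENOTYPE_DEFAULTS["age"][group]
        e_mu, e_sd = PHENOTYPE_DEFAULTS["education"][group]
        age = _truncated_normal(rng, a_mu, a_sd, *PHENOTYPE_DEFAULTS["age"]["bounds"], size=n)
        edu = _truncated_normal(rng, e_mu, e_sd, *PHENOTYPE_DEFAULTS["education"]["bounds"], size=n)
        male = rng.random(n) < PHENOTYPE_DEFAULTS["male_fraction"][group]
        if group == "patient":
            h_mu, h_sd = PHENOTYPE_DEFAULTS["hrsd17"]["patient"]
            hrsd = np.round(_truncated_normal(
                rng, h_mu, h_sd, *PHENOTYPE_DEFAULTS["hrsd17"]["bounds"], size=n)).astype(int)
            duration = np.exp(rng.normal(3.0, 0.7, size=n))
        else:
            hrsd = [None] * n
            duration = [None] * n
        for i in range(n):
            sid += 1
            rows.append({
                "id": f"sub-{sid:03d}",
                "group": group,
                "age": round(float(age[i]), 2),
                "sex": "M" if male[i] else "F",
                "education": round(float(edu[i]), 2),
                "hrsd17": None if hrsd[i] is None else int(hrsd[i]),
                "duration_months": None if duration[i] is None else round(float(duration[i]), 1),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BOLD simulation


def _band_limited_noise(rng: np.random.Generator, n: int, tr_s: float,
                        low: float, high: float, size: tuple = ()) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [low, high] Hz."""
    w = rng.standard_normal(size + (n,))
    x = ideal_bandpass(w, tr_s, low, high, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _ar1_noise(rng: np.random.Generator, shape: tuple, rho: float, sd: float) -> np.ndarray:
    """AR(1) noise along the last axis with marginal standard deviation sd."""
    w = rng.standard_normal(shape)
    out = np.empty(shape)
    out[..., 0] = w[..., 0]
    innov = np.sqrt(1.0 - rho ** 2)
    for t in range(1, shape[-1]):
        out[..., t] = rho * out[..., t - 1] + innov * w[..., t]
    return sd * out


def _bounded_walk(rng: np.random.Generator, n: int, step_sd: float, bound: float) -> np.ndarray:
    """Random walk folded back into [-bound, bound] (reflecting boundaries)."""
    walk = np.cumsum(rng.normal(0.0, step_sd, size=n))
    period = 4.0 * bound
    x = np.mod(walk + bound, period)
    return np.where(x <= 2 * bound, x - bound, 3 * bound - x)


def _simulate_confounds(rng: np.random.Generator, config: SimConfig,
                        violate_motion: bool = False) -> pd.DataFrame:
    n = config.n_volumes
    cols = {}
    for name in CONFOUND_COLUMNS[:6]:
        cols[name] = _bounded_walk(rng, n, step_sd=0.04, bound=1.5)
    if violate_motion:
        spike_at = n // 2
        cols["trans_y_mm"] = cols["trans_y_mm"].copy()
        cols["trans_y_mm"][spike_at] = 2.6
    cols["wm"] = _band_limited_noise(rng, n, config.tr_s, config.band_low_hz,
                                     config.band_high_hz)
    cols["csf"] = _band_limited_noise(rng, n, config.tr_s, config.band_low_hz,
                                      config.band_high_hz)
    return pd.DataFrame(cols, columns=CONFOUND_COLUMNS)


def simulate_subject(config: SimConfig, group: str, subject_id: str,
                     rng: np.random.Generator,
                     rois: dict[str, np.ndarray] | None = None,
                     mask: np.ndarray | None = None,
                     violate_motion: bool = False) -> tuple[BoldScan, pd.DataFrame]:
    """One subject's scan and confound table.

    Voxel series: y_v(t) = lambda_{group, net(v)} * n_net(t) + eps_v(t), with
    each network signal n_net unit-variance band-limited noise (fresh per
    subject) and eps AR(1) noise, spatially smoothed then re-standardised to
    the configured marginal sd.
    """
    if group not in ("patient", "control"):
        raise ValueError(f"unknown group {group!r}")
    if mask is None:
        mask = brain_mask(config)
    if rois is None:
        rois = _validate_rois(config, mask)
    dims = config.grid_dims
    n = config.n_volumes

    noise = _ar1_noise(rng, dims + (n,), config.ar1_rho, 1.0)
    if config.noise_smooth_fwhm_mm > 0:
        from .core import fwhm_to_sigma
        sigma_vox = fwhm_to_sigma(config.noise_smooth_fwhm_mm) / config.voxel_size_mm
        from scipy import ndimage
        noise = ndimage.gaussian_filter(noise, sigma=(sigma_vox,) * 3 + (0.0,))
        # re-standardise each voxel's series to the nominal marginal sd
        noise -= noise.mean(axis=-1, keepdims=True)
        sd = noise.std(axis=-1, keepdims=True)
        noise /= np.where(sd > 0, sd, 1.0)
    data = config.noise_sd * noise

    for net in config.networks:
        lam = net.loading_patients if group == "patient" else net.loading_controls
        if lam == 0:
            # still consume the signal draw so group label does not perturb
            # the random stream
            _band_limited_noise(rng, n, config.tr_s, config.band_low_hz,
                                config.band_high_hz)
            continue
        sig = _band_limited_noise(rng, n, config.tr_s, config.band_low_hz,
                                  config.band_high_hz)
        data[rois[net.name]] += lam * sig

    confounds = _simulate_confounds(rng, config, violate_motion=violate_motion)
    scan = BoldScan(data=data, affine=config.affine, tr_s=config.tr_s,
                    subject_id=subject_id)
    return scan, confounds


@dataclass
class Cohort:
    """In-memory cohort bundle."""

    config: SimConfig
    mask: np.ndarray
    phenotypes: pd.DataFrame
    scans: list[BoldScan]
    confounds: list[pd.DataFrame]
    roi_masks: dict[str, np.ndarray]
    ground_truth: dict = field(default_factory=dict)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Simulate the whole two-group cohort, deterministically given the seed.

    Patients come first in subject order; motion violations (if requested)
    are injected into the first ``n_motion_violators`` subjects.
    """
    mask = brain_mask(config)
    rois = _validate_rois(config, mask)
    pheno = generate_phenotypes(config)
    root = np.random.SeedSequence(config.seed)
    subj_seeds = root.spawn(len(pheno))
    scans, confounds = [], []
    for i, row in pheno.iterrows():
        rng = np.random.default_rng(subj_seeds[i])
        scan, conf = simulate_subject(
            config, row["group"], row["id"], rng, rois=rois, mask=mask,
            violate_motion=i < config.n_motion_violators)
        scans.append(scan)
        confounds.append(conf)
    gt = {
        "networks": [
            {
                "name": net.name,
                "direction": net.direction,
                "loading_patients": net.loading_patients,
                "loading_controls": net.loading_controls,
                "roi_radius_mm": net.roi_radius_mm,
                "roi_centers": [list(c) for c in net.roi_centers],
            }
            for net in config.networks
        ],
        "seed": config.seed,
    }
    return Cohort(config=config, mask=mask, phenotypes=pheno, scans=scans,
                  confounds=confounds, roi_masks=rois, ground_truth=gt)


def _write_pheno_tsv(pheno: pd.DataFrame, path: Path) -> None:
    pheno.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def generate_cohort(config: SimConfig, outdir: str | Path) -> Cohort:
    """Simulate and write the cohort bundle to ``outdir``.

    Layout: ``sub-XXX_bold.nii.gz`` + ``sub-XXX_confounds.tsv`` per subject,
    ``brain_mask.nii.gz``, ``roi-<name>_mask.nii.gz`` per network,
    ``phenotypes.tsv`` and ``ground_truth.json``.
    """
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    _io.write_volume(cohort.mask.astype(np.uint8), config.affine,
                     outdir / "brain_mask.nii.gz")
    for name, m in cohort.roi_masks.items():
        _io.write_volume(m.astype(np.uint8), config.affine,
                         outdir / f"roi-{name}_mask.nii.gz")
    for scan, conf in zip(cohort.scans, cohort.confounds):
        _io.write_bold(scan, outdir / f"{scan.subject_id}_bold.nii.gz")
        conf.to_csv(outdir / f"{scan.subject_id}_confounds.tsv", sep="\t",
                    index=False, float_format="%.6f")
    _write_pheno_tsv(cohort.phenotypes, outdir / "phenotypes.tsv")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(cohort.ground_truth, fh, indent=2, sort_keys=True)
    return cohort
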