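"""Calibration, recovery and sanity experiments for the pipeline.

These experiments quantify, on synthetic data with known ground truth, the
operating characteristics of the implemented methods: the familywise
false-positive rate of the RFT cluster correction under the null, its
concordance with the Freedman-Lane permutation test, recovery of planted
degree effects by the full pipeline, the SVM's behaviour on separable and
label-permuted data, and the accuracy of the residual-smoothness estimator.
They are used both by the test suite and by the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BoldScan, fwhm_to_sigma
from .degcen import DCMap, degree_centrality, dc_pipeline
from .groupstats import (DesignMatrix, estimate_smoothness, fit_voxelwise_glm,
                         grf_cluster_correct, permutation_cluster_correct,
                         group_difference)
from .classify import svm_classify
from .synthdata import SimConfig, simulate_cohort
from .preprocess import preprocess_scan, PreprocessParams

__all__ = [
    "dc_bruteforce",
    "dc_oracle_check",
    "simulate_subject_maps",
    "null_calibration",
    "grf_permutation_concordance",
    "recovery_sim_config",
    "effect_recovery",
    "svm_separated_clouds",
    "svm_label_permutation",
    "smoothness_recovery",
]


# ---------------------------------------------------------------------------
# degree-centrality brute-force oracle


def dc_bruteforce(scan: BoldScan, mask: np.ndarray, r_threshold: float = 0.25,
                  mode: str = "binary") -> np.ndarray:
    """O(n^2) double-loop degree centrality, independent of the chunked path."""
    coords = np.argwhere(mask)
    series = [scan.data[tuple(c)] for c in coords]
    n = len(series)
    out3d = np.zeros(mask.shape)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if i == j:
                continue
            r = np.corrcoef(series[i], series[j])[0, 1]
            if r > r_threshold:
                acc += 1.0 if mode == "binary" else r
        out3d[tuple(coords[i])] = acc
    return out3d


def dc_oracle_check(n_scans: int = 50, seed: int = 0) -> dict:
    """Chunked degree vs brute force on random small scans.

    Returns the max absolute discrepancy over scans for binary (must be
    exactly 0) and weighted (float tolerance) modes, across random chunk
    sizes.
    """
    rng = np.random.default_rng(seed)
    max_bin = 0.0
    max_wgt = 0.0
    for _ in range(n_scans):
        dims = tuple(rng.integers(4, 7, size=3))
        t = int(rng.integers(20, 41))
        mask = rng.random(dims) < 0.8
        if mask.sum() < 3:
            mask[:2, 0, 0] = True
            mask[0, 1, 0] = True
        data = rng.standard_normal(dims + (t,))
        scan = BoldScan(data=data, affine=np.eye(4), tr_s=2.0)
        thr = float(rng.uniform(0.0, 0.6))
        chunk = int(rng.integers(1, mask.sum() + 1))
        for mode, tracker in (("binary", "bin"), ("weighted", "wgt")):
            fast = degree_centrality(scan, mask, thr, mode, chunk_size=chunk)
            slow = dc_bruteforce(scan, mask, thr, mode)
            d = float(np.abs(fast.values - slow).max())
            if tracker == "bin":
                max_bin = max(max_bin, d)
            else:
                max_wgt = max(max_wgt, d)
    return {"binary_max_abs_diff": max_bin, "weighted_max_abs_diff": max_wgt,
            "n_scans": n_scans}


# ---------------------------------------------------------------------------
# direct subject-map simulation (for GLM/RFT experiments, where running the
# full BOLD pipeline for every Monte-Carlo replicate would add nothing)


def _ellipsoid_mask(dims: tuple[int, int, int]) -> np.ndarray:
    d = np.array(dims)
    centre = (d - 1) / 2.0
    semi = 0.45 * d
    idx = np.indices(dims)
    return sum(((idx[a] - centre[a]) / semi[a]) ** 2 for a in range(3)) <= 1.0


def simulate_subject_maps(rng: np.random.Generator, n_subjects: int,
                          dims: tuple[int, int, int], fwhm_vox: float,
                          effect: float = 0.0,
                          effect_mask: np.ndarray | None = None,
                          patient_rows: np.ndarray | None = None) -> np.ndarray:
    """Per-subject smooth Gaussian maps, optionally with a group effect
    added inside ``effect_mask`` for the ``patient_rows`` subjects.

    Fields are smoothed white noise re-standardised to unit variance, the
    stand-in for z-scored smoothed DC maps under the null.
    """
    sigma = fwhm_to_sigma(fwhm_vox)
    maps = np.empty((n_subjects,) + tuple(dims))
    for i in range(n_subjects):
        f = ndimage.gaussian_filter(rng.standard_normal(dims), sigma=sigma)
        f = (f - f.mean()) / f.std()
        maps[i] = f
    if effect != 0.0 and effect_mask is not None and patient_rows is not None:
        for i in np.nonzero(patient_rows)[0]:
            maps[i][effect_mask] += effect
    return maps


def _random_design(rng: np.random.Generator, n_per_group: int) -> DesignMatrix:
    n = 2 * n_per_group
    group = np.r_[np.ones(n_per_group), np.zeros(n_per_group)]
    age = rng.normal(28.0, 7.0, n)
    sex = (rng.random(n) < 0.5).astype(float)
    edu = rng.normal(12.0, 3.0, n)
    X = np.column_stack([np.ones(n), group, age, sex, edu])
    contrast = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
    return DesignMatrix(X=X, columns=["intercept", "group", "age", "sex",
                                      "education"], contrast=contrast,
                        subject_ids=[f"s{i}" for i in range(n)])


def null_calibration(n_sims: int = 500, dims: tuple[int, int, int] = (24, 24, 18),
                     smooth_fwhm_mm: float = 6.0, voxel_size_mm: float = 3.0,
                     n_per_group: int = 20, voxel_p: float = 0.001,
                     cluster_p: float = 0.05, seed: int = 0) -> dict:
    """Familywise false-positive rate of the RFT cluster correction under
    the global null (no group effect anywhere)."""
    rng = np.random.default_rng(seed)
    mask = _ellipsoid_mask(dims)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    vs = np.array([voxel_size_mm] * 3)
    fwhm_vox = smooth_fwhm_mm / voxel_size_mm
    n_fp = 0
    for _ in range(n_sims):
        design = _random_design(rng, n_per_group)
        maps = simulate_subject_maps(rng, 2 * n_per_group, dims, fwhm_vox)
        stat, resid = fit_voxelwise_glm(list(maps), design, mask, affine)
        fwhm_mm, resels = estimate_smoothness(resid, mask, vs)
        stat.residual_fwhm_mm = fwhm_mm
        stat.resel_count = resels
        clusters = grf_cluster_correct(stat, voxel_p, cluster_p, two_sided=True)
        if clusters:
            n_fp += 1
    return {"fwe_rate": n_fp / n_sims, "n_sims": n_sims}


def grf_permutation_concordance(n_datasets: int = 20, n_perm: int = 500,
                                dims: tuple[int, int, int] = (24, 24, 18),
                                smooth_fwhm_mm: float = 6.0,
                                voxel_size_mm: float = 3.0,
                                n_per_group: int = 20,
                                voxel_p: float = 0.001, cluster_p: float = 0.05,
                                ambiguous_band: tuple[float, float] = (0.01, 0.2),
                                seed: int = 0) -> dict:
    """Do RFT and the Freedman-Lane permutation test agree on which clusters
    survive?

    Datasets cycle through effect amplitudes (none, none, strong, very
    strong) planted in a spherical region of the patient maps, producing a
    spread of cluster strengths. For each dataset, every suprathreshold
    component whose corrected p is outside the ambiguous band under *both*
    methods must get the same survive/not-survive decision; the returned
    rate is the fraction of datasets where all such clusters agree.
    """
    rng = np.random.default_rng(seed)
    mask = _ellipsoid_mask(dims)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    vs = np.array([voxel_size_mm] * 3)
    fwhm_vox = smooth_fwhm_mm / voxel_size_mm
    centre = tuple(int(d * 0.4) for d in dims)
    idx = np.indices(dims)
    sphere = sum((idx[a] - centre[a]) ** 2 for a in range(3)) <= (6.0 / voxel_size_mm) ** 2
    sphere &= mask
    amplitudes = [0.0, 0.0, 1.5, 2.5]
    lo, hi = ambiguous_band
    n_agree = 0
    for d in range(n_datasets):
        design = _random_design(rng, n_per_group)
        patient_rows = design.X[:, 1] == 1.0
        maps = simulate_subject_maps(rng, 2 * n_per_group, dims, fwhm_vox,
                                     effect=amplitudes[d % len(amplitudes)],
                                     effect_mask=sphere,
                                     patient_rows=patient_rows)
        maps_list = list(maps)
        stat, resid = fit_voxelwise_glm(maps_list, design, mask, affine)
        fwhm_mm, resels = estimate_smoothness(resid, mask, vs)
        stat.residual_fwhm_mm = fwhm_mm
        stat.resel_count = resels
        # p for every component, not only survivors: rerun with cluster_p=1
        grf_all = grf_cluster_correct(stat, voxel_p, cluster_p=1.0 + 1e-9,
                                      two_sided=True)
        perm_all = permutation_cluster_correct(
            maps_list, design, mask, affine, n_perm, voxel_p,
            cluster_p=1.0 + 1e-9, seed=int(rng.integers(2 ** 31)),
            two_sided=True)
        # components are identical between methods (same threshold); match on
        # (sign, extent, peak voxel)
        key = lambda c: (c.sign, c.n_voxels, c.peak_coord_world)
        perm_by_key = {key(c): c for c in perm_all}
        agree = True
        for c in grf_all:
            pc = perm_by_key.get(key(c))
            if pc is None:
                continue
            if (lo < c.p_corrected < hi) or (lo < pc.p_corrected < hi):
                continue
            if (c.p_corrected < cluster_p) != (pc.p_corrected < cluster_p):
                agree = False
                break
        n_agree += agree
    return {"concordance_rate": n_agree / n_datasets, "n_datasets": n_datasets}


# ---------------------------------------------------------------------------
# full-pipeline effect recovery


def recovery_sim_config(seed: int = 0) -> SimConfig:
    """Reduced-size cohort for repeated full-pipeline recovery runs: the
    default planted loadings on an 18 x 18 x 12 grid, 125 volumes,
    12 subjects per group."""
    return SimConfig(grid_dims=(18, 18, 12), n_volumes=125, n_patients=12,
                     n_controls=12, seed=seed)


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = float((a & b).sum())
    return 2.0 * inter / (a.sum() + b.sum())


def effect_recovery(n_sims: int = 50, seed: int = 0,
                    dice_threshold: float = 0.3) -> dict:
    """Run the full simulate -> preprocess -> DC -> GLM -> RFT pipeline and
    ask how often the planted elevated-degree ROI is recovered by a
    surviving cluster (Dice > threshold), and whether the recovered
    cluster's sign matches the planted direction.

    Also tracks recovery of the planted depreciated-degree ROI.
    """
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_sims)
    n_up = n_dir_ok = n_down = 0
    for s in range(n_sims):
        cfg = recovery_sim_config(seed=int(children[s].generate_state(1)[0] % (2 ** 31)))
        cohort = simulate_cohort(cfg)
        maps = []
        for scan, conf in zip(cohort.scans, cohort.confounds):
            clean, qc = preprocess_scan(scan, conf)
            maps.append(dc_pipeline(clean, cohort.mask))
        design = DesignMatrix.from_phenotypes(cohort.phenotypes)
        stat, clusters = group_difference(
            maps, design, cohort.mask, cfg.affine,
            np.array([cfg.voxel_size_mm] * 3))
        up_roi = cohort.roi_masks["hub_up"]
        down_roi = cohort.roi_masks["hub_down"]
        up_hits = [c for c in clusters if _dice(c.mask, up_roi) > dice_threshold]
        if up_hits:
            n_up += 1
            if all(c.sign == "positive" for c in up_hits):
                n_dir_ok += 1
        if any(_dice(c.mask, down_roi) > dice_threshold and c.sign == "negative"
               for c in clusters):
            n_down += 1
    return {
        "recovery_rate_up": n_up / n_sims,
        "direction_match_rate": (n_dir_ok / n_up) if n_up else float("nan"),
        "recovery_rate_down": n_down / n_sims,
        "n_sims": n_sims,
    }


# ---------------------------------------------------------------------------
# classifier sanity


def svm_separated_clouds(n_per_group: int = 40, separation_sd: float = 6.0,
                         seed: int = 0) -> dict:
    """Held-out accuracy on two Gaussian feature clouds separated by
    ``separation_sd`` standard deviations (Bayes error ~0.13% at 6 sd)."""
    rng = np.random.default_rng(seed)
    X1 = rng.standard_normal((n_per_group, 2))
    X2 = rng.standard_normal((n_per_group, 2)) + separation_sd / np.sqrt(2.0)
    X = pd.DataFrame(np.vstack([X1, X2]), columns=["roi_a", "roi_b"])
    y = np.array(["patient"] * n_per_group + ["control"] * n_per_group)
    rep = svm_classify(X, y, seed=seed)
    return {"accuracy": rep.accuracy, "n": 2 * n_per_group}


def svm_label_permutation(n_per_group: int = 40, n_permutations: int = 100,
                          seed: int = 0) -> dict:
    """Mean held-out accuracy with labels randomly permuted (chance check).

    Uses a small hyperparameter grid and 5-fold outer CV per permutation to
    keep the null ensemble cheap; the leakage property being tested does not
    depend on grid size.
    """
    rng = np.random.default_rng(seed)
    X1 = rng.standard_normal((n_per_group, 2))
    X2 = rng.standard_normal((n_per_group, 2)) + 6.0 / np.sqrt(2.0)
    X = pd.DataFrame(np.vstack([X1, X2]), columns=["roi_a", "roi_b"])
    y = np.array(["patient"] * n_per_group + ["control"] * n_per_group)
    accs = []
    for i in range(n_permutations):
        yp = rng.permutation(y)
        rep = svm_classify(X, yp, cv_scheme="stratified-5fold",
                           C_grid=(1.0, 16.0), gamma_grid=(0.125, 0.5),
                           seed=seed + i)
        accs.append(rep.accuracy)
    return {"mean_accuracy": float(np.mean(accs)),
            "n_permutations": n_permutations}


# ---------------------------------------------------------------------------
# smoothness estimator


def smoothness_recovery(dims: tuple[int, int, int] = (30, 30, 30),
                        voxel_size_mm: float = 3.0, true_fwhm_mm: float = 6.0,
                        n_fields: int = 20, seed: int = 0) -> dict:
    """Estimate the FWHM of white noise smoothed with a known kernel."""
    rng = np.random.default_rng(seed)
    sigma = fwhm_to_sigma(true_fwhm_mm / voxel_size_mm)
    fields = np.empty((n_fields,) + dims)
    for i in range(n_fields):
        fields[i] = ndimage.gaussian_filter(rng.standard_normal(dims), sigma)
    mask = np.ones(dims, dtype=bool)
    fwhm_mm, resels = estimate_smoothness(fields, mask,
                                          np.array([voxel_size_mm] * 3))
    rel_err = np.abs(fwhm_mm - true_fwhm_mm) / true_fwhm_mm
    return {"fwhm_mm": [float(f) for f in fwhm_mm],
            "max_rel_error": float(rel_err.max()),
            "resel_count": resels, "n_fields": n_fields}
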