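# dcfmri — voxelwise degree centrality for resting-state fMRI

`dcfmri` is a tested, reusable implementation of a common resting-state
fMRI case-control analysis: **voxelwise degree centrality (DC) of the
functional connectome**, a covariate-adjusted voxelwise group comparison
with **Gaussian-random-field (GRF) cluster-extent correction**, and **SVM
classification** of groups from cluster-mean DC features. It is aimed at
researchers who want the whole chain — from 4-D BOLD volumes to a cluster
table and a classifier report — as inspectable, scriptable Python, together
with a synthetic BOLD cohort generator that makes every stage testable
without any scanner data.

## The statistic and the inference

For voxel *v* with time series *y_v*, degree centrality over a gray-matter
mask *M* is

  DC(v) = #{ u ∈ M, u ≠ v : r(y_v, y_u) > 0.25 }   (binary mode)

or the sum of those correlations (weighted mode); negative correlations
never contribute. Per subject, the DC map is z-scored across the mask and
smoothed with a 6 mm FWHM Gaussian kernel. Scans are first temporally
preprocessed (discard 5 volumes, ±2 mm/±2° motion QC, linear detrend,
0.01–0.08 Hz ideal band-pass, regression of 6 motion parameters + WM + CSF).

Group inference is a per-voxel OLS GLM (intercept + group + age + sex +
education) with a t contrast on group. Familywise control uses RFT
cluster-extent inference at voxel p < 0.001 (per tail) and cluster
p < 0.05: residual smoothness is estimated from spatial derivatives of the
unit-variance residual fields, the expected cluster count comes from the
3-D Euler-characteristic density, and each cluster's corrected p is the
Poisson bound 1 − exp(−E[m]·P(n ≥ k)) with the exponential extent
approximation P(n ≥ k) = exp(−β k^(2/3)). A Freedman–Lane permutation test
on the maximum cluster extent provides a distribution-free cross-check.
Classification is an RBF SVM on cluster-mean DC features with nested,
stratified cross-validation (inner grid search over C and γ; training-fold
standardisation only).

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
desk-scale cohort (24×24×18 voxel grid at 3 mm, TR 2 s, 150 volumes,
20 patients + 20 controls, two planted "hub" networks — one with elevated,
one with depreciated degree in patients):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_qc.py
python analysis/03_degree_centrality.py
python analysis/04_group_differences.py
python analysis/05_classification.py
```

Step 04 prints the cluster table (this run: df = 35, residual FWHM ≈ 6.9 mm):

```
 label  peak_x_mm  peak_y_mm  peak_z_mm  n_voxels    peak_t     sign  p_corrected
     1       10.5        7.5        4.5        57 -6.320057 negative     0.000005
     2      -13.5       -7.5        4.5        52  6.029334 positive     0.000011
```

Both planted hubs are recovered: a positive cluster (patients > controls)
at the elevated-degree ROI and a negative one at the depreciated-degree
ROI, each familywise-significant; a 1000-permutation test confirms both.
Step 05 trains the SVM on the two cluster-mean features and prints the
pooled held-out confusion:

```
"accuracy_pct": 92.5, "sensitivity_pct": 90.0, "specificity_pct": 95.0
```

i.e. 18/20 patients and 19/20 controls correctly classified, while the
patients' DC features show no significant correlation with symptom severity
or illness duration (all uncorrected p > 0.4) — as expected, since the
simulator plants group effects but no within-patient clinical coupling.

The same pipeline is available as a CLI (`dcfmri simulate|preprocess|dc|
group|classify|all`) driven by a YAML config; `dcfmri all --out DIR` runs
everything end to end.

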