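"""SVM classification from cluster-mean DC features + clinical correlations.

Features are the per-subject mean z-scored smoothed DC over the largest
elevated and largest depreciated surviving clusters (the two-region
biomarker analog). An RBF SVM with nested, stratified 10-fold CV yields
pooled held-out confusion counts; Pearson correlations test whether the
features track symptom severity or illness duration in patients.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dcfmri.io import read_volume
from dcfmri.degcen import DCMap
from dcfmri.classify import (extract_features, svm_classify,
                             correlate_clinical, plot_decision_surface)

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "analysis" / "cohort"
DC_DIR = ROOT / "scratch" / "analysis" / "dcmaps"
GROUP_DIR = ROOT / "scratch" / "analysis" / "group"
RESULTS = ROOT / "results"


def main() -> None:
    mask, affine = read_volume(COHORT_DIR / "brain_mask.nii.gz")
    mask = mask.astype(bool)
    labels_map, _ = read_volume(GROUP_DIR / "cluster_labels.nii.gz")
    tmap, _ = read_volume(GROUP_DIR / "tmap.nii.gz")
    pheno = pd.read_csv(COHORT_DIR / "phenotypes.tsv", sep="\t",
                        na_values=["NA"])

    # largest elevated / depreciated surviving clusters as the two ROIs
    rois = {}
    tab = pd.read_csv(RESULTS / "cluster_table.tsv", sep="\t")
    for sign in ("positive", "negative"):
        sub = tab[tab["sign"] == sign]
        if len(sub):
            lab = int(sub.sort_values("n_voxels").iloc[-1]["label"])
            rois[f"cluster{lab}_{sign}"] = labels_map == lab
    if not rois:
        raise SystemExit("no surviving clusters to build features from")

    maps, ids = [], []
    for _, row in pheno.iterrows():
        p = DC_DIR / f"{row['id']}_dcz.nii.gz"
        if not p.exists():
            continue
        vals, _ = read_volume(p)
        maps.append(DCMap(values=vals, mask=mask, kind="zscored_smoothed",
                          r_threshold=0.25, affine=affine,
                          subject_id=row["id"]))
        ids.append(row["id"])
    pheno = pheno[pheno["id"].isin(ids)].reset_index(drop=True)

    feats = extract_features(maps, rois, ids)
    feats.to_csv(RESULTS / "features.tsv", sep="\t", float_format="%.6f")
    rep = svm_classify(feats, pheno["group"].to_numpy(), seed=13)
    report = {
        "tp": rep.tp, "fn": rep.fn, "tn": rep.tn, "fp": rep.fp,
        "accuracy_pct": round(100 * rep.accuracy, 2),
        "sensitivity_pct": round(100 * rep.sensitivity, 2),
        "specificity_pct": round(100 * rep.specificity, 2),
        "best_C": rep.best_C, "best_gamma": rep.best_gamma,
        "cv_scheme": rep.cv_scheme, "seed": rep.seed,
        "features": list(feats.columns),
    }
    (RESULTS / "classifier_report.json").write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))

    if feats.shape[1] == 2:
        fig_dir = ROOT / "scratch" / "analysis" / "figures"
        fig_dir.mkdir(parents=True, exist_ok=True)
        plot_decision_surface(feats, pheno["group"].to_numpy(),
                              fig_dir / "decision_surface.png",
                              C=rep.best_C, gamma=rep.best_gamma)
        print(f"\ndecision-surface figure: {fig_dir / 'decision_surface.png'}")

    clin = correlate_clinical(feats, pheno)
    clin.to_csv(RESULTS / "clinical_correlations.tsv", sep="\t", index=False,
                float_format="%.4f")
    print("\nclinical correlations (patients, uncorrected p):")
    print(clin.to_string(index=False))


if __name__ == "__main__":
    main()
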