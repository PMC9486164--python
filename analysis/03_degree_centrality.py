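"""Voxelwise degree centrality per subject.

Degree at r > 0.25 over the brain mask (binary count), z-scored across the
mask and smoothed at 6 mm FWHM; maps go to scratch/analysis/dcmaps.
"""

from pathlib import Path

import numpy as np

from dcfmri.io import read_bold, read_volume, write_volume
from dcfmri.degcen import dc_pipeline

ROOT = Path(__file__).resolve().parents[1]
CLEAN_DIR = ROOT / "scratch" / "analysis" / "clean"
COHORT_DIR = ROOT / "scratch" / "analysis" / "cohort"
DC_DIR = ROOT / "scratch" / "analysis" / "dcmaps"


def main() -> None:
    DC_DIR.mkdir(parents=True, exist_ok=True)
    mask, affine = read_volume(COHORT_DIR / "brain_mask.nii.gz")
    mask = mask.astype(bool)
    n = 0
    for path in sorted(CLEAN_DIR.glob("*_clean.nii.gz")):
        sid = path.name.replace("_clean.nii.gz", "")
        scan = read_bold(path, subject_id=sid)
        dcm = dc_pipeline(scan, mask)
        write_volume(dcm.values.astype(np.float32), affine,
                     DC_DIR / f"{sid}_dcz.nii.gz")
        n += 1
    print(f"wrote {n} z-scored smoothed DC maps "
          f"({int(mask.sum())} in-mask voxels) to {DC_DIR}")


if __name__ == "__main__":
    main()
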