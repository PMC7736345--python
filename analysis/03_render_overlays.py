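#!/usr/bin/env python
"""Render per-specimen prediction overlays (tumor green, normal yellow).

For each specimen of the stored cohort this re-runs the LOOCV predictions
and writes two PNGs: the full color-coded prediction and the "merged"
variant that blanks the boundary-exclusion corridor and draws the
pathologist boundary in blue.
"""

import argparse
from pathlib import Path

import numpy as np
from PIL import Image

from gisthsi.pipeline_eval import PipelineConfig, load_cohort, loocv_run
from gisthsi.pipeline_eval import overlay


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--out-dir", type=Path, default=Path("scratch/overlays"))
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    records = load_cohort(args.cohort_dir)
    preds, _ = loocv_run(records, PipelineConfig(seed=args.seed))
    args.out_dir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        for variant, merged in (("prediction", False), ("merged", True)):
            img = overlay(preds[rec.id], rec.cube, rec.annotations,
                          merged=merged)
            path = args.out_dir / f"{rec.id}_{variant}.png"
            Image.fromarray(img.to_uint8()).save(path)
        print(f"rendered {rec.id}")
    print(f"overlays in {args.out_dir}")


if __name__ == "__main__":
    main()
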