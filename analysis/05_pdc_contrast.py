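#!/usr/bin/env python
"""Directed corticomuscular coupling: MVAR/PDC band values and contrasts.

Reads scratch/study, fits a 3-channel MVAR (C3, C4, contracting-side EMG)
per subject and condition on the continuous cleaned segment, averages PDC in
beta/gamma1/gamma2, and paired-tests deprived vs rested with BH-FDR over the
(directed pair x band) family.  Writes results/pdc_band_values.csv and
results/pdc_contrast_left_contraction.csv.
"""

import sys
from pathlib import Path

from myocortex import RunConfig
from myocortex.pipeline import contrast_stage, load_dataset, pdc_stage

DATA = Path("scratch/study")
OUT = Path("results")


def main() -> int:
    cfg = RunConfig(seed=2024, out_dir=str(OUT), pdc_segment_s=30.0, pdc_max_order=12)
    OUT.mkdir(exist_ok=True)
    recs = load_dataset(DATA)
    table, rep = pdc_stage(recs, cfg, OUT)
    print(f"{len(table)} band-PDC values -> {rep.outputs[0]}")
    contrasts, rep = contrast_stage(table, cfg, OUT, state="left_contraction")
    print(f"left-contraction contrast -> {rep.outputs[0]}")
    sig = contrasts[contrasts.significant]
    if sig.empty:
        print("no significant directed changes after FDR")
    for _, row in sig.iterrows():
        print(f"  {row.source} -> {row.target} [{row.band}]: {row.direction} "
              f"(t = {row.t:.2f}, p = {row.p:.4g})")
    return 0


if __name__ == "__main__":
    sys.exit(main())
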