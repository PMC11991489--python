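#!/usr/bin/env python
"""EMG fatigue indices per epoch and band, plus the deprivation contrast.

Reads scratch/study (run 01 first), cleans the EMG channel, computes
RMS/MPF/MF in 20-100 and 100-150 Hz, writes results/emg_features.csv, and
tests whether the left-biceps high-band median frequency drops after sleep
deprivation (Wilcoxon signed-rank on subject means).
"""

import sys
from pathlib import Path

from myocortex import RunConfig
from myocortex.pipeline import emg_stage, load_dataset, preprocess_stage
from myocortex.stats import PairedSample, wilcoxon_signed

DATA = Path("scratch/study")
OUT = Path("results")


def main() -> int:
    cfg = RunConfig(seed=2024, out_dir=str(OUT))
    OUT.mkdir(exist_ok=True)
    recs = load_dataset(DATA)
    pre, _ = preprocess_stage(recs, cfg)
    table, rep = emg_stage(pre, cfg, OUT)
    print(f"{len(table)} feature rows -> {rep.outputs[0]}")

    hi = table[(table.band_lo == 100.0) & (table.state == "left_contraction")]
    per_subj = hi.groupby(["condition", "subject"]).mf.mean().unstack(level=0)
    w, p = wilcoxon_signed(PairedSample(per_subj["poor"].values, per_subj["good"].values))
    print(f"left biceps MF (100-150 Hz): good {per_subj['good'].mean():.1f} Hz, "
          f"poor {per_subj['poor'].mean():.1f} Hz, Wilcoxon p = {p:.4g}")
    direction = "decreased" if per_subj["poor"].mean() < per_subj["good"].mean() else "increased"
    print(f"-> high-band MF {direction} after sleep deprivation")
    return 0


if __name__ == "__main__":
    sys.exit(main())
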