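#!/usr/bin/env python
"""Generate the desk-scale synthetic study that the later analyses consume.

Writes 12 subjects x {good, poor} sleep x {rest, left, right contraction}
EDF recordings (30 s each, 31 channels at 1000 Hz) plus the ground-truth
JSON under scratch/study/.  The three injected effects are:

  (i)   reduced interhemispheric alpha PLV at rest after deprivation,
  (ii)  a downshifted left-biceps EMG spectrum after deprivation,
  (iii) increased C4 -> left-EMG and decreased left-EMG -> C4 directed
        coupling in the gamma1 range after deprivation.
"""

import sys
from pathlib import Path

from myocortex import gen_study

OUT = Path("scratch/study")
SEED = 2024


def main() -> int:
    if OUT.exists():
        print(f"{OUT} already exists; delete it to regenerate.")
        return 0
    study = gen_study(n_subjects=12, duration_s=30.0, seed=SEED, out_dir=OUT)
    n = len(study.recordings)
    gt = study.ground_truth
    print(f"wrote {n} recordings ({study.duration_s:.0f} s @ {study.rate:.0f} Hz) to {OUT}")
    print(f"EMG centroid good/poor-left: {gt.effects.emg_centroid_good:.0f} / "
          f"{gt.effects.emg_centroid_poor_left:.0f} Hz")
    print(f"C4->EMG coupling good/poor: {gt.effects.cortex_to_emg_good} / "
          f"{gt.effects.cortex_to_emg_poor}")
    print(f"EMG->C4 coupling good/poor: {gt.effects.emg_to_cortex_good} / "
          f"{gt.effects.emg_to_cortex_poor}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
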