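#!/usr/bin/env python
"""Network-based statistic: deprived vs well-rested alpha PLV per motor state.

Reads scratch/study, builds the subject-matched PLV stacks, and runs the NBS
with 2000 sign-flip permutations (edge and component alpha 0.05).  Writes
results/nbs_alpha.json and prints any surviving components with their
direction.
"""

import sys
from pathlib import Path

from myocortex import RunConfig
from myocortex.pipeline import load_dataset, nbs_stage, plv_stage, preprocess_stage
from myocortex.plv import ROI_NAMES

DATA = Path("scratch/study")
OUT = Path("results")


def main() -> int:
    cfg = RunConfig(seed=2024, out_dir=str(OUT))
    OUT.mkdir(exist_ok=True)
    recs = load_dataset(DATA)
    pre, _ = preprocess_stage(recs, cfg)
    matrices, _ = plv_stage(pre, cfg, OUT, bands=("alpha",))
    results, rep = nbs_stage(matrices, cfg, OUT, band="alpha")
    print(f"NBS (deprived vs rested, alpha band) -> {rep.outputs[0]}")
    for state, res in results.items():
        sig = res.significant_components()
        if not sig:
            print(f"  {state}: no significant component")
            continue
        for comp, p in zip(res.components, res.component_p):
            if p >= cfg.comp_alpha:
                continue
            signs = {"decreased" if res.t_matrix[i, j] < 0 else "increased"
                     for i, j in comp}
            label = "/".join(sorted(signs))
            sample = ", ".join(f"{ROI_NAMES[i]}-{ROI_NAMES[j]}" for i, j in comp[:4])
            print(f"  {state}: {len(comp)}-edge {label} component (p = {p:.4f}); "
                  f"e.g. {sample} ...")
    return 0


if __name__ == "__main__":
    sys.exit(main())
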