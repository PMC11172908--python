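"""From raw window counts to absolute copy numbers and per-sample CNV calls.

GC bias is removed by per-sample median-ratio correction in 20 GC bins, each
sample is rescaled so its median window maps to copy number 2, and windows
crossing the loss (<= 1.5) or gain (>= 2.5) thresholds are segmented into
calls.
"""

import numpy as np

from cnvpopscan import (
    GCBias,
    call_sample_cnvs,
    demo_region_specs,
    gc_correct,
    make_windowed_genome,
    normalize_copy_number,
    plant_truth,
    simulate_depth,
)
from cnvpopscan.depth import calls_to_frame

genome = make_windowed_genome({"chr1": 800_000}, gc_profile_seed=2, mask_fraction=0.02)
groups = {g: 10 for g in ("RC", "T", "WZS", "YL", "LR")}
specs = demo_region_specs(genome, groups=tuple(groups), n_shared=7, seed=2)
truth = plant_truth(genome, groups, specs, seed=2)
depth = simulate_depth(genome, truth, mean_coverage=50, gc_bias=GCBias(0.45, 0.5), seed=2)

cnmat = normalize_copy_number(gc_correct(depth, genome))
medians = [np.median(row[genome.unmasked]) for row in cnmat.cn]
print(f"per-sample median CN: {min(medians):.3f} .. {max(medians):.3f} (diploid baseline 2)")

calls = call_sample_cnvs(cnmat, loss_max=1.5, gain_min=2.5, min_windows=2, max_gap_windows=1)
df = calls_to_frame(calls)
print(f"{len(df)} calls across {df['sample'].nunique()} samples")
print(df.groupby("kind").agg(n=("kind", "size"), mean_len=("n_windows", "mean")))
print(df.head(5).to_string(index=False))
# Every call is a run of windows whose copy number crossed a threshold; losses
# have mean CN < 2 and gains > 2 by construction.
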