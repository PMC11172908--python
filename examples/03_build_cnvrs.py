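"""Aggregate per-window copy numbers into population CNVRs.

Windows where >18% of samples deviate from CN 2 are flagged, flagged runs are
merged (correlated neighbours joined), every sample is genotyped by its median
CN over the region, and regions are classified Loss/Gain/Both from carrier
frequencies, then filtered on silhouette (> 0.6) and length caps (50 kb for
losses and complex regions, 500 kb for gains).
"""

from cnvpopscan import (
    GCBias,
    MergeConfig,
    build_cnvrs,
    demo_region_specs,
    gc_correct,
    make_windowed_genome,
    normalize_copy_number,
    plant_truth,
    simulate_depth,
)
from cnvpopscan.cnvr import cnvrs_to_frame

genome = make_windowed_genome({"chr1": 800_000}, gc_profile_seed=3, mask_fraction=0.02)
groups = {g: 10 for g in ("RC", "T", "WZS", "YL", "LR")}
specs = demo_region_specs(genome, groups=tuple(groups), n_shared=7, seed=3)
truth = plant_truth(genome, groups, specs, seed=3)
depth = simulate_depth(genome, truth, mean_coverage=50, gc_bias=GCBias(0.45, 0.5), seed=3)
cnmat = normalize_copy_number(gc_correct(depth, genome))

cnvrs = build_cnvrs(cnmat, MergeConfig(min_variant_freq=0.18), af_mode="carrier")
df = cnvrs_to_frame(cnvrs)
print(f"{len(cnvrs)} CNVRs retained ({len(truth.regions)} regions planted)")
print(df.to_string(index=False))
# loss_af / gain_af are carrier fractions (samples with CN < 2 / CN > 2);
# silhouette close to 1 means the per-sample copy numbers separate cleanly
# into integer CN states.
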