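"""Simulate a five-population cohort with planted, stratified CNVs.

Builds an 800 bp windowed genome, plants 20 CNV regions whose carrier
frequencies differ between populations (e.g. a duplication fixed in RC but at
50% in the commercial breeds), and draws Poisson read counts per window with
a mild GC bias.
"""

from cnvpopscan import GCBias, demo_region_specs, make_windowed_genome, plant_truth, simulate_depth

genome = make_windowed_genome(
    {"chr1": 1_000_000, "chr2": 600_000, "chr3": 400_000},
    window_size=800,
    gc_profile_seed=1,
    mask_fraction=0.02,
)
groups = {g: 10 for g in ("RC", "T", "WZS", "YL", "LR")}
specs = demo_region_specs(genome, groups=tuple(groups), seed=1)
truth = plant_truth(genome, groups, specs, seed=1)
depth = simulate_depth(
    genome, truth, mean_coverage=50, gc_bias=GCBias(0.45, 0.5), dispersion=0.0, seed=1
)

print(f"windows: {genome.n_windows} ({genome.masked.sum()} masked)")
print(f"samples: {len(truth.samples)} in {len(groups)} populations")
print(f"planted regions: {len(truth.regions)}")
print(truth.regions_frame().head(8).to_string(index=False))
print(f"mean depth: {depth.values.mean():.1f} reads/window")
# Each row above is one planted region with its requested and realized carrier
# frequency per population; depth should sit near the 50x target.
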