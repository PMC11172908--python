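"""Annotate CNVRs with genomic context, genes and QTLs; compare to another study.

Context labels use exon > intron > intergenic precedence; genes are assigned
when >= 50% of the gene overlaps the CNVR; QTL overlap is any-overlap. The
cross-study comparison reports how many of our CNVRs intersect another
interval set, the ratio over our total, and the intersected length in Mb.
"""

import pandas as pd

from cnvpopscan import chromosome_summary, compare_study, genomic_context, overlap_genes, overlap_qtls
from cnvpopscan.cnvr import cnvrs_to_frame
from cnvpopscan.pipeline import demo_config, run_pipeline

_, state = run_pipeline(demo_config(seed=5), "scratch/example_annotate_run", return_state=True)
cnvrs = cnvrs_to_frame(state["cnvrs"])
annotation = state["annotation"]

context = genomic_context(cnvrs, annotation)
print("genomic context:", context.value_counts().to_dict())

genes = overlap_genes(cnvrs, annotation, min_gene_fraction=0.5)
qtl_map, n_hit, n_traits = overlap_qtls(cnvrs, annotation.qtls)
print(f"CNVRs with >=50%-overlapped genes: {len(genes)}")
print(f"CNVRs with QTL hits: {n_hit} (distinct traits: {n_traits})")

summary = chromosome_summary(cnvrs, state["genome"].chrom_lengths)
print(f"CNVR count vs chromosome length: R^2 = {summary.r2:.2f}, p = {summary.p_value:.3f}")

# compare against a shifted copy of our own set standing in for another study
theirs = cnvrs[["chrom", "start", "end"]].copy()
theirs["start"] += 2400
theirs["end"] += 2400
cmp = compare_study(cnvrs, theirs, label="shifted_self")
print(
    f"vs {cmp.other_study_label}: overlap number {cmp.overlap_number}/{cmp.n_ours}, "
    f"ratio {cmp.overlap_ratio}, overlap length {cmp.overlap_length_mb:.4f} Mb"
)
# A 3-window shift keeps most regions partially overlapping, so the ratio is
# high while the intersected length drops below the full union length.
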