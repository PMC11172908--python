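# cnvpopscan

Population copy-number-variation (CNV) analysis for multi-breed whole-genome
resequencing cohorts, built around read-depth detection in fixed 800 bp
windows. The package is aimed at livestock and population genomicists who
want a transparent, testable implementation of the standard pipeline:

1. **Depth calling** — per-window read counts are GC-corrected (per-sample
   median-ratio adjustment in GC bins), rescaled to absolute copy number
   (diploid baseline CN = 2), and segmented into per-sample gain/loss calls.
2. **CNVR construction** — per-sample evidence is aggregated into copy number
   variation regions (CNVRs): windows where enough samples deviate from CN 2
   are flagged, flagged runs are merged (correlated neighbours joined), every
   sample is genotyped by its median CN over the region, and regions are
   classified from deletion/duplication allele frequencies:

   * Loss: 0.05 < Loss AF ≤ 0.95 and Gain AF ≤ 0.01
   * Gain: 0.05 < Gain AF < 0.95 and Loss AF ≤ 0.01
   * Both: 0.05 < Gain AF < 0.95 and 0.05 < Loss AF ≤ 0.95

   followed by a silhouette filter (> 0.6) and length caps (50 kb for Loss
   and Both, 500 kb for Gain).
3. **Vst selective scan** — per CNVR and population contrast,

   Vst = (V_T − V_S) / V_T

   where V_T is the population variance of copy number across the pooled
   samples and V_S = (n_A·V_A + n_B·V_B)/(n_A + n_B) is the size-weighted mean
   within-group variance. With population variances, 0 ≤ Vst ≤ 1 by the law of
   total variance. Regions in the empirical top 5% of a contrast are flagged
   as differentiation candidates.
4. **Annotation & comparison** — genomic context (exon > intron > intergenic),
   gene assignment at ≥ 50% gene overlap, any-overlap QTL annotation,
   per-chromosome count-vs-length regression, and cross-study CNVR overlap
   statistics (overlap number, ratio, intersected Mb).
5. **Synthetic cohorts** — a first-class generator that tiles a genome, plants
   population-stratified CNV regions with exact per-group carrier frequencies,
   and draws Poisson / negative-binomial depth with a configurable GC bias, so
   the whole pipeline is verifiable against a known truth without any
   external data.

All coordinates are BED-style 0-based half-open; CNVR ids use 1-based
inclusive locus notation (`chr3:8001-16800`).

## Worked example

The Vst statistic on a hand-checkable input — two groups of four samples,
one with two duplication carriers (V_T = 0.1875, V_S = 0.125):

```python
>>> from cnvpopscan import vst
>>> vst([2, 2, 3, 3], [2, 2, 2, 2])
0.3333333333333333
```

A full demo run — five populations (RC, T, WZS, YL, LR) of ten samples on a
2 Mb genome with 20 planted regions at 50 reads/window — then the flagged
top-5% candidates per contrast:

```python
from cnvpopscan.pipeline import demo_config, run_pipeline

_, state = run_pipeline(demo_config(seed=1), "demo_run", return_state=True)
records = state["vst"]
print(records[records.candidate].round(3).to_string(index=False))
```

```
           cnvr_id     contrast    vt    vs   vst  rank_pct  candidate
chr3:136801-148000  RC_vs_YL+LR 0.914 0.677 0.260     100.0       True
   chr3:8001-16800   T_vs_YL+LR 0.910 0.133 0.854     100.0       True
  chr2:84801-95200 WZS_vs_YL+LR 0.795 0.218 0.726     100.0       True
```

Each contrast flags exactly one region: the duplication fixed in RC (but at
50% elsewhere, hence the moderate Vst of 0.26), the deletion at 95% frequency
in T (Vst 0.85), and the deletion nearly absent in WZS but fixed in the
commercial breeds (Vst 0.73) — precisely the three population-differential
regions the generator planted.

The `examples/` directory has one short script per capability (simulation,
depth calling, CNVR construction, Vst scan, annotation/comparison); each
prints the numbers it computes and says what they mean. A thin CLI mirrors the
stages:

```bash
cnvpopscan run --config run.yaml --out rundir/
cnvpopscan vst --genotypes geno.tsv --groups groups.tsv --contrast RC:YL,LR --out vst.tsv
```

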