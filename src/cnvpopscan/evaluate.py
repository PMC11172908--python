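"""Evaluation of pipeline output against a planted truth set.

Used to validate the method on synthetic cohorts: reciprocal-overlap matching
of planted regions to calls/CNVRs, carrier-frequency recovery, and residual
GC correlation after correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .cnvr import CNVR
from .cohort import TruthSet
from .depth import CNVCall
from .genome import WindowedGenome
from .matrix import DepthMatrix


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """min(intersection/len(a), intersection/len(b)); 0 when disjoint."""
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def match_truth_to_cnvrs(
    truth: TruthSet, cnvrs: list[CNVR], min_ro: float = 0.8
) -> dict[str, CNVR | None]:
    """Best reciprocal-overlap CNVR (>= min_ro) for each planted region."""
    out: dict[str, CNVR | None] = {}
    for r in truth.regions:
        best, best_ro = None, 0.0
        for c in cnvrs:
            if c.chrom != r.chrom:
                continue
            ro = reciprocal_overlap(r.start, r.end, c.start, c.end)
            if ro > best_ro:
                best, best_ro = c, ro
        out[r.region_id] = best if best_ro >= min_ro else None
    return out


def cnvr_recovery_rate(truth: TruthSet, cnvrs: list[CNVR], min_ro: float = 0.8) -> float:
    """Fraction of planted regions matched by a final CNVR at >= min_ro."""
    matched = match_truth_to_cnvrs(truth, cnvrs, min_ro)
    return sum(v is not None for v in matched.values()) / len(matched)


def carrier_freq_errors(truth: TruthSet, cnvrs: list[CNVR], min_ro: float = 0.8) -> pd.DataFrame:
    """Per (matched region, group): |estimated - realized| carrier fraction.

    The estimate is the fraction of the group's samples whose integer CNVR
    genotype deviates from 2 on the planted side (CN < 2 for losses, > 2 for
    gains); the reference is the realized (post-rounding) planted fraction.
    """
    matched = match_truth_to_cnvrs(truth, cnvrs, min_ro)
    groups = sorted(set(truth.sample_groups.values()))
    rows = []
    for i, r in enumerate(truth.regions):
        c = matched[r.region_id]
        if c is None:
            continue
        for g in groups:
            members = [s for s, gg in truth.sample_groups.items() if gg == g]
            truth_frac = sum(1 for s in members if s in truth.carriers[i]) / len(members)
            if r.kind == "gain":
                est = np.mean([c.per_sample_cn_int[s] > 2 for s in members])
            else:
                est = np.mean([c.per_sample_cn_int[s] < 2 for s in members])
            rows.append(
                {
                    "region_id": r.region_id,
                    "group": g,
                    "kind": r.kind,
                    "truth_freq": truth_frac,
                    "estimated_freq": float(est),
                    "abs_error": abs(float(est) - truth_frac),
                }
            )
    return pd.DataFrame(rows)


def call_recovery(
    truth: TruthSet, calls: list[CNVCall], min_ro: float = 0.8, min_windows: int = 3,
    window_size: int = 800,
) -> pd.DataFrame:
    """Per (planted region, carrier sample): was a same-kind call recovered?

    Only regions spanning at least ``min_windows`` windows are scored (shorter
    events are below the caller's resolution by design).
    """
    by_sample: dict[str, list[CNVCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample, []).append(c)
    rows = []
    for i, r in enumerate(truth.regions):
        if (r.end - r.start) < min_windows * window_size:
            continue
        for sample, cn in truth.carriers[i].items():
            kind = "gain" if cn > 2 else "loss"
            best = 0.0
            for c in by_sample.get(sample, []):
                if c.chrom == r.chrom and c.kind == kind:
                    best = max(best, reciprocal_overlap(r.start, r.end, c.start, c.end))
            rows.append(
                {
                    "region_id": r.region_id,
                    "sample": sample,
                    "kind": kind,
                    "best_ro": best,
                    "recovered": best >= min_ro,
                }
            )
    return pd.DataFrame(rows)


def gc_residual_correlation(depth: DepthMatrix, genome: WindowedGenome) -> pd.Series:
    """Per-sample Pearson r between depth and GC over unmasked windows."""
    sel = genome.unmasked
    gc = genome.gc[sel]
    out = {}
    for si, sample in enumerate(depth.samples):
        out[sample] = float(pearsonr(depth.values[si, sel], gc).statistic)
    return pd.Series(out, name="r_depth_gc")
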