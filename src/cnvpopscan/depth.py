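"""Read depth -> absolute copy number -> per-sample CNV calls.

The detection chain mirrors population-scale read-depth callers: per-window
counts are corrected for GC bias by a per-sample median-ratio adjustment in GC
bins, rescaled so each sample's genome-wide median equals the diploid copy
number 2, and segmented into gain/loss calls by run-length grouping of
threshold-crossing windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .genome import WindowedGenome
from .matrix import CopyNumberMatrix, DepthMatrix

DEFAULT_LOSS_MAX = 1.5
DEFAULT_GAIN_MIN = 2.5
DEFAULT_MIN_WINDOWS = 2
DEFAULT_MAX_GAP_WINDOWS = 0
DEFAULT_GC_BINS = 20


@dataclass
class CNVCall:
    """One per-sample gain or loss segment (window-boundary resolution).

    ``mean_cn`` is averaged over the threshold-crossing (seed) windows of the
    run, so a loss call always has mean_cn < 2 and a gain call > 2;
    ``n_windows`` is the full window span including bridged gaps.
    """

    sample: str
    chrom: str
    start: int
    end: int
    kind: str
    mean_cn: float
    n_windows: int


def gc_correct(depth: DepthMatrix, genome: WindowedGenome, n_bins: int = DEFAULT_GC_BINS) -> DepthMatrix:
    """Median-ratio GC correction, per sample.

    Unmasked windows are grouped into ``n_bins`` equal-width GC bins; each
    sample's depths in a bin are scaled by (sample global median / bin median).
    Bins whose median is 0 are left unchanged (a warning lists them). Masked
    windows pass through untouched.
    """
    if n_bins < 1:
        raise ConfigurationError(f"n_bins must be >= 1, got {n_bins}")
    if depth.n_samples == 0 or depth.values.size == 0:
        raise InputError("empty depth matrix")

    gc = genome.gc
    unmasked = genome.unmasked
    if not unmasked.any():
        raise InputError("no unmasked windows")

    lo, hi = gc[unmasked].min(), gc[unmasked].max()
    if hi <= lo:
        edges = np.array([lo - 0.5, hi + 0.5])
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    bin_of = np.clip(np.digitize(gc, edges) - 1, 0, len(edges) - 2)

    out = depth.values.copy()
    zero_bins: set[int] = set()
    for si in range(depth.n_samples):
        row = depth.values[si]
        global_med = np.median(row[unmasked])
        for b in range(len(edges) - 1):
            sel = unmasked & (bin_of == b)
            if not sel.any():
                continue
            med = np.median(row[sel])
            if med <= 0:
                zero_bins.add(b)
                continue
            out[si, sel] = row[sel] * (global_med / med)
    if zero_bins:
        warnings.warn(
            f"GC bins with zero median depth left uncorrected: {sorted(zero_bins)}",
            stacklevel=2,
        )
    return DepthMatrix(samples=list(depth.samples), values=out, genome=genome)


def normalize_copy_number(corrected: DepthMatrix) -> CopyNumberMatrix:
    """Rescale each sample so its median unmasked depth maps to copy number 2.

    cn[s, w] = 2 * depth[s, w] / median_w(depth[s, unmasked]). Masked windows
    become NaN sentinels.
    """
    if corrected.n_samples == 0 or corrected.values.size == 0:
        raise InputError("empty depth matrix")
    unmasked = corrected.genome.unmasked
    cn = np.full_like(corrected.values, np.nan, dtype=float)
    for si, sample in enumerate(corrected.samples):
        med = np.median(corrected.values[si, unmasked])
        if med <= 0:
            raise InputError(f"sample {sample!r} has zero median depth")
        cn[si, unmasked] = 2.0 * corrected.values[si, unmasked] / med
    return CopyNumberMatrix(samples=list(corrected.samples), cn=cn, genome=corrected.genome)


def _runs_for_kind(
    seed_idx: np.ndarray,
    opposite: np.ndarray,
    max_gap: int,
) -> list[tuple[int, int]]:
    """Group sorted seed indices into runs; gaps <= max_gap windows are bridged
    unless an opposite-kind seed sits in the gap. Returns (first, last) pairs."""
    runs: list[tuple[int, int]] = []
    if seed_idx.size == 0:
        return runs
    first = last = int(seed_idx[0])
    for i in seed_idx[1:]:
        i = int(i)
        gap = i - last - 1
        if gap <= max_gap and not opposite[last + 1 : i].any():
            last = i
        else:
            runs.append((first, last))
            first = last = i
    runs.append((first, last))
    return runs


def call_sample_cnvs(
    cnmat: CopyNumberMatrix,
    loss_max: float = DEFAULT_LOSS_MAX,
    gain_min: float = DEFAULT_GAIN_MIN,
    min_windows: int = DEFAULT_MIN_WINDOWS,
    max_gap_windows: int = DEFAULT_MAX_GAP_WINDOWS,
) -> list[CNVCall]:
    """Segment each sample's copy-number track into gain/loss calls.

    Windows with cn <= loss_max (resp. >= gain_min) seed calls; same-kind seeds
    separated by at most ``max_gap_windows`` non-seed windows are merged; runs
    with fewer than ``min_windows`` seed windows are dropped. Calls are
    non-overlapping per sample and sorted by position.
    """
    if not loss_max < 2 < gain_min:
        raise ConfigurationError(
            f"thresholds must satisfy loss_max < 2 < gain_min, got {loss_max}, {gain_min}"
        )
    if min_windows < 1 or max_gap_windows < 0:
        raise ConfigurationError("min_windows must be >= 1 and max_gap_windows >= 0")

    genome = cnmat.genome
    starts = genome.windows["start"].to_numpy()
    ends = genome.windows["end"].to_numpy()
    calls: list[CNVCall] = []
    with np.errstate(invalid="ignore"):
        loss_seed_all = cnmat.cn <= loss_max
        gain_seed_all = cnmat.cn >= gain_min
    loss_seed_all &= genome.unmasked[None, :]
    gain_seed_all &= genome.unmasked[None, :]

    for si, sample in enumerate(cnmat.samples):
        for chrom in genome.chrom_lengths:
            sl = genome.chrom_slice(chrom)
            for kind, seeds, opposite in (
                ("loss", loss_seed_all[si, sl], gain_seed_all[si, sl]),
                ("gain", gain_seed_all[si, sl], loss_seed_all[si, sl]),
            ):
                idx = np.flatnonzero(seeds)
                for first, last in _runs_for_kind(idx, opposite, max_gap_windows):
                    run_seeds = idx[(idx >= first) & (idx <= last)]
                    if run_seeds.size < min_windows:
                        continue
                    calls.append(
                        CNVCall(
                            sample=sample,
                            chrom=chrom,
                            start=int(starts[sl.start + first]),
                            end=int(ends[sl.start + last]),
                            kind=kind,
                            mean_cn=float(np.mean(cnmat.cn[si, sl.start + run_seeds])),
                            n_windows=int(last - first + 1),
                        )
                    )
    calls.sort(key=lambda c: (c.sample, c.chrom, c.start))
    return calls


def calls_to_frame(calls: list[CNVCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "sample": c.sample,
                "kind": c.kind,
                "mean_cn": c.mean_cn,
                "n_windows": c.n_windows,
            }
            for c in calls
        ],
        columns=["chrom", "start", "end", "sample", "kind", "mean_cn", "n_windows"],
    )


def write_calls(calls: list[CNVCall], path) -> None:
    """BED5+ TSV: chrom, start, end, sample, kind, mean_cn, n_windows."""
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
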