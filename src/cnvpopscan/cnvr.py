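"""Population-level CNVR construction.

Per-window copy numbers across the cohort are reduced to copy number variation
regions (CNVRs): windows where enough samples deviate from the diploid state
are flagged, flagged runs become candidate intervals, adjacent intervals with
correlated per-sample copy-number profiles are merged, every sample is
genotyped by its median copy number over the interval, and regions are
classified as Loss / Gain / Both from the deletion and duplication allele
frequencies, then filtered on clustering quality (silhouette) and length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.metrics import silhouette_samples

from .errors import AnnotationError, ConfigurationError, InputError
from .matrix import CopyNumberMatrix

DEFAULT_SIL_MIN = 0.6
DEFAULT_LOSS_MAX_LEN = 50_000
DEFAULT_GAIN_MAX_LEN = 500_000
DEFAULT_BOTH_MAX_LEN = 50_000


@dataclass
class MergeConfig:
    """Window flagging and interval merging parameters.

    min_variant_freq:
        A window is a CNVR candidate when the fraction of samples whose copy
        number deviates from 2 by at least ``cn_dev_min`` exceeds this
        (strictly).
    corr_min:
        Pearson correlation of per-sample mean CN vectors required to merge
        two nearby candidate intervals.
    max_gap_windows:
        Non-flagged windows tolerated inside one candidate run.
    corr_merge_gap_windows:
        Maximum window gap between consecutive intervals considered for the
        correlation merge.
    cn_dev_min:
        Deviation from CN 2 that counts a sample as variant in a window.
    """

    min_variant_freq: float = 0.05
    corr_min: float = 0.5
    max_gap_windows: int = 1
    corr_merge_gap_windows: int = 3
    cn_dev_min: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.min_variant_freq < 1.0:
            raise ConfigurationError(
                f"min_variant_freq must be in (0,1), got {self.min_variant_freq}"
            )
        if not -1.0 <= self.corr_min <= 1.0:
            raise ConfigurationError(f"corr_min must be in [-1,1], got {self.corr_min}")
        if self.max_gap_windows < 0 or self.corr_merge_gap_windows < 0:
            raise ConfigurationError("window gaps must be >= 0")
        if self.cn_dev_min <= 0:
            raise ConfigurationError(f"cn_dev_min must be positive, got {self.cn_dev_min}")


@dataclass
class CNVR:
    """A copy number variation region with per-sample genotypes.

    ``id`` uses 1-based inclusive locus notation (chrom:start-end) while
    ``start``/``end`` stay 0-based half-open.
    """

    id: str
    chrom: str
    start: int
    end: int
    per_sample_cn_real: dict[str, float]
    per_sample_cn_int: dict[str, int]
    loss_af: float
    gain_af: float
    type: str  # "loss" | "gain" | "both" | "none"
    silhouette: float

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_samples(self) -> int:
        return len(self.per_sample_cn_int)


def cnvr_id(chrom: str, start: int, end: int) -> str:
    """1-based inclusive id, e.g. window span [7638800, 7679600) -> '3:7638801-7679600'."""
    return f"{chrom}:{start + 1}-{end}"


def round_cn(x: float) -> int:
    """Integer CN: round half away from zero, floored at 0."""
    return max(0, int(np.floor(x + 0.5)))


def candidate_windows(cnmat: CopyNumberMatrix, cfg: MergeConfig) -> np.ndarray:
    """Boolean flag per window: variant-sample fraction strictly above threshold.

    Masked windows are never flagged.
    """
    dev = np.abs(np.nan_to_num(cnmat.cn, nan=2.0) - 2.0) >= cfg.cn_dev_min
    frac = dev.mean(axis=0)
    flags = frac > cfg.min_variant_freq
    flags &= cnmat.genome.unmasked
    return flags


def _interval_mean_cn(cnmat: CopyNumberMatrix, lo: int, hi: int) -> np.ndarray:
    """Per-sample mean CN over window indices [lo, hi), unmasked only."""
    sel = cnmat.genome.unmasked[lo:hi]
    block = cnmat.cn[:, lo:hi][:, sel]
    if block.shape[1] == 0:
        return np.full(cnmat.n_samples, np.nan)
    return block.mean(axis=1)


def merge_to_cnvrs(
    flags: np.ndarray, cnmat: CopyNumberMatrix, cfg: MergeConfig
) -> list[tuple[str, int, int]]:
    """Candidate intervals (chrom, window_lo, window_hi) from flagged windows.

    Maximal runs of flagged windows (gaps of at most ``max_gap_windows``
    allowed) form intervals; consecutive intervals separated by at most
    ``corr_merge_gap_windows`` windows are merged when the Pearson correlation
    of their per-sample mean CN vectors is >= ``corr_min``. Output is sorted
    and non-overlapping; indices are genome-wide window indices.
    """
    genome = cnmat.genome
    if flags.shape != (genome.n_windows,):
        raise InputError("flags not aligned to the copy-number matrix windows")
    intervals: list[tuple[str, int, int]] = []
    for chrom in genome.chrom_lengths:
        sl = genome.chrom_slice(chrom)
        idx = np.flatnonzero(flags[sl])
        if idx.size == 0:
            continue
        runs: list[list[int]] = [[int(idx[0]), int(idx[0])]]
        for i in idx[1:]:
            if int(i) - runs[-1][1] - 1 <= cfg.max_gap_windows:
                runs[-1][1] = int(i)
            else:
                runs.append([int(i), int(i)])

        merged: list[list[int]] = [runs[0]]
        for run in runs[1:]:
            prev = merged[-1]
            gap = run[0] - prev[1] - 1
            if gap <= cfg.corr_merge_gap_windows:
                a = _interval_mean_cn(cnmat, sl.start + prev[0], sl.start + prev[1] + 1)
                b = _interval_mean_cn(cnmat, sl.start + run[0], sl.start + run[1] + 1)
                ok = np.isfinite(a).all() and np.isfinite(b).all()
                if ok and np.std(a) > 0 and np.std(b) > 0:
                    r = pearsonr(a, b).statistic
                    if r >= cfg.corr_min:
                        prev[1] = run[1]
                        continue
            merged.append(run)
        intervals.extend((chrom, sl.start + lo, sl.start + hi + 1) for lo, hi in merged)
    return intervals


def genotype_cnvr(cnmat: CopyNumberMatrix, interval: tuple[str, int, int]):
    """Per-sample (real, integer) CN over a window-index interval.

    Real CN is the median of the sample's unmasked window CNs; integer CN is
    rounded half away from zero and floored at 0.
    """
    _, lo, hi = interval
    sel = cnmat.genome.unmasked[lo:hi]
    if not sel.any():
        raise AnnotationError("interval has no unmasked windows")
    block = cnmat.cn[:, lo:hi][:, sel]
    reals = np.median(block, axis=1)
    real = {s: float(v) for s, v in zip(cnmat.samples, reals)}
    integer = {s: round_cn(v) for s, v in real.items()}
    return real, integer


def allele_frequencies(per_sample_cn_int: dict[str, int], mode: str = "carrier"):
    """(loss_af, gain_af) from integer genotypes.

    carrier mode: fraction of samples with CN < 2 (loss) / CN > 2 (gain).
    allele mode: per sample, loss alleles = min(2, max(0, 2 - CN)) and gain
    alleles = min(2, max(0, CN - 2)); AF = total alleles / 2N.
    """
    if not per_sample_cn_int:
        raise InputError("no samples to compute allele frequencies over")
    cns = np.array(list(per_sample_cn_int.values()), dtype=float)
    n = len(cns)
    if mode == "carrier":
        return float(np.mean(cns < 2)), float(np.mean(cns > 2))
    if mode == "allele":
        loss = np.clip(2 - cns, 0, 2).sum()
        gain = np.clip(cns - 2, 0, 2).sum()
        return float(loss / (2 * n)), float(gain / (2 * n))
    raise ConfigurationError(f"unknown AF mode {mode!r}")


def classify_cnvr(loss_af: float, gain_af: float) -> str:
    """Loss / Gain / Both classification from deletion and duplication AFs.

    loss:  0.05 < loss_af <= 0.95 and gain_af <= 0.01
    gain:  0.05 < gain_af <  0.95 and loss_af <= 0.01
    both:  0.05 < gain_af <  0.95 and 0.05 < loss_af <= 0.95
    otherwise none (excluded from the final set).
    """
    if not (0.0 <= loss_af <= 1.0 and 0.0 <= gain_af <= 1.0):
        raise InputError("allele frequencies must be in [0,1]")
    if 0.05 < loss_af <= 0.95 and gain_af <= 0.01:
        return "loss"
    if 0.05 < gain_af < 0.95 and loss_af <= 0.01:
        return "gain"
    if 0.05 < gain_af < 0.95 and 0.05 < loss_af <= 0.95:
        return "both"
    return "none"


def silhouette_cn(per_sample_cn_real: dict[str, float], per_sample_cn_int: dict[str, int]) -> float:
    """Mean silhouette of real CNs clustered by their integer CN state.

    One cluster (all samples share an integer CN) scores 1.0 by convention;
    when every cluster is a singleton each sample contributes 0. Distances are
    Euclidean on the 1-D real copy numbers.
    """
    samples = list(per_sample_cn_real)
    if len(samples) < 2:
        raise InputError("silhouette needs at least 2 samples")
    x = np.array([per_sample_cn_real[s] for s in samples], dtype=float).reshape(-1, 1)
    labels = np.array([per_sample_cn_int[s] for s in samples])
    k = len(np.unique(labels))
    if k == 1:
        return 1.0
    if k == len(samples):
        return 0.0
    return float(np.mean(silhouette_samples(x, labels)))


_TYPE_CAPS = {"loss": DEFAULT_LOSS_MAX_LEN, "gain": DEFAULT_GAIN_MAX_LEN, "both": DEFAULT_BOTH_MAX_LEN}


def filter_cnvrs(
    cnvrs: list[CNVR],
    sil_min: float = DEFAULT_SIL_MIN,
    loss_max_len: int = DEFAULT_LOSS_MAX_LEN,
    gain_max_len: int = DEFAULT_GAIN_MAX_LEN,
    both_max_len: int = DEFAULT_BOTH_MAX_LEN,
) -> list[CNVR]:
    """Keep CNVRs with a recognized type, silhouette strictly above ``sil_min``
    and length within the type cap (loss/both 50 kb, gain 500 kb by default)."""
    caps = {"loss": loss_max_len, "gain": gain_max_len, "both": both_max_len}
    return [
        r
        for r in cnvrs
        if r.type in caps and r.silhouette > sil_min and r.length <= caps[r.type]
    ]


def build_cnvrs(
    cnmat: CopyNumberMatrix,
    cfg: MergeConfig | None = None,
    af_mode: str = "carrier",
    sil_min: float = DEFAULT_SIL_MIN,
    loss_max_len: int = DEFAULT_LOSS_MAX_LEN,
    gain_max_len: int = DEFAULT_GAIN_MAX_LEN,
    both_max_len: int = DEFAULT_BOTH_MAX_LEN,
    keep_all: bool = False,
) -> list[CNVR]:
    """Full CNVR construction: flag -> merge -> genotype -> classify -> filter.

    With ``keep_all`` the unfiltered candidate set (including type 'none') is
    returned for inspection.
    """
    cfg = cfg or MergeConfig()
    flags = candidate_windows(cnmat, cfg)
    intervals = merge_to_cnvrs(flags, cnmat, cfg)
    starts = cnmat.genome.windows["start"].to_numpy()
    ends = cnmat.genome.windows["end"].to_numpy()
    out: list[CNVR] = []
    for chrom, lo, hi in intervals:
        real, integer = genotype_cnvr(cnmat, (chrom, lo, hi))
        loss_af, gain_af = allele_frequencies(integer, mode=af_mode)
        start, end = int(starts[lo]), int(ends[hi - 1])
        out.append(
            CNVR(
                id=cnvr_id(chrom, start, end),
                chrom=chrom,
                start=start,
                end=end,
                per_sample_cn_real=real,
                per_sample_cn_int=integer,
                loss_af=loss_af,
                gain_af=gain_af,
                type=classify_cnvr(loss_af, gain_af),
                silhouette=silhouette_cn(real, integer) if len(real) >= 2 else 1.0,
            )
        )
    if keep_all:
        return out
    return filter_cnvrs(out, sil_min, loss_max_len, gain_max_len, both_max_len)


def cnvrs_to_frame(cnvrs: list[CNVR]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "id": r.id,
                "type": r.type,
                "loss_af": r.loss_af,
                "gain_af": r.gain_af,
                "silhouette": r.silhouette,
                "n_samples": r.n_samples,
            }
            for r in cnvrs
        ],
        columns=["chrom", "start", "end", "id", "type", "loss_af", "gain_af", "silhouette", "n_samples"],
    )


def genotypes_frame(cnvrs: list[CNVR], kind: str = "int") -> pd.DataFrame:
    """CNVR x sample genotype matrix (``kind`` = 'int' or 'real')."""
    rows = {}
    for r in cnvrs:
        src = r.per_sample_cn_int if kind == "int" else r.per_sample_cn_real
        rows[r.id] = src
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "cnvr_id"
    return df


def write_cnvrs(cnvrs: list[CNVR], path) -> None:
    cnvrs_to_frame(cnvrs).to_csv(path, sep="\t", index=False)


def read_cnvrs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
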