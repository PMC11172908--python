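"""Genomic-context annotation, gene/QTL overlap, summaries and study comparison.

All coordinates are BED-style 0-based half-open; adjacent intervals do not
overlap. Overlap queries are served by per-chromosome interval trees; interval
unions are computed with a sort-and-sweep merge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import linregress

from .errors import ConfigurationError, InputError

BED3 = ["chrom", "start", "end"]


def _check_frame(df: pd.DataFrame, cols: list[str], what: str) -> pd.DataFrame:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{what} missing columns: {missing}")
    out = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    if len(out) and (out["end"] <= out["start"]).any():
        raise InputError(f"{what} contains empty or inverted intervals")
    return out


def _trees(df: pd.DataFrame, data_col: str | None = None) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        tree = IntervalTree()
        for row in sub.itertuples(index=False):
            tree.addi(row.start, row.end, getattr(row, data_col) if data_col else None)
        trees[chrom] = tree
    return trees


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals per chromosome (sort-and-sweep)."""
    rows = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom", sort=False):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_e is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append({"chrom": chrom, "start": cur_s, "end": cur_e})
                cur_s, cur_e = s, e
        if cur_e is not None:
            rows.append({"chrom": chrom, "start": cur_s, "end": cur_e})
    return pd.DataFrame(rows, columns=BED3)


def union_length(df: pd.DataFrame) -> int:
    m = merge_intervals(df)
    if m.empty:
        return 0
    return int((m["end"] - m["start"]).sum())


@dataclass
class GenomeAnnotation:
    """Gene bodies with exon sub-intervals plus QTL intervals.

    genes/exons: columns chrom, start, end, gene_id; qtls: chrom, start, end,
    trait. Exons must lie within their gene body.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame
    qtls: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=BED3 + ["trait"]))

    def __post_init__(self) -> None:
        self.genes = _check_frame(self.genes, BED3 + ["gene_id"], "genes") if len(self.genes) else self.genes
        self.exons = _check_frame(self.exons, BED3 + ["gene_id"], "exons") if len(self.exons) else self.exons
        self.qtls = _check_frame(self.qtls, BED3 + ["trait"], "qtls") if len(self.qtls) else self.qtls
        if len(self.exons):
            spans = self.genes.set_index("gene_id")
            for row in self.exons.itertuples(index=False):
                g = spans.loc[row.gene_id]
                if row.start < g["start"] or row.end > g["end"]:
                    raise InputError(f"exon outside gene body for {row.gene_id}")


def genomic_context(cnvrs: pd.DataFrame, annotation: GenomeAnnotation) -> pd.Series:
    """Label each CNVR exon / intron / intergenic (precedence exon > intron).

    A single base of exon overlap makes a CNVR exonic; otherwise any gene-body
    overlap makes it intronic; otherwise it is intergenic.
    """
    cnvrs = _check_frame(cnvrs, BED3, "cnvrs") if len(cnvrs) else cnvrs
    exon_trees = _trees(annotation.exons) if len(annotation.exons) else {}
    gene_trees = _trees(annotation.genes) if len(annotation.genes) else {}
    labels = []
    for row in cnvrs.itertuples(index=False):
        if row.chrom in exon_trees and exon_trees[row.chrom].overlap(row.start, row.end):
            labels.append("exon")
        elif row.chrom in gene_trees and gene_trees[row.chrom].overlap(row.start, row.end):
            labels.append("intron")
        else:
            labels.append("intergenic")
    ids = cnvrs["id"] if "id" in cnvrs.columns else pd.RangeIndex(len(cnvrs))
    return pd.Series(labels, index=list(ids), name="context")


def overlap_genes(
    cnvrs: pd.DataFrame,
    annotation: GenomeAnnotation,
    min_gene_fraction: float = 0.5,
    denominator: str = "gene",
) -> dict[str, list[str]]:
    """Genes assigned to each CNVR.

    A gene is assigned when it is fully contained in the CNVR or when the
    intersection covers at least ``min_gene_fraction`` of the denominator
    interval (the gene by default; ``denominator='cnvr'`` uses the CNVR).
    Returns cnvr id -> sorted gene ids (only CNVRs with hits).
    """
    if denominator not in ("gene", "cnvr"):
        raise ConfigurationError(f"unknown denominator {denominator!r}")
    cnvrs = _check_frame(cnvrs, BED3, "cnvrs") if len(cnvrs) else cnvrs
    gene_trees = _trees(annotation.genes, "gene_id") if len(annotation.genes) else {}
    out: dict[str, list[str]] = {}
    for row in cnvrs.itertuples(index=False):
        rid = getattr(row, "id", f"{row.chrom}:{row.start}-{row.end}")
        hits = set()
        for iv in gene_trees.get(row.chrom, IntervalTree()).overlap(row.start, row.end):
            inter = min(row.end, iv.end) - max(row.start, iv.begin)
            denom = (iv.end - iv.begin) if denominator == "gene" else (row.end - row.start)
            contained = iv.begin >= row.start and iv.end <= row.end
            if contained or inter / denom >= min_gene_fraction:
                hits.add(iv.data)
        if hits:
            out[rid] = sorted(hits)
    return out


def overlap_qtls(cnvrs: pd.DataFrame, qtls: pd.DataFrame):
    """Any-overlap (>= 1 bp) QTL annotation.

    Returns (cnvr id -> sorted trait labels, number of CNVRs with >= 1 QTL hit,
    number of distinct traits hit).
    """
    cnvrs = _check_frame(cnvrs, BED3, "cnvrs") if len(cnvrs) else cnvrs
    if len(qtls) == 0:
        return {}, 0, 0
    qtls = _check_frame(qtls, BED3 + ["trait"], "qtls")
    trees = _trees(qtls, "trait")
    mapping: dict[str, list[str]] = {}
    traits: set[str] = set()
    for row in cnvrs.itertuples(index=False):
        rid = getattr(row, "id", f"{row.chrom}:{row.start}-{row.end}")
        hits = {iv.data for iv in trees.get(row.chrom, IntervalTree()).overlap(row.start, row.end)}
        if hits:
            mapping[rid] = sorted(hits)
            traits |= hits
    return mapping, len(mapping), len(traits)


@dataclass
class ChromosomeSummary:
    """CNVR counts per chromosome and the count-vs-length regression."""

    per_chrom: pd.DataFrame  # chrom, cnvr_count, chrom_length
    slope: float | None
    intercept: float | None
    r2: float | None
    p_value: float | None


def chromosome_summary(cnvrs: pd.DataFrame, chrom_lengths: dict[str, int]) -> ChromosomeSummary:
    """OLS of per-chromosome CNVR count on chromosome length.

    With fewer than 3 chromosomes the regression is skipped with a warning and
    the regression fields are None.
    """
    counts = (
        cnvrs.groupby("chrom").size() if len(cnvrs) else pd.Series(dtype=int)
    )
    per_chrom = pd.DataFrame(
        {
            "chrom": list(chrom_lengths),
            "cnvr_count": [int(counts.get(c, 0)) for c in chrom_lengths],
            "chrom_length": [int(chrom_lengths[c]) for c in chrom_lengths],
        }
    )
    if len(per_chrom) < 3:
        warnings.warn("fewer than 3 chromosomes: count-vs-length regression skipped", stacklevel=2)
        return ChromosomeSummary(per_chrom, None, None, None, None)
    if per_chrom["cnvr_count"].nunique() == 1:
        # flat response: length explains none of the (zero) count variance
        return ChromosomeSummary(
            per_chrom, 0.0, float(per_chrom["cnvr_count"].iloc[0]), 0.0, 1.0
        )
    fit = linregress(per_chrom["chrom_length"], per_chrom["cnvr_count"])
    return ChromosomeSummary(
        per_chrom,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
    )


def mean_calls_per_individual(total_calls: int, n_samples: int) -> float:
    """Average number of per-sample CNV events per individual."""
    if n_samples <= 0:
        raise InputError("n_samples must be positive")
    return total_calls / n_samples


def summary_stats(
    calls: pd.DataFrame | None = None,
    cnvrs: pd.DataFrame | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> dict:
    """Whole-set summary table.

    From per-sample calls: total count, per-kind counts, per-individual
    mean/min/max counts, event length median/mean. From CNVRs: per-type counts
    and (when chromosome lengths are given) the fraction of the genome covered
    by the CNVR union.
    """
    out: dict = {}
    if calls is not None and len(calls):
        lengths = calls["end"] - calls["start"]
        per_ind = calls.groupby("sample").size()
        out.update(
            total_cnvs=int(len(calls)),
            kind_counts={k: int(v) for k, v in calls["kind"].value_counts().items()},
            per_individual_mean=mean_calls_per_individual(len(calls), per_ind.size),
            per_individual_min=int(per_ind.min()),
            per_individual_max=int(per_ind.max()),
            length_median=float(lengths.median()),
            length_mean=float(lengths.mean()),
        )
    if cnvrs is not None and len(cnvrs):
        out["cnvr_total"] = int(len(cnvrs))
        if "type" in cnvrs.columns:
            out["cnvr_type_counts"] = {k: int(v) for k, v in cnvrs["type"].value_counts().items()}
        out["cnvr_length_median"] = float((cnvrs["end"] - cnvrs["start"]).median())
        out["cnvr_length_mean"] = float((cnvrs["end"] - cnvrs["start"]).mean())
        if chrom_lengths:
            genome_bp = sum(chrom_lengths.values())
            out["genome_fraction_covered"] = union_length(cnvrs[BED3]) / genome_bp
    return out


@dataclass
class StudyOverlapSummary:
    """Cross-study CNVR overlap: how much of *our* set intersects *theirs*.

    overlap_ratio = overlap_number / n_ours, reported to 2 decimals;
    overlap_length_mb is total intersected bp (their intervals merged first)
    in Mb.
    """

    other_study_label: str
    n_ours: int
    n_theirs: int
    overlap_number: int
    overlap_ratio: float
    overlap_length_mb: float


def overlap_ratio(overlap_number: int, n_ours: int) -> float:
    """Fraction of this study's CNVRs overlapping the other set (2 decimals)."""
    if n_ours <= 0:
        raise InputError("n_ours must be positive")
    if not 0 <= overlap_number <= n_ours:
        raise InputError("overlap_number must be between 0 and n_ours")
    return round(overlap_number / n_ours, 2)


def compare_study(ours: pd.DataFrame, theirs: pd.DataFrame, label: str) -> StudyOverlapSummary:
    """Overlap statistics between our CNVR set and another study's intervals."""
    ours = _check_frame(ours, BED3, "ours") if len(ours) else ours
    n_theirs = int(len(theirs))
    theirs_m = merge_intervals(theirs[BED3]) if len(theirs) else pd.DataFrame(columns=BED3)
    trees = _trees(theirs_m) if len(theirs_m) else {}
    n_hit = 0
    inter_bp = 0
    for row in ours.itertuples(index=False):
        hits = trees.get(row.chrom, IntervalTree()).overlap(row.start, row.end)
        if hits:
            n_hit += 1
            inter_bp += sum(min(row.end, iv.end) - max(row.start, iv.begin) for iv in hits)
    n_ours = int(len(ours))
    return StudyOverlapSummary(
        other_study_label=label,
        n_ours=n_ours,
        n_theirs=n_theirs,
        overlap_number=n_hit,
        overlap_ratio=overlap_ratio(n_hit, n_ours) if n_ours else 0.0,
        overlap_length_mb=inter_bp / 1e6,
    )


def read_bed(path, columns: list[str] | None = None) -> pd.DataFrame:
    """Read a headerless BED-like TSV into a named-column frame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    names = columns or BED3[: df.shape[1]]
    df.columns = names + [f"col{i}" for i in range(len(names), df.shape[1])]
    return df


def write_bed(df: pd.DataFrame, path, columns: list[str] | None = None) -> None:
    cols = columns or list(df.columns)
    df[cols].to_csv(path, sep="\t", index=False, header=False)
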