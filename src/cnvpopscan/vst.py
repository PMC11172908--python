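"""Vst population-differentiation scan over CNVR genotypes.

Vst is the CNV analogue of Fst: for a region genotyped (real copy number)
in two sample groups A and B,

    Vst = (Vt - Vs) / Vt

where Vt is the population variance of the pooled copy numbers and Vs is the
size-weighted mean of the within-group population variances,
Vs = (nA*VA + nB*VB) / (nA + nB). With population (ddof=0) variances the law of
total variance guarantees 0 <= Vst <= 1; Vst is 0 when Vt is 0. A scan
computes Vst per CNVR for each contrast (a focal population against a pooled
reference set), ranks regions within the contrast, and flags the empirical
top tail (default 5%) as differentiation candidates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigurationError, InputError

DEFAULT_TOP_FRACTION = 0.05

VST_COLUMNS = ["cnvr_id", "contrast", "vt", "vs", "vst", "rank_pct", "candidate"]


def vst(values_a, values_b, stat: str = "variance") -> float:
    """Vst between two groups of real copy numbers.

    ``stat="variance"`` is the canonical definition (bounded in [0,1]);
    ``stat="sd"`` substitutes standard deviations for exploration and is not
    bounded below by 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    if stat not in ("variance", "sd"):
        raise ConfigurationError(f"unknown stat {stat!r}")
    pooled = np.concatenate([a, b])
    if stat == "variance":
        vt = pooled.var(ddof=0)
        vs = (a.size * a.var(ddof=0) + b.size * b.var(ddof=0)) / pooled.size
    else:
        vt = pooled.std(ddof=0)
        vs = (a.size * a.std(ddof=0) + b.size * b.std(ddof=0)) / pooled.size
    if vt == 0:
        return 0.0
    return float((vt - vs) / vt)


def contrast_label(focal: str, reference: list[str]) -> str:
    return f"{focal}_vs_{'+'.join(reference)}"


def scan(
    cnvr_genotypes: pd.DataFrame,
    sample_groups: dict[str, str],
    contrasts: list[tuple[str, list[str]]],
    q: float = DEFAULT_TOP_FRACTION,
    stat: str = "variance",
) -> pd.DataFrame:
    """Per-CNVR Vst for each contrast, with empirical percentile and candidate flag.

    Parameters
    ----------
    cnvr_genotypes:
        CNVR x sample matrix of real copy numbers (index cnvr_id).
    sample_groups:
        sample -> group for every column used by the contrasts.
    contrasts:
        (focal group, reference groups) pairs; the reference groups are pooled
        into a single comparison set. Focal and reference groups must be
        disjoint.
    """
    groups_present = set(sample_groups.values())
    records = []
    for focal, reference in contrasts:
        if focal in reference:
            raise ConfigurationError(f"contrast groups must be disjoint: {focal}")
        for g in [focal, *reference]:
            if g not in groups_present:
                raise ConfigurationError(f"unknown group {g!r} in contrast")
        a_samples = [s for s, g in sample_groups.items() if g == focal]
        b_samples = [s for s, g in sample_groups.items() if g in set(reference)]
        missing = [s for s in a_samples + b_samples if s not in cnvr_genotypes.columns]
        if missing:
            raise InputError(f"samples missing from genotype matrix: {missing[:5]}")
        label = contrast_label(focal, reference)
        a = cnvr_genotypes[a_samples].to_numpy(dtype=float)
        b = cnvr_genotypes[b_samples].to_numpy(dtype=float)
        for i, cnvr in enumerate(cnvr_genotypes.index):
            pooled = np.concatenate([a[i], b[i]])
            if stat == "variance":
                vt = pooled.var(ddof=0)
                vs_ = (a.shape[1] * a[i].var(ddof=0) + b.shape[1] * b[i].var(ddof=0)) / pooled.size
            else:
                vt = pooled.std(ddof=0)
                vs_ = (a.shape[1] * a[i].std(ddof=0) + b.shape[1] * b[i].std(ddof=0)) / pooled.size
            v = vst(a[i], b[i], stat=stat)
            records.append(
                {"cnvr_id": cnvr, "contrast": label, "vt": float(vt), "vs": float(vs_), "vst": v}
            )
    df = pd.DataFrame(records, columns=VST_COLUMNS[:5])
    if df.empty:
        df["rank_pct"] = pd.Series(dtype=float)
        df["candidate"] = pd.Series(dtype=bool)
        return df
    df["rank_pct"] = df.groupby("contrast")["vst"].transform(
        lambda v: 100.0 * rankdata(v, method="average") / len(v)
    )
    df["candidate"] = False
    for label, sub in df.groupby("contrast"):
        df.loc[sub.index, "candidate"] = top_candidates(sub["vst"].to_numpy(), q=q)
    return df


def top_candidates(vst_values, q: float = DEFAULT_TOP_FRACTION) -> np.ndarray:
    """Flag values strictly above the empirical (1-q) quantile.

    The quantile uses linear interpolation on the sorted values; ties at the
    threshold are excluded, so a constant set flags nothing.
    """
    if not 0.0 < q < 1.0:
        raise ConfigurationError(f"q must be in (0,1), got {q}")
    v = np.asarray(vst_values, dtype=float)
    if v.size == 0:
        return np.zeros(0, dtype=bool)
    threshold = np.quantile(v, 1.0 - q)
    return v > threshold


def group_frequency_panel(
    cnvr_genotypes_int: pd.DataFrame, sample_groups: dict[str, str]
) -> pd.DataFrame:
    """Per-group loss/normal/gain sample fractions for each CNVR.

    ``cnvr_genotypes_int`` is CNVR x sample integer copy numbers. Every mapped
    sample must be genotyped (no missing columns or NaNs). The three fractions
    sum to 1 per (cnvr, group).
    """
    missing = [s for s in sample_groups if s not in cnvr_genotypes_int.columns]
    if missing:
        raise InputError(f"samples missing from genotype matrix: {missing[:5]}")
    block = cnvr_genotypes_int[list(sample_groups)]
    if block.isna().any().any():
        raise InputError("genotype matrix contains missing values")
    rows = []
    groups: dict[str, list[str]] = {}
    for s, g in sample_groups.items():
        groups.setdefault(g, []).append(s)
    for cnvr in cnvr_genotypes_int.index:
        for g, members in groups.items():
            cns = block.loc[cnvr, members].to_numpy(dtype=float)
            rows.append(
                {
                    "cnvr_id": cnvr,
                    "group": g,
                    "loss_fraction": float(np.mean(cns < 2)),
                    "normal_fraction": float(np.mean(cns == 2)),
                    "gain_fraction": float(np.mean(cns > 2)),
                }
            )
    return pd.DataFrame(rows)


def write_vst(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
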