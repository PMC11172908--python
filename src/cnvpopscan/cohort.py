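"""Synthetic multi-population cohorts with planted, stratified CNVs.

This module generates everything a desk-scale run of the pipeline needs:

* a windowed genome (via :mod:`cnvpopscan.genome`),
* a :class:`TruthSet` of planted CNV regions with per-group carrier
  frequencies (e.g. a duplication fixed in one breed but at 50% in the
  commercial reference breeds, or a deletion private to one breed),
* a noisy read-depth matrix with GC bias and Poisson / negative-binomial
  counting noise,
* gene and QTL annotation fixtures.

The cohort emulated by :func:`demo_config` (see :mod:`cnvpopscan.pipeline`)
is five populations of ten diploid samples each; carriers of a planted region
get an integer copy number in {0, 1, 3, 4} and the expected read depth of a
window scales with CN/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, SpecificationError
from .genome import WindowedGenome
from .matrix import DepthMatrix

GroupKey = "str | tuple[str, ...]"


def round_half_away(x: float) -> int:
    """Round half away from zero (for nonnegative x: 0.5 -> 1, 9.5 -> 10)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


@dataclass
class RegionSpec:
    """One planted CNV region.

    ``freq`` maps a group name -- or a tuple of group names, whose samples are
    pooled before carrier sampling -- to the requested carrier frequency.
    Groups not mentioned have frequency 0. ``carrier_cn`` is the integer copy
    number assigned to every carrier (defaults: gain -> 3, loss -> 1).
    """

    chrom: str
    start: int
    end: int
    kind: str  # "gain" | "loss"
    freq: dict
    carrier_cn: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gain", "loss"):
            raise SpecificationError(f"kind must be gain or loss, got {self.kind!r}")
        if self.carrier_cn is None:
            self.carrier_cn = 3 if self.kind == "gain" else 1
        if self.kind == "gain" and self.carrier_cn not in (3, 4):
            raise SpecificationError("gain carrier_cn must be 3 or 4")
        if self.kind == "loss" and self.carrier_cn not in (0, 1):
            raise SpecificationError("loss carrier_cn must be 0 or 1")
        for key, f in self.freq.items():
            if not 0.0 <= f <= 1.0:
                raise SpecificationError(f"frequency for {key!r} must be in [0,1], got {f}")

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class TruthSet:
    """Planted regions plus realized per-sample copy numbers.

    ``carriers[i]`` maps sample -> integer CN for carriers of region ``i``;
    every sample absent from that map has CN 2 (diploid non-carrier).
    """

    regions: list[RegionSpec]
    sample_groups: dict[str, str]
    carriers: list[dict[str, int]]

    @property
    def samples(self) -> list[str]:
        return list(self.sample_groups)

    def cn_for(self, sample: str, region_index: int) -> int:
        return self.carriers[region_index].get(sample, 2)

    def realized_group_freq(self, region_index: int, group: "str | tuple") -> float:
        """Realized carrier fraction of a group (or pooled groups)."""
        groups = (group,) if isinstance(group, str) else tuple(group)
        members = [s for s, g in self.sample_groups.items() if g in groups]
        if not members:
            raise InputError(f"no samples in group(s) {groups}")
        hits = sum(1 for s in members if s in self.carriers[region_index])
        return hits / len(members)

    def regions_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.regions):
            for key, f in r.freq.items():
                label = "+".join(key) if isinstance(key, tuple) else key
                rows.append(
                    {
                        "region_id": r.region_id,
                        "chrom": r.chrom,
                        "start": r.start,
                        "end": r.end,
                        "kind": r.kind,
                        "carrier_cn": r.carrier_cn,
                        "group": label,
                        "requested_freq": f,
                        "realized_freq": self.realized_group_freq(i, key),
                    }
                )
        return pd.DataFrame(rows)

    def per_sample_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.regions):
            for sample, cn in sorted(self.carriers[i].items()):
                rows.append({"region_id": r.region_id, "sample": sample, "cn": cn})
        return pd.DataFrame(rows, columns=["region_id", "sample", "cn"])


def make_samples(group_sizes: dict[str, int]) -> dict[str, str]:
    """Deterministic sample naming: ``<group>_01 ...``; returns sample -> group."""
    out: dict[str, str] = {}
    for group, n in group_sizes.items():
        if n <= 0:
            raise SpecificationError(f"group {group!r} must have positive size")
        for i in range(int(n)):
            out[f"{group}_{i + 1:02d}"] = group
    return out


def plant_truth(
    genome: WindowedGenome,
    group_sizes: dict[str, int],
    region_specs: list[RegionSpec],
    seed: int = 0,
) -> TruthSet:
    """Sample carriers for each planted region at the requested per-group frequency.

    Carrier counts are ``round(freq * n)`` exactly (half away from zero), drawn
    without replacement within each group (or pooled group tuple). Regions must
    align to window boundaries and must not overlap each other.
    """
    sample_groups = make_samples(group_sizes)
    by_group: dict[str, list[str]] = {}
    for s, g in sample_groups.items():
        by_group.setdefault(g, []).append(s)

    # validate regions
    spans: dict[str, list[tuple[int, int]]] = {}
    for r in region_specs:
        if r.chrom not in genome.chrom_lengths:
            raise SpecificationError(f"region {r.region_id}: unknown chromosome")
        L = genome.chrom_lengths[r.chrom]
        if not (0 <= r.start < r.end <= L):
            raise SpecificationError(f"region {r.region_id} is off the genome (length {L})")
        if r.start % genome.window_size or (r.end % genome.window_size and r.end != L):
            raise SpecificationError(f"region {r.region_id} not aligned to window boundaries")
        for s0, e0 in spans.get(r.chrom, []):
            if r.start < e0 and s0 < r.end:
                raise SpecificationError(f"region {r.region_id} overlaps another region")
        spans.setdefault(r.chrom, []).append((r.start, r.end))

    rng = np.random.default_rng(seed)
    carriers: list[dict[str, int]] = []
    for r in region_specs:
        chosen: dict[str, int] = {}
        for key, f in r.freq.items():
            groups = (key,) if isinstance(key, str) else tuple(key)
            pool: list[str] = []
            for g in groups:
                if g not in by_group:
                    raise SpecificationError(f"region {r.region_id}: unknown group {g!r}")
                pool.extend(by_group[g])
            k = round_half_away(f * len(pool))
            for s in rng.choice(pool, size=k, replace=False):
                chosen[str(s)] = int(r.carrier_cn)
        carriers.append(chosen)
    return TruthSet(regions=list(region_specs), sample_groups=sample_groups, carriers=carriers)


@dataclass
class GCBias:
    """Unimodal multiplicative depth bias: factor(gc) = 1 - strength*(gc-peak)^2.

    ``strength=0`` is no bias. The factor is floored at 0.05 so expected depth
    stays positive.
    """

    peak: float = 0.45
    strength: float = 0.0

    def factor(self, gc: np.ndarray) -> np.ndarray:
        return np.maximum(0.05, 1.0 - self.strength * (np.asarray(gc) - self.peak) ** 2)


def truth_cn_array(genome: WindowedGenome, truth: TruthSet) -> np.ndarray:
    """(samples x windows) integer CN array implied by the truth set."""
    samples = truth.samples
    cn = np.full((len(samples), genome.n_windows), 2.0)
    index = {s: i for i, s in enumerate(samples)}
    for r, carr in zip(truth.regions, truth.carriers):
        sl = genome.window_range(r.chrom, r.start, r.end)
        for s, c in carr.items():
            cn[index[s], sl] = c
    return cn


def simulate_depth(
    genome: WindowedGenome,
    truth: TruthSet,
    mean_coverage: float = 50.0,
    gc_bias: GCBias | None = None,
    dispersion: float = 0.0,
    seed: int = 0,
) -> DepthMatrix:
    """Draw per-window read counts for every sample.

    Expected depth of a window is ``mean_coverage * (CN/2) * gc_factor(gc)``.
    Counts are negative binomial with variance ``mu + dispersion*mu^2``
    (Poisson when ``dispersion`` is 0). Masked windows get erratic depth
    (log-normally perturbed expectation) to emulate unalignable sequence;
    they are excluded from every downstream statistic.
    """
    if mean_coverage <= 0:
        raise InputError(f"mean_coverage must be positive, got {mean_coverage}")
    if dispersion < 0:
        raise InputError(f"dispersion must be >= 0, got {dispersion}")
    gc_bias = gc_bias or GCBias()
    rng = np.random.default_rng(seed)

    cn = truth_cn_array(genome, truth)
    mu = mean_coverage * (cn / 2.0) * gc_bias.factor(genome.gc)[None, :]
    masked = genome.masked
    if masked.any():
        jitter = rng.lognormal(mean=0.0, sigma=1.2, size=(cn.shape[0], int(masked.sum())))
        mu[:, masked] = mean_coverage * jitter

    if dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    return DepthMatrix(samples=truth.samples, values=counts.astype(float), genome=genome)


# ---------------------------------------------------------------------------
# annotation fixtures

_TRAITS = (
    "backfat_thickness",
    "intramuscular_fat",
    "meat_color",
    "tenderness",
    "loin_muscle_area",
    "daily_gain",
    "teat_number",
    "litter_size",
)


def emit_annotations(
    genome: WindowedGenome,
    n_genes: int,
    exons_per_gene: int = 3,
    n_qtls: int = 0,
    seed: int = 0,
):
    """Generate non-overlapping gene bodies with exon sub-intervals, plus QTLs.

    Returns a :class:`~cnvpopscan.annotate.GenomeAnnotation`. Genes are placed
    uniformly at random without overlap; each gene body is split into
    ``exons_per_gene`` exons anchored at its two ends. QTLs are broad intervals
    with trait labels cycled from a fixed list and may overlap each other.
    """
    from .annotate import GenomeAnnotation  # local import avoids a cycle

    if n_genes < 0 or n_qtls < 0 or exons_per_gene < 1:
        raise SpecificationError("feature counts must be nonnegative (exons_per_gene >= 1)")

    rng = np.random.default_rng(seed)
    chroms = list(genome.chrom_lengths)
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    gene_rows, exon_rows = [], []
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for gi in range(int(n_genes)):
        gene_len = int(rng.integers(2, 8)) * genome.window_size // 2
        for _ in range(200):
            chrom = str(rng.choice(chroms, p=probs))
            L = genome.chrom_lengths[chrom]
            if L <= gene_len:
                continue
            start = int(rng.integers(0, L - gene_len))
            end = start + gene_len
            if all(end <= s or e <= start for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                break
        else:
            raise SpecificationError(f"could not place gene {gi + 1} of {n_genes} on the genome")
        gene_id = f"GENE{gi + 1:04d}"
        gene_rows.append({"chrom": chrom, "start": start, "end": end, "gene_id": gene_id})
        bounds = np.linspace(start, end, 2 * exons_per_gene, dtype=int)
        for ei in range(exons_per_gene):
            exon_rows.append(
                {
                    "chrom": chrom,
                    "start": int(bounds[2 * ei]),
                    "end": int(max(bounds[2 * ei] + 1, bounds[2 * ei + 1])),
                    "gene_id": gene_id,
                }
            )

    qtl_rows = []
    for qi in range(int(n_qtls)):
        chrom = str(rng.choice(chroms, p=probs))
        L = genome.chrom_lengths[chrom]
        qtl_len = min(L - 1, int(rng.integers(5, 40)) * genome.window_size)
        start = int(rng.integers(0, L - qtl_len))
        qtl_rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + qtl_len,
                "trait": _TRAITS[qi % len(_TRAITS)],
            }
        )

    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene_id"])
    exons = pd.DataFrame(exon_rows, columns=["chrom", "start", "end", "gene_id"])
    qtls = pd.DataFrame(qtl_rows, columns=["chrom", "start", "end", "trait"])
    return GenomeAnnotation(genes=genes, exons=exons, qtls=qtls)


# ---------------------------------------------------------------------------
# demo truth layout

def demo_region_specs(
    genome: WindowedGenome,
    groups: tuple[str, ...] = ("RC", "T", "WZS", "YL", "LR"),
    n_shared: int = 17,
    region_windows: tuple[int, int] = (8, 14),
    seed: int = 0,
) -> list[RegionSpec]:
    """The default planted-truth layout for demo cohorts.

    Three strongly population-differential regions, one per local breed
    contrasted against the pooled commercial breeds (the last two groups):

    * a duplication fixed in the first group and at 50% everywhere else,
    * a deletion at 95% in the second group and 5% elsewhere,
    * a deletion at 15% in the third group and fixed in all other groups,

    plus ``n_shared`` regions at 30% carrier frequency in every group (no
    differentiation). Regions are 8-14 windows long (6.4-11.2 kb at 800 bp
    windows, matching the kb-scale sizes typical of real read-depth CNVs),
    placed on unmasked stretches with wide spacing.
    """
    if len(groups) < 3:
        raise SpecificationError("demo layout needs at least 3 groups")
    rng = np.random.default_rng(seed)
    focal = groups[:-2]
    ref = tuple(groups[-2:])

    w = genome.window_size
    slots: list[tuple[str, int, int]] = []
    n_regions = 3 + n_shared
    masked = genome.masked

    # allocate regions across chromosomes proportionally to length
    chroms = list(genome.chrom_lengths)
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    raw = n_regions * lengths / lengths.sum()
    alloc = np.floor(raw).astype(int)
    for i in np.argsort(raw - alloc)[::-1][: n_regions - alloc.sum()]:
        alloc[i] += 1

    for chrom, target in zip(chroms, alloc):
        sl = genome.chrom_slice(chrom)
        pos = sl.start + 10
        placed = 0
        while placed < target and pos + region_windows[1] + 10 < sl.stop:
            n_win = int(rng.integers(region_windows[0], region_windows[1] + 1))
            if not masked[pos : pos + n_win].any():
                s = int(genome.windows["start"].iloc[pos])
                slots.append((chrom, s, s + n_win * w))
                placed += 1
                pos += n_win + int(rng.integers(30, 60))
            else:
                pos += 3
    if len(slots) < n_regions:
        raise SpecificationError(
            f"genome too small for {n_regions} demo regions ({len(slots)} placed)"
        )
    rng.shuffle(slots)

    specs: list[RegionSpec] = []
    c, s, e = slots[0]
    f0: dict = {focal[0]: 1.0, ref: 0.5}
    f0.update({g: 0.5 for g in focal[1:]})
    specs.append(RegionSpec(c, s, e, "gain", f0, carrier_cn=4))

    c, s, e = slots[1]
    f1: dict = {focal[1]: 0.95, ref: 0.05}
    f1.update({g: 0.05 for g in focal if g != focal[1]})
    specs.append(RegionSpec(c, s, e, "loss", f1, carrier_cn=0))

    c, s, e = slots[2]
    f2: dict = {focal[2]: 0.15, ref: 1.0}
    f2.update({g: 1.0 for g in focal if g != focal[2]})
    specs.append(RegionSpec(c, s, e, "loss", f2, carrier_cn=0))

    shared_cn = [4, 1, 3, 0, 4, 1, 4, 3, 1, 0, 4, 1, 3, 4, 1, 4, 0]
    for i in range(n_shared):
        c, s, e = slots[3 + i]
        cn_i = shared_cn[i % len(shared_cn)]
        kind = "gain" if cn_i > 2 else "loss"
        specs.append(
            RegionSpec(c, s, e, kind, {g: 0.3 for g in groups}, carrier_cn=cn_i)
        )
    specs.sort(key=lambda r: (r.chrom, r.start))
    return specs


def demo_differential_regions(specs: list[RegionSpec], groups=("RC", "T", "WZS")) -> dict:
    """Map focal group -> its planted differential RegionSpec (demo layout)."""
    out = {}
    for r in specs:
        per_single = {k: v for k, v in r.freq.items() if isinstance(k, str)}
        vals = set(per_single.values())
        if len(vals) > 1:  # stratified
            for g in groups:
                others = [v for k, v in per_single.items() if k != g]
                if g in per_single and all(v != per_single[g] for v in others):
                    out[g] = r
    return out
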