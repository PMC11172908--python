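"""End-to-end orchestration: simulate -> depth call -> CNVR -> Vst -> annotate.

A run is fully described by a :class:`RunConfig` (loadable from YAML; unknown
keys are rejected by name). One top-level seed fans out to per-stage seeds by
stable hashing, so a stage rerun standalone with its derived seed reproduces
the pipeline's output byte for byte. Every stage records its parameters and
output checksums in a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import cnvr as cnvr_mod
from . import cohort, depth, genome as genome_mod, vst as vst_mod
from .errors import ConfigurationError

STAGES = ["simulate", "depthcall", "cnvr", "vst", "annotate"]


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the run seed (< 2**31)."""
    return zlib.crc32(f"{seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class GenomeSpec:
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 600_000, "chr3": 400_000}
    )
    window_size: int = 800
    mask_fraction: float = 0.02


@dataclass
class CohortSpec:
    groups: dict = field(default_factory=lambda: {g: 10 for g in ("RC", "T", "WZS", "YL", "LR")})


@dataclass
class SimulationSpec:
    mean_coverage: float = 50.0
    gc_peak: float = 0.45
    gc_strength: float = 0.5
    dispersion: float = 0.0
    n_shared_regions: int = 17


@dataclass
class CallerSpec:
    loss_max: float = 1.5
    gain_min: float = 2.5
    min_windows: int = 2
    max_gap_windows: int = 1
    gc_bins: int = 20


@dataclass
class MergeSpec:
    min_variant_freq: float = 0.18
    corr_min: float = 0.5
    max_gap_windows: int = 1
    corr_merge_gap_windows: int = 3
    cn_dev_min: float = 0.5


@dataclass
class FilterSpec:
    sil_min: float = 0.6
    loss_max_len: int = 50_000
    gain_max_len: int = 500_000
    both_max_len: int = 50_000
    af_mode: str = "carrier"


@dataclass
class AnnotationSpec:
    n_genes: int = 60
    exons_per_gene: int = 3
    n_qtls: int = 15


@dataclass
class RunConfig:
    """Full pipeline configuration; every downstream default is overridable."""

    seed: int = 0
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    simulation: SimulationSpec = field(default_factory=SimulationSpec)
    caller: CallerSpec = field(default_factory=CallerSpec)
    merge: MergeSpec = field(default_factory=MergeSpec)
    filters: FilterSpec = field(default_factory=FilterSpec)
    annotations: AnnotationSpec = field(default_factory=AnnotationSpec)
    contrasts: list = field(
        default_factory=lambda: [
            {"focal": "RC", "reference": ["YL", "LR"]},
            {"focal": "T", "reference": ["YL", "LR"]},
            {"focal": "WZS", "reference": ["YL", "LR"]},
        ]
    )
    top_fraction: float = 0.05


_NESTED = {
    "genome": GenomeSpec,
    "cohort": CohortSpec,
    "simulation": SimulationSpec,
    "caller": CallerSpec,
    "merge": MergeSpec,
    "filters": FilterSpec,
    "annotations": AnnotationSpec,
}


def config_from_dict(data: dict) -> RunConfig:
    """Build a RunConfig, rejecting unknown keys by name at any level."""
    if not isinstance(data, dict):
        raise ConfigurationError("config must be a mapping")
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - top_fields
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    kwargs: dict = {}
    for key, value in data.items():
        if key in _NESTED:
            cls = _NESTED[key]
            sub_fields = {f.name for f in dataclasses.fields(cls)}
            sub_unknown = set(value) - sub_fields
            if sub_unknown:
                raise ConfigurationError(f"unknown config key(s) in {key!r}: {sorted(sub_unknown)}")
            kwargs[key] = cls(**value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def demo_config(seed: int = 0) -> RunConfig:
    """The default demo cohort: 3 chromosomes totalling 2 Mb (2,500 windows of
    800 bp), 5 populations x 10 samples, 20 planted regions, 50 reads/window."""
    return config_from_dict({"seed": seed})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir, return_state: bool = False):
    """Execute all stages into ``outdir``; returns the manifest dict.

    With ``return_state`` the in-memory stage products (genome, truth, copy
    number matrix, CNVRs, Vst records, summary) are returned alongside the
    manifest as ``(manifest, state)``.

    Stage failures raise with the failing stage named; files written before the
    failure are retained for debugging.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}
    state: dict = {}

    def record(stage: str, params: dict, outputs: list[Path]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "seed": stage_seed(config.seed, stage),
                "params": params,
                "param_hash": hashlib.sha256(
                    json.dumps(params, sort_keys=True).encode()
                ).hexdigest()[:16],
                "outputs": {p.name: _sha256(p) for p in outputs},
            }
        )

    for stage in STAGES:
        try:
            outputs = _STAGE_FUNCS[stage](config, outdir, state)
        except Exception as exc:
            raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
        record(stage, state.pop("_params"), outputs)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if return_state:
        return manifest, state
    return manifest


def _stage_simulate(config: RunConfig, outdir: Path, state: dict) -> list[Path]:
    seed = stage_seed(config.seed, "simulate")
    g = genome_mod.make_windowed_genome(
        config.genome.chrom_lengths,
        window_size=config.genome.window_size,
        gc_profile_seed=seed,
        mask_fraction=config.genome.mask_fraction,
    )
    groups = tuple(config.cohort.groups)
    specs = cohort.demo_region_specs(
        g, groups=groups, n_shared=config.simulation.n_shared_regions, seed=seed
    )
    truth = cohort.plant_truth(g, config.cohort.groups, specs, seed=seed)
    dm = cohort.simulate_depth(
        g,
        truth,
        mean_coverage=config.simulation.mean_coverage,
        gc_bias=cohort.GCBias(config.simulation.gc_peak, config.simulation.gc_strength),
        dispersion=config.simulation.dispersion,
        seed=seed,
    )
    annotation = cohort.emit_annotations(
        g,
        n_genes=config.annotations.n_genes,
        exons_per_gene=config.annotations.exons_per_gene,
        n_qtls=config.annotations.n_qtls,
        seed=seed,
    )
    state.update(genome=g, truth=truth, depth=dm, annotation=annotation)

    from .matrix import write_depth

    paths = {
        "windows": outdir / "windows.tsv",
        "depth": outdir / "depth.tsv",
        "truth_regions": outdir / "truth_regions.tsv",
        "truth_cn": outdir / "truth_cn.tsv",
        "samples": outdir / "samples.tsv",
        "genes": outdir / "genes.bed",
        "exons": outdir / "exons.bed",
        "qtls": outdir / "qtls.bed",
    }
    genome_mod.write_windows(g, paths["windows"])
    write_depth(dm, paths["depth"])
    truth.regions_frame().to_csv(paths["truth_regions"], sep="\t", index=False)
    truth.per_sample_frame().to_csv(paths["truth_cn"], sep="\t", index=False)
    pd.DataFrame(
        {"sample": list(truth.sample_groups), "group": list(truth.sample_groups.values())}
    ).to_csv(paths["samples"], sep="\t", index=False)
    ann.write_bed(annotation.genes, paths["genes"])
    ann.write_bed(annotation.exons, paths["exons"])
    ann.write_bed(annotation.qtls, paths["qtls"])
    state["_params"] = {
        "genome": dataclasses.asdict(config.genome),
        "cohort": dataclasses.asdict(config.cohort),
        "simulation": dataclasses.asdict(config.simulation),
        "annotations": dataclasses.asdict(config.annotations),
    }
    return list(paths.values())


def _stage_depthcall(config: RunConfig, outdir: Path, state: dict) -> list[Path]:
    from .matrix import write_copy_number

    corrected = depth.gc_correct(state["depth"], state["genome"], n_bins=config.caller.gc_bins)
    cnmat = depth.normalize_copy_number(corrected)
    calls = depth.call_sample_cnvs(
        cnmat,
        loss_max=config.caller.loss_max,
        gain_min=config.caller.gain_min,
        min_windows=config.caller.min_windows,
        max_gap_windows=config.caller.max_gap_windows,
    )
    state.update(cnmat=cnmat, calls=calls)
    cn_path = outdir / "copy_number.tsv"
    calls_path = outdir / "calls.bed"
    write_copy_number(cnmat, cn_path)
    depth.write_calls(calls, calls_path)
    state["_params"] = dataclasses.asdict(config.caller)
    return [cn_path, calls_path]


def _stage_cnvr(config: RunConfig, outdir: Path, state: dict) -> list[Path]:
    cfg = cnvr_mod.MergeConfig(
        min_variant_freq=config.merge.min_variant_freq,
        corr_min=config.merge.corr_min,
        max_gap_windows=config.merge.max_gap_windows,
        corr_merge_gap_windows=config.merge.corr_merge_gap_windows,
        cn_dev_min=config.merge.cn_dev_min,
    )
    cnvrs = cnvr_mod.build_cnvrs(
        state["cnmat"],
        cfg,
        af_mode=config.filters.af_mode,
        sil_min=config.filters.sil_min,
        loss_max_len=config.filters.loss_max_len,
        gain_max_len=config.filters.gain_max_len,
        both_max_len=config.filters.both_max_len,
    )
    state["cnvrs"] = cnvrs
    p1 = outdir / "cnvrs.tsv"
    p2 = outdir / "cnvr_genotypes_int.tsv"
    p3 = outdir / "cnvr_genotypes_real.tsv"
    cnvr_mod.write_cnvrs(cnvrs, p1)
    cnvr_mod.genotypes_frame(cnvrs, "int").to_csv(p2, sep="\t")
    cnvr_mod.genotypes_frame(cnvrs, "real").to_csv(p3, sep="\t")
    state["_params"] = {**dataclasses.asdict(config.merge), **dataclasses.asdict(config.filters)}
    return [p1, p2, p3]


def _stage_vst(config: RunConfig, outdir: Path, state: dict) -> list[Path]:
    genotypes = cnvr_mod.genotypes_frame(state["cnvrs"], "real")
    contrasts = [(c["focal"], list(c["reference"])) for c in config.contrasts]
    records = vst_mod.scan(
        genotypes, state["truth"].sample_groups, contrasts, q=config.top_fraction
    )
    panel = vst_mod.group_frequency_panel(
        cnvr_mod.genotypes_frame(state["cnvrs"], "int"), state["truth"].sample_groups
    )
    state["vst"] = records
    p1 = outdir / "vst.tsv"
    p2 = outdir / "group_frequency_panel.tsv"
    vst_mod.write_vst(records, p1)
    panel.to_csv(p2, sep="\t", index=False)
    state["_params"] = {"contrasts": config.contrasts, "top_fraction": config.top_fraction}
    return [p1, p2]


def _stage_annotate(config: RunConfig, outdir: Path, state: dict) -> list[Path]:
    cnvrs_df = cnvr_mod.cnvrs_to_frame(state["cnvrs"])
    annotation = state["annotation"]
    context = ann.genomic_context(cnvrs_df, annotation)
    genes = ann.overlap_genes(cnvrs_df, annotation)
    qtl_map, n_hit, n_traits = ann.overlap_qtls(cnvrs_df, annotation.qtls)
    chrom_sum = ann.chromosome_summary(cnvrs_df, state["genome"].chrom_lengths)
    stats = ann.summary_stats(
        calls=depth.calls_to_frame(state["calls"]),
        cnvrs=cnvrs_df,
        chrom_lengths=state["genome"].chrom_lengths,
    )
    stats["qtl_cnvrs_hit"] = n_hit
    stats["qtl_distinct_traits"] = n_traits
    stats["context_counts"] = {k: int(v) for k, v in context.value_counts().items()}
    if chrom_sum.r2 is not None:
        stats["chrom_count_vs_length_r2"] = chrom_sum.r2
        stats["chrom_count_vs_length_p"] = chrom_sum.p_value

    p1 = outdir / "cnvr_context.tsv"
    p2 = outdir / "cnvr_genes.tsv"
    p3 = outdir / "cnvr_qtls.tsv"
    p4 = outdir / "summary.json"
    context.rename_axis("cnvr_id").to_frame().to_csv(p1, sep="\t")
    pd.DataFrame(
        [{"cnvr_id": k, "genes": ",".join(v)} for k, v in genes.items()],
        columns=["cnvr_id", "genes"],
    ).to_csv(p2, sep="\t", index=False)
    pd.DataFrame(
        [{"cnvr_id": k, "traits": ",".join(v)} for k, v in qtl_map.items()],
        columns=["cnvr_id", "traits"],
    ).to_csv(p3, sep="\t", index=False)
    p4.write_text(json.dumps(stats, indent=2, sort_keys=True))
    state["summary"] = stats
    state["_params"] = dataclasses.asdict(config.annotations)
    return [p1, p2, p3, p4]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "depthcall": _stage_depthcall,
    "cnvr": _stage_cnvr,
    "vst": _stage_vst,
    "annotate": _stage_annotate,
}
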