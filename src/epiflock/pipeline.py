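"""End-to-end orchestration of the analysis stages over a run directory.

Stages: simulate -> lncrna -> methylation -> targets -> network. Each stage
reads and writes plain-text files under the run directory and appends an
entry to ``manifest.json``; an identical config and seed reproduces
identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import association, genome_model, lncrna_id, methylation, network_enrichment
from .synthetic_data import SimulationConfig, GroundTruth, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "lncrna", "methylation", "targets", "network")


@dataclass
class PipelineConfig:
    """Paths, thresholds and stage toggles for a pipeline run.

    The thresholds default to the analysis' canonical values: minimum FPKM
    0.5 for lncRNA detectability, a 100 kb co-location window, |PCC| > 0.95
    for co-expression, DE and DMR alpha 0.05, enrichment alpha 0.01, 2 kb
    promoters, 10 kb methylation bins.
    """

    out_dir: str = "epiflock_run"
    seed: int = 0
    contrast: str = "NF-BF"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    min_fpkm: float = 0.5
    min_exons: int = 2
    min_length: int = 200
    overlap_strand: str = "both"
    window_bp: int = 100_000
    pcc_min: float = 0.95
    de_alpha: float = 0.05
    enrich_alpha: float = 0.01
    promoter_bp: int = 2000
    bin_bp: int = 10_000
    dmr_min_sites: int = 3
    dmr_max_gap: int = 200
    dmr_alpha: float = 0.05
    dmr_min_delta: float = 0.1
    share_min: float = 0.75
    annotation_sets: str | None = None
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.contrast not in association.CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}")
        for name, lo, hi in (
            ("min_fpkm", 0, None), ("pcc_min", 0, 1), ("de_alpha", 0, 1),
            ("enrich_alpha", 0, 1), ("dmr_alpha", 0, 1), ("dmr_min_delta", 0, 1),
            ("share_min", 0, 1),
        ):
            v = getattr(self, name)
            if v < lo or (hi is not None and v > hi):
                raise ValueError(f"{name}={v} outside documented range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


class StageError(RuntimeError):
    """A pipeline stage failed or its inputs are missing."""


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    Fails with :class:`StageError` when a stage's inputs are missing (for
    example the network stage without DMR genes); partial outputs and the
    manifest up to the failure point are retained on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    manifest_path = out / "manifest.json"
    runners = {
        "simulate": _stage_simulate,
        "lncrna": _stage_lncrna,
        "methylation": _stage_methylation,
        "targets": _stage_targets,
        "network": _stage_network,
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            outputs = runners[stage](config, out)
        except Exception as exc:
            manifest.append({"stage": stage, "status": "failed", "error": str(exc), "seed": config.seed})
            manifest_path.write_text(json.dumps(manifest, indent=1))
            raise StageError(f"stage {stage} failed: {exc}") from exc
        manifest.append(
            {
                "stage": stage,
                "status": "completed",
                "outputs": [str(p) for p in outputs],
                "seed": config.seed,
                "parameters": {k: v for k, v in asdict(config).items() if k not in ("stages", "simulation")},
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }
        )
        manifest_path.write_text(json.dumps(manifest, indent=1))
    return out


# ---------------------------------------------------------------------------
# Stage implementations


def _data_dir(out: Path) -> Path:
    return out / "data"


def _stage_simulate(config: PipelineConfig, out: Path) -> list[Path]:
    sim_cfg = SimulationConfig(**{"seed": config.seed, **config.simulation})
    ds = simulate_dataset(sim_cfg)
    write_dataset(ds, _data_dir(out))
    return sorted(_data_dir(out).iterdir())


def _load_inputs(config: PipelineConfig, out: Path):
    data = _data_dir(out)
    if not (data / "annotation.gtf").exists():
        raise StageError(f"no input data under {data}; run the simulate stage or place inputs there")
    ann = genome_model.read_annotation(
        data / "annotation.gtf", data / "cgi.bed", data / "repeats.bed"
    )
    expr = genome_model.read_expression(data / "expression.tsv", data / "design.tsv")
    return ann, expr


def _stage_lncrna(config: PipelineConfig, out: Path) -> list[Path]:
    data = _data_dir(out)
    ann, expr = _load_inputs(config, out)
    calls = lncrna_id.read_coding_calls(data / "coding_calls.tsv")
    candidates = [
        lncrna_id.CandidateTranscript(ann.transcripts[cid], calls[cid])
        for cid in sorted(calls)
        if cid in ann.transcripts
    ]
    lncs, report = lncrna_id.run_cascade(
        candidates,
        ann,
        expr.subset([c.transcript_id for c in candidates]),
        min_exons=config.min_exons,
        min_length=config.min_length,
        min_fpkm=config.min_fpkm,
        strand_mode=config.overlap_strand,
    )
    gtf = out / "lncrnas.gtf"
    lncrna_id.write_lncrnas(lncs, gtf)
    rep = out / "cascade_report.tsv"
    report.to_frame().to_csv(rep, sep="\t", index=False)
    return [gtf, rep]


def _group_tables(config: PipelineConfig, out: Path) -> tuple[list[pd.DataFrame], list[pd.DataFrame], float]:
    """Load per-sample cytosine tables for the contrast groups; estimate r."""
    data = _data_dir(out)
    design = genome_model.SampleDesign.from_frame(pd.read_csv(data / "design.tsv", sep="\t"))
    (ta, tra), (tb, trb) = association.CONTRASTS[config.contrast]
    tables_a, tables_b, lam = [], [], []
    for s in design.samples:
        path = data / f"{s.sample_id}.cytosine.tsv"
        if not path.exists():
            continue
        table = methylation.read_cytosine_table(path)
        genomic, spike = methylation.split_spikein(table)
        lam.append(spike)
        if (s.tissue, s.treatment) == (ta, tra):
            tables_a.append(genomic)
        elif (s.tissue, s.treatment) == (tb, trb):
            tables_b.append(genomic)
    if not tables_a or not tables_b:
        raise StageError(f"no cytosine tables for contrast {config.contrast} under {data}")
    r = methylation.non_conversion_rate(pd.concat(lam, ignore_index=True))
    return tables_a, tables_b, r


def _stage_methylation(config: PipelineConfig, out: Path) -> list[Path]:
    ann, _ = _load_inputs(config, out)
    tables_a, tables_b, r = _group_tables(config, out)
    pooled_a = methylation.pool_counts(tables_a)
    pooled_b = methylation.pool_counts(tables_b)
    params = methylation.DMRParams(
        min_sites=config.dmr_min_sites,
        max_gap=config.dmr_max_gap,
        alpha=config.dmr_alpha,
        min_delta=config.dmr_min_delta,
    )
    # groups are (A, B) = the contrast's two groups; direction is B vs A
    dmrs = methylation.call_dmrs(pooled_b, pooled_a, params)
    dmr_genes = methylation.map_dmr_genes(dmrs, ann, config.promoter_bp)
    bins = methylation.bin_levels(pd.concat([pooled_a, pooled_b]), r, config.bin_bp)
    paths = [out / "dmrs.bed", out / "dmr_genes.tsv", out / "bin_levels.tsv", out / "non_conversion.json"]
    methylation.write_dmrs(dmrs, paths[0])
    methylation.write_dmr_genes(dmr_genes, paths[1])
    bins.to_csv(paths[2], sep="\t", index=False)
    paths[3].write_text(json.dumps({"non_conversion_rate": r}))
    return paths


def _read_lnc_ids(out: Path) -> dict[str, genome_model.GenomicInterval]:
    gtf = out / "lncrnas.gtf"
    if not gtf.exists():
        raise StageError("lncrnas.gtf missing; run the lncrna stage first")
    spans: dict[str, genome_model.GenomicInterval] = {}
    import pyranges as pr

    df = pr.read_gtf(str(gtf)).df
    if df.empty:
        return spans
    for tid, sub in df[df.Feature == "transcript"].groupby("transcript_id"):
        row = sub.iloc[0]
        spans[str(tid)] = genome_model.GenomicInterval(
            str(row.Chromosome), int(row.Start), int(row.End), str(row.Strand)
        )
    return spans


def _stage_targets(config: PipelineConfig, out: Path) -> list[Path]:
    ann, expr = _load_inputs(config, out)
    lnc_spans = _read_lnc_ids(out)
    gene_spans = {g.gene_id: g.interval for g in ann.coding_genes()}
    lnc_ids = sorted(lnc_spans)
    gene_ids = sorted(gene_spans)

    lnc_expr = expr.subset(lnc_ids)
    gene_expr = expr.subset(gene_ids)
    de_lnc = association.diff_expression(lnc_expr, config.contrast, config.de_alpha)
    de_gene = association.diff_expression(gene_expr, config.contrast, config.de_alpha)
    coloc = association.colocation_targets(lnc_spans, gene_spans, config.window_bp)
    coexp = association.coexpression_targets(lnc_expr, gene_expr, config.pcc_min, config.de_alpha)
    targets = association.merge_targets(coloc, coexp)

    paths = [out / "targets.tsv", out / "de_lncrnas.tsv", out / "de_genes.tsv"]
    association.targets_table(targets).to_csv(paths[0], sep="\t", index=False)
    association.de_table(de_lnc).to_csv(paths[1], sep="\t", index=False)
    association.de_table(de_gene).to_csv(paths[2], sep="\t", index=False)
    return paths


def _stage_network(config: PipelineConfig, out: Path) -> list[Path]:
    for name in ("targets.tsv", "de_lncrnas.tsv", "de_genes.tsv"):
        if not (out / name).exists():
            raise StageError(f"{name} missing; run the targets stage first")
    if not (out / "dmr_genes.tsv").exists():
        raise StageError("dmr_genes.tsv missing; run the methylation stage first")
    ann, _ = _load_inputs(config, out)

    tdf = pd.read_csv(out / "targets.tsv", sep="\t")
    targets = [
        association.TargetPair(
            str(r.lnc_id), str(r.gene_id), str(r.evidence),
            distance=None if pd.isna(r.distance) else int(r.distance),
            pcc=None if pd.isna(r.pcc) else float(r.pcc),
            p_adj=None if pd.isna(r.p_adj) else float(r.p_adj),
        )
        for r in tdf.itertuples()
    ]
    dmrs = methylation.read_dmrs(out / "dmrs.bed") if (out / "dmrs.bed").exists() else []
    dmr_genes = methylation.map_dmr_genes(dmrs, ann, config.promoter_bp)

    def _read_de(path: Path) -> list[association.DiffExprResult]:
        df = pd.read_csv(path, sep="\t")
        return [
            association.DiffExprResult(
                str(r.feature_id), float(r.log2fc), float(r.p), float(r.p_adj),
                bool(r.significant), str(r.contrast),
            )
            for r in df.itertuples()
        ]

    net = network_enrichment.build_network(
        targets, dmr_genes, _read_de(out / "de_lncrnas.tsv"), _read_de(out / "de_genes.tsv"),
        config.contrast,
    )
    modules = network_enrichment.find_modules(net, config.share_min)
    written = network_enrichment.export_network(net, out / "network")
    mod_path = out / "modules.tsv"
    network_enrichment.modules_table(modules).to_csv(mod_path, sep="\t", index=False)
    written.append(mod_path)

    if config.annotation_sets:
        sets = network_enrichment.AnnotationSets.from_tsv(config.annotation_sets)
        enr = network_enrichment.hypergeom_enrich(set(net.genes), sets, config.enrich_alpha)
        enr_path = out / "enrichment.tsv"
        network_enrichment.enrichment_table(enr).to_csv(enr_path, sep="\t", index=False)
        written.append(enr_path)
    return written
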