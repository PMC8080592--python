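"""Synthetic dataset generator with recorded ground truth.

Emulates the data the pipeline consumes for a 2 tissue x 2 treatment x 3
replicate design: a genome annotation with coding genes, CGI and repeat
tracks; lncRNA candidate transcripts spanning every positional class and
every identification-filter fail mode; FPKM expression with tissue structure,
planted treatment effects and planted lncRNA-gene co-expression pairs;
coding-potential predictor calls; and per-cytosine bisulfite counts with a
known non-conversion rate, an unmethylated lambda spike-in, and planted
differentially methylated regions.

Defaults mirror typical mammalian WGBS structure: mean CG methylation 70.6%,
CHG/CHH background 0.27%, and a 0.5% bisulfite non-conversion rate. All
randomness flows from a single seed; the same seed reproduces every output
byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import (
    ExpressionMatrix,
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    Sample,
    SampleDesign,
    Transcript,
    write_annotation,
    write_bed,
    write_expression,
)
from .lncrna_id import CandidateTranscript, PREDICTORS, write_coding_calls
from .methylation import CYTOSINE_COLUMNS, write_cytosine_table

FAIL_MODES = ("single_exon", "short", "known_overlap", "low_expression", "coding")

# Stage offsets for deriving independent per-stage random streams from the seed.
_STREAM = {"annotation": 0, "expression": 1, "calls": 2, "bisulfite": 3}


@dataclass
class SimulationConfig:
    """All knobs of the simulator; the defaults are the reference conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 120_000
    n_genes: int = 30
    n_lnc_candidates: int = 40
    n_replicates: int = 3  # per (tissue, treatment) cell -> 12 samples
    mean_depth: float = 20.0
    cg_level: float = 0.706
    non_cg_level: float = 0.0027
    non_conversion_rate: float = 0.005
    n_planted_dmrs: int = 8
    dmr_effect: float = 0.25
    dmr_length: int = 800
    dmr_tissue: str = "adipose"  # DMRs planted in control-vs-WEA of this tissue
    n_planted_targets: int = 10
    planted_pcc: float = 0.99
    n_planted_de: int = 12
    de_log2fc: float = 4.0
    lambda_length: int = 6_000
    n_fail_single_exon: int = 5
    n_fail_short: int = 3
    n_fail_known_overlap: int = 4
    n_fail_low_expression: int = 4
    n_fail_coding: int = 5
    cac_enriched_chh: bool = False

    def __post_init__(self) -> None:
        for name in ("cg_level", "non_cg_level", "non_conversion_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1 < self.planted_pcc < 1:
            raise ValueError("planted_pcc must be in (-1, 1)")
        if self.n_fail_total > self.n_lnc_candidates:
            raise ValueError("fail-mode counts exceed n_lnc_candidates")
        if self.n_planted_targets > min(self.n_pass_candidates, self.n_genes):
            raise ValueError(
                "n_planted_targets exceeds available passing candidates or genes"
            )
        if self.n_genes and max(self.chrom_length - 4500, 0) // 4000 * self.n_chroms < self.n_genes:
            raise ValueError("chromosomes too short for the requested gene count")

    @property
    def n_fail_total(self) -> int:
        return (
            self.n_fail_single_exon
            + self.n_fail_short
            + self.n_fail_known_overlap
            + self.n_fail_low_expression
            + self.n_fail_coding
        )

    @property
    def n_pass_candidates(self) -> int:
        return self.n_lnc_candidates - self.n_fail_total

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stage]])


@dataclass
class GroundTruth:
    """Everything a recovery test needs about what was planted."""

    dmrs: list[dict] = field(default_factory=list)  # chrom,start,end,direction,context
    target_pairs: list[dict] = field(default_factory=list)  # lnc_id,gene_id,sign
    de_features: dict[str, str] = field(default_factory=dict)  # id -> up/down (WEA vs control)
    non_conversion_rate: float = 0.0
    candidate_modes: dict[str, str] = field(default_factory=dict)  # id -> pass/<fail mode>
    lnc_classes: dict[str, str] = field(default_factory=dict)  # passing id -> class

    def fail_count(self, mode: str) -> int:
        return sum(1 for m in self.candidate_modes.values() if m == mode)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def make_design(n_replicates: int = 3) -> SampleDesign:
    """The 2x2xR design with the study's sample codes (B=control, N=treated;
    M=muscle, F=adipose/fat)."""
    samples = []
    for tissue, tcode in (("muscle", "M"), ("adipose", "F")):
        for treatment, code in (("control", "B"), ("WEA", "N")):
            for rep in range(1, n_replicates + 1):
                samples.append(Sample(f"{code}{tcode}{rep}", tissue, treatment, rep))
    return SampleDesign(samples)


# ---------------------------------------------------------------------------
# Sequence and annotation


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length, p=[0.29, 0.21, 0.21, 0.29]))


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[GenomeAnnotation, dict[str, str], GroundTruth]:
    """Generate the genome: sequences, coding genes, tracks, lnc candidates.

    Candidate transcripts are appended to the annotation under their own
    single-transcript genes with biotype ``other``; the ground truth records
    which fail mode (or ``pass``) each was built for and, for passing
    candidates, their expected positional class. Planted DMR intervals are
    placed inside gene bodies so each corresponds to a recoverable DMR gene.
    """
    rng = config.rng("annotation")
    truth = GroundTruth(non_conversion_rate=config.non_conversion_rate)
    ann = GenomeAnnotation(
        chrom_lengths={f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    )
    refseqs = {c: _random_seq(rng, L) for c, L in ann.chrom_lengths.items()}

    chroms = sorted(ann.chrom_lengths)
    per_chrom = _split_evenly(config.n_genes, len(chroms))
    gene_no = 0
    gaps: list[GenomicInterval] = []  # intergenic space for lnc placement
    introns: list[tuple[GenomicInterval, str]] = []  # (interval, host strand)
    for chrom, n_here in zip(chroms, per_chrom):
        cursor = 2500
        usable = config.chrom_length - cursor - 2000
        slot = usable // max(n_here, 1)
        if n_here and slot < 4000:
            raise ValueError(f"chromosome {chrom} too short for {n_here} genes")
        for _ in range(n_here):
            gap = int(rng.integers(int(0.20 * slot), int(0.35 * slot)))
            glen = int(rng.integers(int(0.45 * slot), int(0.60 * slot)))
            start = cursor + gap
            end = start + glen
            if end + 2000 > config.chrom_length:
                raise ValueError(f"chromosome {chrom} too short for requested genes")
            if gap > 600:
                gaps.append(GenomicInterval(chrom, cursor + 100, start - 100))
            gene_no += 1
            gid = f"G{gene_no:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            if gene_no % 2 == 0:
                # sparse gene: two terminal exons around one large intron,
                # guaranteeing intron space for intronic/antisense candidates
                exons = (
                    GenomicInterval(chrom, start, start + 300, strand),
                    GenomicInterval(chrom, end - 300, end, strand),
                )
            else:
                n_exons = int(rng.integers(1, 13))
                exons = _make_exons(rng, chrom, start, end, strand, n_exons)
            ann.genes[gid] = Gene(gid, GenomicInterval(chrom, start, end, strand), "coding")
            ann.transcripts[f"{gid}.t1"] = Transcript(f"{gid}.t1", gid, exons)
            for a, b in zip(exons, exons[1:]):
                if b.start - a.end >= 800:
                    introns.append((GenomicInterval(chrom, a.end, b.start, strand), strand))
            cursor = end
        if config.chrom_length - cursor > 800:
            gaps.append(GenomicInterval(chrom, cursor + 100, config.chrom_length - 100))

    _place_candidates(config, rng, ann, truth, gaps, introns)
    _place_tracks(config, rng, ann)
    _plant_dmrs(config, rng, ann, truth)
    ann.validate()
    return ann, refseqs, truth


def _split_evenly(n: int, k: int) -> list[int]:
    base, rem = divmod(n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def _make_exons(rng, chrom, start, end, strand, n_exons) -> tuple[GenomicInterval, ...]:
    """Carve ``n_exons`` disjoint exons out of [start, end), first and last anchored."""
    span = end - start
    if n_exons == 1:
        return (GenomicInterval(chrom, start, end, strand),)
    # choose 2*(n-1) interior cut points -> alternating exon/intron segments
    while True:
        cuts = np.sort(rng.choice(np.arange(start + 1, end - 1), size=2 * (n_exons - 1), replace=False))
        bounds = [start, *cuts.tolist(), end]
        exons = [
            GenomicInterval(chrom, bounds[2 * i], bounds[2 * i + 1], strand)
            for i in range(n_exons)
        ]
        if all(len(e) >= 1 for e in exons):
            return tuple(exons)


def _place_candidates(config, rng, ann, truth, gaps, introns) -> None:
    """Create lncRNA candidate transcripts for each fail mode and class."""
    jobs: list[str] = (
        ["single_exon"] * config.n_fail_single_exon
        + ["short"] * config.n_fail_short
        + ["known_overlap"] * config.n_fail_known_overlap
        + ["low_expression"] * config.n_fail_low_expression
        + ["coding"] * config.n_fail_coding
        + ["pass"] * config.n_pass_candidates
    )
    classes = ["intergenic", "intronic", "antisense"]
    gap_pool = [g for g in gaps if len(g) >= 900]
    intron_pool = [iv for iv, _ in introns if len(iv) >= 900]
    gi = ii = 0
    n_pass_done = 0
    for i, mode in enumerate(jobs):
        cid = f"LNC{i + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if mode == "pass":
            cls = classes[n_pass_done % len(classes)]
            n_pass_done += 1
        else:
            cls = "intergenic"
        if mode == "known_overlap":
            # two exons, the first sharing >= 1 bp with a coding exon
            host = sorted(ann.transcripts.values(), key=lambda t: t.transcript_id)[
                int(rng.integers(0, config.n_genes))
            ]
            hx = host.exons[0]
            s = max(0, hx.start - 150)
            exons = (
                GenomicInterval(hx.chrom, s, hx.start + 1, strand),
                GenomicInterval(hx.chrom, hx.start + 50, hx.start + 250, strand),
            )
        elif mode != "pass" or cls == "intergenic":
            if gi >= len(gap_pool):
                raise ValueError("not enough intergenic space for candidates")
            slot = gap_pool[gi]
            gi += 1
            exons = _candidate_exons(rng, slot, strand, mode)
        elif cls in ("intronic", "antisense"):
            if ii >= len(intron_pool):
                raise ValueError("not enough intron space for candidates")
            slot_iv = intron_pool[ii]
            host_strand = next(s for iv, s in introns if iv == slot_iv)
            ii += 1
            if cls == "intronic":
                strand = host_strand
            else:  # antisense: opposite strand to the host gene
                strand = "-" if host_strand == "+" else "+"
            exons = _candidate_exons(rng, slot_iv, strand, "pass")
        gid = f"LNCG{i + 1:04d}"
        t = Transcript(cid, gid, exons)
        ann.genes[gid] = Gene(gid, t.span, "other")
        ann.transcripts[cid] = t
        truth.candidate_modes[cid] = mode
        if mode == "pass":
            truth.lnc_classes[cid] = cls


def _candidate_exons(rng, slot: GenomicInterval, strand: str, mode: str):
    chrom = slot.chrom
    s = slot.start + int(rng.integers(0, max(1, len(slot) - 850)))
    if mode == "single_exon":
        return (GenomicInterval(chrom, s, s + 500, strand),)
    if mode == "short":  # two exons, total length exactly 200 bp (fails strict >)
        return (
            GenomicInterval(chrom, s, s + 100, strand),
            GenomicInterval(chrom, s + 200, s + 300, strand),
        )
    e1 = int(rng.integers(150, 400))
    gap = int(rng.integers(60, 200))
    e2 = int(rng.integers(150, 400))
    return (
        GenomicInterval(chrom, s, s + e1, strand),
        GenomicInterval(chrom, s + e1 + gap, s + e1 + gap + e2, strand),
    )


def _place_tracks(config, rng, ann) -> None:
    """CGI track at a subset of promoters plus random repeats."""
    from .genome_model import cgi_shores, promoter_of

    cgis = []
    for g in sorted(ann.coding_genes(), key=lambda g: g.gene_id):
        if rng.random() < 0.5:
            p = promoter_of(g, 1000, ann.chrom_lengths)
            if p is not None:
                cgis.append(GenomicInterval(p.chrom, p.start, p.end))
    ann.cgi_intervals = sorted(cgis)
    ann.cgi_shore_intervals = cgi_shores(ann.cgi_intervals, 2000, ann.chrom_lengths)
    repeats = []
    for chrom, L in sorted(ann.chrom_lengths.items()):
        for _ in range(max(1, L // 40_000)):
            s = int(rng.integers(0, L - 500))
            repeats.append(GenomicInterval(chrom, s, s + int(rng.integers(200, 500))))
    ann.repeat_intervals = sorted(repeats)


def _plant_dmrs(config, rng, ann, truth) -> None:
    genes = sorted(ann.coding_genes(), key=lambda g: g.gene_id)
    hosts = rng.choice(len(genes), size=min(config.n_planted_dmrs, len(genes)), replace=False)
    for j, gidx in enumerate(sorted(hosts.tolist())):
        g = genes[gidx]
        iv = g.interval
        length = min(config.dmr_length, len(iv) - 2)
        s = iv.start + int(rng.integers(0, len(iv) - length))
        direction = "hyper" if j % 2 == 0 else "hypo"
        truth.dmrs.append(
            {
                "chrom": iv.chrom,
                "start": int(s),
                "end": int(s + length),
                "direction": direction,
                "context": "CG",
                "gene_id": g.gene_id,
            }
        )


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    truth: GroundTruth,
) -> ExpressionMatrix:
    """FPKM matrix for coding genes and lnc candidates across the 12 samples.

    Expression is log-normal: a per-feature baseline plus a per-feature
    tissue effect, a planted treatment effect (log2 fold change applied to
    treated samples) for the DE set, and Gaussian noise. Planted
    lncRNA-gene pairs are instead driven by a shared latent factor per pair,
    giving |PCC| ~ ``planted_pcc`` by construction without distorting the
    marginal distribution. lncRNA baselines sit below mRNA baselines.
    """
    rng = config.rng("expression")
    design = make_design(config.n_replicates)
    n_s = len(design.samples)
    is_muscle = np.array([s.tissue == "muscle" for s in design.samples], dtype=float)
    is_treated = np.array([s.treatment == "WEA" for s in design.samples], dtype=float)

    gene_ids = sorted(g.gene_id for g in annotation.coding_genes())
    cand_ids = sorted(truth.candidate_modes)
    feature_ids = gene_ids + cand_ids

    # choose planted DE features: genes not reserved for planted pairs, plus
    # passing lnc candidates, so downstream networks have DE nodes of both kinds
    pass_ids = sorted(cid for cid, m in truth.candidate_modes.items() if m == "pass")
    pair_lncs = pass_ids[: config.n_planted_targets]
    pair_genes = gene_ids[: config.n_planted_targets]
    free_genes = [g for g in gene_ids if g not in pair_genes]
    free_lncs = [c for c in pass_ids if c not in pair_lncs]
    n_de_genes = min(len(free_genes), (config.n_planted_de + 1) // 2)
    n_de_lncs = min(len(free_lncs), config.n_planted_de - n_de_genes)
    de_ids = free_genes[:n_de_genes] + free_lncs[:n_de_lncs]
    for i, fid in enumerate(de_ids):
        truth.de_features[fid] = "up" if i % 2 == 0 else "down"

    log2x = np.zeros((len(feature_ids), n_s))
    row = {fid: i for i, fid in enumerate(feature_ids)}
    noise_sd, tissue_sd = 0.5, 2.0
    for fid in feature_ids:
        i = row[fid]
        is_lnc = fid in truth.candidate_modes
        mode = truth.candidate_modes.get(fid, "")
        if mode == "low_expression":
            # below the detectability threshold in every sample: no design
            # effects, tight noise around a low baseline
            log2x[i] = rng.normal(-3.0, 0.3) + rng.normal(0, noise_sd, n_s)
            continue
        if fid in truth.de_features and is_lnc:
            # DE-planted lncRNAs sit high enough that a downward fold change
            # stays above the pseudocount floor and remains detectable
            base = rng.normal(4.0, 0.3)
        elif is_lnc:
            base = max(rng.normal(2.0, 1.0), 0.5)  # detectable by construction
        else:
            base = rng.normal(5.0, 1.5)
        log2x[i] = base + rng.normal(0, noise_sd, n_s)
        log2x[i] += rng.normal(0, tissue_sd) * is_muscle
        if fid in truth.de_features:
            sign = 1.0 if truth.de_features[fid] == "up" else -1.0
            log2x[i] += sign * config.de_log2fc * is_treated

    # planted co-expression pairs override: shared latent factor, no design effects
    rho = config.planted_pcc
    for lnc_id, gene_id in zip(pair_lncs, pair_genes):
        sign = 1 if rng.random() < 0.5 else -1
        z = rng.normal(0, 1, n_s)
        e1 = rng.normal(0, 1, n_s)
        e2 = rng.normal(0, 1, n_s)
        a = np.sqrt(rho)
        b = np.sqrt(1 - rho)
        log2x[row[lnc_id]] = 2.0 + 1.0 * (a * z + b * e1)
        log2x[row[gene_id]] = 5.0 + sign * 1.0 * (a * z + b * e2)
        truth.target_pairs.append({"lnc_id": lnc_id, "gene_id": gene_id, "sign": sign})

    values = pd.DataFrame(
        np.power(2.0, log2x), index=pd.Index(feature_ids, name="feature_id"),
        columns=design.sample_ids,
    )
    return ExpressionMatrix(values, design)


# ---------------------------------------------------------------------------
# Coding-potential predictor calls


def simulate_coding_calls(
    config: SimulationConfig, truth: GroundTruth
) -> dict[str, dict[str, str]]:
    """Boolean predictor calls: every candidate non-coding except the
    ``coding`` fail mode, which gets a coding call from >= 1 predictor."""
    rng = config.rng("calls")
    calls = {}
    for cid in sorted(truth.candidate_modes):
        mode = truth.candidate_modes[cid]
        d = {p: "noncoding" for p in PREDICTORS}
        if mode == "coding":
            n_coding = int(rng.integers(1, len(PREDICTORS) + 1))
            for p in rng.choice(PREDICTORS, size=n_coding, replace=False):
                d[str(p)] = "coding"
        calls[cid] = d
    return calls


def candidates_from_truth(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    calls: dict[str, dict[str, str]],
) -> list[CandidateTranscript]:
    return [
        CandidateTranscript(annotation.transcripts[cid], calls[cid])
        for cid in sorted(truth.candidate_modes)
    ]


# ---------------------------------------------------------------------------
# Bisulfite counts


def simulate_bisulfite(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    refseqs: dict[str, str],
    truth: GroundTruth,
) -> tuple[dict[str, pd.DataFrame], str]:
    """Per-sample cytosine count tables plus the lambda spike-in sequence.

    Per cytosine and sample, depth ~ Poisson(mean_depth) and methylated
    counts ~ Binomial(depth, p_obs) with p_obs = p + (1 - p) * r, where p is
    the context baseline (CG vs CHG/CHH), overridden inside planted DMRs for
    the treated samples of the DMR tissue, and r is the non-conversion rate.
    The lambda chromosome is fully unmethylated (p = 0), so its observed
    methylated fraction estimates r.
    """
    from .methylation import cytosine_positions

    rng = config.rng("bisulfite")
    design = make_design(config.n_replicates)
    r = config.non_conversion_rate

    lam_seq = _random_seq(rng, config.lambda_length)
    frames = [cytosine_positions(refseqs[c], c) for c in sorted(refseqs)]
    frames.append(cytosine_positions(lam_seq, "lambda"))
    sites = pd.concat(frames, ignore_index=True)

    p_base = np.where(sites["context"] == "CG", config.cg_level, config.non_cg_level)
    p_base = np.where(sites["chrom"] == "lambda", 0.0, p_base)

    dmr_mask = np.zeros(len(sites), dtype=bool)
    dmr_delta = np.zeros(len(sites))
    pos = sites["pos"].to_numpy()
    for d in truth.dmrs:
        in_d = (
            (sites["chrom"].to_numpy() == d["chrom"])
            & (pos >= d["start"])
            & (pos < d["end"])
            & (sites["context"].to_numpy() == d["context"])
        )
        dmr_mask |= in_d
        dmr_delta[in_d] = config.dmr_effect if d["direction"] == "hyper" else -config.dmr_effect

    tables = {}
    for s in design.samples:
        affected = s.tissue == config.dmr_tissue and s.treatment == "WEA"
        p = np.clip(p_base + (dmr_delta if affected else 0.0) * dmr_mask, 0.0, 1.0)
        p_obs = p + (1.0 - p) * r
        depth = rng.poisson(config.mean_depth, len(sites))
        m = rng.binomial(depth, p_obs)
        tables[s.sample_id] = pd.DataFrame(
            {
                "chrom": sites["chrom"],
                "pos": sites["pos"],
                "strand": sites["strand"],
                "context": sites["context"],
                "m": m,
                "u": depth - m,
            }
        )[CYTOSINE_COLUMNS]
    return tables, lam_seq


# ---------------------------------------------------------------------------
# Full dataset


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: GenomeAnnotation
    refseqs: dict[str, str]
    lambda_seq: str
    expression: ExpressionMatrix
    coding_calls: dict[str, dict[str, str]]
    bisulfite: dict[str, pd.DataFrame]
    truth: GroundTruth

    def candidates(self) -> list[CandidateTranscript]:
        return candidates_from_truth(self.annotation, self.truth, self.coding_calls)


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Run all simulator stages under one seed."""
    config = config or SimulationConfig()
    annotation, refseqs, truth = simulate_annotation(config)
    expression = simulate_expression(config, annotation, truth)
    calls = simulate_coding_calls(config, truth)
    bisulfite, lam_seq = simulate_bisulfite(config, annotation, refseqs, truth)
    return SimulatedDataset(config, annotation, refseqs, lam_seq, expression, calls, bisulfite, truth)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write every simulated artifact as plain-text files under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_annotation(ds.annotation, out / "annotation.gtf")
    write_bed(ds.annotation.cgi_intervals, out / "cgi.bed")
    write_bed(ds.annotation.repeat_intervals, out / "repeats.bed")
    _write_fasta({**ds.refseqs, "lambda": ds.lambda_seq}, out / "reference.fa")
    write_expression(ds.expression, out / "expression.tsv", out / "design.tsv")
    write_coding_calls(ds.coding_calls, out / "coding_calls.tsv")
    for sid, table in ds.bisulfite.items():
        write_cytosine_table(table, out / f"{sid}.cytosine.tsv")
    ds.truth.to_json(out / "ground_truth.json")
    (out / "config.json").write_text(json.dumps(asdict(ds.config), indent=1))


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")
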