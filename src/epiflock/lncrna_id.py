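"""lncRNA identification cascade and positional classification.

Candidate transcripts pass four conjunctive filters: structure (>= 2 exons
and mature length > 200 bp), no exonic overlap with annotated coding exons,
detectable expression (max FPKM across samples >= 0.5), and a consensus
non-coding call from every available coding-potential predictor. Survivors
are classified as antisense, intronic or intergenic relative to coding genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genome_model import (
    ExpressionMatrix,
    GenomeAnnotation,
    GenomicInterval,
    IntervalIndex,
    Transcript,
    build_interval_index,
)

logger = logging.getLogger(__name__)

PREDICTORS = ("cnci", "cpc", "pfam", "phylocsf")
LNC_CLASSES = ("intergenic", "intronic", "antisense")


@dataclass(frozen=True)
class CandidateTranscript:
    """A transcript with coding-potential calls from external predictors.

    ``coding_calls`` maps predictor name to ``"coding"`` or ``"noncoding"``;
    a predictor may be absent but at least one call must be present.
    """

    transcript: Transcript
    coding_calls: dict[str, str] = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        if not self.coding_calls:
            raise ValueError(
                f"candidate {self.transcript.transcript_id}: no predictor calls"
            )
        bad = {v for v in self.coding_calls.values()} - {"coding", "noncoding"}
        if bad:
            raise ValueError(f"invalid coding calls: {bad}")

    @property
    def transcript_id(self) -> str:
        return self.transcript.transcript_id


@dataclass(frozen=True)
class LncRNA:
    transcript: Transcript
    lnc_class: str  # {intergenic, intronic, antisense}


@dataclass
class CascadeReport:
    """Per-stage bookkeeping: candidates in, out, and removed."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int) -> None:
        self.stages.append((stage, n_in, n_out))

    def removed(self, stage: str) -> int:
        for s, n_in, n_out in self.stages:
            if s == stage:
                return n_in - n_out
        raise KeyError(stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_in", "n_out"])


def filter_structure(
    candidates: list[CandidateTranscript],
    min_exons: int = 2,
    min_length: int = 200,
) -> list[CandidateTranscript]:
    """Keep candidates with >= ``min_exons`` exons and length > ``min_length`` bp.

    Length is the summed exon length; the length threshold is strict.
    """
    return [
        c
        for c in candidates
        if c.transcript.n_exons >= min_exons and c.transcript.length > min_length
    ]


def filter_known_overlap(
    candidates: list[CandidateTranscript],
    annotation: GenomeAnnotation,
    strand_mode: str = "both",
) -> list[CandidateTranscript]:
    """Remove candidates with >= 1 bp exonic overlap against annotated coding exons.

    ``strand_mode="both"`` ignores strand (any overlapping coding exon
    removes the candidate); ``"same"`` only counts same-strand overlaps.
    Fully intronic candidates survive this stage.
    """
    if strand_mode not in ("both", "same"):
        raise ValueError("strand_mode must be 'both' or 'same'")
    idx = build_interval_index(
        (exon, exon.strand) for exon, _gene_id in annotation.coding_exons()
    )
    kept = []
    for c in candidates:
        hit = False
        for exon in c.transcript.exons:
            for known, known_strand in idx.query(exon):
                if strand_mode == "both" or known_strand == exon.strand:
                    hit = True
                    break
            if hit:
                break
        if not hit:
            kept.append(c)
    return kept


def filter_expression(
    candidates: list[CandidateTranscript],
    expr: ExpressionMatrix,
    min_fpkm: float = 0.5,
) -> list[CandidateTranscript]:
    """Keep candidates whose maximum FPKM over samples is >= ``min_fpkm`` (inclusive)."""
    missing = [c.transcript_id for c in candidates if c.transcript_id not in expr.values.index]
    if missing:
        raise KeyError(f"candidates missing from expression matrix: {missing}")
    max_fpkm = expr.values.max(axis=1)
    return [c for c in candidates if max_fpkm[c.transcript_id] >= min_fpkm]


def consensus_noncoding(
    candidates: list[CandidateTranscript],
    predictors: tuple[str, ...] | None = None,
) -> list[CandidateTranscript]:
    """Keep candidates called non-coding by ALL available predictors.

    ``predictors`` restricts the consensus to a subset; predictors absent from
    a candidate's calls are ignored with a warning. A candidate with no
    usable predictor at all is an error.
    """
    kept = []
    warned: set[str] = set()
    for c in candidates:
        calls = c.coding_calls
        if predictors is not None:
            calls = {k: v for k, v in calls.items() if k in predictors}
            for p in predictors:
                if p not in c.coding_calls and p not in warned:
                    logger.warning("predictor %s missing; ignored in consensus", p)
                    warned.add(p)
        if not calls:
            raise ValueError(
                f"candidate {c.transcript_id}: no predictor calls among {predictors}"
            )
        if all(v == "noncoding" for v in calls.values()):
            kept.append(c)
    return kept


def classify_lncrna(transcript: Transcript, annotation: GenomeAnnotation) -> str:
    """Positional class of a surviving lncRNA relative to coding genes.

    Precedence: antisense (exonic overlap with a coding gene's span on the
    opposite strand) > intronic (fully contained in a coding gene's span on
    the same strand) > intergenic.
    """
    gene_idx = build_interval_index(
        (g.interval, g) for g in annotation.coding_genes()
    )
    span = transcript.span
    hits = [g for _, g in gene_idx.query(span)]
    for exon in transcript.exons:
        for g in hits:
            if g.interval.overlaps(exon) and _opposite(g.interval.strand, exon.strand):
                return "antisense"
    for g in hits:
        if (
            g.interval.strand == span.strand
            and g.interval.start <= span.start
            and span.end <= g.interval.end
        ):
            return "intronic"
    return "intergenic"


def _opposite(a: str, b: str) -> bool:
    return {a, b} == {"+", "-"}


def run_cascade(
    candidates: list[CandidateTranscript],
    annotation: GenomeAnnotation,
    expr: ExpressionMatrix,
    min_exons: int = 2,
    min_length: int = 200,
    min_fpkm: float = 0.5,
    strand_mode: str = "both",
    predictors: tuple[str, ...] | None = None,
) -> tuple[list[LncRNA], CascadeReport]:
    """Run the full identification cascade and classify survivors.

    The filters are conjunctive predicates, so the surviving set is the same
    for any stage order; the report reflects the canonical order
    structure -> known-overlap -> expression -> coding-potential.
    """
    report = CascadeReport()
    stage1 = filter_structure(candidates, min_exons, min_length)
    report.record("structure", len(candidates), len(stage1))
    stage2 = filter_known_overlap(stage1, annotation, strand_mode)
    report.record("known_overlap", len(stage1), len(stage2))
    stage3 = filter_expression(stage2, expr, min_fpkm)
    report.record("expression", len(stage2), len(stage3))
    stage4 = consensus_noncoding(stage3, predictors)
    report.record("coding_potential", len(stage3), len(stage4))
    lncs = [
        LncRNA(c.transcript, classify_lncrna(c.transcript, annotation)) for c in stage4
    ]
    return lncs, report


# ---------------------------------------------------------------------------
# I/O


def read_coding_calls(path: str | Path) -> dict[str, dict[str, str]]:
    """Read predictor calls TSV: transcript_id + one column per predictor."""
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c != "transcript_id"]
    out = {}
    for r in df.itertuples(index=False):
        out[str(r.transcript_id)] = {
            c: str(getattr(r, c)) for c in cols if pd.notna(getattr(r, c))
        }
    return out


def write_coding_calls(calls: dict[str, dict[str, str]], path: str | Path) -> None:
    predictors = sorted({p for d in calls.values() for p in d})
    rows = [
        {"transcript_id": tid, **{p: d.get(p, "") for p in predictors}}
        for tid, d in calls.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_lncrnas(lncs: list[LncRNA], path: str | Path, source: str = "epiflock") -> None:
    """GTF export of identified lncRNAs with a ``class`` attribute."""
    lines = []
    for l in sorted(lncs, key=lambda x: (x.transcript.chrom, x.transcript.start)):
        t = l.transcript
        attrs = (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'class "{l.lnc_class}";'
        )
        lines.append(
            f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}"
        )
        for e in t.exons:
            lines.append(
                f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
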