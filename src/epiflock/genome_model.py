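"""Shared genomic data model: coordinate conventions, interval indexing, and I/O.

All internal coordinates are 0-based half-open ``[start, end)``. Conversion to
and from 1-based inclusive coordinates happens only at the GTF boundary; BED
files are already 0-based half-open and pass through unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pyranges as pr
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")
TISSUES = ("muscle", "adipose")
TREATMENTS = ("control", "WEA")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval.

    Attributes
    ----------
    chrom : str
        Chromosome name, non-empty.
    start : int
        0-based inclusive start.
    end : int
        0-based exclusive end; must exceed ``start``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must be > start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the half-open ranges intersect on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Gene:
    """A gene locus with a biotype.

    The transcription start site (TSS) is strand-aware: ``interval.start`` on
    the plus strand, ``interval.end - 1`` on the minus strand. Unstranded
    genes fall back to ``interval.start`` with a warning.
    """

    gene_id: str
    interval: GenomicInterval
    biotype: str = "coding"  # {coding, lncRNA, other}

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        if self.interval.strand == ".":
            logger.warning("gene %s is unstranded; using interval.start as TSS", self.gene_id)
        return self.interval.start

    @property
    def tes(self) -> int:
        if self.interval.strand == "-":
            return self.interval.start
        return self.interval.end - 1


@dataclass(frozen=True)
class Transcript:
    """A transcript as an ordered list of disjoint exons on one chrom/strand."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"transcript {self.transcript_id}: exons span chrom/strands")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons unsorted or overlapping"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        """Summed exon length in bp (mature transcript length)."""
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class GenomeAnnotation:
    """Genes, transcripts and auxiliary interval tracks for one assembly."""

    genes: dict[str, Gene] = field(default_factory=dict)
    transcripts: dict[str, Transcript] = field(default_factory=dict)
    cgi_intervals: list[GenomicInterval] = field(default_factory=list)
    cgi_shore_intervals: list[GenomicInterval] = field(default_factory=list)
    repeat_intervals: list[GenomicInterval] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        for t in self.transcripts.values():
            if t.gene_id not in self.genes:
                raise ValueError(f"transcript {t.transcript_id}: unknown gene {t.gene_id}")
        if self.chrom_lengths:
            for g in self.genes.values():
                L = self.chrom_lengths.get(g.interval.chrom)
                if L is not None and g.interval.end > L:
                    raise ValueError(
                        f"gene {g.gene_id} extends past end of {g.interval.chrom}"
                    )

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]

    def coding_genes(self) -> list[Gene]:
        return [g for g in self.genes.values() if g.biotype == "coding"]

    def coding_exons(self) -> list[tuple[GenomicInterval, str]]:
        """All exons of transcripts belonging to coding genes, with gene id."""
        out = []
        for t in self.transcripts.values():
            g = self.genes.get(t.gene_id)
            if g is not None and g.biotype == "coding":
                out.extend((e, g.gene_id) for e in t.exons)
        return out


@dataclass(frozen=True)
class Sample:
    """One sequenced sample in the 2 tissue x 2 treatment x replicate design."""

    sample_id: str
    tissue: str
    treatment: str
    replicate: int

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")

    @property
    def group(self) -> str:
        return f"{self.tissue}_{self.treatment}"


@dataclass
class SampleDesign:
    """Ordered collection of samples; (tissue, treatment, replicate) unique."""

    samples: list[Sample]

    def __post_init__(self) -> None:
        keys = [(s.tissue, s.treatment, s.replicate) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (tissue, treatment, replicate) in design")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in design")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def select(self, tissue: str | None = None, treatment: str | None = None) -> list[Sample]:
        return [
            s
            for s in self.samples
            if (tissue is None or s.tissue == tissue)
            and (treatment is None or s.treatment == treatment)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "tissue": [s.tissue for s in self.samples],
                "treatment": [s.treatment for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleDesign":
        return cls(
            [
                Sample(str(r.sample_id), str(r.tissue), str(r.treatment), int(r.replicate))
                for r in df.itertuples()
            ]
        )


@dataclass
class ExpressionMatrix:
    """FPKM values, one row per feature and one column per sample."""

    values: pd.DataFrame  # index: feature_id, columns: sample_id
    design: SampleDesign

    def __post_init__(self) -> None:
        if list(self.values.columns) != self.design.sample_ids:
            raise ValueError("expression columns do not match sample design order")
        arr = self.values.to_numpy()
        import numpy as np

        if not np.all(np.isfinite(arr)) or (arr < 0).any():
            raise ValueError("FPKM values must be finite and non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def subset(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids)], self.design)


# ---------------------------------------------------------------------------
# Promoters and flanks


def promoter_of(
    gene: Gene,
    upstream_bp: int = 2000,
    chrom_lengths: dict[str, int] | None = None,
) -> GenomicInterval | None:
    """Strand-aware promoter: up to ``upstream_bp`` immediately 5' of the TSS.

    Clipped at position 0 and, when ``chrom_lengths`` is given, at the
    chromosome end. Returns ``None`` in the degenerate case where no upstream
    base exists (TSS flush against the chrom edge).
    """
    iv = gene.interval
    if iv.strand == "-":
        start = iv.end  # first base past the TSS on the genomic axis
        end = iv.end + upstream_bp
        if chrom_lengths and iv.chrom in chrom_lengths:
            end = min(end, chrom_lengths[iv.chrom])
    else:
        start = max(0, iv.start - upstream_bp)
        end = iv.start
    if end <= start:
        return None
    return GenomicInterval(iv.chrom, start, end, iv.strand)


def clip_to_chrom(iv: GenomicInterval, chrom_lengths: dict[str, int]) -> GenomicInterval | None:
    """Clip an interval to chromosome bounds; None if nothing remains."""
    L = chrom_lengths.get(iv.chrom)
    if L is None:
        return iv
    start, end = max(0, iv.start), min(L, iv.end)
    if end <= start:
        return None
    return GenomicInterval(iv.chrom, start, end, iv.strand)


def cgi_shores(
    cgis: Sequence[GenomicInterval],
    shore_bp: int = 2000,
    chrom_lengths: dict[str, int] | None = None,
) -> list[GenomicInterval]:
    """Derive CGI shores as ``shore_bp`` flanks of CGIs minus the CGIs themselves."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for c in cgis:
        by_chrom.setdefault(c.chrom, []).append(c)
    shores: list[GenomicInterval] = []
    for chrom, ivs in by_chrom.items():
        tree = IntervalTree()
        for c in ivs:
            tree[c.start : c.end] = True
        for c in ivs:
            for s, e in ((c.start - shore_bp, c.start), (c.end, c.end + shore_bp)):
                s = max(0, s)
                if chrom_lengths and chrom in chrom_lengths:
                    e = min(chrom_lengths[chrom], e)
                if e <= s:
                    continue
                # subtract any overlapping CGI
                pieces = [(s, e)]
                for hit in sorted(tree[s:e]):
                    pieces = _subtract(pieces, hit.begin, hit.end)
                shores.extend(GenomicInterval(chrom, a, b) for a, b in pieces)
    return sorted(set(shores))


def _subtract(pieces: list[tuple[int, int]], hs: int, he: int) -> list[tuple[int, int]]:
    out = []
    for a, b in pieces:
        if he <= a or hs >= b:
            out.append((a, b))
            continue
        if a < hs:
            out.append((a, hs))
        if he < b:
            out.append((he, b))
    return out


# ---------------------------------------------------------------------------
# Interval index


class IntervalIndex:
    """Per-chromosome interval tree over arbitrary payloads.

    Query semantics are half-open: ``[0, 100)`` and ``[100, 200)`` do not
    overlap each other.
    """

    def __init__(self, items: Iterable[tuple[GenomicInterval, object]] = ()):
        self._trees: dict[str, IntervalTree] = {}
        for iv, payload in items:
            self.add(iv, payload)

    def add(self, iv: GenomicInterval, payload: object) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree())[iv.start : iv.end] = (iv, payload)

    def query(self, iv: GenomicInterval) -> list[tuple[GenomicInterval, object]]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        hits = tree[iv.start : iv.end]
        return sorted((h.data for h in hits), key=lambda x: (x[0].start, x[0].end))

    def any_overlap(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.chrom)
        return bool(tree is not None and tree.overlaps(iv.start, iv.end))


def build_interval_index(
    intervals: Iterable[GenomicInterval | tuple[GenomicInterval, object]],
) -> IntervalIndex:
    """Build an IntervalIndex; bare intervals are stored as their own payload."""
    idx = IntervalIndex()
    for item in intervals:
        if isinstance(item, GenomicInterval):
            idx.add(item, item)
        else:
            iv, payload = item
            idx.add(iv, payload)
    return idx


# ---------------------------------------------------------------------------
# GTF / BED / TSV I/O


def read_annotation(
    gtf_path: str | Path,
    cgi_bed: str | Path | None = None,
    repeat_bed: str | Path | None = None,
    chrom_lengths: dict[str, int] | None = None,
    shore_bp: int = 2000,
) -> GenomeAnnotation:
    """Read a GTF plus optional CGI/repeat BED tracks into a GenomeAnnotation.

    GTF coordinates (1-based inclusive) are converted to the internal 0-based
    half-open convention. Gene records are taken from ``gene`` feature lines
    when present, otherwise inferred as the span of each gene's exons.
    A ``biotype`` (or ``gene_biotype``) attribute is honoured; absent, genes
    default to ``coding``.
    """
    gtf_path = Path(gtf_path)
    df = pr.read_gtf(str(gtf_path)).df
    if df.empty:
        raise ValueError(f"{gtf_path}: no GTF records")

    ann = GenomeAnnotation(chrom_lengths=dict(chrom_lengths or {}))

    biotype_col = next(
        (c for c in ("biotype", "gene_biotype", "gene_type") if c in df.columns), None
    )

    gene_rows = df[df.Feature == "gene"]
    for r in gene_rows.itertuples():
        biotype = getattr(r, biotype_col) if biotype_col else "coding"
        if not isinstance(biotype, str):
            biotype = "coding"
        ann.genes[r.gene_id] = Gene(
            r.gene_id,
            GenomicInterval(str(r.Chromosome), int(r.Start), int(r.End), str(r.Strand)),
            biotype,
        )

    exon_rows = df[df.Feature == "exon"]
    if "transcript_id" not in exon_rows.columns:
        raise ValueError(f"{gtf_path}: exon records lack transcript_id")
    for tid, sub in exon_rows.groupby("transcript_id", sort=False):
        sub = sub.sort_values("Start")
        exons = tuple(
            GenomicInterval(str(r.Chromosome), int(r.Start), int(r.End), str(r.Strand))
            for r in sub.itertuples()
        )
        gene_id = str(sub.gene_id.iloc[0])
        ann.transcripts[str(tid)] = Transcript(str(tid), gene_id, exons)

    # infer missing gene records from transcript spans
    for t in ann.transcripts.values():
        if t.gene_id not in ann.genes:
            ann.genes[t.gene_id] = Gene(t.gene_id, t.span, "coding")

    if cgi_bed is not None:
        ann.cgi_intervals = read_bed(cgi_bed)
        ann.cgi_shore_intervals = cgi_shores(ann.cgi_intervals, shore_bp, ann.chrom_lengths)
    if repeat_bed is not None:
        ann.repeat_intervals = read_bed(repeat_bed)

    ann.validate()
    return ann


def write_annotation(ann: GenomeAnnotation, gtf_path: str | Path, source: str = "epiflock") -> None:
    """Write genes/transcripts/exons as GTF (1-based inclusive on disk)."""
    lines = []
    for g in sorted(ann.genes.values(), key=lambda g: (g.interval.chrom, g.interval.start)):
        iv = g.interval
        attrs = f'gene_id "{g.gene_id}"; biotype "{g.biotype}";'
        lines.append(
            f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}"
        )
        for t in sorted(ann.transcripts_of(g.gene_id), key=lambda t: t.transcript_id):
            tattrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
            lines.append(
                f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{tattrs}"
            )
            for e in t.exons:
                lines.append(
                    f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t{tattrs}"
                )
    Path(gtf_path).write_text("\n".join(lines) + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 (0-based half-open; strand from column 6 when present)."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        f = line.split("\t")
        if len(f) < 3:
            raise ValueError(f"{path}:{ln}: BED line has fewer than 3 fields")
        strand = f[5] if len(f) >= 6 and f[5] in STRANDS else "."
        out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path, names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_expression(
    expr_tsv: str | Path, design_tsv: str | Path
) -> ExpressionMatrix:
    """Read an expression TSV (feature_id + sample columns) and a design TSV."""
    design = SampleDesign.from_frame(pd.read_csv(design_tsv, sep="\t"))
    values = pd.read_csv(expr_tsv, sep="\t", index_col="feature_id")
    values = values[design.sample_ids]
    return ExpressionMatrix(values, design)


def write_expression(expr: ExpressionMatrix, expr_tsv: str | Path, design_tsv: str | Path) -> None:
    expr.values.rename_axis("feature_id").to_csv(expr_tsv, sep="\t")
    expr.design.to_frame().to_csv(design_tsv, sep="\t", index=False)
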