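"""Bisulfite methylation analysis.

Per-cytosine methylation levels from methylated/unmethylated read counts, a
non-conversion correction estimated from an unmethylated lambda-phage
spike-in, binomial site calling, windowed and per-feature profiles, a
Fisher-exact differentially-methylated-region (DMR) caller, and DMR-to-gene
mapping.

The methylation level at a cytosine (or pooled over a window/region) is

    ML = m / (m + u)

where ``m`` and ``u`` are methylated and unmethylated read counts. Incomplete
bisulfite conversion at rate ``r`` (estimated from the fully unmethylated
lambda spike-in) inflates apparent methylation; the corrected level is

    ML_corrected = (ML - r) / (1 - r)

clamped into [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_model import (
    GenomeAnnotation,
    GenomicInterval,
    IntervalIndex,
    build_interval_index,
    clip_to_chrom,
    promoter_of,
)

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "context", "m", "u"]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def validate_cytosine_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a per-cytosine count table and return it with canonical dtypes."""
    missing = [c for c in CYTOSINE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cytosine table missing columns: {missing}")
    df = df.copy()
    df["m"] = df["m"].astype(np.int64)
    df["u"] = df["u"].astype(np.int64)
    if (df["m"] < 0).any() or (df["u"] < 0).any():
        raise ValueError("negative read counts in cytosine table")
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        raise ValueError(f"unknown contexts: {sorted(df.loc[bad, 'context'].unique())}")
    return df


def read_cytosine_table(path) -> pd.DataFrame:
    """Read a cytosine count TSV.

    Accepts either the native header (chrom, pos, strand, context, m, u) or
    headerless Bismark-style cytosine reports
    (chrom, 1-based pos, strand, count_methylated, count_unmethylated,
    context, trinucleotide) which are converted to 0-based positions.
    """
    first = open(path).readline().rstrip("\n").split("\t")
    if "chrom" in first and "context" in first:
        return validate_cytosine_table(pd.read_csv(path, sep="\t"))
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] < 6:
        raise ValueError(f"{path}: unrecognised cytosine table layout")
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "pos": df[1].astype(np.int64) - 1,
            "strand": df[2].astype(str),
            "context": df[5].astype(str).str.replace("CpG", "CG"),
            "m": df[3].astype(np.int64),
            "u": df[4].astype(np.int64),
        }
    )
    return validate_cytosine_table(out)


def write_cytosine_table(df: pd.DataFrame, path) -> None:
    df[CYTOSINE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Context calling


def call_context(refseq: str, pos: int, strand: str = "+") -> str:
    """Classify the cytosine at ``pos`` as CG, CHG or CHH (H = A, C or T).

    On the minus strand the context is read 5'->3' on the reverse complement,
    i.e. leftwards along the given sequence.
    """
    seq = refseq.upper()
    if strand == "-":
        if seq[pos] != "G":
            raise ValueError(f"position {pos} is not a C on the - strand (ref base {seq[pos]!r})")
        nxt = _COMPLEMENT.get(seq[pos - 1], "N") if pos >= 1 else "N"
        nxt2 = _COMPLEMENT.get(seq[pos - 2], "N") if pos >= 2 else "N"
    else:
        if seq[pos] != "C":
            raise ValueError(f"position {pos} is not a C on the + strand (got {seq[pos]!r})")
        nxt = seq[pos + 1] if pos + 1 < len(seq) else "N"
        nxt2 = seq[pos + 2] if pos + 2 < len(seq) else "N"
    if nxt == "G":
        return "CG"
    if nxt in "ACT" and nxt2 == "G":
        return "CHG"
    return "CHH"


def cytosine_positions(refseq: str, chrom: str) -> pd.DataFrame:
    """All cytosines (both strands) in a sequence with their contexts.

    Vectorized equivalent of calling :func:`call_context` at every C;
    terminal positions whose context window runs off the sequence end are
    skipped.
    """
    seq = refseq.upper()
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    C, G = ord("C"), ord("G")

    plus = np.flatnonzero(arr == C)
    plus = plus[plus + 1 < n]
    nxt = arr[plus + 1]
    nxt2 = np.where(plus + 2 < n, arr[np.minimum(plus + 2, n - 1)], 0)
    ctx_plus = np.where(nxt == G, "CG", np.where(nxt2 == G, "CHG", "CHH"))

    minus = np.flatnonzero(arr == G)
    minus = minus[minus >= 1]
    prv = arr[minus - 1]  # complement(prev) == G iff prev == C
    prv2 = np.where(minus >= 2, arr[np.maximum(minus - 2, 0)], 0)
    ctx_minus = np.where(prv == C, "CG", np.where(prv2 == C, "CHG", "CHH"))

    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.concatenate([plus, minus]),
            "strand": np.concatenate([np.repeat("+", len(plus)), np.repeat("-", len(minus))]),
            "context": np.concatenate([ctx_plus, ctx_minus]),
        }
    )
    return df.sort_values(["pos", "strand"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Levels and non-conversion correction


def methylation_level(m, u):
    """ML = m / (m + u); scalar or elementwise. Zero-coverage input is an error."""
    m = np.asarray(m, dtype=float)
    u = np.asarray(u, dtype=float)
    total = m + u
    if np.any(total <= 0):
        raise ValueError("methylation level undefined at zero coverage")
    out = m / total
    return float(out) if out.ndim == 0 else out


def correct_ml(ml, r: float):
    """Non-conversion-corrected level (ml - r) / (1 - r), clamped to [0, 1]."""
    if not 0 <= r < 1:
        raise ValueError(f"non-conversion rate must be in [0, 1), got {r}")
    ml = np.asarray(ml, dtype=float)
    out = np.clip((ml - r) / (1.0 - r), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def non_conversion_rate(lambda_records: pd.DataFrame) -> float:
    """Pooled methylated fraction over the unmethylated spike-in cytosines.

    Because the lambda spike-in is fully unmethylated, any read reporting a
    retained cytosine reflects failed bisulfite conversion, so the pooled
    fraction estimates the non-conversion rate r.
    """
    total = int(lambda_records["m"].sum() + lambda_records["u"].sum())
    if total == 0:
        raise ValueError("no coverage on spike-in cytosines; cannot estimate r")
    return float(lambda_records["m"].sum() / total)


def split_spikein(
    records: pd.DataFrame, spikein_chrom: str = "lambda"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cytosine table into (genomic, spike-in) parts."""
    mask = records["chrom"] == spikein_chrom
    return records[~mask].reset_index(drop=True), records[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Site calling


def call_methylated_sites(
    records: pd.DataFrame, r: float, alpha: float = 0.05
) -> pd.DataFrame:
    """Flag sites whose methylated-count excess is inconsistent with noise.

    Per site, a one-sided binomial test of H0: p = r against p > r, where r
    is the non-conversion rate; p-values are BH-adjusted within each context
    and sites with adjusted p < alpha are flagged ``methylated``.

    Zero-coverage rows are dropped (with a logged count).
    """
    records = validate_cytosine_table(records)
    cov = records["m"] + records["u"]
    n_dropped = int((cov == 0).sum())
    if n_dropped:
        logger.info("dropping %d zero-coverage sites", n_dropped)
    df = records[cov > 0].copy()
    n = (df["m"] + df["u"]).to_numpy()
    m = df["m"].to_numpy()
    # P(X >= m) under Binomial(n, r)
    df["p"] = stats.binom.sf(m - 1, n, r)
    df["p_adj"] = np.nan
    for ctx, idx in df.groupby("context").groups.items():
        df.loc[idx, "p_adj"] = multipletests(df.loc[idx, "p"], method="fdr_bh")[1]
    df["methylated"] = df["p_adj"] < alpha
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Windowed and per-feature profiles


def bin_levels(records: pd.DataFrame, r: float = 0.0, bin_bp: int = 10_000) -> pd.DataFrame:
    """Pooled-count methylation level per (chrom, bin, context).

    Counts are summed within each fixed-width window, the level is the pooled
    fraction, and the non-conversion correction is applied to the pooled
    level. Windows with no covered cytosine are omitted.
    """
    records = validate_cytosine_table(records)
    df = records[(records["m"] + records["u"]) > 0].copy()
    if df.empty:
        return pd.DataFrame(columns=["chrom", "bin_start", "bin_end", "context", "n_sites", "ml", "ml_corrected"])
    df["bin_start"] = (df["pos"] // bin_bp) * bin_bp
    g = df.groupby(["chrom", "bin_start", "context"], sort=True).agg(
        m=("m", "sum"), u=("u", "sum"), n_sites=("pos", "size")
    )
    g = g.reset_index()
    g["bin_end"] = g["bin_start"] + bin_bp
    g["ml"] = g["m"] / (g["m"] + g["u"])
    g["ml_corrected"] = correct_ml(g["ml"].to_numpy(), r)
    return g[["chrom", "bin_start", "bin_end", "context", "n_sites", "ml", "ml_corrected"]]


REGION_CLASSES = ("CGI", "CGI_shore", "promoter", "utr5", "exon", "intron", "utr3", "repeat")


def _region_tracks(ann: GenomeAnnotation, promoter_bp: int = 2000) -> dict[str, list[GenomicInterval]]:
    """Derive the standard region classes from an annotation.

    Without explicit UTR records, the first and last 200 bp of each coding
    transcript's mature sequence stand in for the 5' and 3' UTRs; introns are
    the gaps between consecutive exons.
    """
    tracks: dict[str, list[GenomicInterval]] = {
        "CGI": list(ann.cgi_intervals),
        "CGI_shore": list(ann.cgi_shore_intervals),
        "repeat": list(ann.repeat_intervals),
        "promoter": [],
        "utr5": [],
        "exon": [],
        "intron": [],
        "utr3": [],
    }
    for g in ann.coding_genes():
        p = promoter_of(g, promoter_bp, ann.chrom_lengths)
        if p is not None:
            tracks["promoter"].append(p)
    utr_bp = 200
    for t in ann.transcripts.values():
        g = ann.genes.get(t.gene_id)
        if g is None or g.biotype != "coding":
            continue
        tracks["exon"].extend(t.exons)
        for a, b in zip(t.exons, t.exons[1:]):
            if b.start > a.end:
                tracks["intron"].append(GenomicInterval(t.chrom, a.end, b.start, t.strand))
        five = (t.start, min(t.start + utr_bp, t.end))
        three = (max(t.end - utr_bp, t.start), t.end)
        if t.strand == "-":
            five, three = three, five
        tracks["utr5"].append(GenomicInterval(t.chrom, five[0], five[1], t.strand))
        tracks["utr3"].append(GenomicInterval(t.chrom, three[0], three[1], t.strand))
    return tracks


def feature_profile(
    records: pd.DataFrame,
    ann: GenomeAnnotation,
    r: float = 0.0,
    promoter_bp: int = 2000,
) -> pd.DataFrame:
    """Pooled methylation level per region class and context.

    Region classes: CGI, CGI shore, promoter, 5'UTR, exon, intron, 3'UTR and
    repeat. Classes with no covered cytosine in a context are reported with
    NaN level.
    """
    records = validate_cytosine_table(records)
    df = records[(records["m"] + records["u"]) > 0]
    tracks = _region_tracks(ann, promoter_bp)
    rows = []
    for cls in REGION_CLASSES:
        key = cls.replace(" ", "_")
        ivs = tracks.get(key, [])
        idx = build_interval_index(ivs)
        if ivs:
            chroms = {iv.chrom for iv in ivs}
            sub = df[df["chrom"].isin(chroms)]
            in_region = sub.apply(
                lambda row: idx.any_overlap(
                    GenomicInterval(row["chrom"], int(row["pos"]), int(row["pos"]) + 1)
                ),
                axis=1,
            ) if not sub.empty else pd.Series(dtype=bool)
            sel = sub[in_region] if not sub.empty else sub
        else:
            sel = df.iloc[0:0]
        for ctx in CONTEXTS:
            c = sel[sel["context"] == ctx]
            m, u = int(c["m"].sum()), int(c["u"].sum())
            if m + u == 0:
                rows.append((cls, ctx, 0, np.nan, np.nan))
            else:
                ml = m / (m + u)
                rows.append((cls, ctx, len(c), ml, float(correct_ml(ml, r))))
    return pd.DataFrame(rows, columns=["region", "context", "n_sites", "ml", "ml_corrected"])


def metagene_profile(
    records: pd.DataFrame,
    ann: GenomeAnnotation,
    flank_bp: int = 2000,
    n_body_bins: int = 20,
    n_flank_bins: int = 10,
    r: float = 0.0,
) -> pd.DataFrame:
    """Meta-gene methylation profile over upstream 2 kb, gene body, downstream 2 kb.

    The gene body is scaled into ``n_body_bins`` relative bins; each flank is
    divided into fixed-width bins. Counts are pooled over genes per bin.
    """
    records = validate_cytosine_table(records)
    df = records[(records["m"] + records["u"]) > 0]
    segments = []  # (segment, bin, chrom, start, end)
    for g in ann.coding_genes():
        iv = g.interval
        body_len = len(iv)
        for b in range(n_body_bins):
            s = iv.start + (body_len * b) // n_body_bins
            e = iv.start + (body_len * (b + 1)) // n_body_bins
            if e > s:
                segments.append(("body", b, iv.chrom, s, e))
        step = flank_bp // n_flank_bins
        for b in range(n_flank_bins):
            up = (iv.start - flank_bp + b * step, iv.start - flank_bp + (b + 1) * step)
            dn = (iv.end + b * step, iv.end + (b + 1) * step)
            if iv.strand == "-":
                # upstream is 3'-ward on the genomic axis; reverse bin order
                up = (iv.end + (n_flank_bins - 1 - b) * step, iv.end + (n_flank_bins - b) * step)
                dn = (iv.start - flank_bp + (n_flank_bins - 1 - b) * step,
                      iv.start - flank_bp + (n_flank_bins - b) * step)
            for name, (s, e) in (("upstream", up), ("downstream", dn)):
                s = max(0, s)
                if e > s:
                    segments.append((name, b, iv.chrom, s, e))
    rows = []
    by_chrom = {c: sub.sort_values("pos") for c, sub in df.groupby("chrom")}
    agg: dict[tuple[str, int, str], list[int]] = {}
    for seg, b, chrom, s, e in segments:
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        lo = sub["pos"].searchsorted(s, "left")
        hi = sub["pos"].searchsorted(e, "left")
        sel = sub.iloc[lo:hi]
        for ctx, c in sel.groupby("context"):
            key = (seg, b, ctx)
            cur = agg.setdefault(key, [0, 0])
            cur[0] += int(c["m"].sum())
            cur[1] += int(c["u"].sum())
    for (seg, b, ctx), (m, u) in sorted(agg.items()):
        ml = m / (m + u)
        rows.append((seg, b, ctx, ml, float(correct_ml(ml, r))))
    return pd.DataFrame(rows, columns=["segment", "bin", "context", "ml", "ml_corrected"])


# ---------------------------------------------------------------------------
# DMR calling


def fisher_exact_two_sided(ma, ua, mb, ub, chunk: int = 20_000) -> np.ndarray:
    """Vectorized two-sided Fisher exact test on 2x2 tables [[ma, ua], [mb, ub]].

    Uses the conditional hypergeometric distribution and the
    minimum-likelihood two-sided rule (sum of all outcome probabilities not
    exceeding the observed one), the same definition scipy's
    ``fisher_exact`` implements.
    """
    ma = np.asarray(ma, dtype=np.int64)
    ua = np.asarray(ua, dtype=np.int64)
    mb = np.asarray(mb, dtype=np.int64)
    ub = np.asarray(ub, dtype=np.int64)
    n_a = ma + ua
    K = ma + mb
    N = n_a + mb + ub
    out = np.empty(len(ma))
    for lo in range(0, len(ma), chunk):
        hi = min(lo + chunk, len(ma))
        out[lo:hi] = _fisher_chunk(ma[lo:hi], n_a[lo:hi], K[lo:hi], N[lo:hi])
    return out


def _fisher_chunk(m_obs, n_a, K, N) -> np.ndarray:
    x_min = np.maximum(0, K - (N - n_a))
    x_max = np.minimum(K, n_a)
    width = int((x_max - x_min).max()) + 1
    x = x_min[:, None] + np.arange(width)[None, :]
    valid = x <= x_max[:, None]
    xc = np.minimum(x, x_max[:, None])
    pmf = stats.hypergeom.pmf(xc, N[:, None], K[:, None], n_a[:, None])
    pmf = np.where(valid, pmf, np.inf)  # padding never counted
    p_obs = stats.hypergeom.pmf(m_obs, N, K, n_a)
    take = pmf <= p_obs[:, None] * (1 + 1e-7)
    return np.minimum(np.where(take, pmf, 0.0).sum(axis=1), 1.0)


@dataclass(frozen=True)
class DMR:
    """A differentially methylated region between two sample groups.

    ``direction`` is the state of group B relative to group A: ``hyper`` if
    the pooled level in B exceeds A within the region, else ``hypo``.
    """

    interval: GenomicInterval
    context: str
    ml_a: float
    ml_b: float
    direction: str  # {hyper, hypo}
    n_sites: int
    p_adj: float

    def __post_init__(self) -> None:
        expected = "hyper" if self.ml_b > self.ml_a else "hypo"
        if self.direction != expected:
            raise ValueError("DMR direction inconsistent with group levels")


@dataclass
class DMRParams:
    """Tuning knobs for the Fisher-exact DMR caller."""

    min_sites: int = 3
    min_len: int = 1
    max_gap: int = 200
    alpha: float = 0.05
    min_delta: float = 0.1


def pool_counts(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum m/u counts across samples at identical (chrom, pos, strand, context)."""
    cat = pd.concat([validate_cytosine_table(t) for t in tables], ignore_index=True)
    g = cat.groupby(["chrom", "pos", "strand", "context"], as_index=False, sort=True).agg(
        m=("m", "sum"), u=("u", "sum")
    )
    return g[CYTOSINE_COLUMNS]


def call_dmrs(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    params: DMRParams | None = None,
) -> list[DMR]:
    """Call DMRs from pooled per-cytosine counts of two groups.

    Per shared site, a two-sided Fisher exact test compares the pooled
    (m, u) counts of the two groups; p-values are BH-adjusted within context.
    Consecutive significant sites with a consistent sign of the level
    difference and gaps <= ``max_gap`` bp are merged; merged runs must have at
    least ``min_sites`` sites, span at least ``min_len`` bp, and show a pooled
    level difference of at least ``min_delta`` in absolute value.
    """
    params = params or DMRParams()
    a = validate_cytosine_table(group_a)
    b = validate_cytosine_table(group_b)
    for name, t in (("A", a), ("B", b)):
        if t.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError(f"group {name} has duplicate cytosine positions; pool counts first")
    merged = a.merge(
        b,
        on=["chrom", "pos", "strand", "context"],
        suffixes=("_a", "_b"),
        how="inner",
    )
    cov = (merged["m_a"] + merged["u_a"] > 0) & (merged["m_b"] + merged["u_b"] > 0)
    merged = merged[cov].sort_values(["chrom", "pos"]).reset_index(drop=True)
    if merged.empty:
        return []

    ma = merged["m_a"].to_numpy()
    ua = merged["u_a"].to_numpy()
    mb = merged["m_b"].to_numpy()
    ub = merged["u_b"].to_numpy()
    merged["p"] = fisher_exact_two_sided(ma, ua, mb, ub)
    merged["p_adj"] = np.nan
    for ctx, idx in merged.groupby("context").groups.items():
        merged.loc[idx, "p_adj"] = multipletests(merged.loc[idx, "p"], method="fdr_bh")[1]
    merged["ml_a"] = ma / (ma + ua)
    merged["ml_b"] = mb / (mb + ub)
    merged["sig"] = merged["p_adj"] < params.alpha
    merged["sign"] = np.sign(merged["ml_b"] - merged["ml_a"])

    dmrs: list[DMR] = []
    for (chrom, ctx), sub in merged.groupby(["chrom", "context"], sort=True):
        sub = sub[sub["sig"] & (sub["sign"] != 0)]
        if sub.empty:
            continue
        run: list[pd.Series] = []
        for _, row in sub.iterrows():
            if run and (
                row["pos"] - run[-1]["pos"] > params.max_gap
                or row["sign"] != run[-1]["sign"]
            ):
                d = _finalize_run(run, chrom, ctx, params)
                if d is not None:
                    dmrs.append(d)
                run = []
            run.append(row)
        d = _finalize_run(run, chrom, ctx, params)
        if d is not None:
            dmrs.append(d)
    return sorted(dmrs, key=lambda d: (d.interval.chrom, d.interval.start, d.context))


def _finalize_run(run: list[pd.Series], chrom: str, ctx: str, params: DMRParams) -> DMR | None:
    if len(run) < params.min_sites:
        return None
    start = int(run[0]["pos"])
    end = int(run[-1]["pos"]) + 1
    if end - start < params.min_len:
        return None
    m_a = sum(int(r["m_a"]) for r in run)
    u_a = sum(int(r["u_a"]) for r in run)
    m_b = sum(int(r["m_b"]) for r in run)
    u_b = sum(int(r["u_b"]) for r in run)
    ml_a = m_a / (m_a + u_a)
    ml_b = m_b / (m_b + u_b)
    if abs(ml_b - ml_a) < params.min_delta:
        return None
    return DMR(
        interval=GenomicInterval(chrom, start, end),
        context=ctx,
        ml_a=ml_a,
        ml_b=ml_b,
        direction="hyper" if ml_b > ml_a else "hypo",
        n_sites=len(run),
        p_adj=float(min(r["p_adj"] for r in run)),
    )


def write_dmrs(dmrs: list[DMR], path) -> None:
    """BED6+ export: name=context, score=-log10 adjusted p, then levels."""
    with open(path, "w") as fh:
        for d in dmrs:
            score = -np.log10(max(d.p_adj, 1e-300))
            fh.write(
                f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}\t{d.context}"
                f"\t{score:.3f}\t.\t{d.ml_a:.4f}\t{d.ml_b:.4f}\t{d.direction}\t{d.n_sites}\n"
            )


def read_dmrs(path) -> list[DMR]:
    out = []
    for line in open(path):
        f = line.rstrip("\n").split("\t")
        out.append(
            DMR(
                GenomicInterval(f[0], int(f[1]), int(f[2])),
                f[3],
                float(f[6]),
                float(f[7]),
                f[8],
                int(f[9]),
                10 ** (-float(f[4])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# DMR-gene mapping


@dataclass(frozen=True)
class DMRGene:
    """A gene whose body or promoter overlaps at least one DMR."""

    gene_id: str
    dmrs: tuple[DMR, ...]
    location: str  # {body, promoter, both}


def map_dmr_genes(
    dmrs: list[DMR],
    ann: GenomeAnnotation,
    promoter_bp: int = 2000,
) -> list[DMRGene]:
    """Genes with >= 1 bp overlap between any DMR and the gene body or promoter.

    The gene body spans TSS to TES (the full gene interval); the promoter is
    the ``promoter_bp`` region immediately upstream of the TSS.
    """
    dmr_idx = build_interval_index((d.interval, d) for d in dmrs)
    out = []
    for g in sorted(ann.genes.values(), key=lambda g: g.gene_id):
        body_hits = {id(p): p for _, p in dmr_idx.query(g.interval)}
        prom = promoter_of(g, promoter_bp, ann.chrom_lengths)
        prom_hits = {id(p): p for _, p in dmr_idx.query(prom)} if prom else {}
        if not body_hits and not prom_hits:
            continue
        if body_hits and prom_hits:
            loc = "both"
        elif body_hits:
            loc = "body"
        else:
            loc = "promoter"
        all_hits = {**body_hits, **prom_hits}
        hits = tuple(sorted(all_hits.values(), key=lambda d: (d.interval.start, d.context)))
        out.append(DMRGene(g.gene_id, hits, loc))
    return out


def write_dmr_genes(dmr_genes: list[DMRGene], path) -> None:
    rows = []
    for dg in dmr_genes:
        dirs = sorted({d.direction for d in dg.dmrs})
        rows.append(
            {
                "gene_id": dg.gene_id,
                "n_dmrs": len(dg.dmrs),
                "location": dg.location,
                "directions": ",".join(dirs),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
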