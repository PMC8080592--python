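"""Differential expression and lncRNA target prediction.

Targets of a lncRNA are genes satisfying either of two criteria: co-location
(gene span within 100 kb up- or downstream of the lncRNA) or co-expression
(|Pearson correlation| > 0.95 with BH-adjusted p < 0.05 across samples).

Differential expression here is a Welch t-test on log2(FPKM + 1) between
groups with BH adjustment; externally computed DE tables in the same shape
can be supplied instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_model import ExpressionMatrix, GenomicInterval, build_interval_index

logger = logging.getLogger(__name__)

CONTRASTS = {
    # label: ((tissue, treatment) for group A, group B)
    "BM-BF": (("muscle", "control"), ("adipose", "control")),
    "NM-NF": (("muscle", "WEA"), ("adipose", "WEA")),
    "NM-BM": (("muscle", "WEA"), ("muscle", "control")),
    "NF-BF": (("adipose", "WEA"), ("adipose", "control")),
}


@dataclass(frozen=True)
class DiffExprResult:
    feature_id: str
    log2fc: float
    p: float
    p_adj: float
    significant: bool
    contrast: str

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else "down"


@dataclass(frozen=True)
class TargetPair:
    """One lncRNA-gene target relation with its supporting evidence."""

    lnc_id: str
    gene_id: str
    evidence: str  # {colocation, coexpression, both}
    distance: int | None = None
    pcc: float | None = None
    p_adj: float | None = None

    def __post_init__(self) -> None:
        if self.evidence not in ("colocation", "coexpression", "both"):
            raise ValueError(f"bad evidence {self.evidence!r}")
        if self.pcc is not None and abs(self.pcc) > 1 + 1e-12:
            raise ValueError("|PCC| cannot exceed 1")


# ---------------------------------------------------------------------------
# Differential expression


def diff_expression(
    expr: ExpressionMatrix,
    contrast: str,
    alpha: float = 0.05,
) -> list[DiffExprResult]:
    """Welch t-test on log2(FPKM + 1) per feature between the contrast groups.

    ``log2fc`` is the difference of group means on the log2(FPKM + 1) scale,
    group A minus group B. Features with BH-adjusted p < alpha are flagged.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; choose from {sorted(CONTRASTS)}")
    (ta, tra), (tb, trb) = CONTRASTS[contrast]
    a_ids = [s.sample_id for s in expr.design.select(ta, tra)]
    b_ids = [s.sample_id for s in expr.design.select(tb, trb)]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError(f"contrast {contrast}: each group needs >= 2 replicates")
    log_a = np.log2(expr.values[a_ids].to_numpy() + 1.0)
    log_b = np.log2(expr.values[b_ids].to_numpy() + 1.0)
    t, p = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance-in-both features
    p_adj = multipletests(p, method="fdr_bh")[1]
    log2fc = log_a.mean(axis=1) - log_b.mean(axis=1)
    return [
        DiffExprResult(fid, float(fc), float(pv), float(pa), bool(pa < alpha), contrast)
        for fid, fc, pv, pa in zip(expr.feature_ids, log2fc, p, p_adj)
    ]


def de_table(results: list[DiffExprResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "log2fc": [r.log2fc for r in results],
            "p": [r.p for r in results],
            "p_adj": [r.p_adj for r in results],
            "significant": [r.significant for r in results],
            "direction": [r.direction for r in results],
            "contrast": [r.contrast for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Co-location


def colocation_targets(
    lncrnas: dict[str, GenomicInterval],
    genes: dict[str, GenomicInterval],
    window_bp: int = 100_000,
) -> list[TargetPair]:
    """Pair each lncRNA with genes within ``window_bp`` up- or downstream.

    A gene qualifies if any part of its span intersects
    ``[lnc.start - window_bp, lnc.end + window_bp)`` on the same chromosome,
    regardless of strand. ``distance`` is 0 for overlapping pairs, otherwise
    the gap in bp.
    """
    gene_idx = build_interval_index((iv, gid) for gid, iv in genes.items())
    pairs = []
    for lid in sorted(lncrnas):
        liv = lncrnas[lid]
        window = GenomicInterval(
            liv.chrom, max(0, liv.start - window_bp), liv.end + window_bp
        )
        for giv, gid in gene_idx.query(window):
            if giv.start >= liv.end:
                dist = giv.start - liv.end
            elif giv.end <= liv.start:
                dist = liv.start - giv.end
            else:
                dist = 0
            pairs.append(TargetPair(lid, gid, "colocation", distance=dist))
    return pairs


# ---------------------------------------------------------------------------
# Co-expression


def pearson_test(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p-value.

    p is computed from t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of
    freedom; |r| = 1 yields p = 0. Constant input is an error (callers skip
    and log such pairs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n or n < 3:
        raise ValueError("pearson_test needs equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson_test undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def coexpression_targets(
    lnc_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    pcc_min: float = 0.95,
    alpha: float = 0.05,
    log2_transform: bool = True,
) -> list[TargetPair]:
    """All lncRNA x gene pairs with |PCC| > ``pcc_min`` and BH-adjusted p < alpha.

    Correlation is computed on log2(FPKM + 1) by default: FPKM is roughly
    log-normal, and on the raw scale strong negative correlations are
    mathematically unattainable (the Pearson correlation of two log-normals
    is bounded well above -1), so raw-scale screening at a +/-0.95 threshold
    would be blind to negative co-expression. Set ``log2_transform=False``
    to correlate raw values.

    The BH family is every tested pair (constant features are dropped with a
    logged count and never enter the family). The PCC threshold is strict.
    """
    if lnc_expr.design.sample_ids != gene_expr.design.sample_ids:
        raise ValueError("lncRNA and gene expression matrices have different samples")
    L = lnc_expr.values.to_numpy(dtype=float)
    G = gene_expr.values.to_numpy(dtype=float)
    if log2_transform:
        L = np.log2(L + 1.0)
        G = np.log2(G + 1.0)
    n = L.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for correlation testing")

    l_ok = L.std(axis=1) > 0
    g_ok = G.std(axis=1) > 0
    n_const = int((~l_ok).sum() + (~g_ok).sum())
    if n_const:
        logger.info("dropping %d constant features from co-expression testing", n_const)
    lnc_ids = np.asarray(lnc_expr.feature_ids)[l_ok]
    gene_ids = np.asarray(gene_expr.feature_ids)[g_ok]
    Lz = _standardize(L[l_ok])
    Gz = _standardize(G[g_ok])
    R = np.clip(Lz @ Gz.T / n, -1.0, 1.0)

    with np.errstate(divide="ignore"):
        tstat = R * np.sqrt((n - 2) / np.maximum(1.0 - R * R, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p[np.abs(R) == 1.0] = 0.0
    p_adj = multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)

    keep = (np.abs(R) > pcc_min) & (p_adj < alpha)
    pairs = []
    for i, j in zip(*np.nonzero(keep)):
        pairs.append(
            TargetPair(
                str(lnc_ids[i]),
                str(gene_ids[j]),
                "coexpression",
                pcc=float(R[i, j]),
                p_adj=float(p_adj[i, j]),
            )
        )
    return pairs


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return (x - mu) / sd


# ---------------------------------------------------------------------------
# Merge


def merge_targets(
    coloc: list[TargetPair], coexp: list[TargetPair]
) -> list[TargetPair]:
    """Union of the two evidence streams keyed by (lncRNA, gene).

    Pairs present in both get evidence ``both`` and carry the distance from
    the co-location record and the PCC/adjusted p from co-expression.
    """
    by_key: dict[tuple[str, str], TargetPair] = {}
    for p in coloc:
        by_key[(p.lnc_id, p.gene_id)] = p
    out: dict[tuple[str, str], TargetPair] = dict(by_key)
    for p in coexp:
        key = (p.lnc_id, p.gene_id)
        if key in by_key:
            c = by_key[key]
            out[key] = TargetPair(
                p.lnc_id, p.gene_id, "both", distance=c.distance, pcc=p.pcc, p_adj=p.p_adj
            )
        else:
            out[key] = p
    return [out[k] for k in sorted(out)]


def targets_table(pairs: list[TargetPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lnc_id": [p.lnc_id for p in pairs],
            "gene_id": [p.gene_id for p in pairs],
            "evidence": [p.evidence for p in pairs],
            "distance": [p.distance for p in pairs],
            "pcc": [p.pcc for p in pairs],
            "p_adj": [p.p_adj for p in pairs],
        }
    )
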