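"""Hypergeometric enrichment, the joint lncRNA + methylation regulatory
network, and co-regulated-module statistics.

The regulatory network is bipartite: differentially expressed lncRNAs point
to target genes that are simultaneously (i) predicted lncRNA targets,
(ii) DMR genes (body or promoter overlapping a differentially methylated
region), and (iii) differentially expressed in the same contrast.
Co-regulated modules are sets of target genes governed by (nearly) the same
lncRNA regulator set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .association import DiffExprResult, TargetPair
from .methylation import DMRGene

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Hypergeometric enrichment


@dataclass
class AnnotationSets:
    """Flat term -> gene-set annotation (GO terms or KEGG pathways)."""

    sets: dict[str, set[str]]
    universe: set[str]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(f"term {term}: genes outside universe: {sorted(extra)[:5]}")

    @classmethod
    def from_tsv(cls, path: str | Path, universe: set[str] | None = None) -> "AnnotationSets":
        df = pd.read_csv(path, sep="\t")
        sets: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        for r in df.itertuples(index=False):
            sets.setdefault(str(r.term_id), set()).add(str(r.gene_id))
            if hasattr(r, "term_name"):
                names[str(r.term_id)] = str(r.term_name)
        if universe is None:
            universe = set().union(*sets.values()) if sets else set()
        return cls(sets, universe, names)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # query genes in the term
    K: int  # term size
    n: int  # query size
    N: int  # universe size
    p: float
    p_adj: float
    enriched: bool


def hypergeom_enrich(
    query: set[str],
    sets: AnnotationSets,
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of a gene set against each term.

    For a term of size K in a universe of size N, with n query genes of which
    k fall in the term, p = P(X >= k) for X ~ Hypergeom(N, K, n); p-values
    are BH-adjusted across terms and a term is enriched if adjusted p < alpha.
    Query genes outside the universe are dropped with a warning.
    """
    if not sets.universe:
        raise ValueError("empty annotation universe")
    extra = query - sets.universe
    if extra:
        logger.warning("dropping %d query genes outside the universe", len(extra))
    q = query & sets.universe
    N, n = len(sets.universe), len(q)
    results = []
    terms = sorted(sets.sets)
    pvals = []
    for term in terms:
        K = len(sets.sets[term])
        k = len(q & sets.sets[term])
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        pvals.append(min(p, 1.0))
    p_adj = multipletests(pvals, method="fdr_bh")[1] if terms else []
    for term, p, pa in zip(terms, pvals, p_adj):
        K = len(sets.sets[term])
        k = len(q & sets.sets[term])
        results.append(EnrichmentResult(term, k, K, n, N, p, float(pa), bool(pa < alpha)))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "N": [r.N for r in results],
            "p": [r.p for r in results],
            "p_adj": [r.p_adj for r in results],
            "enriched": [r.enriched for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Regulatory network


@dataclass
class RegulatoryNetwork:
    """Bipartite lncRNA -> target-gene graph with epigenetic annotation.

    Every target gene is both a predicted lncRNA target and a DMR gene, and
    every node is differentially expressed in the contrast.
    """

    graph: nx.Graph
    contrast: str

    @property
    def lncrnas(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "lncRNA")

    @property
    def genes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "gene")

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def regulators_of(self, gene_id: str) -> set[str]:
        return set(self.graph.neighbors(gene_id))

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def mean_targets_per_lncrna(self) -> float:
        lncs = self.lncrnas
        if not lncs:
            raise ValueError("network has no lncRNAs")
        return self.n_edges / len(lncs)


def build_network(
    target_pairs: list[TargetPair],
    dmr_genes: list[DMRGene],
    de_lnc: list[DiffExprResult],
    de_genes: list[DiffExprResult],
    contrast: str,
) -> RegulatoryNetwork:
    """Assemble the joint regulatory network for one contrast.

    Edges (l, g) are kept when l is a DE lncRNA, g is a DE gene, (l, g) is a
    predicted target pair, and g is a DMR gene. Isolated nodes never enter
    the graph. Node attributes carry DE direction, node kind, and (for
    genes) the DMR methylation direction(s).
    """
    de_l = {r.feature_id: r for r in de_lnc if r.significant}
    de_g = {r.feature_id: r for r in de_genes if r.significant}
    dmr_by_gene = {dg.gene_id: dg for dg in dmr_genes}
    g = nx.Graph()
    for p in target_pairs:
        if p.lnc_id not in de_l or p.gene_id not in de_g or p.gene_id not in dmr_by_gene:
            continue
        dg = dmr_by_gene[p.gene_id]
        meth_dirs = ",".join(sorted({d.direction for d in dg.dmrs}))
        g.add_node(p.lnc_id, kind="lncRNA", de_direction=de_l[p.lnc_id].direction)
        g.add_node(
            p.gene_id,
            kind="gene",
            de_direction=de_g[p.gene_id].direction,
            dmr_direction=meth_dirs,
            dmr_location=dg.location,
        )
        g.add_edge(p.lnc_id, p.gene_id, evidence=p.evidence)
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree[node]
    return RegulatoryNetwork(g, contrast)


# ---------------------------------------------------------------------------
# Regulator overlap and co-regulated modules


def regulator_overlap(regulators_a: set[str], regulators_b: set[str]) -> tuple[float, float]:
    """Percentage of each gene's regulators shared with the other gene.

    Returns ``(100*|A∩B|/|A|, 100*|A∩B|/|B|)`` rounded half-up to two
    decimals. Empty input sets are an error.
    """
    if not regulators_a or not regulators_b:
        raise ValueError("regulator sets must be non-empty")
    inter = len(regulators_a & regulators_b)
    return (
        _round2(100.0 * inter / len(regulators_a)),
        _round2(100.0 * inter / len(regulators_b)),
    )


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CoRegulatedModule:
    """Target genes governed by (nearly) the same lncRNA regulator set."""

    genes: tuple[str, ...]
    shared_regulators: tuple[str, ...]
    pair_shares: tuple[tuple[str, str, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("a module needs at least 2 genes")
        if not self.shared_regulators:
            raise ValueError("module with empty shared regulator set")


def find_modules(
    network: RegulatoryNetwork,
    share_min: float = 0.75,
    min_genes: int = 2,
) -> list[CoRegulatedModule]:
    """Detect co-regulated modules among the network's target genes.

    Two genes are linked when BOTH pairwise regulator-overlap shares are at
    least ``share_min`` (as fractions; at ``share_min=1.0`` this is exact
    regulator-set equality). Modules are connected components with at least
    ``min_genes`` genes; the shared regulator set is the intersection over
    the module's genes.
    """
    genes = network.genes
    regs = {g: network.regulators_of(g) for g in genes}
    link = nx.Graph()
    link.add_nodes_from(genes)
    shares: dict[tuple[str, str], tuple[float, float]] = {}
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            inter = len(regs[a] & regs[b])
            if not regs[a] or not regs[b]:
                continue
            sa = inter / len(regs[a])
            sb = inter / len(regs[b])
            if sa >= share_min and sb >= share_min:
                link.add_edge(a, b)
                shares[(a, b)] = (sa, sb)
    modules = []
    for comp in nx.connected_components(link):
        if len(comp) < min_genes:
            continue
        comp_genes = tuple(sorted(comp))
        shared = set.intersection(*(regs[g] for g in comp_genes))
        if not shared:
            logger.warning("component %s has empty regulator intersection; skipped", comp_genes)
            continue
        pair_shares = tuple(
            (a, b, _round2(100 * s[0]), _round2(100 * s[1]))
            for (a, b), s in sorted(shares.items())
            if a in comp and b in comp
        )
        modules.append(CoRegulatedModule(comp_genes, tuple(sorted(shared)), pair_shares))
    return sorted(modules, key=lambda m: m.genes)


def modules_table(modules: list[CoRegulatedModule]) -> pd.DataFrame:
    rows = []
    for i, m in enumerate(modules):
        rows.append(
            {
                "module_id": f"M{i + 1}",
                "n_genes": len(m.genes),
                "genes": ",".join(m.genes),
                "n_shared_regulators": len(m.shared_regulators),
                "shared_regulators": ",".join(m.shared_regulators),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Export / import


def export_network(network: RegulatoryNetwork, out_prefix: str | Path, formats=("sif", "graphml")) -> list[Path]:
    """Write the network as SIF and/or GraphML plus a node-attribute TSV."""
    out_prefix = Path(out_prefix)
    written = []
    for fmt in formats:
        if fmt == "sif":
            path = out_prefix.with_suffix(".sif")
            with open(path, "w") as fh:
                for l, g in sorted(network.graph.edges):
                    a, b = (l, g) if network.graph.nodes[l]["kind"] == "lncRNA" else (g, l)
                    fh.write(f"{a}\tregulates\t{b}\n")
        elif fmt == "graphml":
            path = out_prefix.with_suffix(".graphml")
            nx.write_graphml(network.graph, path)
        else:
            raise ValueError(f"unknown export format {fmt!r}")
        written.append(path)
    attr_path = out_prefix.with_suffix(".nodes.tsv")
    rows = []
    for node, d in sorted(network.graph.nodes(data=True)):
        rows.append(
            {
                "node": node,
                "kind": d["kind"],
                "de_direction": d.get("de_direction", ""),
                "degree": d.get("degree", network.graph.degree[node]),
                "dmr_direction": d.get("dmr_direction", ""),
            }
        )
    pd.DataFrame(rows).to_csv(attr_path, sep="\t", index=False)
    written.append(attr_path)
    return written


def import_network(graphml_path: str | Path, contrast: str = "") -> RegulatoryNetwork:
    g = nx.read_graphml(graphml_path)
    g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    g.graph.pop("node_default", None)
    g.graph.pop("edge_default", None)
    return RegulatoryNetwork(g, contrast)
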