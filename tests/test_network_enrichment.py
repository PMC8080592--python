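import itertools
from math import comb

import numpy as np
import pytest

from epiflock.association import DiffExprResult, TargetPair
from epiflock.genome_model import GenomicInterval
from epiflock.methylation import DMR, DMRGene
from epiflock.network_enrichment import (
    AnnotationSets,
    CoRegulatedModule,
    build_network,
    export_network,
    find_modules,
    hypergeom_enrich,
    import_network,
    regulator_overlap,
)


def _de(fid, fc=2.0, sig=True):
    return DiffExprResult(fid, fc, 0.001, 0.01 if sig else 0.5, sig, "NM-BM")


def _dmr_gene(gid):
    d = DMR(GenomicInterval("c", 0, 100), "CG", 0.2, 0.6, "hyper", 5, 0.001)
    return DMRGene(gid, (d,), "body")


def _network(edges):
    lncs = sorted({l for l, _ in edges})
    genes = sorted({g for _, g in edges})
    return build_network(
        [TargetPair(l, g, "colocation", distance=0) for l, g in edges],
        [_dmr_gene(g) for g in genes],
        [_de(l) for l in lncs],
        [_de(g) for g in genes],
        "NM-BM",
    )


class TestHypergeomEnrich:
    def test_saturated_query(self):
        universe = {f"g{i}" for i in range(20)}
        sets = AnnotationSets({"t1": set(list(universe)[:5])}, universe)
        res = hypergeom_enrich(universe, sets)[0]
        assert res.k == res.K == 5
        assert res.p == pytest.approx(1.0)

    def test_closed_form(self):
        # N=20, K=5, n=5, k=5 -> p = 1/C(20,5)
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        res = hypergeom_enrich(term, AnnotationSets({"t": term}, universe))[0]
        assert res.p == pytest.approx(1 / comb(20, 5), rel=1e-12)

    def test_matches_enumeration_oracle(self):
        """P(X >= k) by exhaustive enumeration over all C(N, n) draws, N <= 15."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            N = int(rng.integers(5, 15))
            universe = {f"g{i}" for i in range(N)}
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            term = set(list(sorted(universe))[:K])
            query = set(rng.choice(sorted(universe), size=n, replace=False))
            k_obs = len(query & term)
            hits = total = 0
            for draw in itertools.combinations(sorted(universe), n):
                total += 1
                if len(set(draw) & term) >= k_obs:
                    hits += 1
            res = hypergeom_enrich(query, AnnotationSets({"t": term}, universe))[0]
            assert res.p == pytest.approx(hits / total, rel=1e-9)

    def test_uniform_null_enrichment_rate(self):
        rng = np.random.default_rng(12)
        universe = {f"g{i}" for i in range(200)}
        sets = {}
        for t in range(100):
            sets[f"t{t}"] = set(rng.choice(sorted(universe), size=20, replace=False))
        ann = AnnotationSets(sets, universe)
        alpha = 0.05
        enriched = 0
        n_rep = 20
        for _ in range(n_rep):
            q = set(rng.choice(sorted(universe), size=30, replace=False))
            enriched += sum(
                1 for r in hypergeom_enrich(q, ann, alpha=alpha) if r.enriched
            )
        assert enriched / n_rep <= alpha * len(sets)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich({"g"}, AnnotationSets({}, set()))


class TestRegulatorOverlap:
    @pytest.mark.parametrize(
        "na,nb,inter,expected",
        [
            (135, 121, 108, (80.00, 89.26)),
            (46, 40, 35, (76.09, 87.50)),
        ],
    )
    def test_printed_examples(self, na, nb, inter, expected):
        a = {f"l{i}" for i in range(na)}
        b = {f"l{i}" for i in range(inter)} | {f"x{i}" for i in range(nb - inter)}
        assert regulator_overlap(a, b) == expected

    def test_identity(self):
        a = {"l1", "l2"}
        assert regulator_overlap(a, set(a)) == (100.00, 100.00)

    def test_exchangeable(self):
        a = {f"l{i}" for i in range(7)}
        b = {f"l{i}" for i in range(4)} | {"x"}
        sa, sb = regulator_overlap(a, b)
        assert regulator_overlap(b, a) == (sb, sa)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            regulator_overlap(set(), {"l"})


class TestBuildNetwork:
    def test_requires_dmr_gene(self):
        net = build_network(
            [TargetPair("l1", "g1", "colocation", distance=0)],
            [],  # no DMR genes
            [_de("l1")],
            [_de("g1")],
            "NM-BM",
        )
        assert net.n_edges == 0 and net.genes == []

    def test_requires_differential_expression(self):
        net = build_network(
            [TargetPair("l1", "g1", "colocation", distance=0)],
            [_dmr_gene("g1")],
            [_de("l1", sig=False)],
            [_de("g1")],
            "NM-BM",
        )
        assert net.n_edges == 0

    def test_degree_sum_identity(self):
        rng = np.random.default_rng(13)
        edges = {
            (f"l{rng.integers(0, 9)}", f"g{rng.integers(0, 23)}") for _ in range(80)
        }
        net = _network(sorted(edges))
        lnc_deg = sum(net.degree(l) for l in net.lncrnas)
        gene_deg = sum(net.degree(g) for g in net.genes)
        assert lnc_deg == gene_deg == net.n_edges

    def test_mean_targets_per_lncrna(self):
        # 9 regulators x 7 targets each, disjoint -> 63 edges, mean exactly 7
        edges = [(f"l{i}", f"g{i}_{j}") for i in range(9) for j in range(7)]
        net = _network(edges)
        assert len(net.lncrnas) == 9 and net.n_edges == 63
        assert net.mean_targets_per_lncrna() == 7.0


class TestFindModules:
    def test_identical_regulator_sets_form_module(self):
        edges = [("l1", "gA"), ("l2", "gA"), ("l1", "gB"), ("l2", "gB")]
        net = _network(edges)
        mods = find_modules(net, share_min=1.0)
        assert len(mods) == 1
        assert mods[0].genes == ("gA", "gB")
        assert mods[0].shared_regulators == ("l1", "l2")

    def test_share_min_one_partitions_by_equality(self):
        rng = np.random.default_rng(14)
        lncs = [f"l{i}" for i in range(8)]
        edges = []
        reg_sets = {}
        for gi in range(12):
            regs = frozenset(
                rng.choice(lncs, size=int(rng.integers(1, 5)), replace=False)
            )
            reg_sets[f"g{gi}"] = regs
            edges.extend((l, f"g{gi}") for l in sorted(regs))
        net = _network(edges)
        mods = find_modules(net, share_min=1.0)
        got = {m.genes for m in mods}
        classes: dict[frozenset, list] = {}
        for g, regs in reg_sets.items():
            classes.setdefault(regs, []).append(g)
        expected = {tuple(sorted(v)) for v in classes.values() if len(v) >= 2}
        assert expected  # the instance must exercise a non-trivial class
        assert got == expected
        for m in mods:
            assert set(m.shared_regulators) == set(reg_sets[m.genes[0]])

    def test_partial_sharing_at_default_threshold(self):
        # two genes sharing 0.80 / 0.89 of regulators: a module at share_min=0.75
        a_regs = [f"l{i}" for i in range(135)]
        b_regs = [f"l{i}" for i in range(108)] + [f"x{i}" for i in range(13)]
        edges = [(l, "MAPKAP1") for l in a_regs] + [(l, "FOXP2") for l in b_regs]
        net = _network(edges)
        mods = find_modules(net, share_min=0.75)
        assert len(mods) == 1 and mods[0].genes == ("FOXP2", "MAPKAP1")
        (pair,) = mods[0].pair_shares
        assert (pair[2], pair[3]) == (89.26, 80.00) or (pair[3], pair[2]) == (89.26, 80.00)

    def test_planted_seven_gene_module(self):
        regs = [f"l{i}" for i in range(18)]
        genes = [f"g{i}" for i in range(7)]
        edges = [(l, g) for g in genes for l in regs]
        net = _network(edges)
        mods = find_modules(net, share_min=0.75)
        assert len(mods) == 1
        assert len(mods[0].genes) == 7
        assert len(mods[0].shared_regulators) == 18


class TestExport:
    def test_empty_network_valid_files(self, tmp_path):
        net = _network([])
        written = export_network(net, tmp_path / "net")
        assert all(p.exists() for p in written)

    def test_sif_line_count(self, tmp_path):
        edges = [("l1", "g1"), ("l1", "g2"), ("l2", "g1")]
        net = _network(edges)
        export_network(net, tmp_path / "net")
        lines = (tmp_path / "net.sif").read_text().splitlines()
        assert len(lines) == net.n_edges

    def test_graphml_round_trip(self, tmp_path):
        import networkx as nx

        edges = [("l1", "g1"), ("l2", "g1"), ("l2", "g2")]
        net = _network(edges)
        export_network(net, tmp_path / "net")
        back = import_network(tmp_path / "net.graphml", "NM-BM")
        assert nx.utils.graphs_equal(net.graph, back.graph)
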