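import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from epiflock.genome_model import Gene, GenomeAnnotation, GenomicInterval
from epiflock.methylation import (
    DMR,
    DMRParams,
    bin_levels,
    call_context,
    call_dmrs,
    call_methylated_sites,
    correct_ml,
    cytosine_positions,
    feature_profile,
    fisher_exact_two_sided,
    map_dmr_genes,
    methylation_level,
    non_conversion_rate,
    pool_counts,
    read_cytosine_table,
    write_cytosine_table,
)


def _records(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "m", "u"])


class TestContext:
    @pytest.mark.parametrize(
        "seq,pos,strand,expected",
        [
            ("ACGT", 1, "+", "CG"),
            ("ACAG", 1, "+", "CHG"),
            ("ACAC", 1, "+", "CHH"),  # the CAC motif
            ("ACGT", 2, "-", "CG"),   # G at 2, complement context reads leftwards
            ("AATG", 3, "-", "CHH"),
            ("CAGT", 2, "-", "CHG"),  # G at 2: prev A (->T, an H), prev2 C -> CHG
        ],
    )
    def test_examples(self, seq, pos, strand, expected):
        assert call_context(seq, pos, strand) == expected

    def test_non_cytosine_raises(self):
        with pytest.raises(ValueError):
            call_context("AAAA", 1, "+")

    def test_scan_matches_per_site_calls(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 500))
        df = cytosine_positions(seq, "c")
        assert len(df) > 0
        for row in df.itertuples():
            assert call_context(seq, row.pos, row.strand) == row.context


class TestLevels:
    @pytest.mark.parametrize("m,u,ml", [(7, 3, 0.7), (0, 10, 0.0), (10, 0, 1.0)])
    def test_methylation_level(self, m, u, ml):
        assert methylation_level(m, u) == ml

    def test_zero_coverage_raises(self):
        with pytest.raises(ValueError):
            methylation_level(0, 0)

    def test_correction_fixed_points(self):
        assert correct_ml(0.005, 0.005) == 0.0
        assert correct_ml(1.0, 0.3) == 1.0
        assert correct_ml(0.5, 0.005) == pytest.approx(0.4974874, abs=1e-6)

    def test_correction_clamps_below_r(self):
        assert correct_ml(0.001, 0.005) == 0.0

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            correct_ml(0.5, 1.0)

    @given(
        ml1=st.floats(0, 1), ml2=st.floats(0, 1),
        r=st.floats(0, 0.99, exclude_max=True),
    )
    @settings(max_examples=200, deadline=None)
    def test_correction_monotone_and_bounded(self, ml1, ml2, r):
        c1, c2 = correct_ml(ml1, r), correct_ml(ml2, r)
        assert 0.0 <= c1 <= 1.0
        if ml1 <= ml2:
            assert c1 <= c2


class TestNonConversion:
    def test_all_converted(self):
        recs = _records([("lambda", i, "+", "CHH", 0, 10) for i in range(5)])
        assert non_conversion_rate(recs) == 0.0

    def test_arithmetic(self):
        recs = _records([("lambda", 0, "+", "CG", 50, 9950)])
        assert non_conversion_rate(recs) == 0.005

    def test_zero_coverage_raises(self):
        with pytest.raises(ValueError):
            non_conversion_rate(_records([("lambda", 0, "+", "CG", 0, 0)]))


class TestSiteCalling:
    def test_extremes(self):
        recs = _records(
            [("c", 0, "+", "CG", 0, 20), ("c", 1, "+", "CG", 20, 0)]
        )
        out = call_methylated_sites(recs, r=0.005)
        flags = dict(zip(out["pos"], out["methylated"]))
        assert flags[0] == False and flags[1] == True  # noqa: E712

    def test_null_type_one_error(self):
        rng = np.random.default_rng(11)
        r = 0.01
        n = rng.poisson(30, 5000) + 1
        m = rng.binomial(n, r)
        recs = _records(
            [("c", i, "+", "CG", int(m[i]), int(n[i] - m[i])) for i in range(5000)]
        )
        out = call_methylated_sites(recs, r=r, alpha=0.05)
        assert out["methylated"].mean() <= 0.05


class TestBinLevels:
    def test_single_site(self):
        recs = _records([("c", 123, "+", "CG", 7, 3)])
        out = bin_levels(recs, bin_bp=10_000)
        assert len(out) == 1
        assert out.iloc[0]["ml"] == 0.7
        assert (out.iloc[0]["bin_start"], out.iloc[0]["bin_end"]) == (0, 10_000)

    def test_empty_bins_omitted(self):
        recs = _records([("c", 25_000, "+", "CG", 1, 1)])
        out = bin_levels(recs, bin_bp=10_000)
        assert list(out["bin_start"]) == [20_000]

    def test_matches_pooled_recomputation(self, dataset):
        table = next(iter(dataset.bisulfite.values()))
        sub = table[table["chrom"] == "chr1"].head(5000)
        out = bin_levels(sub, r=0.0, bin_bp=1000)
        for row in out.itertuples():
            sel = sub[
                (sub["pos"] >= row.bin_start)
                & (sub["pos"] < row.bin_end)
                & (sub["context"] == row.context)
            ]
            cov = sel[(sel["m"] + sel["u"]) > 0]
            assert row.ml == pytest.approx(cov["m"].sum() / (cov["m"] + cov["u"]).sum())

    def test_invariant_to_record_splitting(self):
        whole = _records([("c", 5, "+", "CG", 6, 4)])
        split = _records([("c", 5, "+", "CG", 2, 1), ("c", 5, "+", "CG", 4, 3)])
        a = bin_levels(whole)
        b = bin_levels(pool_counts([split]))
        assert a.iloc[0]["ml"] == b.iloc[0]["ml"]


class TestFisherVec:
    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        n1 = rng.poisson(40, 300) + 1
        n2 = rng.poisson(40, 300) + 1
        m1 = rng.binomial(n1, rng.uniform(0, 1, 300))
        m2 = rng.binomial(n2, rng.uniform(0, 1, 300))
        mine = fisher_exact_two_sided(m1, n1 - m1, m2, n2 - m2)
        for i in range(300):
            ref = stats.fisher_exact([[m1[i], n1[i] - m1[i]], [m2[i], n2[i] - m2[i]]])[1]
            assert mine[i] == pytest.approx(ref, rel=1e-10)


class TestDmrCaller:
    def test_identical_groups_no_dmrs(self):
        rng = np.random.default_rng(0)
        n = rng.poisson(30, 200) + 1
        m = rng.binomial(n, 0.7)
        recs = _records(
            [("c", i * 50, "+", "CG", int(m[i]), int(n[i] - m[i])) for i in range(200)]
        )
        assert call_dmrs(recs, recs.copy()) == []

    def test_duplicate_positions_rejected(self):
        recs = _records([("c", 0, "+", "CG", 1, 1), ("c", 0, "+", "CG", 2, 2)])
        with pytest.raises(ValueError, match="duplicate"):
            call_dmrs(recs, recs.copy())

    def test_planted_recovery_with_direction(self):
        """10 CpGs with a +0.3 shift at depth ~20x3 come out as one hyper DMR."""
        rng = np.random.default_rng(21)
        pos = np.arange(0, 3000, 30)
        base = np.full(len(pos), 0.5)
        shifted = base.copy()
        planted = (pos >= 1000) & (pos < 1300)
        assert planted.sum() == 10
        shifted[planted] += 0.3
        na = rng.poisson(60, len(pos)) + 1
        nb = rng.poisson(60, len(pos)) + 1
        ma = rng.binomial(na, base)
        mb = rng.binomial(nb, shifted)
        a = _records([("c", int(p), "+", "CG", int(ma[i]), int(na[i] - ma[i])) for i, p in enumerate(pos)])
        b = _records([("c", int(p), "+", "CG", int(mb[i]), int(nb[i] - mb[i])) for i, p in enumerate(pos)])
        dmrs = call_dmrs(a, b)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.direction == "hyper"
        assert d.interval.start >= 900 and d.interval.end <= 1400
        assert d.ml_b - d.ml_a == pytest.approx(0.3, abs=0.08)

    def test_null_simulation_few_false_regions(self):
        rng = np.random.default_rng(8)
        n_sites = 10_000
        pos = np.arange(n_sites) * 40
        na = rng.poisson(40, n_sites) + 1
        nb = rng.poisson(40, n_sites) + 1
        ma = rng.binomial(na, 0.7)
        mb = rng.binomial(nb, 0.7)
        a = _records([("c", int(p), "+", "CG", int(ma[i]), int(na[i] - ma[i])) for i, p in enumerate(pos)])
        b = _records([("c", int(p), "+", "CG", int(mb[i]), int(nb[i] - mb[i])) for i, p in enumerate(pos)])
        assert len(call_dmrs(a, b)) == 0


class TestDmrGeneMapping:
    @staticmethod
    def _ann():
        ann = GenomeAnnotation(chrom_lengths={"c": 100_000})
        ann.genes["g1"] = Gene("g1", GenomicInterval("c", 10_000, 20_000, "+"))
        return ann

    @staticmethod
    def _dmr(start, end):
        return DMR(GenomicInterval("c", start, end), "CG", 0.2, 0.6, "hyper", 5, 0.001)

    def test_body_overlap(self):
        out = map_dmr_genes([self._dmr(15_000, 15_100)], self._ann())
        assert len(out) == 1 and out[0].location == "body"

    def test_promoter_one_bp_inside(self):
        # promoter of g1 is [8000, 10000); DMR ending at 8001 overlaps 1 bp
        out = map_dmr_genes([self._dmr(7900, 8001)], self._ann())
        assert len(out) == 1 and out[0].location == "promoter"

    def test_just_outside_promoter(self):
        out = map_dmr_genes([self._dmr(7900, 8000)], self._ann())
        assert out == []

    def test_matches_brute_force(self, dataset):
        ann = dataset.annotation
        rng = np.random.default_rng(4)
        dmrs = []
        for _ in range(50):
            chrom = f"chr{rng.integers(1, len(ann.chrom_lengths) + 1)}"
            s = int(rng.integers(0, ann.chrom_lengths[chrom] - 500))
            dmr = DMR(
                GenomicInterval(chrom, s, s + int(rng.integers(50, 500))),
                "CG", 0.2, 0.6, "hyper", 5, 0.001,
            )
            dmrs.append(dmr)
        mapped = {dg.gene_id: dg for dg in map_dmr_genes(dmrs, ann)}
        from epiflock.genome_model import promoter_of

        for g in ann.genes.values():
            prom = promoter_of(g, 2000, ann.chrom_lengths)
            body_hits = [d for d in dmrs if d.interval.overlaps(g.interval)]
            prom_hits = [d for d in dmrs if prom and d.interval.overlaps(prom)]
            if body_hits or prom_hits:
                assert g.gene_id in mapped
                expected = (
                    "both" if body_hits and prom_hits else "body" if body_hits else "promoter"
                )
                assert mapped[g.gene_id].location == expected
            else:
                assert g.gene_id not in mapped


class TestFeatureProfile:
    def test_constant_field_uniform_levels(self, dataset):
        ann = dataset.annotation
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(ann.chrom_lengths["chr1"], 3000, replace=False))
        recs = _records([("chr1", int(p), "+", "CG", 7, 3) for p in pos])
        out = feature_profile(recs, ann)
        covered = out[(out["context"] == "CG") & (out["n_sites"] > 0)]
        assert len(covered) > 3
        assert np.allclose(covered["ml"], 0.7)

    def test_uncovered_regions_reported_missing(self):
        ann = GenomeAnnotation(chrom_lengths={"c": 50_000})
        ann.genes["g1"] = Gene("g1", GenomicInterval("c", 10_000, 20_000, "+"))
        out = feature_profile(_records([("c", 30_000, "+", "CG", 5, 5)]), ann)
        assert out["ml"].isna().any()


class TestCytosineIO:
    def test_round_trip(self, tmp_path):
        recs = _records([("chr1", 5, "+", "CG", 3, 7), ("chr1", 9, "-", "CHH", 0, 4)])
        path = tmp_path / "cyto.tsv"
        write_cytosine_table(recs, path)
        back = read_cytosine_table(path)
        pd.testing.assert_frame_equal(recs, back)

    def test_bismark_style_accepted(self, tmp_path):
        path = tmp_path / "bismark.txt"
        path.write_text("chr1\t6\t+\t3\t7\tCpG\tCGA\nchr1\t10\t-\t0\t4\tCHH\tCAT\n")
        df = read_cytosine_table(path)
        assert list(df["pos"]) == [5, 9]
        assert list(df["context"]) == ["CG", "CHH"]
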