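from __future__ import annotations

import random

import pytest

from varkin.variant_filters import (
    AlleleFrequencyTable,
    FilterError,
    GenomicRegionSet,
    UnannotatedInputError,
    filter_aaf,
    filter_call_quality,
    filter_mutation_type,
    filter_novel,
    filter_physical_location,
    filter_read_depth,
    filter_same_gene,
    filter_same_variant,
)
from varkin.vcf_io import (
    FunctionalAnnotation,
    RegionAnnotation,
    SampleCall,
    Variant,
)


def make_variant(
    chrom="1", pos=100, rsid=None, ref="A", alt="G", qual=50.0,
    dp=None, ad=None, genes=(), types=(),
):
    calls = {}
    fmt = []
    if dp is not None or ad is not None:
        data = {"GT": "0/1"}
        if ad is not None:
            data["AD"] = ad
        if dp is not None:
            data["DP"] = str(dp)
        fmt = list(data)
        calls["S1"] = SampleCall(data)
    v = Variant(chrom, pos, rsid, ref, [alt], qual, "PASS", {}, fmt, calls)
    for i, g in enumerate(genes):
        region = types[i] if i < len(types) and types[i] in (
            "splice_donor", "splice_acceptor", "promoter_up", "intron"
        ) else "exon"
        v.annotations.append(RegionAnnotation(g, f"NM_{g}_{i}", region, "c.1"))
        mt = types[i] if i < len(types) else "missense"
        v.functional.append(FunctionalAnnotation(mt, "c.1A>G"))
    return v


def random_variants(rng, n, with_annotations=False):
    out = []
    genes = [f"G{i}" for i in range(8)]
    mtypes = ["missense", "nonsense", "synonymous", "noncoding"]
    for i in range(n):
        kwargs = dict(
            chrom=rng.choice(["1", "2", "X"]),
            pos=rng.randint(1, 5000),
            rsid=f"rs{i}" if rng.random() < 0.5 else None,
            qual=float(rng.randint(0, 99)) if rng.random() < 0.9 else None,
            dp=rng.randint(0, 50) if rng.random() < 0.9 else None,
        )
        if with_annotations:
            k = rng.randint(1, 3)
            kwargs["genes"] = [rng.choice(genes) for _ in range(k)]
            kwargs["types"] = [rng.choice(mtypes) for _ in range(k)]
        out.append(make_variant(**kwargs))
    return out


class TestPhysicalLocation:
    def test_empty_stream(self):
        regions = GenomicRegionSet([("1", 10, 20)])
        assert filter_physical_location([], regions) == []

    def test_keep_discard_partition(self):
        rng = random.Random(0)
        vs = random_variants(rng, 300)
        regions = GenomicRegionSet(
            [("1", 100, 800), ("2", 2000, 2500), ("X", 1, 50)]
        )
        kept = filter_physical_location(vs, regions, "keep")
        dropped = filter_physical_location(vs, regions, "discard")
        assert len(kept) + len(dropped) == len(vs)
        assert set(map(id, kept)).isdisjoint(set(map(id, dropped)))

    def test_matches_membership_oracle(self):
        rng = random.Random(1)
        vs = random_variants(rng, 1000)
        ivals = [
            (rng.choice(["1", "2", "X"]), s, s + rng.randint(10, 900))
            for s in (rng.randint(1, 4000) for _ in range(5))
        ]
        regions = GenomicRegionSet(ivals)
        kept = filter_physical_location(vs, regions, "keep")
        oracle = [
            v
            for v in vs
            if any(c == v.chrom and s <= v.pos <= e for c, s, e in ivals)
        ]
        assert kept == oracle

    def test_bed_is_zero_based_half_open(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("chr1\t99\t200\n")
        regions = GenomicRegionSet.from_bed(bed)
        assert regions.intervals == [("1", 100, 200)]


class TestReadDepth:
    def test_min_dp_zero_keeps_all_with_depth(self):
        vs = [make_variant(dp=d) for d in (0, 5, 50)]
        assert filter_read_depth(vs, 0) == vs

    def test_boundary(self):
        (v,) = [make_variant(dp=9)]
        assert filter_read_depth([v], 10) == []
        assert filter_read_depth([v], 9) == [v]

    @pytest.mark.parametrize("scope", ["any_sample", "all_samples"])
    def test_matches_predicate_oracle(self, scope):
        rng = random.Random(2)
        vs = random_variants(rng, 1000)
        got = filter_read_depth(vs, 15, scope=scope)
        q = any if scope == "any_sample" else all
        oracle = [
            v
            for v in vs
            if q(
                [c.depth is not None and c.depth >= 15 for c in v.calls.values()]
                or [False]
            )
        ]
        assert got == oracle


class TestCallQuality:
    def test_strict_threshold(self):
        at = make_variant(qual=20.0)
        above = make_variant(qual=20.01)
        assert filter_call_quality([at, above], 20) == [above]

    def test_null_quality_fails(self):
        assert filter_call_quality([make_variant(qual=None)], 20) == []

    def test_matches_predicate_oracle(self):
        rng = random.Random(3)
        vs = random_variants(rng, 1000)
        got = filter_call_quality(vs, 30)
        assert got == [v for v in vs if v.qual is not None and v.qual > 30]


class TestMutationType:
    def test_any_annotation_match_keeps_variant(self):
        v = make_variant(genes=["G1", "G1"], types=["synonymous", "missense"])
        assert filter_mutation_type([v], {"missense", "nonsense"}) == [v]
        assert len(v.functional) == 2  # non-matching annotations retained

    def test_all_synonymous_dropped(self):
        v = make_variant(genes=["G1", "G2"], types=["synonymous", "synonymous"])
        assert filter_mutation_type([v], {"missense", "nonsense"}) == []

    def test_region_classes_are_selectable(self):
        v = make_variant(genes=["G1"], types=["splice_donor"])
        assert filter_mutation_type([v], {"splice_donor"}) == [v]

    def test_keep_all_types_is_identity(self):
        rng = random.Random(4)
        vs = random_variants(rng, 50, with_annotations=True)
        all_types = {"missense", "nonsense", "synonymous", "noncoding"}
        assert filter_mutation_type(vs, all_types) == vs

    def test_unannotated_input_raises(self):
        with pytest.raises(UnannotatedInputError, match="annotation"):
            filter_mutation_type([make_variant()], {"missense"})


class TestAAF:
    @pytest.fixture()
    def table(self, tmp_path):
        rows = [
            ("1", 100, "A", "G", 0.009),
            ("1", 200, "A", "G", 0.01),
            ("2", 300, "C", "T", 0.25),
        ]
        return AlleleFrequencyTable.write(rows, tmp_path / "af.tsv")

    def test_strict_upper_bound(self, table):
        rare = make_variant(pos=100)
        at_bound = make_variant(pos=200)
        out = filter_aaf([rare, at_bound], table, 0.01)
        assert out == [rare]

    def test_absent_policy(self, table):
        novel = make_variant(pos=999)
        assert filter_aaf([novel], table, 0.01, absent_policy="keep") == [novel]
        assert filter_aaf([novel], table, 0.01, absent_policy="drop") == []

    def test_lazy_per_chromosome_loading(self, table):
        table.lookup("1", 100, "A", "G")
        assert set(table._by_chrom) == {"1"}
        table.lookup("2", 300, "C", "T")
        assert set(table._by_chrom) == {"1", "2"}

    def test_matches_predicate_oracle(self, tmp_path):
        rng = random.Random(5)
        vs = random_variants(rng, 1000)
        rows = [
            (v.chrom, v.pos, v.ref, v.alt[0], round(rng.random(), 3))
            for v in vs
            if rng.random() < 0.7
        ]
        table = AlleleFrequencyTable.write(rows, tmp_path / "af.tsv")
        lookup = {(c, p, r, a): af for c, p, r, a, af in rows}
        got = filter_aaf(vs, table, 0.2, absent_policy="keep")
        oracle = [
            v
            for v in vs
            if lookup.get((v.chrom, v.pos, v.ref, v.alt[0])) is None
            or lookup[(v.chrom, v.pos, v.ref, v.alt[0])] < 0.2
        ]
        assert got == oracle


class TestNovel:
    def test_known_rsid_dropped_in_keep_novel(self):
        known = {"rs1"}
        v = make_variant(rsid="rs1")
        assert filter_novel([v], known, "keep_novel") == []

    def test_null_id_absent_is_novel(self):
        v = make_variant(rsid=None)
        assert filter_novel([v], {"rs1"}, "keep_novel") == [v]

    def test_modes_partition(self):
        rng = random.Random(6)
        vs = random_variants(rng, 500)
        known = {f"rs{i}" for i in range(0, 500, 3)}
        novel = filter_novel(vs, known, "keep_novel")
        kept = filter_novel(vs, known, "keep_known")
        assert len(novel) + len(kept) == len(vs)
        assert set(map(id, novel)).isdisjoint(set(map(id, kept)))


class TestMultiFile:
    def _streams(self, seed, n_files=4, n=250):
        rng = random.Random(seed)
        streams = []
        for _ in range(n_files):
            streams.append(random_variants(rng, n, with_annotations=True))
        return streams

    def test_same_variant_identity_on_identical_streams(self):
        rng = random.Random(7)
        base = random_variants(rng, 100)
        out = filter_same_variant([list(base), list(base)])
        assert out[0] == base and out[1] == base

    def test_variant_in_three_of_four_files_removed(self):
        shared = make_variant(pos=42)
        streams = [[shared], [shared], [shared], [make_variant(pos=43)]]
        out = filter_same_variant(streams)
        assert all(s == [] for s in out)

    def test_same_variant_matches_set_intersection_oracle(self):
        streams = self._streams(8)
        out = filter_same_variant(streams)
        key = lambda v: (v.chrom, v.pos, v.ref, tuple(v.alt))
        shared = set.intersection(*[{key(v) for v in s} for s in streams])
        for orig, filt in zip(streams, out):
            assert filt == [v for v in orig if key(v) in shared]

    def test_same_gene_keeps_different_variants_in_shared_gene(self):
        a = make_variant(pos=10, genes=["GENE_C"])
        b = make_variant(pos=99, genes=["GENE_C"])
        out = filter_same_gene([[a], [b]])
        assert out == [[a], [b]]  # the compound-het motivating case

    def test_gene_in_one_file_only_dropped_everywhere(self):
        a = make_variant(pos=10, genes=["ONLY_A"])
        b = make_variant(pos=99, genes=["ONLY_B"])
        assert filter_same_gene([[a], [b]]) == [[], []]

    def test_same_gene_matches_set_oracle(self):
        streams = self._streams(9)
        out = filter_same_gene(streams)
        gene_sets = [
            {a.gene for v in s for a in v.annotations} for s in streams
        ]
        shared = set.intersection(*gene_sets)
        for orig, filt in zip(streams, out):
            assert filt == [
                v for v in orig if {a.gene for a in v.annotations} & shared
            ]

    def test_fewer_than_two_streams_rejected(self):
        with pytest.raises(FilterError):
            filter_same_variant([[make_variant()]])
        with pytest.raises(FilterError):
            filter_same_gene([[make_variant(genes=["G"])]])


class TestFilterAlgebra:
    """Contraction, idempotence and order-independence of predicate filters."""

    def test_filters_are_contractions_and_idempotent(self):
        rng = random.Random(10)
        vs = random_variants(rng, 300, with_annotations=True)
        filters = [
            lambda x: filter_call_quality(x, 25),
            lambda x: filter_read_depth(x, 10),
            lambda x: filter_novel(x, {f"rs{i}" for i in range(100)}),
            lambda x: filter_mutation_type(x, {"missense", "nonsense"}),
            lambda x: filter_physical_location(
                x, GenomicRegionSet([("1", 1, 4000), ("X", 1, 2500)])
            ),
        ]
        for f in filters:
            out = f(vs)
            assert set(map(id, out)) <= set(map(id, vs))
            assert f(out) == out

    def test_order_independence_of_predicate_filters(self):
        rng = random.Random(11)
        vs = random_variants(rng, 300, with_annotations=True)
        f1 = lambda x: filter_call_quality(x, 25)
        f2 = lambda x: filter_read_depth(x, 10)
        f3 = lambda x: filter_novel(x, {f"rs{i}" for i in range(150)})
        a = f3(f2(f1(vs)))
        b = f1(f3(f2(vs)))
        c = f2(f1(f3(vs)))
        assert a == b == c
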