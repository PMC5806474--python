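from __future__ import annotations

import itertools

import pytest

from varkin.core_annotation import (
    CODON_TABLE,
    GenomeSequence,
    annotate_functions,
    annotate_genes,
    assign_zygosity,
    classify_function,
    reverse_complement,
)
from varkin.gene_model import GeneMapParams, build_region_map
from varkin.vcf_io import RegionAnnotation, SampleCall, Variant, Zygosity

from oracles import classify_substitution
from test_gene_model import make_tx

BASES = "ACGT"
ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]


@pytest.fixture(scope="module")
def codon_genome(tmp_path_factory):
    """Genome containing every codon once, as a plus- and a minus-strand CDS.

    chrom "1": 100bp flank + the 192bp codon run + 100bp flank.
    chrom "2": same but holding the reverse complement of the run, read as a
    minus-strand CDS so transcript codon i is again ALL_CODONS[i].
    """
    run = "".join(ALL_CODONS)
    flank = "A" * 100
    d = tmp_path_factory.mktemp("codon_genome")
    fa = d / "genome.fa"
    with open(fa, "w") as fh:
        fh.write(">1\n" + flank + run + flank + "\n")
        fh.write(">2\n" + flank + reverse_complement(run) + flank + "\n")
    genome = GenomeSequence(fa)
    plus_tx = make_tx(
        tx_id="NM_P", chrom="1", strand="+",
        exons=[(101, 100 + len(run))], cds=(101, 100 + len(run)),
    )
    minus_tx = make_tx(
        tx_id="NM_M", chrom="2", strand="-",
        exons=[(101, 100 + len(run))], cds=(101, 100 + len(run)),
    )
    return genome, plus_tx, minus_tx


def _classify(genome, tx, coding_index, alt_sense):
    """Run the package classifier for coding position ``coding_index`` (1-based)
    and a sense-strand alternate base."""
    pos = tx.cds_positions()[coding_index - 1]
    genome_ref = genome.fetch(tx.chrom, pos, pos)
    genome_alt = alt_sense if tx.strand == "+" else reverse_complement(alt_sense)
    v = Variant(tx.chrom, pos, None, genome_ref, [genome_alt], 50.0, "PASS", {})
    ann = RegionAnnotation(tx.gene, tx.tx_id, "exon", f"c.{coding_index}", transcript=tx)
    return classify_function(v, ann, genome)


class TestCodonEnumeration:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_all_codon_substitutions_match_translation_oracle(
        self, codon_genome, strand
    ):
        """64 codons x 3 positions x 4 bases against Biopython translation."""
        genome, plus_tx, minus_tx = codon_genome
        tx = plus_tx if strand == "+" else minus_tx
        mismatches = []
        for ci, codon in enumerate(ALL_CODONS):
            for offset in range(3):
                coding_index = ci * 3 + offset + 1
                for alt in BASES:
                    got = _classify(genome, tx, coding_index, alt)
                    expected = classify_substitution(codon, offset, alt)
                    if got.mutation_type != expected:
                        mismatches.append((codon, offset, alt, got.mutation_type, expected))
        assert mismatches == []

    def test_codon_table_agrees_with_biopython(self):
        from Bio.Seq import Seq

        for codon, aa in CODON_TABLE.items():
            assert str(Seq(codon).translate()) == aa

    def test_worked_missense_example(self, tmp_path):
        # CDS of 141 codons whose last is CGC (Arg); substituting the middle
        # base (coding position 422) G>A gives CAC (His): a classic
        # c.422G>A / p.R141H missense call.
        cds = "GCT" * 140 + "CGC"
        fa = tmp_path / "g.fa"
        fa.write_text(">1\n" + "A" * 100 + cds + "A" * 100 + "\n")
        genome = GenomeSequence(fa)
        tx = make_tx(chrom="1", strand="+",
                     exons=[(101, 100 + len(cds))], cds=(101, 100 + len(cds)))
        fn = _classify(genome, tx, 422, "A")
        assert fn.cdna_change == "c.422G>A"
        assert fn.mutation_type == "missense"
        assert fn.protein_change == "p.R141H"


class TestClassifyFunction:
    def test_noncoding_region_gets_offset_label(self, codon_genome):
        genome, plus_tx, _ = codon_genome
        v = Variant("1", 50, None, "A", ["T"], 50.0, "PASS", {})
        ann = RegionAnnotation("G1", plus_tx.tx_id, "promoter_up", "c.-51",
                               transcript=plus_tx)
        fn = classify_function(v, ann, genome)
        assert fn.mutation_type == "noncoding"
        assert fn.cdna_change == "c.-51A>T"
        assert fn.protein_change is None

    def test_frameshift_vs_inframe_indel(self, codon_genome):
        genome, plus_tx, _ = codon_genome
        pos = plus_tx.cds_positions()[29]
        ref = genome.fetch("1", pos, pos + 2)
        ann = RegionAnnotation("G1", plus_tx.tx_id, "exon", "c.30", transcript=plus_tx)
        fs = classify_function(
            Variant("1", pos, None, ref[:2], [ref[0]], 50.0, "PASS", {}), ann, genome
        )
        assert fs.mutation_type == "frameshift"
        ref4 = genome.fetch("1", pos, pos + 3)
        inframe = classify_function(
            Variant("1", pos, None, ref4, [ref4[0]], 50.0, "PASS", {}), ann, genome
        )
        assert inframe.mutation_type == "inframe_indel"

    def test_reference_mismatch_warns_and_flags(self, codon_genome):
        genome, plus_tx, _ = codon_genome
        pos = plus_tx.cds_positions()[0]
        actual = genome.fetch("1", pos, pos)
        wrong = next(b for b in BASES if b != actual)
        alt = next(b for b in BASES if b not in (actual, wrong))
        v = Variant("1", pos, None, wrong, [alt], 50.0, "PASS", {})
        ann = RegionAnnotation("G1", plus_tx.tx_id, "exon", "c.1", transcript=plus_tx)
        with pytest.warns(UserWarning, match="reference mismatch"):
            fn = classify_function(v, ann, genome)
        assert fn.ref_mismatch


class TestAnnotateGenes:
    def _variants(self, positions, chrom="1"):
        return [
            Variant(chrom, p, None, "A", ["G"], 50.0, "PASS", {}) for p in positions
        ]

    def test_intergenic_discarded_by_default(self):
        tx = make_tx()
        rmap = build_region_map([tx], GeneMapParams(promoter_bp=10))
        out = annotate_genes(self._variants([5, 1060]), rmap)
        assert [v.pos for v in out] == [1060]
        kept = annotate_genes(self._variants([5, 1060]), rmap, keep_intergenic=True)
        assert [v.pos for v in kept] == [5, 1060]
        assert kept[0].annotations == []

    def test_three_isoforms_one_variant_three_annotations(self):
        txs = [make_tx(tx_id=f"NM_{i}") for i in range(3)]
        rmap = build_region_map(txs, GeneMapParams())
        (v,) = annotate_genes(self._variants([1060]), rmap)
        assert len(v.annotations) == 3

    def test_idempotent(self):
        tx = make_tx()
        rmap = build_region_map([tx], GeneMapParams())
        out1 = annotate_genes(self._variants([1060]), rmap)
        out2 = annotate_genes(out1, rmap)
        assert [len(v.annotations) for v in out2] == [len(v.annotations) for v in out1]
        assert [a.tx_id for a in out2[0].annotations] == [
            a.tx_id for a in out1[0].annotations
        ]

    def test_unsorted_input_rejected(self):
        tx = make_tx()
        rmap = build_region_map([tx], GeneMapParams())
        vs = self._variants([1070, 1060])
        with pytest.raises(Exception, match="sorted"):
            annotate_genes(vs, rmap)


class TestAssignZygosity:
    def _call(self, ad=None, gt=None):
        data = {}
        if gt is not None:
            data["GT"] = gt
        if ad is not None:
            data["AD"] = ad
        v = Variant("1", 1, None, "A", ["G"], None, "PASS", {},
                    format_keys=list(data), calls={"S1": SampleCall(data)})
        return v

    @pytest.mark.parametrize(
        "ad,expected",
        [
            ("5,5", Zygosity.HET),       # f = 0.5
            ("0,12", Zygosity.HOM_ALT),  # f = 1.0
            ("9,1", Zygosity.HOM_REF),   # f = 0.1 < 0.15
            ("17,3", Zygosity.HET),      # f = 0.15 boundary inclusive
            ("3,17", Zygosity.HET),      # f = 0.85 boundary inclusive
        ],
    )
    def test_base_count_rule(self, ad, expected):
        v = self._call(ad=ad, gt="0/1")
        assert assign_zygosity(v)["S1"] is expected

    def test_gt_fallback_when_depths_absent(self):
        assert assign_zygosity(self._call(gt="1/1"))["S1"] is Zygosity.HOM_ALT
        assert assign_zygosity(self._call(gt="0/1"))["S1"] is Zygosity.HET
        assert assign_zygosity(self._call(gt="0/0"))["S1"] is Zygosity.HOM_REF
        assert assign_zygosity(self._call(gt="1"))["S1"] is Zygosity.HOM_ALT
        assert assign_zygosity(self._call(ad="0,0", gt="0/1"))["S1"] is Zygosity.HET

    def test_no_gt_no_depth_is_missing(self):
        assert assign_zygosity(self._call(gt="./."))["S1"] is Zygosity.MISSING

    def test_total_function_every_sample_assigned(self):
        v = self._call(ad="5,5", gt="0/1")
        v.calls["S2"] = SampleCall({"GT": "./."})
        v.format_keys = ["GT", "AD"]
        z = assign_zygosity(v)
        assert set(z) == {"S1", "S2"}


class TestSerializationFidelity:
    def test_functional_annotations_survive_write_read(self, codon_genome, tmp_path):
        from varkin.vcf_io import new_header, read_vcf, write_vcf

        genome, plus_tx, _ = codon_genome
        rmap = build_region_map([plus_tx], GeneMapParams())
        pos = plus_tx.cds_positions()[9]
        ref = genome.fetch("1", pos, pos)
        alt = next(b for b in BASES if b != ref)
        v = Variant("1", pos, None, ref, [alt], 50.0, "PASS", {})
        (v,) = annotate_genes([v], rmap)
        annotate_functions([v], genome)
        out = tmp_path / "fn.vcf"
        write_vcf(new_header([], ["1"]), [v], out)
        _, (back,) = read_vcf(out)
        assert len(back.functional) == len(v.functional) == 1
        assert back.functional[0].mutation_type == v.functional[0].mutation_type
        assert back.functional[0].cdna_change == v.functional[0].cdna_change
        assert back.functional[0].protein_change == v.functional[0].protein_change
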