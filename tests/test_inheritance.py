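from __future__ import annotations

import itertools

import pytest

from varkin.inheritance import (
    FamilyGenotypeView,
    InheritanceError,
    MosaicWindow,
    filter_autosomal_dominant,
    filter_autosomal_recessive,
    filter_mosaic,
    filter_x_dominant,
    filter_x_recessive,
    mosaic_keys,
)
from varkin.vcf_io import SampleCall, Sex, Variant, Zygosity

from oracles import ad_denovo_truth, ad_truth, ar_hom_truth

ZYGS = [Zygosity.HOM_REF, Zygosity.HET, Zygosity.HOM_ALT]


def trio_view(child, father, mother, chrom="1",
              father_affected=True, genes=None, alt_fraction=None):
    """Trio FamilyGenotypeView with the child always affected."""
    key = (chrom, 100, "A", "G")
    affected = ["C1"] + (["FA"] if father_affected else [])
    unaffected = (["FA"] if not father_affected else []) + ["MO"]
    zyg = {key: {"C1": child, "FA": father, "MO": mother}}
    return FamilyGenotypeView(
        family_id="F1",
        affected=affected,
        unaffected=unaffected,
        sex={"FA": Sex.MALE, "MO": Sex.FEMALE, "C1": Sex.MALE},
        parents={"C1": ("FA", "MO"), "FA": (None, None), "MO": (None, None)},
        zygosity=zyg,
        alt_fraction=alt_fraction or {},
        genes_by_key=genes or {},
    )


def family_view(
    zyg_by_key,
    affected,
    unaffected,
    sex,
    parents,
    chrom="1",
    genes=None,
):
    return FamilyGenotypeView(
        family_id="F1",
        affected=affected,
        unaffected=unaffected,
        sex=sex,
        parents=parents,
        zygosity=zyg_by_key,
        genes_by_key=genes or {},
    )


class TestDominantTruthTable:
    def test_complete_penetrance_matches_truth_table(self):
        """All 27 trio zygosity combinations vs the hand-coded rule."""
        for child, father, mother in itertools.product(ZYGS, repeat=3):
            view = trio_view(child, father, mother, father_affected=True)
            got = filter_autosomal_dominant(view)
            expected = ad_truth(child, father, mother)
            assert (len(got) == 1) == expected, (child, father, mother)

    def test_de_novo_matches_truth_table(self):
        for child, father, mother in itertools.product(ZYGS, repeat=3):
            view = trio_view(child, father, mother, father_affected=False)
            got = filter_autosomal_dominant(view, de_novo=True)
            expected = ad_denovo_truth(child, father, mother)
            assert (len(got) == 1) == expected, (child, father, mother)

    def test_de_novo_drops_variant_present_in_controls(self):
        view = trio_view(Zygosity.HET, Zygosity.HET, Zygosity.HET,
                         father_affected=False)
        assert filter_autosomal_dominant(view, de_novo=True) == set()

    def test_incomplete_penetrance_allows_unaffected_carriers(self):
        view = trio_view(Zygosity.HET, Zygosity.HET, Zygosity.HET,
                         father_affected=True)
        assert filter_autosomal_dominant(view) == set()
        assert len(filter_autosomal_dominant(view, incomplete_penetrance=True)) == 1

    def test_x_keys_ignored_by_autosomal_filter(self):
        view = trio_view(Zygosity.HET, Zygosity.HET, Zygosity.HOM_REF, chrom="X")
        assert filter_autosomal_dominant(view) == set()

    def test_no_affected_raises(self):
        view = trio_view(Zygosity.HET, Zygosity.HET, Zygosity.HOM_REF)
        view.affected = []
        with pytest.raises(InheritanceError):
            filter_autosomal_dominant(view)


class TestRecessiveTruthTable:
    def test_hom_path_matches_truth_table(self):
        for child, father, mother in itertools.product(ZYGS, repeat=3):
            view = trio_view(child, father, mother, father_affected=False)
            hom, _ = filter_autosomal_recessive(view)
            expected = ar_hom_truth(child, father, mother)
            assert (len(hom) == 1) == expected, (child, father, mother)

    def test_hom_alt_in_unaffected_sib_eliminates(self):
        key = (("1", 100, "A", "G"))
        view = family_view(
            {key: {"C1": Zygosity.HOM_ALT, "C2": Zygosity.HOM_ALT,
                   "FA": Zygosity.HET, "MO": Zygosity.HET}},
            affected=["C1"],
            unaffected=["FA", "MO", "C2"],
            sex={"FA": Sex.MALE, "MO": Sex.FEMALE, "C1": Sex.MALE, "C2": Sex.FEMALE},
            parents={"C1": ("FA", "MO"), "C2": ("FA", "MO"),
                     "FA": (None, None), "MO": (None, None)},
        )
        hom, _ = filter_autosomal_recessive(view)
        assert hom == set()


class TestCompoundHet:
    def _quad(self, father_carries, mother_carries, sib_unaffected=None):
        """Quad with two HET candidate keys in gene G; parental carriage per
        key given by the two flag tuples."""
        k1 = ("1", 100, "A", "G")
        k2 = ("1", 200, "C", "T")
        zyg = {}
        for k, fa_c, mo_c in [(k1, *father_carries[0:1] + mother_carries[0:1]),
                              (k2, *father_carries[1:2] + mother_carries[1:2])]:
            zyg[k] = {
                "C1": Zygosity.HET,
                "C2": Zygosity.HET,
                "FA": Zygosity.HET if fa_c else Zygosity.HOM_REF,
                "MO": Zygosity.HET if mo_c else Zygosity.HOM_REF,
            }
            if sib_unaffected is not None:
                zyg[k]["C3"] = sib_unaffected
        unaffected = ["FA", "MO"] + (["C3"] if sib_unaffected is not None else [])
        sex = {"FA": Sex.MALE, "MO": Sex.FEMALE, "C1": Sex.MALE,
               "C2": Sex.FEMALE, "C3": Sex.MALE}
        parents = {i: ("FA", "MO") for i in ("C1", "C2", "C3")}
        parents.update({"FA": (None, None), "MO": (None, None)})
        view = family_view(
            zyg, affected=["C1", "C2"], unaffected=unaffected, sex=sex,
            parents=parents, genes={k1: {"G"}, k2: {"G"}},
        )
        return view, k1, k2

    def test_opposite_parental_origin_reported(self):
        view, k1, k2 = self._quad((True, False), (False, True))
        _, chet = filter_autosomal_recessive(view)
        assert len(chet) == 1
        cg = chet[0]
        assert cg.gene == "G" and set(cg.keys) == {k1, k2}
        assert cg.origins[k1] == "paternal" and cg.origins[k2] == "maternal"

    def test_single_parent_carrying_both_rejects_gene(self):
        view, _, _ = self._quad((True, True), (False, True))
        _, chet = filter_autosomal_recessive(view)
        assert chet == []

    def test_candidate_hom_in_unaffected_sib_removed(self):
        view, k1, k2 = self._quad(
            (True, False), (False, True), sib_unaffected=Zygosity.HOM_ALT
        )
        _, chet = filter_autosomal_recessive(view)
        assert chet == []  # both keys HOM in sib -> no pair survives

    def test_unaffected_het_carriers_permitted(self):
        view, k1, k2 = self._quad(
            (True, False), (False, True), sib_unaffected=Zygosity.HET
        )
        _, chet = filter_autosomal_recessive(view)
        assert len(chet) == 1

    def test_ungenotyped_parents_degrade_gracefully(self):
        view, k1, k2 = self._quad((True, False), (False, True))
        view.genotyped -= {"FA", "MO"}
        view.unaffected = []
        _, chet = filter_autosomal_recessive(view)
        assert len(chet) == 1
        assert chet[0].origins[k1] == "unknown"


class TestXLinked:
    def _x_view(self, zyg_by_key, affected, unaffected, sex, parents, genes=None):
        return family_view(zyg_by_key, affected, unaffected, sex, parents,
                           genes=genes)

    def test_autosomal_key_rejected(self):
        view = trio_view(Zygosity.HET, Zygosity.HET, Zygosity.HOM_REF, chrom="1")
        with pytest.raises(InheritanceError, match="X-chromosome"):
            filter_x_dominant(view)
        with pytest.raises(InheritanceError, match="X-chromosome"):
            filter_x_recessive(view)

    def test_xd_follows_dominant_rules_on_x(self):
        key = ("X", 500, "G", "T")
        view = self._x_view(
            {key: {"C1": Zygosity.HET, "MO": Zygosity.HET, "FA": Zygosity.HOM_REF}},
            affected=["MO", "C1"], unaffected=["FA"],
            sex={"FA": Sex.MALE, "MO": Sex.FEMALE, "C1": Sex.FEMALE},
            parents={"C1": ("FA", "MO"), "FA": (None, None), "MO": (None, None)},
        )
        assert filter_x_dominant(view) == {key}

    def test_affected_male_het_coded_call_is_hemizygous_hom(self):
        key = ("X", 500, "G", "T")
        view = self._x_view(
            {key: {"C1": Zygosity.HET, "MO": Zygosity.HET, "FA": Zygosity.HOM_REF}},
            affected=["C1"], unaffected=["FA", "MO"],
            sex={"FA": Sex.MALE, "MO": Sex.FEMALE, "C1": Sex.MALE},
            parents={"C1": ("FA", "MO"), "FA": (None, None), "MO": (None, None)},
        )
        hom, chet = filter_x_recessive(view)
        assert hom == {key}

    def test_affected_male_two_hets_no_chet_machinery(self):
        k1, k2 = ("X", 500, "G", "T"), ("X", 900, "A", "C")
        view = self._x_view(
            {k1: {"C1": Zygosity.HET, "MO": Zygosity.HET, "FA": Zygosity.HOM_REF},
             k2: {"C1": Zygosity.HET, "MO": Zygosity.HET, "FA": Zygosity.HOM_REF}},
            affected=["C1"], unaffected=["FA", "MO"],
            sex={"FA": Sex.MALE, "MO": Sex.FEMALE, "C1": Sex.MALE},
            parents={"C1": ("FA", "MO"), "FA": (None, None), "MO": (None, None)},
            genes={k1: {"GX"}, k2: {"GX"}},
        )
        hom, chet = filter_x_recessive(view)
        assert hom == {k1, k2}  # kept via hemizygosity
        assert chet == []       # pairing machinery not invoked

    def test_unaffected_male_carrier_eliminates(self):
        key = ("X", 500, "G", "T")
        view = self._x_view(
            {key: {"C1": Zygosity.HOM_ALT, "MO": Zygosity.HET,
                   "FA": Zygosity.HET}},
            affected=["C1"], unaffected=["FA", "MO"],
            sex={"FA": Sex.MALE, "MO": Sex.FEMALE, "C1": Sex.MALE},
            parents={"C1": ("FA", "MO"), "FA": (None, None), "MO": (None, None)},
        )
        hom, _ = filter_x_recessive(view)
        assert hom == set()

    def test_unknown_sex_affected_raises(self):
        key = ("X", 500, "G", "T")
        view = self._x_view(
            {key: {"C1": Zygosity.HOM_ALT}},
            affected=["C1"], unaffected=[],
            sex={"C1": Sex.UNKNOWN},
            parents={"C1": (None, None)},
        )
        with pytest.raises(InheritanceError, match="unknown sex"):
            filter_x_recessive(view)

    def test_empty_x_set_empty_result(self):
        view = self._x_view({}, affected=["C1"], unaffected=[],
                            sex={"C1": Sex.MALE}, parents={"C1": (None, None)})
        assert filter_x_dominant(view) == set()


class TestMosaic:
    def _variant_with_fraction(self, f, depth=20, pos=100):
        alt_d = round(depth * f)
        return Variant(
            "1", pos, None, "A", ["G"], 50.0, "PASS", {},
            ["GT", "AD", "DP"],
            {"S1": SampleCall({"GT": "0/1", "AD": f"{depth - alt_d},{alt_d}",
                               "DP": str(depth)})},
        )

    def test_window_bounds(self):
        assert MosaicWindow().min_af == 0.10
        assert MosaicWindow().max_af == 0.35
        with pytest.raises(ValueError):
            MosaicWindow(0.4, 0.2)

    @pytest.mark.parametrize(
        "fraction,kept",
        [(0.05, False), (0.10, True), (0.20, True), (0.35, True), (0.50, False)],
    )
    def test_default_window_membership(self, fraction, kept):
        v = self._variant_with_fraction(fraction)
        out = filter_mosaic([v], MosaicWindow())
        assert (out == [v]) is kept

    def test_no_depth_data_raises(self):
        v = Variant("1", 100, None, "A", ["G"], 50.0, "PASS", {},
                    ["GT"], {"S1": SampleCall({"GT": "0/1"})})
        with pytest.raises(InheritanceError, match="AD"):
            filter_mosaic([v], MosaicWindow())

    def test_view_level_scope_is_affected_only(self):
        key = ("1", 100, "A", "G")
        view = FamilyGenotypeView(
            "F1", affected=["C1"], unaffected=["FA"],
            sex={"C1": Sex.MALE, "FA": Sex.MALE},
            parents={"C1": ("FA", None), "FA": (None, None)},
            zygosity={key: {"C1": Zygosity.HET, "FA": Zygosity.HET}},
            alt_fraction={key: {"FA": 0.2}},  # mosaic fraction in control only
        )
        assert mosaic_keys(view, MosaicWindow()) == set()
        view.alt_fraction[key]["C1"] = 0.2
        assert mosaic_keys(view, MosaicWindow()) == {key}
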