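"""Trait-penetrance filtering over pedigree-linked multi-file variant sets.

Models: autosomal dominant (with a de novo variant), autosomal recessive
(homozygous and compound-heterozygous paths), X-linked dominant and
recessive (hemizygous male handling), and mosaicism (allele-fraction
window).  All filters operate on a FamilyGenotypeView — a per-family table
of zygosities keyed by (chrom, pos, ref, alt) — and return the surviving
variant keys; they are contractions over the union of input keys.

Assumptions, following the complete-penetrance reading of the models:
an unaffected individual carrying a dominant candidate eliminates it; a
recessive parent is assumed to be a heterozygous carrier when genotyped;
a record absent from an individual's single-sample VCF means homozygous
reference, while an explicit ./. call is MISSING and non-informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .vcf_io import (
    Affection,
    Pedigree,
    Sex,
    Variant,
    Zygosity,
    normalize_chrom,
)

Key = Tuple[str, int, str, str]


class InheritanceError(Exception):
    pass


def is_x(chrom: str) -> bool:
    return normalize_chrom(chrom).upper() == "X"


def variant_key(v: Variant) -> Key:
    return (normalize_chrom(v.chrom), v.pos, v.ref, ",".join(v.alt))


@dataclass
class MosaicWindow:
    """Allele-fraction bounds for mosaic detection, inclusive on both ends."""

    min_af: float = 0.10
    max_af: float = 0.35

    def __post_init__(self):
        if not (0.0 <= self.min_af < self.max_af <= 1.0):
            raise ValueError("require 0 <= min_af < max_af <= 1")

    def contains(self, f: float) -> bool:
        return self.min_af <= f <= self.max_af


@dataclass
class CHetGene:
    """A gene carrying a compound-heterozygous pair in all affecteds."""

    gene: str
    keys: List[Key]
    origins: Dict[Key, str] = field(default_factory=dict)  # paternal/maternal/unknown


class FamilyGenotypeView:
    """Zygosity/allele-fraction table for one family across variant keys."""

    def __init__(
        self,
        family_id: str,
        affected: List[str],
        unaffected: List[str],
        sex: Dict[str, Sex],
        parents: Dict[str, Tuple[Optional[str], Optional[str]]],
        zygosity: Dict[Key, Dict[str, Zygosity]],
        alt_fraction: Optional[Dict[Key, Dict[str, float]]] = None,
        genes_by_key: Optional[Dict[Key, Set[str]]] = None,
        genotyped: Optional[Set[str]] = None,
    ):
        self.family_id = family_id
        self.affected = list(affected)
        self.unaffected = list(unaffected)
        self.sex = dict(sex)
        self.parents = dict(parents)
        self.zygosity = zygosity
        self.alt_fraction = alt_fraction or {}
        self.genes_by_key = genes_by_key or {}
        self.genotyped = set(genotyped) if genotyped is not None else (
            set(affected) | set(unaffected)
        )

    @classmethod
    def from_variants(
        cls,
        pedigree: Pedigree,
        family_id: str,
        variants_by_individual: Dict[str, List[Variant]],
    ) -> "FamilyGenotypeView":
        members = pedigree.members(family_id)
        if not members:
            raise InheritanceError(f"family {family_id!r} not in pedigree")
        affected = [
            m.individual_id
            for m in members
            if m.affected is Affection.AFFECTED and m.individual_id in variants_by_individual
        ]
        unaffected = [
            m.individual_id
            for m in members
            if m.affected is Affection.UNAFFECTED and m.individual_id in variants_by_individual
        ]
        sex = {m.individual_id: m.sex for m in members}
        parents = {m.individual_id: (m.father_id, m.mother_id) for m in members}
        zyg: Dict[Key, Dict[str, Zygosity]] = {}
        af: Dict[Key, Dict[str, float]] = {}
        genes: Dict[Key, Set[str]] = {}
        genotyped = set(variants_by_individual)
        for indiv, variants in variants_by_individual.items():
            for v in variants:
                k = variant_key(v)
                call = next(iter(v.calls.values()), None)
                z = None
                if call is not None:
                    z = call.zygosity
                    if z is None:
                        from .core_annotation import _zygosity_for_call

                        z = _zygosity_for_call(call, 0.15, 0.85)
                    ad = call.allele_depths
                    if ad and len(ad) >= 2 and sum(ad) > 0:
                        af.setdefault(k, {})[indiv] = sum(ad[1:]) / (ad[0] + sum(ad[1:]))
                zyg.setdefault(k, {})[indiv] = z or Zygosity.MISSING
                if v.annotations:
                    genes.setdefault(k, set()).update(a.gene for a in v.annotations)
        # absent record in a genotyped individual's file => homozygous reference
        for k, per in zyg.items():
            for indiv in genotyped:
                per.setdefault(indiv, Zygosity.HOM_REF)
        return cls(
            family_id, affected, unaffected, sex, parents, zyg, af, genes, genotyped
        )

    # -- helpers ----------------------------------------------------------
    def keys(self) -> List[Key]:
        return list(self.zygosity)

    def zyg(self, key: Key, indiv: str) -> Zygosity:
        per = self.zygosity.get(key, {})
        if indiv in per:
            return per[indiv]
        return Zygosity.HOM_REF if indiv in self.genotyped else Zygosity.MISSING

    def carries(self, key: Key, indiv: str) -> bool:
        return self.zyg(key, indiv) in (Zygosity.HET, Zygosity.HOM_ALT)

    def genotyped_parents(self, indiv: str) -> List[str]:
        fa, mo = self.parents.get(indiv, (None, None))
        return [p for p in (fa, mo) if p is not None and p in self.genotyped]

    def is_affected(self, indiv: str) -> bool:
        return indiv in self.affected


# ---------------------------------------------------------------------------
# autosomal dominant

def filter_autosomal_dominant(
    view: FamilyGenotypeView,
    de_novo: bool = False,
    incomplete_penetrance: bool = False,
    missing_eliminates: bool = False,
    _allow_x: bool = False,
) -> Set[Key]:
    """Dominant-model survivors.

    Complete penetrance: every affected carries the alternate allele
    (HET or HOM_ALT); no unaffected carries it; when an affected's parents
    are genotyped, at least one *affected* parent also carries it.  De novo
    mode instead requires all affecteds to carry and every unaffected
    control to be homozygous reference.
    """
    if not view.affected:
        raise InheritanceError("dominant filter requires >=1 affected individual")
    survivors: Set[Key] = set()
    for key in view.keys():
        if not _allow_x and is_x(key[0]):
            continue
        if not all(_carrier_status(view, key, a, missing_eliminates) for a in view.affected):
            continue
        if de_novo:
            if any(
                view.zyg(key, u) is not Zygosity.HOM_REF
                and not (view.zyg(key, u) is Zygosity.MISSING and not missing_eliminates)
                for u in view.unaffected
            ):
                continue
        else:
            if not incomplete_penetrance and any(
                view.carries(key, u) for u in view.unaffected
            ):
                continue
            ok = True
            for a in view.affected:
                gps = view.genotyped_parents(a)
                if not gps:
                    continue  # singleton fallback: carrier presence only
                affected_parent_carries = any(
                    view.is_affected(p) and view.carries(key, p) for p in gps
                )
                if not affected_parent_carries:
                    ok = False
                    break
            if not ok:
                continue
        survivors.add(key)
    return survivors


def _carrier_status(
    view: FamilyGenotypeView, key: Key, indiv: str, missing_eliminates: bool
) -> bool:
    z = view.zyg(key, indiv)
    if z is Zygosity.MISSING:
        return not missing_eliminates
    return z in (Zygosity.HET, Zygosity.HOM_ALT)


# ---------------------------------------------------------------------------
# autosomal recessive

def filter_autosomal_recessive(
    view: FamilyGenotypeView,
    genes_by_key: Optional[Dict[Key, Set[str]]] = None,
    _allow_x: bool = False,
    _x_mode: bool = False,
) -> Tuple[Set[Key], List[CHetGene]]:
    """Recessive-model survivors: (homozygous keys, compound-het genes).

    HOM path: key homozygous-alt in every affected; each genotyped parent a
    heterozygous carrier; no unaffected control homozygous-alt.  C-HET
    path: per gene, >=2 distinct keys heterozygous in every affected, with
    opposite parental origin when both parents are genotyped and no single
    parent carrying both members of a pair (such a parent would be an
    unaffected compound heterozygote).  Unaffected HET carriers are
    permitted everywhere.
    """
    if not view.affected:
        raise InheritanceError("recessive filter requires >=1 affected individual")
    genes_by_key = genes_by_key if genes_by_key is not None else view.genes_by_key

    hom: Set[Key] = set()
    for key in view.keys():
        if _x_mode:
            if not is_x(key[0]):
                continue
        elif is_x(key[0]) and not _allow_x:
            continue
        if not _hom_path_ok(view, key, x_mode=_x_mode):
            continue
        hom.add(key)

    chet = _chet_genes(view, genes_by_key, x_mode=_x_mode, allow_x=_allow_x)
    return hom, chet


def _hom_path_ok(view: FamilyGenotypeView, key: Key, x_mode: bool = False) -> bool:
    for a in view.affected:
        if x_mode and view.sex.get(a) is Sex.MALE:
            if not view.carries(key, a):  # hemizygous: any alt copy counts
                return False
        elif view.zyg(key, a) is not Zygosity.HOM_ALT:
            return False
    for u in view.unaffected:
        if x_mode and view.sex.get(u) is Sex.MALE:
            if view.carries(key, u):  # unaffected hemizygous carrier
                return False
        elif view.zyg(key, u) is Zygosity.HOM_ALT:
            return False
    for a in view.affected:
        for p in view.genotyped_parents(a):
            if x_mode:
                fa, mo = view.parents.get(a, (None, None))
                male_affected = view.sex.get(a) is Sex.MALE
                if p == fa and male_affected:
                    continue  # father does not transmit X to sons
                if not view.carries(key, p):
                    return False
            else:
                if view.zyg(key, p) is not Zygosity.HET:  # carrier assumption
                    return False
    return True


def _chet_genes(
    view: FamilyGenotypeView,
    genes_by_key: Dict[Key, Set[str]],
    x_mode: bool = False,
    allow_x: bool = False,
) -> List[CHetGene]:
    # affecteds participating in the pairing requirement: on X, hemizygous
    # males are exempt from compound-het checking
    pairing_affected = [
        a for a in view.affected if not (x_mode and view.sex.get(a) is Sex.MALE)
    ]
    if not pairing_affected:
        return []
    by_gene: Dict[str, List[Key]] = {}
    for key, genes in genes_by_key.items():
        if not allow_x and not x_mode and is_x(key[0]):
            continue
        if x_mode and not is_x(key[0]):
            continue
        for g in genes:
            by_gene.setdefault(g, []).append(key)

    out: List[CHetGene] = []
    for gene in sorted(by_gene):
        cands = []
        for key in by_gene[gene]:
            if not all(view.zyg(key, a) is Zygosity.HET for a in pairing_affected):
                continue
            if any(view.zyg(key, u) is Zygosity.HOM_ALT for u in view.unaffected):
                continue
            if x_mode and any(
                view.sex.get(u) is Sex.MALE and view.carries(key, u)
                for u in view.unaffected
            ):
                continue
            cands.append(key)
        if len(cands) < 2:
            continue
        fa, mo = view.parents.get(pairing_affected[0], (None, None))
        both_parents = (
            fa in view.genotyped if fa else False
        ) and (mo in view.genotyped if mo else False)
        valid_keys: List[Key] = []
        origins: Dict[Key, str] = {}
        for k1, k2 in combinations(sorted(cands), 2):
            if both_parents:
                fa1, fa2 = view.carries(k1, fa), view.carries(k2, fa)
                mo1, mo2 = view.carries(k1, mo), view.carries(k2, mo)
                if fa1 and fa2:
                    continue  # father would be an unaffected compound het
                if mo1 and mo2:
                    continue
                if not ((fa1 and mo2) or (fa2 and mo1)):
                    continue  # need one paternal + one maternal origin
            for k in (k1, k2):
                if k not in valid_keys:
                    valid_keys.append(k)
                    origins[k] = _origin(view, k, fa, mo) if both_parents else "unknown"
        if valid_keys:
            out.append(CHetGene(gene=gene, keys=valid_keys, origins=origins))
    return out


def _origin(view, key, fa, mo) -> str:
    f = view.carries(key, fa)
    m = view.carries(key, mo)
    if f and not m:
        return "paternal"
    if m and not f:
        return "maternal"
    return "unknown"


# ---------------------------------------------------------------------------
# X-linked

def _check_x_only(keys: Iterable[Key], model: str) -> None:
    for k in keys:
        if not is_x(k[0]):
            raise InheritanceError(
                f"{model} filter accepts X-chromosome variants only, got {k[0]}:{k[1]}"
            )


def filter_x_dominant(view: FamilyGenotypeView) -> Set[Key]:
    """Dominant rules on the X chromosome; any alt-carrying male call counts
    as carrying (hemizygous males cannot be heterozygous)."""
    _check_x_only(view.keys(), "X-dominant")
    return filter_autosomal_dominant(view, de_novo=False, _allow_x=True)


def filter_x_recessive(
    view: FamilyGenotypeView,
    genes_by_key: Optional[Dict[Key, Set[str]]] = None,
) -> Tuple[Set[Key], List[CHetGene]]:
    """Recessive rules on the X chromosome.

    Affected males are hemizygous: a single alt-carrying call satisfies the
    recessive requirement and they are exempt from compound-het pairing.
    An unaffected male carrying a candidate eliminates it (a hemizygous
    carrier male must be affected).  Affected females follow the full
    recessive logic.
    """
    _check_x_only(view.keys(), "X-recessive")
    for a in view.affected:
        if view.sex.get(a) in (None, Sex.UNKNOWN):
            raise InheritanceError(
                f"affected individual {a!r} has unknown sex; X-linked "
                "recessive filtering depends on sex"
            )
    return filter_autosomal_recessive(view, genes_by_key, _x_mode=True)


# ---------------------------------------------------------------------------
# mosaicism

def mosaic_keys(view: FamilyGenotypeView, window: MosaicWindow) -> Set[Key]:
    """Keys whose alt fraction falls inside the mosaic window in at least
    one affected individual."""
    if not view.alt_fraction:
        raise InheritanceError("mosaic filter requires allele depths (AD)")
    out: Set[Key] = set()
    for key, per in view.alt_fraction.items():
        if any(
            indiv in view.affected and window.contains(f) for indiv, f in per.items()
        ):
            out.add(key)
    return out


def filter_mosaic(
    variants: Iterable[Variant],
    window: MosaicWindow,
    samples: Optional[Iterable[str]] = None,
) -> list:
    """Stream-level mosaic filter over a (multi-)sample VCF.

    Keeps a variant iff the alt fraction of at least one scoped sample lies
    inside the window (inclusive bounds)."""
    variants = list(variants)
    scoped = set(samples) if samples is not None else None
    any_depth = False
    out = []
    for v in variants:
        keep = False
        for name, call in v.calls.items():
            if scoped is not None and name not in scoped:
                continue
            ad = call.allele_depths
            if not ad or len(ad) < 2 or sum(ad) == 0:
                continue
            any_depth = True
            f = sum(ad[1:]) / sum(ad)
            if window.contains(f):
                keep = True
        if keep:
            out.append(v)
    if variants and not any_depth:
        raise InheritanceError(
            "mosaic filter found no allele-depth (AD) data in scoped samples"
        )
    return out
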