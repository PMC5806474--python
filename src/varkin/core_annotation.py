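"""The three mandatory annotators: Adding Genes, Adding Function, Adding Zygosity.

These prime variants for every downstream filter.  Gene context comes from a
RegionMap; functional change is derived by reconstructing the reference
codon from the genome FASTA and substituting the alternate base (strand
aware, standard nuclear code); zygosity is assigned from nucleotide base
counts alone, falling back to the GT field when depths are absent.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional

from pyfaidx import Fasta

from .gene_model import (
    REGION_EXON,
    RegionMap,
    Transcript,
    cdna_position,
)
from .vcf_io import (
    FunctionalAnnotation,
    RegionAnnotation,
    SampleCall,
    Variant,
    Zygosity,
    normalize_chrom,
)

MUT_SYNONYMOUS = "synonymous"
MUT_MISSENSE = "missense"
MUT_NONSENSE = "nonsense"
MUT_STOPLOSS = "stoploss"
MUT_FRAMESHIFT = "frameshift"
MUT_INFRAME_INDEL = "inframe_indel"
MUT_NONCODING = "noncoding"

#: ordering used to pick one class per transcript for multi-allelic records
_SEVERITY = [
    MUT_FRAMESHIFT,
    MUT_NONSENSE,
    MUT_STOPLOSS,
    MUT_MISSENSE,
    MUT_INFRAME_INDEL,
    MUT_SYNONYMOUS,
    MUT_NONCODING,
]

# standard nuclear genetic code, '*' = stop
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


class AnnotationError(Exception):
    pass


class GenomeSequence:
    """Random-access, 1-based inclusive view over an indexed FASTA."""

    def __init__(self, path):
        self._fasta = Fasta(str(path), sequence_always_upper=True)
        self._names = {normalize_chrom(n): n for n in self._fasta.keys()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        name = self._names.get(normalize_chrom(chrom))
        if name is None:
            raise AnnotationError(f"chromosome {chrom!r} not in genome FASTA")
        return str(self._fasta[name][start - 1 : end]).upper()

    def chromosomes(self) -> list:
        return list(self._fasta.keys())

    def length(self, chrom: str) -> int:
        name = self._names[normalize_chrom(chrom)]
        return len(self._fasta[name])


# ---------------------------------------------------------------------------
# Adding Genes

def annotate_genes(
    variants: Iterable[Variant],
    region_map: RegionMap,
    keep_intergenic: bool = False,
) -> list:
    """Attach one RegionAnnotation per overlapping (transcript, region).

    Wholly intergenic variants are discarded unless ``keep_intergenic``.
    Prior annotations (ours or recognized from a previous run) are replaced,
    so the operation is idempotent.  Input must be coordinate-sorted per
    chromosome; an unsorted stream raises.
    """
    out = []
    last_seen: dict = {}
    promoter_bp = region_map.params.promoter_bp
    for v in variants:
        c = normalize_chrom(v.chrom)
        if c in last_seen and v.pos < last_seen[c]:
            raise AnnotationError(
                f"variants not sorted: {v.chrom}:{v.pos} after {c}:{last_seen[c]}"
            )
        last_seen[c] = v.pos
        hits = region_map.query_span(v.chrom, v.pos, v.end())
        v.annotations = []
        v.functional = []
        for tx, region in hits:
            try:
                label = cdna_position(tx, v.pos, promoter_bp)
            except Exception:
                label = ""
            v.annotations.append(
                RegionAnnotation(
                    gene=tx.gene,
                    tx_id=tx.tx_id,
                    region=region,
                    cdna=label,
                    transcript=tx,
                )
            )
        if v.annotations or keep_intergenic:
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# Adding Function

def _classify_snv(
    tx: Transcript, pos: int, ref: str, alt: str, genome: GenomeSequence
) -> FunctionalAnnotation:
    n = tx.cds_index(pos)
    if n is None:
        raise AnnotationError(
            f"{tx.tx_id}: position {pos} labelled exon but not in CDS"
        )
    codon_idx = (n - 1) // 3
    offset = (n - 1) % 3
    cp = tx.cds_positions()
    codon_pos = cp[codon_idx * 3 : codon_idx * 3 + 3]
    if len(codon_pos) < 3:
        # trailing partial codon (CDS length not a multiple of 3)
        return FunctionalAnnotation(
            mutation_type=MUT_NONCODING, cdna_change=f"c.{n}{ref}>{alt}"
        )
    bases = [genome.fetch(tx.chrom, p, p) for p in codon_pos]
    if tx.strand == "-":
        bases = [complement(b) for b in bases]
    codon_before = "".join(bases)
    genome_ref = genome.fetch(tx.chrom, pos, pos)
    mismatch = genome_ref != ref
    if mismatch:
        warnings.warn(
            f"reference mismatch at {tx.chrom}:{pos}: VCF ref {ref!r}, "
            f"FASTA {genome_ref!r}; annotation flagged unreliable",
            stacklevel=2,
        )
    sense_ref = ref if tx.strand == "+" else complement(ref)
    sense_alt = alt if tx.strand == "+" else complement(alt)
    bases[offset] = sense_alt
    codon_after = "".join(bases)
    aa_before = CODON_TABLE.get(codon_before, "X")
    aa_after = CODON_TABLE.get(codon_after, "X")
    if aa_before == aa_after:
        mtype = MUT_SYNONYMOUS
    elif aa_after == "*":
        mtype = MUT_NONSENSE
    elif aa_before == "*":
        mtype = MUT_STOPLOSS
    else:
        mtype = MUT_MISSENSE
    return FunctionalAnnotation(
        mutation_type=mtype,
        cdna_change=f"c.{n}{sense_ref}>{sense_alt}",
        protein_change=f"p.{aa_before}{codon_idx + 1}{aa_after}",
        codon_before=codon_before,
        codon_after=codon_after,
        ref_mismatch=mismatch,
    )


def classify_function(
    variant: Variant,
    annotation: RegionAnnotation,
    genome: GenomeSequence,
    alt: Optional[str] = None,
) -> FunctionalAnnotation:
    """Codon/amino-acid consequence of one alt allele on one transcript.

    Exonic SNVs are classified by codon substitution and translation;
    exonic indels by frame (length delta mod 3); everything non-exonic is
    ``noncoding`` with the cDNA offset label retained so splice and
    promoter hits stay selectable downstream.
    """
    tx = annotation.transcript
    if tx is None:
        raise AnnotationError(
            "annotation has no transcript reference; run annotate_genes first"
        )
    alts = [alt] if alt is not None else (variant.alt or ["."])
    results = []
    for a in alts:
        if annotation.region != REGION_EXON:
            base = annotation.cdna or f"g.{variant.pos}"
            if len(variant.ref) == 1 and len(a) == 1:
                sense_ref = variant.ref if tx.strand == "+" else complement(variant.ref)
                sense_alt = a if tx.strand == "+" else complement(a)
                change = f"{base}{sense_ref}>{sense_alt}"
            else:
                change = base
            results.append(
                FunctionalAnnotation(mutation_type=MUT_NONCODING, cdna_change=change)
            )
        elif len(variant.ref) == 1 and len(a) == 1:
            results.append(_classify_snv(tx, variant.pos, variant.ref, a, genome))
        else:
            delta = len(a) - len(variant.ref)
            mtype = MUT_FRAMESHIFT if delta % 3 != 0 else MUT_INFRAME_INDEL
            base = annotation.cdna or f"g.{variant.pos}"
            if delta < 0:
                change = f"{base}del{variant.ref[len(a):] if a in variant.ref else variant.ref[1:]}"
            else:
                change = f"{base}ins{a[len(variant.ref):] if variant.ref in a else a[1:]}"
            results.append(FunctionalAnnotation(mutation_type=mtype, cdna_change=change))
    results.sort(key=lambda f: _SEVERITY.index(f.mutation_type))
    return results[0]


def annotate_functions(variants: Iterable[Variant], genome: GenomeSequence) -> list:
    """Fill ``variant.functional`` index-aligned with ``variant.annotations``."""
    variants = list(variants)
    for v in variants:
        v.functional = [classify_function(v, ann, genome) for ann in v.annotations]
    return variants


# ---------------------------------------------------------------------------
# Adding Zygosity

def assign_zygosity(
    variant: Variant, lo: float = 0.15, hi: float = 0.85
) -> dict:
    """Assign HOM_REF/HET/HOM_ALT per sample from allele base counts.

    The alternate-allele fraction f = alt_depth / (ref_depth + alt_depth)
    maps to HOM_REF (f < lo), HET (lo <= f <= hi) or HOM_ALT (f > hi).
    Samples with no usable depths fall back to the GT field; with no GT the
    sample is MISSING.  The result is also stored on each call (VKZ).
    """
    out = {}
    for name, call in variant.calls.items():
        z = _zygosity_for_call(call, lo, hi)
        call.zygosity = z
        out[name] = z
    return out


def _zygosity_for_call(call: SampleCall, lo: float, hi: float) -> Zygosity:
    ad = call.allele_depths
    if ad and len(ad) >= 2:
        ref_d = ad[0]
        alt_d = sum(ad[1:])
        total = ref_d + alt_d
        if total > 0:
            f = alt_d / total
            if f < lo:
                return Zygosity.HOM_REF
            if f > hi:
                return Zygosity.HOM_ALT
            return Zygosity.HET
    gt = call.gt
    if gt is None:
        return Zygosity.MISSING
    if all(a == 0 for a in gt):
        return Zygosity.HOM_REF
    if all(a > 0 for a in gt):
        if len(gt) == 1 or len(set(gt)) == 1:
            return Zygosity.HOM_ALT
        return Zygosity.HET  # two different alt alleles
    return Zygosity.HET


def add_zygosity(variants: Iterable[Variant], lo: float = 0.15, hi: float = 0.85) -> list:
    variants = list(variants)
    for v in variants:
        assign_zygosity(v, lo, hi)
    return variants
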