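"""Read, sort, annotate in place and write VCF files; parse pedigrees.

The whole pipeline is built around one contract: every stage consumes and
emits valid VCF, one line per variant, with all foreign INFO/FORMAT keys
preserved verbatim.  Per-transcript annotations are stored *in line* as a
reserved family of INFO keys (``VK_GENE``, ``VK_TX``, ``VK_REGION``,
``VK_CDNA``, ``VK_MUT``, ``VK_PROT``, ...), each a pipe-delimited array with
one element per transcript, index-aligned across keys.  A variant bisecting
three isoforms is therefore still a single VCF line carrying three-element
arrays, never three lines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional


class VCFError(Exception):
    """Base class for VCF format errors."""


class VCFParseError(VCFError):
    pass


class PedigreeError(Exception):
    pass


class Zygosity(str, Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    MISSING = "MISSING"


#: FORMAT key used to persist base-count zygosity per sample.
ZYGOSITY_KEY = "VKZ"

#: Reserved INFO keys for in-line per-transcript annotation arrays, in the
#: order they are emitted.  Values are pipe-delimited, comma-free, and
#: index-aligned: element i of every key refers to the same transcript.
ANNOTATION_INFO_KEYS = (
    "VK_GENE",    # gene symbol
    "VK_TX",      # transcript id
    "VK_REGION",  # region class (exon/intron/splice_donor/...)
    "VK_CDNA",    # simplified HGVS-like c. position / change
    "VK_MUT",     # mutation type (missense/nonsense/...)
    "VK_PROT",    # protein change (p.R141H) or '.'
    "VK_REFSEQ",  # RefSeq accession or '.'
    "VK_ISO",     # REF (reference isoform) / ISO (alternate) or '.'
    "VK_DOM",     # protein domain name or '.'
)

#: INFO keys set by the inheritance stage (not per-transcript arrays).
MODEL_INFO_KEY = "VK_MODEL"
CHET_INFO_KEY = "VK_CHET"

_FIELD_SANITIZE = str.maketrans({",": "_", ";": "_", "|": "_", "=": "_", " ": "_"})


def _san(value: Optional[str]) -> str:
    if value is None or value == "":
        return "."
    return str(value).translate(_FIELD_SANITIZE)


def _unsan(value: str) -> Optional[str]:
    return None if value == "." else value


@dataclass
class RegionAnnotation:
    """One (transcript, region-class, cDNA offset) triple attached to a variant."""

    gene: str
    tx_id: str
    region: str
    cdna: str
    refseq_id: Optional[str] = None
    iso_tag: Optional[str] = None
    domain: Optional[str] = None
    #: live Transcript object when produced in-memory; not serialized.
    transcript: object = field(default=None, repr=False, compare=False)


@dataclass
class FunctionalAnnotation:
    """Codon/amino-acid level consequence for one transcript annotation."""

    mutation_type: str
    cdna_change: str
    protein_change: Optional[str] = None
    codon_before: Optional[str] = None
    codon_after: Optional[str] = None
    #: set when the VCF REF base disagreed with the genome FASTA.
    ref_mismatch: bool = field(default=False, compare=False)


@dataclass
class SampleCall:
    """Per-sample genotype column; raw FORMAT values kept verbatim."""

    data: dict  # FORMAT key -> raw string

    @property
    def gt(self) -> Optional[tuple]:
        raw = self.data.get("GT")
        if raw is None or raw in (".", "./.", ".|."):
            return None
        alleles = re.split(r"[/|]", raw)
        out = []
        for a in alleles:
            if a == ".":
                return None
            out.append(int(a))
        return tuple(out)

    @property
    def depth(self) -> Optional[int]:
        raw = self.data.get("DP")
        if raw in (None, "."):
            return None
        return int(raw)

    @property
    def allele_depths(self) -> Optional[list]:
        raw = self.data.get("AD")
        if raw in (None, "."):
            return None
        try:
            return [int(x) for x in raw.split(",")]
        except ValueError:
            return None

    @property
    def gq(self) -> Optional[float]:
        raw = self.data.get("GQ")
        if raw in (None, "."):
            return None
        return float(raw)

    @property
    def zygosity(self) -> Optional[Zygosity]:
        raw = self.data.get(ZYGOSITY_KEY)
        return Zygosity(raw) if raw else None

    @zygosity.setter
    def zygosity(self, value: Zygosity) -> None:
        self.data[ZYGOSITY_KEY] = value.value


@dataclass
class Variant:
    chrom: str
    pos: int
    id: Optional[str]
    ref: str
    alt: list
    qual: Optional[float]
    filter_field: str
    info: dict                       # ordered key -> str value, or True for flags
    format_keys: list = field(default_factory=list)
    calls: dict = field(default_factory=dict)   # sample name -> SampleCall
    annotations: list = field(default_factory=list)
    functional: list = field(default_factory=list)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, ",".join(self.alt))

    @property
    def zygosity(self) -> dict:
        """Sample -> Zygosity mapping (only samples with an assigned value)."""
        out = {}
        for name, call in self.calls.items():
            z = call.zygosity
            if z is not None:
                out[name] = z
        return out

    def end(self) -> int:
        """Last reference base covered by this record (1-based inclusive)."""
        return self.pos + len(self.ref) - 1


def normalize_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix so VCF/gene-map/FASTA dialects interoperate."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


# ---------------------------------------------------------------------------
# header

class VCFHeader:
    """Meta lines plus the #CHROM column line; sample names parsed from it."""

    def __init__(self, meta_lines: list, samples: list):
        self.meta_lines = list(meta_lines)
        self.samples = list(samples)

    def copy(self) -> "VCFHeader":
        return VCFHeader(self.meta_lines, self.samples)

    @property
    def column_line(self) -> str:
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if self.samples:
            cols += ["FORMAT"] + self.samples
        return "\t".join(cols)

    def has_info(self, key: str) -> bool:
        needle = f"##INFO=<ID={key},"
        return any(l.startswith(needle) for l in self.meta_lines)

    def has_format(self, key: str) -> bool:
        needle = f"##FORMAT=<ID={key},"
        return any(l.startswith(needle) for l in self.meta_lines)

    def ensure_info(self, key: str, number: str, vtype: str, desc: str) -> None:
        if not self.has_info(key):
            self.meta_lines.append(
                f'##INFO=<ID={key},Number={number},Type={vtype},Description="{desc}">'
            )

    def ensure_format(self, key: str, number: str, vtype: str, desc: str) -> None:
        if not self.has_format(key):
            self.meta_lines.append(
                f'##FORMAT=<ID={key},Number={number},Type={vtype},Description="{desc}">'
            )

    def provenance_lines(self) -> list:
        return [l for l in self.meta_lines if l.startswith("##VK_STAGE=")]


def new_header(samples: Iterable[str], contigs: Optional[Iterable[str]] = None) -> VCFHeader:
    meta = ["##fileformat=VCFv4.2"]
    for c in contigs or ():
        meta.append(f"##contig=<ID={c}>")
    meta.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    meta.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    meta.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    meta.append('##FORMAT=<ID=GQ,Number=1,Type=Float,Description="Genotype quality">')
    return VCFHeader(meta, list(samples))


# ---------------------------------------------------------------------------
# annotation (de)serialization

def _serialize_annotations(variant: Variant) -> dict:
    """Return an INFO mapping with VK_* arrays regenerated from the
    structured annotation lists (the variant itself is not mutated)."""
    info = {k: v for k, v in variant.info.items() if k not in ANNOTATION_INFO_KEYS}
    if not variant.annotations:
        return info
    anns = variant.annotations
    funcs = variant.functional if variant.functional else [None] * len(anns)
    cols = {k: [] for k in ANNOTATION_INFO_KEYS}
    for ann, fn in zip(anns, funcs):
        cols["VK_GENE"].append(_san(ann.gene))
        cols["VK_TX"].append(_san(ann.tx_id))
        cols["VK_REGION"].append(_san(ann.region))
        cols["VK_REFSEQ"].append(_san(ann.refseq_id))
        cols["VK_ISO"].append(_san(ann.iso_tag))
        cols["VK_DOM"].append(_san(ann.domain))
        if fn is None:
            cols["VK_CDNA"].append(_san(ann.cdna))
            cols["VK_MUT"].append(".")
            cols["VK_PROT"].append(".")
        else:
            cols["VK_CDNA"].append(_san(fn.cdna_change))
            cols["VK_MUT"].append(_san(fn.mutation_type))
            cols["VK_PROT"].append(_san(fn.protein_change))
    has_functional = bool(variant.functional)
    for k in ANNOTATION_INFO_KEYS:
        if k in ("VK_MUT", "VK_PROT") and not has_functional:
            continue
        if k in ("VK_REFSEQ", "VK_ISO") and all(v == "." for v in cols[k]):
            continue
        if k == "VK_DOM" and all(v == "." for v in cols[k]):
            continue
        info[k] = "|".join(cols[k])
    return info


def _deserialize_annotations(variant: Variant) -> None:
    """Rebuild structured annotation lists from VK_* INFO arrays, if present."""
    if "VK_GENE" not in variant.info:
        return
    get = lambda k, n: (
        variant.info.get(k, "|".join(["."] * n)).split("|") if n else []
    )
    genes = variant.info["VK_GENE"].split("|")
    n = len(genes)
    txs = get("VK_TX", n)
    regions = get("VK_REGION", n)
    cdnas = get("VK_CDNA", n)
    muts = get("VK_MUT", n) if "VK_MUT" in variant.info else None
    prots = get("VK_PROT", n)
    refseqs = get("VK_REFSEQ", n)
    isos = get("VK_ISO", n)
    doms = get("VK_DOM", n)
    variant.annotations = []
    variant.functional = []
    for i in range(n):
        variant.annotations.append(
            RegionAnnotation(
                gene=genes[i],
                tx_id=txs[i],
                region=regions[i],
                cdna=_unsan(cdnas[i]) or "",
                refseq_id=_unsan(refseqs[i]),
                iso_tag=_unsan(isos[i]),
                domain=_unsan(doms[i]),
            )
        )
        if muts is not None:
            variant.functional.append(
                FunctionalAnnotation(
                    mutation_type=muts[i],
                    cdna_change=_unsan(cdnas[i]) or "",
                    protein_change=_unsan(prots[i]),
                )
            )
    # structured lists are now authoritative; drop the raw keys so a rewrite
    # regenerates them canonically (prior-run annotations are recognized,
    # foreign annotation keys are left untouched in `info`).
    for k in ANNOTATION_INFO_KEYS:
        variant.info.pop(k, None)


# ---------------------------------------------------------------------------
# reading

def _parse_info(text: str) -> dict:
    info: dict = {}
    if text == ".":
        return info
    for item in text.split(";"):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            info[k] = v
        else:
            info[item] = True
    return info


def read_vcf(path) -> tuple:
    """Parse a VCF file into ``(VCFHeader, list[Variant])``.

    Multi-allelic records are kept as one Variant.  Unknown INFO/FORMAT keys
    are preserved verbatim; VK_* annotation arrays from a prior run are
    recognized and rebuilt into structured annotations.
    """
    path = Path(path)
    meta: list = []
    samples: list = []
    variants: list = []
    saw_fileformat = False
    saw_columns = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                if lineno == 1:
                    if not line.startswith("##fileformat=VCF"):
                        raise VCFParseError(
                            f"{path}: first line must begin '##fileformat=VCF'"
                        )
                    saw_fileformat = True
                meta.append(line)
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) > 9:
                    samples = cols[9:]
                elif len(cols) == 10:
                    samples = cols[9:]
                saw_columns = True
                continue
            if not saw_fileformat:
                raise VCFParseError(f"{path}: missing '##fileformat=VCF' header")
            fields = line.split("\t")
            if len(fields) < 8:
                raise VCFParseError(
                    f"{path}: line {lineno}: expected >=8 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, pos, vid, ref, alt, qual, filt, info = fields[:8]
            variant = Variant(
                chrom=chrom,
                pos=int(pos),
                id=None if vid == "." else vid,
                ref=ref,
                alt=alt.split(",") if alt != "." else [],
                qual=None if qual == "." else float(qual),
                filter_field=filt,
                info=_parse_info(info),
            )
            if len(fields) > 9:
                variant.format_keys = fields[8].split(":")
                for name, raw in zip(samples, fields[9:]):
                    vals = raw.split(":")
                    data = {}
                    for k, v in zip(variant.format_keys, vals):
                        data[k] = v
                    variant.calls[name] = SampleCall(data)
            _deserialize_annotations(variant)
            variants.append(variant)
    if not saw_columns and not saw_fileformat:
        raise VCFParseError(f"{path}: not a VCF file")
    return VCFHeader(meta, samples), variants


# ---------------------------------------------------------------------------
# writing

def _format_qual(q: Optional[float]) -> str:
    if q is None:
        return "."
    if float(q).is_integer():
        return str(int(q))
    return repr(round(float(q), 6))


def _format_info(info: dict) -> str:
    if not info:
        return "."
    parts = []
    for k, v in info.items():
        parts.append(k if v is True else f"{k}={v}")
    return ";".join(parts)


_ANNOT_HEADER_SPECS = {
    "VK_GENE": "Gene symbol per overlapping transcript (pipe-delimited)",
    "VK_TX": "Transcript id, index-aligned with VK_GENE",
    "VK_REGION": "Region class per transcript (exon/intron/splice/UTR/promoter)",
    "VK_CDNA": "Simplified cDNA position or change per transcript",
    "VK_MUT": "Mutation type per transcript",
    "VK_PROT": "Protein change per transcript",
    "VK_REFSEQ": "RefSeq accession per transcript",
    "VK_ISO": "REF for the reference isoform, ISO otherwise",
    "VK_DOM": "Protein domain per transcript",
}


def write_vcf(header: VCFHeader, variants: Iterable[Variant], path) -> None:
    """Serialize variants; VK_* arrays are regenerated from structured lists."""
    header = header.copy()
    variants = list(variants)
    infos = []
    used_keys = set()
    for v in variants:
        info = _serialize_annotations(v)
        infos.append(info)
        used_keys.update(k for k in info if k.startswith("VK_"))
        for call in v.calls.values():
            if ZYGOSITY_KEY in call.data and ZYGOSITY_KEY not in v.format_keys:
                v.format_keys.append(ZYGOSITY_KEY)
    for k in ANNOTATION_INFO_KEYS:
        if k in used_keys:
            header.ensure_info(k, ".", "String", _ANNOT_HEADER_SPECS[k])
    if MODEL_INFO_KEY in used_keys:
        header.ensure_info(MODEL_INFO_KEY, "1", "String", "Inheritance model that retained this variant")
    if CHET_INFO_KEY in used_keys:
        header.ensure_info(CHET_INFO_KEY, ".", "String", "Compound-het gene and partner variant keys")
    if any(ZYGOSITY_KEY in c.data for v in variants for c in v.calls.values()):
        header.ensure_format(ZYGOSITY_KEY, "1", "String", "Base-count zygosity (HOM_REF/HET/HOM_ALT/MISSING)")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header.meta_lines:
            fh.write(line + "\n")
        fh.write(header.column_line + "\n")
        for v, info in zip(variants, infos):
            row = [
                v.chrom,
                str(v.pos),
                v.id or ".",
                v.ref,
                ",".join(v.alt) if v.alt else ".",
                _format_qual(v.qual),
                v.filter_field or ".",
                _format_info(info),
            ]
            if header.samples:
                row.append(":".join(v.format_keys) if v.format_keys else "GT")
                for s in header.samples:
                    call = v.calls.get(s)
                    if call is None:
                        row.append("./.")
                    else:
                        row.append(
                            ":".join(call.data.get(k, ".") for k in v.format_keys)
                        )
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# sorting

def sort_variants(variants: Iterable[Variant], chrom_order: list) -> list:
    """Stable sort by (chromosome order index, position).

    Every chromosome present must appear in ``chrom_order`` (names compared
    after ``chr``-prefix normalization).
    """
    order = {normalize_chrom(c): i for i, c in enumerate(chrom_order)}
    variants = list(variants)
    for v in variants:
        if normalize_chrom(v.chrom) not in order:
            raise VCFError(f"chromosome {v.chrom!r} not in chromosome order list")
    return sorted(variants, key=lambda v: (order[normalize_chrom(v.chrom)], v.pos))


# ---------------------------------------------------------------------------
# pedigree

class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


@dataclass
class PedIndividual:
    family_id: str
    individual_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: Sex
    affected: Affection
    vcf_path: Optional[str] = None


@dataclass
class Pedigree:
    individuals: list

    def families(self) -> list:
        seen = []
        for ind in self.individuals:
            if ind.family_id not in seen:
                seen.append(ind.family_id)
        return seen

    def members(self, family_id: str) -> list:
        return [i for i in self.individuals if i.family_id == family_id]

    def get(self, family_id: str, individual_id: str) -> Optional[PedIndividual]:
        for i in self.individuals:
            if i.family_id == family_id and i.individual_id == individual_id:
                return i
        return None

    def affected(self, family_id: Optional[str] = None) -> list:
        return [
            i
            for i in self.individuals
            if i.affected is Affection.AFFECTED
            and (family_id is None or i.family_id == family_id)
        ]

    def validate(self) -> None:
        for fam in self.families():
            members = self.members(fam)
            ids = [m.individual_id for m in members]
            if len(ids) != len(set(ids)):
                dup = next(i for i in ids if ids.count(i) > 1)
                raise PedigreeError(f"duplicate individual id {dup!r} in family {fam!r}")
            idset = set(ids)
            for m in members:
                for parent in (m.father_id, m.mother_id):
                    if parent is not None and parent not in idset:
                        raise PedigreeError(
                            f"individual {m.individual_id!r} in family {fam!r} "
                            f"references unknown parent {parent!r}"
                        )
            # no individual may be its own ancestor
            parent_of = {
                m.individual_id: [p for p in (m.father_id, m.mother_id) if p]
                for m in members
            }
            for start in idset:
                stack, seen = list(parent_of[start]), set()
                while stack:
                    cur = stack.pop()
                    if cur == start:
                        raise PedigreeError(
                            f"individual {start!r} in family {fam!r} is its own ancestor"
                        )
                    if cur in seen:
                        continue
                    seen.add(cur)
                    stack.extend(parent_of.get(cur, []))


_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_PHENO_CODES = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED}


def parse_pedigree(path) -> Pedigree:
    """Parse a whitespace-delimited PED file (6 columns, optional 7th VCF path).

    Sex is coded 1=male, 2=female; phenotype 2=affected, 1=unaffected; any
    other code maps to unknown.  A parent id of "0" means no parent recorded.
    """
    path = Path(path)
    individuals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise PedigreeError(
                    f"{path}: line {lineno}: expected >=6 columns, got {len(cols)}"
                )
            fam, iid, fa, mo, sex, pheno = cols[:6]
            if fa == iid or mo == iid:
                raise PedigreeError(
                    f"{path}: line {lineno}: individual {iid!r} is its own parent"
                )
            individuals.append(
                PedIndividual(
                    family_id=fam,
                    individual_id=iid,
                    father_id=None if fa == "0" else fa,
                    mother_id=None if mo == "0" else mo,
                    sex=_SEX_CODES.get(sex, Sex.UNKNOWN),
                    affected=_PHENO_CODES.get(pheno, Affection.UNKNOWN),
                    vcf_path=cols[6] if len(cols) > 6 else None,
                )
            )
    ped = Pedigree(individuals)
    ped.validate()
    return ped
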