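"""Transcript models, region maps and cDNA coordinate labelling.

A gene map is loaded from a UCSC refGene-style flat table, expanded into a
per-chromosome interval index labelling every base covered by a transcript
(exon / intron / splice_donor / splice_acceptor / utr5 / utr3 /
promoter_up / promoter_down), and queried per position.  All internal
coordinates are 1-based inclusive (the VCF convention); UCSC's 0-based
half-open coordinates are converted at load time.
"""

from __future__ import annotations

import bisect
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .vcf_io import normalize_chrom

REGION_EXON = "exon"
REGION_INTRON = "intron"
REGION_SPLICE_DONOR = "splice_donor"
REGION_SPLICE_ACCEPTOR = "splice_acceptor"
REGION_UTR5 = "utr5"
REGION_UTR3 = "utr3"
REGION_PROMOTER_UP = "promoter_up"
REGION_PROMOTER_DOWN = "promoter_down"

ALL_REGIONS = frozenset(
    {
        REGION_EXON,
        REGION_INTRON,
        REGION_SPLICE_DONOR,
        REGION_SPLICE_ACCEPTOR,
        REGION_UTR5,
        REGION_UTR3,
        REGION_PROMOTER_UP,
        REGION_PROMOTER_DOWN,
    }
)


class GeneMapError(Exception):
    pass


@dataclass
class GeneMapParams:
    """User parameters controlling region-map expansion.

    promoter_bp
        Length in bp of the promoter windows flanking the transcript,
        strand-aware: ``promoter_up`` is 5' of the transcription start,
        ``promoter_down`` 3' of the transcription end.  Default 500.
    splice_bp
        Essential splice-site window carved out of each intron end.
        Default 5 (the donor window is the first 5 intronic bases in
        transcription direction, the acceptor the last 5).
    enabled_regions
        Region classes to emit; disabled classes are simply absent from the
        map, so positions covered only by them look intergenic.
    """

    promoter_bp: int = 500
    splice_bp: int = 5
    enabled_regions: frozenset = ALL_REGIONS

    def __post_init__(self):
        if self.promoter_bp < 0 or self.splice_bp < 0:
            raise ValueError("promoter_bp and splice_bp must be >= 0")
        self.enabled_regions = frozenset(self.enabled_regions)
        unknown = self.enabled_regions - ALL_REGIONS
        if unknown:
            raise ValueError(f"unknown region classes: {sorted(unknown)}")

    def cache_token(self) -> str:
        payload = {
            "promoter_bp": self.promoter_bp,
            "splice_bp": self.splice_bp,
            "enabled_regions": sorted(self.enabled_regions),
        }
        return json.dumps(payload, sort_keys=True)


@dataclass
class Transcript:
    gene: str
    tx_id: str
    refseq_id: Optional[str]
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: list                       # [(start, end)] 1-based inclusive, sorted
    is_reference_isoform: bool = False
    _cds_positions: Optional[list] = field(default=None, repr=False, compare=False)

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    def validate(self) -> None:
        if self.strand not in "+-":
            raise GeneMapError(f"{self.tx_id}: bad strand {self.strand!r}")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise GeneMapError(f"{self.tx_id}: exon start {s} > end {e}")
            if s <= prev_end:
                raise GeneMapError(f"{self.tx_id}: exons overlap or are unsorted")
            prev_end = e
        if not (self.tx_start <= self.exons[0][0] and self.exons[-1][1] <= self.tx_end):
            raise GeneMapError(f"{self.tx_id}: exons outside transcript bounds")
        if self.is_coding and not (
            self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end
        ):
            raise GeneMapError(f"{self.tx_id}: CDS bounds outside transcript bounds")

    def cds_positions(self) -> list:
        """Genomic positions of CDS bases in transcription (5'->3') order."""
        if self._cds_positions is None:
            pos = []
            if self.is_coding:
                for s, e in self.exons:
                    lo = max(s, self.cds_start)
                    hi = min(e, self.cds_end)
                    if lo <= hi:
                        pos.extend(range(lo, hi + 1))
                if self.strand == "-":
                    pos.reverse()
            self._cds_positions = pos
        return self._cds_positions

    def cds_index(self, pos: int) -> Optional[int]:
        """1-based coding position of a genomic base, or None if not in CDS."""
        cp = self.cds_positions()
        if not cp:
            return None
        if self.strand == "+":
            i = bisect.bisect_left(cp, pos)
            if i < len(cp) and cp[i] == pos:
                return i + 1
            return None
        rev = cp[::-1]  # ascending
        i = bisect.bisect_left(rev, pos)
        if i < len(rev) and rev[i] == pos:
            return len(cp) - i
        return None


# ---------------------------------------------------------------------------
# refGene-dialect loader
#
# Expected tab-separated columns (UCSC refGene order, optional leading bin):
#   [bin] name chrom strand txStart txEnd cdsStart cdsEnd exonCount
#   exonStarts exonEnds score name2 [cdsStartStat cdsEndStat exonFrames]
# txStart/cdsStart/exonStarts are 0-based half-open on disk.

def load_gene_map(path) -> list:
    path = Path(path)
    transcripts: list = []
    seen_genes: set = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            # tolerate the optional UCSC bin column
            if len(cols) >= 13 and cols[3] in "+-":
                pass
            elif len(cols) >= 12 and cols[2] in "+-":
                cols = [""] + cols
            else:
                raise GeneMapError(
                    f"{path}: line {lineno}: not a refGene-dialect row"
                )
            name, chrom, strand = cols[1], cols[2], cols[3]
            tx_start0, tx_end = int(cols[4]), int(cols[5])
            cds_start0, cds_end = int(cols[6]), int(cols[7])
            exon_count = int(cols[8])
            exon_starts = [int(x) for x in cols[9].rstrip(",").split(",") if x != ""]
            exon_ends = [int(x) for x in cols[10].rstrip(",").split(",") if x != ""]
            gene = cols[12] if len(cols) > 12 and cols[12] else name
            if len(exon_starts) != len(exon_ends):
                raise GeneMapError(
                    f"{path}: line {lineno}: exonStarts/exonEnds length mismatch"
                )
            if exon_count != len(exon_starts):
                raise GeneMapError(
                    f"{path}: line {lineno}: exonCount {exon_count} != "
                    f"{len(exon_starts)} parsed intervals"
                )
            exons = [(s + 1, e) for s, e in zip(exon_starts, exon_ends)]
            if cds_start0 == cds_end:
                cds_start, cds_e = cds_end, cds_end  # noncoding sentinel
            else:
                cds_start, cds_e = cds_start0 + 1, cds_end
            tx = Transcript(
                gene=gene,
                tx_id=name,
                refseq_id=name if name[:3] in ("NM_", "NR_", "XM_", "XR_") else None,
                chrom=chrom,
                strand=strand,
                tx_start=tx_start0 + 1,
                tx_end=tx_end,
                cds_start=cds_start,
                cds_end=cds_e,
                exons=exons,
                is_reference_isoform=gene not in seen_genes,
            )
            tx.validate()
            seen_genes.add(gene)
            transcripts.append(tx)
    return transcripts


# ---------------------------------------------------------------------------
# region carving

def transcript_region_intervals(tx: Transcript, params: GeneMapParams) -> list:
    """Disjoint (start, end, region) intervals for one transcript.

    Splice windows are carved out of the intron (exonic bases keep the exon
    label); the donor window sits at the 5' end of the intron in
    transcription direction.  Promoters are strand-aware and clipped at
    position 1.
    """
    out = []

    def emit(start, end, region):
        if start <= end and region in params.enabled_regions:
            out.append((start, end, region))

    plus = tx.strand == "+"

    # exonic bases: exon within CDS, UTR outside
    for s, e in tx.exons:
        if not tx.is_coding:
            # all exonic bases sit 5'/3' of the empty CDS point
            pivot = tx.cds_start  # == cds_end
            left_r = REGION_UTR5 if plus else REGION_UTR3
            right_r = REGION_UTR3 if plus else REGION_UTR5
            emit(s, min(e, pivot), left_r)
            if pivot + 1 <= e:
                emit(max(s, pivot + 1), e, right_r)
            continue
        if e < tx.cds_start:
            emit(s, e, REGION_UTR5 if plus else REGION_UTR3)
            continue
        if s > tx.cds_end:
            emit(s, e, REGION_UTR3 if plus else REGION_UTR5)
            continue
        if s < tx.cds_start:
            emit(s, tx.cds_start - 1, REGION_UTR5 if plus else REGION_UTR3)
        emit(max(s, tx.cds_start), min(e, tx.cds_end), REGION_EXON)
        if e > tx.cds_end:
            emit(tx.cds_end + 1, e, REGION_UTR3 if plus else REGION_UTR5)

    # introns with splice windows carved out of each end
    for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
        ilo, ihi = e1 + 1, s2 - 1
        if ilo > ihi:
            continue
        length = ihi - ilo + 1
        w = min(params.splice_bp, length)
        if plus:
            donor = (ilo, ilo + w - 1)
            rem_lo = ilo + w
            w2 = min(params.splice_bp, ihi - rem_lo + 1)
            acceptor = (ihi - w2 + 1, ihi) if w2 > 0 else None
        else:
            donor = (ihi - w + 1, ihi)
            rem_hi = ihi - w
            w2 = min(params.splice_bp, rem_hi - ilo + 1)
            acceptor = (ilo, ilo + w2 - 1) if w2 > 0 else None
        emit(donor[0], donor[1], REGION_SPLICE_DONOR)
        if acceptor:
            emit(acceptor[0], acceptor[1], REGION_SPLICE_ACCEPTOR)
        mid_lo = (donor[1] + 1) if plus else ((acceptor[1] + 1) if acceptor else ilo)
        mid_hi = ((acceptor[0] - 1) if acceptor else ihi) if plus else donor[0] - 1
        emit(mid_lo, mid_hi, REGION_INTRON)

    # promoters
    if params.promoter_bp > 0:
        if plus:
            emit(max(1, tx.tx_start - params.promoter_bp), tx.tx_start - 1, REGION_PROMOTER_UP)
            emit(tx.tx_end + 1, tx.tx_end + params.promoter_bp, REGION_PROMOTER_DOWN)
        else:
            emit(tx.tx_end + 1, tx.tx_end + params.promoter_bp, REGION_PROMOTER_UP)
            emit(max(1, tx.tx_start - params.promoter_bp), tx.tx_start - 1, REGION_PROMOTER_DOWN)

    return out


class RegionMap:
    """Chromosome -> interval index of (transcript, region) labels."""

    def __init__(self, transcripts: Iterable[Transcript], params: GeneMapParams):
        self.params = params
        self.transcripts = list(transcripts)
        self._trees: dict = {}
        for tx in self.transcripts:
            tx.validate()
            chrom = normalize_chrom(tx.chrom)
            tree = self._trees.setdefault(chrom, IntervalTree())
            for start, end, region in transcript_region_intervals(tx, params):
                tree.addi(start, end + 1, (tx, region))

    def query(self, chrom: str, pos: int) -> list:
        """All (Transcript, region) pairs covering a position.

        An empty result means the position is wholly intergenic under the
        map's parameters.  Results are deterministically ordered by
        (gene, transcript id, region).
        """
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos)]
        hits.sort(key=lambda d: (d[0].gene, d[0].tx_id, d[1]))
        return hits

    def query_span(self, chrom: str, start: int, end: int) -> list:
        """(Transcript, region) pairs overlapping a 1-based inclusive span."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        seen = {}
        for iv in tree.overlap(start, end + 1):
            tx, region = iv.data
            seen[(tx.tx_id, region, id(tx))] = (tx, region)
        hits = list(seen.values())
        hits.sort(key=lambda d: (d[0].gene, d[0].tx_id, d[1]))
        return hits


def build_region_map(transcripts: Iterable[Transcript], params: Optional[GeneMapParams] = None) -> RegionMap:
    return RegionMap(transcripts, params or GeneMapParams())


def save_region_map(rmap: RegionMap, path) -> Path:
    """Serialize a built region map to JSON (a pre-computed gene map cache)."""
    tx_index = {id(tx): i for i, tx in enumerate(rmap.transcripts)}
    payload = {
        "params": {
            "promoter_bp": rmap.params.promoter_bp,
            "splice_bp": rmap.params.splice_bp,
            "enabled_regions": sorted(rmap.params.enabled_regions),
        },
        "transcripts": [
            {
                "gene": tx.gene,
                "tx_id": tx.tx_id,
                "refseq_id": tx.refseq_id,
                "chrom": tx.chrom,
                "strand": tx.strand,
                "tx_start": tx.tx_start,
                "tx_end": tx.tx_end,
                "cds_start": tx.cds_start,
                "cds_end": tx.cds_end,
                "exons": [list(e) for e in tx.exons],
                "is_reference_isoform": tx.is_reference_isoform,
            }
            for tx in rmap.transcripts
        ],
        "intervals": {
            chrom: [
                [iv.begin, iv.end, tx_index[id(iv.data[0])], iv.data[1]]
                for iv in sorted(tree)
            ]
            for chrom, tree in rmap._trees.items()
        },
    }
    path = Path(path)
    path.write_text(json.dumps(payload))
    return path


def load_region_map(path) -> RegionMap:
    """Reload a serialized region map without re-carving the transcripts."""
    payload = json.loads(Path(path).read_text())
    params = GeneMapParams(
        promoter_bp=payload["params"]["promoter_bp"],
        splice_bp=payload["params"]["splice_bp"],
        enabled_regions=frozenset(payload["params"]["enabled_regions"]),
    )
    transcripts = [
        Transcript(
            gene=t["gene"],
            tx_id=t["tx_id"],
            refseq_id=t["refseq_id"],
            chrom=t["chrom"],
            strand=t["strand"],
            tx_start=t["tx_start"],
            tx_end=t["tx_end"],
            cds_start=t["cds_start"],
            cds_end=t["cds_end"],
            exons=[tuple(e) for e in t["exons"]],
            is_reference_isoform=t["is_reference_isoform"],
        )
        for t in payload["transcripts"]
    ]
    rmap = RegionMap.__new__(RegionMap)
    rmap.params = params
    rmap.transcripts = transcripts
    rmap._trees = {}
    for chrom, ivals in payload["intervals"].items():
        tree = IntervalTree()
        for begin, end, tx_idx, region in ivals:
            tree.addi(begin, end, (transcripts[tx_idx], region))
        rmap._trees[chrom] = tree
    return rmap


def cached_region_map(gene_map_path, params: GeneMapParams, cache_dir) -> RegionMap:
    """Build-or-load a region map, cached under a (file, params) digest.

    Emulates pre-built static gene maps: repeated pipeline configurations
    reuse the expanded map instead of re-carving it."""
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = region_map_cache_key(gene_map_path, params)
    cache_path = cache_dir / f"region_map_{key}.json"
    if cache_path.exists():
        try:
            return load_region_map(cache_path)
        except Exception:
            cache_path.unlink()  # stale/corrupt cache: rebuild
    rmap = RegionMap(load_gene_map(gene_map_path), params)
    save_region_map(rmap, cache_path)
    return rmap


def region_map_cache_key(gene_map_path, params: GeneMapParams) -> str:
    """Stable digest identifying a (gene-map file, parameters) pair.

    Used to name pre-built map caches so a pipeline can detect whether a map
    on disk corresponds to its configuration.
    """
    h = hashlib.sha256()
    h.update(Path(gene_map_path).read_bytes())
    h.update(params.cache_token().encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# cDNA numbering

def cdna_position(tx: Transcript, pos: int, promoter_bp: int = 500) -> str:
    """Simplified HGVS-like c. label for a genomic position.

    Coding exonic base n -> ``c.n``; intronic base k bases past the exon
    ending at coding position n -> ``c.n+k`` (donor side) or ``c.m-k``
    (acceptor side, nearest boundary wins, ties go to the + side); 5' of the
    CDS -> ``c.-k``; 3' of the CDS -> ``c.*k``.  For positions upstream of
    the transcript the count continues in genomic bases (so a promoter base
    167 bp upstream of a UTR-less transcription start is ``c.-167``).
    """
    if not tx.is_coding:
        return f"n.{pos}"
    lo = tx.tx_start - promoter_bp
    hi = tx.tx_end + promoter_bp
    if not (lo <= pos <= hi):
        raise GeneMapError(
            f"position {pos} outside reach of transcript {tx.tx_id} "
            f"({lo}-{hi})"
        )
    n = tx.cds_index(pos)
    if n is not None:
        return f"c.{n}"
    plus = tx.strand == "+"
    cp = tx.cds_positions()
    first_cds, last_cds = cp[0], cp[-1]

    in_exon = any(s <= pos <= e for s, e in tx.exons)
    five_prime = pos < first_cds if plus else pos > first_cds
    three_prime = pos > last_cds if plus else pos < last_cds

    if in_exon and five_prime:
        k = _exonic_distance(tx, pos, first_cds)
        return f"c.-{k}"
    if in_exon and three_prime:
        k = _exonic_distance(tx, pos, last_cds)
        return f"c.*{k}"
    if not in_exon and _within_tx(tx, pos):
        # intronic: distance to nearest flanking exon boundary
        prev_b, next_b = _flanking_exon_bases(tx, pos)
        d_prev = abs(pos - prev_b)
        d_next = abs(next_b - pos)
        if d_prev <= d_next:
            return f"{_anchor_label(tx, prev_b)}+{d_prev}"
        return f"{_anchor_label(tx, next_b)}-{d_next}"
    # outside the transcript span: promoter / downstream, genomic distance
    if plus:
        if pos < tx.tx_start:
            utr5_len = _exonic_distance(tx, tx.tx_start, first_cds) if tx.tx_start != first_cds else 0
            return f"c.-{utr5_len + (tx.tx_start - pos)}"
        utr3_len = _exonic_distance(tx, tx.tx_end, last_cds) if tx.tx_end != last_cds else 0
        return f"c.*{utr3_len + (pos - tx.tx_end)}"
    else:
        if pos > tx.tx_end:
            utr5_len = _exonic_distance(tx, tx.tx_end, first_cds) if tx.tx_end != first_cds else 0
            return f"c.-{utr5_len + (pos - tx.tx_end)}"
        utr3_len = _exonic_distance(tx, tx.tx_start, last_cds) if tx.tx_start != last_cds else 0
        return f"c.*{utr3_len + (tx.tx_start - pos)}"


def _within_tx(tx: Transcript, pos: int) -> bool:
    return tx.tx_start <= pos <= tx.tx_end


def _exonic_distance(tx: Transcript, a: int, b: int) -> int:
    """Exonic-base distance between two exonic positions (adjacent bases: 1)."""
    lo, hi = min(a, b), max(a, b)
    between = 0
    for s, e in tx.exons:
        olo, ohi = max(s, lo + 1), min(e, hi - 1)
        if olo <= ohi:
            between += ohi - olo + 1
    return between + 1


def _flanking_exon_bases(tx: Transcript, pos: int) -> tuple:
    """(previous exonic base, next exonic base) flanking an intronic position,
    in transcription direction."""
    for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
        if e1 < pos < s2:
            if tx.strand == "+":
                return e1, s2
            return s2, e1
    raise GeneMapError(f"position {pos} is not intronic in {tx.tx_id}")


def _anchor_label(tx: Transcript, exonic_base: int) -> str:
    """c.-style coordinate of an exonic base used as an intron anchor."""
    n = tx.cds_index(exonic_base)
    if n is not None:
        return f"c.{n}"
    cp = tx.cds_positions()
    plus = tx.strand == "+"
    first_cds, last_cds = cp[0], cp[-1]
    five_prime = exonic_base < first_cds if plus else exonic_base > first_cds
    if five_prime:
        return f"c.-{_exonic_distance(tx, exonic_base, first_cds)}"
    return f"c.*{_exonic_distance(tx, exonic_base, last_cds)}"
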