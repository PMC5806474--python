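"""Order-flexible, chainable variant filters.

Every filter is a contraction (output is a subset of the input, annotations
untouched) and idempotent.  Thresholds follow the conventions printed with
the method: call quality is a strict ``>``, allele frequency a strict ``<``,
read depth a non-strict ``>=``.  Multi-allelic records survive a per-allele
filter if any alternate allele passes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .vcf_io import Variant, normalize_chrom


class FilterError(Exception):
    pass


class UnannotatedInputError(FilterError):
    """Raised when a filter needing annotations meets unannotated input."""


# ---------------------------------------------------------------------------
# genomic regions

class GenomicRegionSet:
    """A list of (chrom, start, end) 1-based inclusive intervals."""

    def __init__(self, intervals: Iterable[tuple]):
        self.intervals = []
        for chrom, start, end in intervals:
            if start > end:
                raise ValueError(f"interval start {start} > end {end}")
            self.intervals.append((normalize_chrom(chrom), int(start), int(end)))
        if not self.intervals:
            raise ValueError("region set must contain at least one interval")

    @classmethod
    def from_bed(cls, path) -> "GenomicRegionSet":
        """Load a BED file (0-based half-open on disk -> 1-based inclusive)."""
        ivals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                cols = line.split("\t")
                ivals.append((cols[0], int(cols[1]) + 1, int(cols[2])))
        return cls(ivals)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        c = normalize_chrom(chrom)
        return any(
            ic == c and s <= end and start <= e for ic, s, e in self.intervals
        )


def filter_physical_location(
    variants: Iterable[Variant],
    regions: GenomicRegionSet,
    mode: str = "keep",
) -> list:
    """Retain (keep) or remove (discard) variants overlapping the regions."""
    if mode not in ("keep", "discard"):
        raise ValueError(f"mode must be 'keep' or 'discard', got {mode!r}")
    out = []
    for v in variants:
        hit = regions.overlaps(v.chrom, v.pos, v.end())
        if (mode == "keep") == hit:
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# per-sample quality filters

def filter_read_depth(
    variants: Iterable[Variant],
    min_dp: int,
    scope: str = "any_sample",
    missing_fails: bool = True,
) -> list:
    """Keep variants with depth >= min_dp in any/all samples.

    A sample with no DP value fails the predicate unless
    ``missing_fails=False`` (in which case it passes)."""
    if min_dp < 0:
        raise ValueError("min_dp must be >= 0")
    if scope not in ("any_sample", "all_samples"):
        raise ValueError(f"unknown scope {scope!r}")
    out = []
    for v in variants:
        verdicts = []
        for call in v.calls.values():
            dp = call.depth
            if dp is None:
                verdicts.append(not missing_fails)
            else:
                verdicts.append(dp >= min_dp)
        if not verdicts:
            verdicts = [not missing_fails]
        ok = any(verdicts) if scope == "any_sample" else all(verdicts)
        if ok:
            out.append(v)
    return out


def filter_call_quality(
    variants: Iterable[Variant],
    min_qual: float,
    missing_fails: bool = True,
) -> list:
    """Keep variants with QUAL strictly greater than the threshold."""
    if min_qual < 0:
        raise ValueError("min_qual must be >= 0")
    out = []
    for v in variants:
        if v.qual is None:
            if not missing_fails:
                out.append(v)
        elif v.qual > min_qual:
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# annotation-driven filters

def filter_mutation_type(variants: Iterable[Variant], keep_types) -> list:
    """Variant-level filter with annotation-level matching.

    ``keep_types`` may mix mutation classes (missense, nonsense, ...) and
    region classes (splice_donor, promoter_up, ...).  A variant survives if
    ANY in-line transcript annotation matches; non-matching annotations are
    retained on survivors."""
    keep_types = set(keep_types)
    out = []
    for v in variants:
        if not v.annotations:
            raise UnannotatedInputError(
                f"{v.chrom}:{v.pos} has no annotations; run gene/function "
                "annotation before the mutation-type filter"
            )
        if not v.functional:
            raise UnannotatedInputError(
                f"{v.chrom}:{v.pos} has no functional annotations; run "
                "function annotation before the mutation-type filter"
            )
        match = False
        for ann, fn in zip(v.annotations, v.functional):
            if fn.mutation_type in keep_types or ann.region in keep_types:
                match = True
                break
        if match:
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# allele-frequency table + rarity/novelty filters

class AlleleFrequencyTable:
    """(chrom, pos, ref, alt) -> population alternate-allele frequency.

    Backed by a TSV with columns chrom, pos, ref, alt, af.  Chromosomes are
    loaded lazily, one at a time on first touch, mirroring a per-chromosome
    memory budget; an absent variant looks up as None.
    """

    def __init__(self, path):
        self.path = Path(path)
        self._by_chrom: dict = {}
        self._index: Optional[dict] = None

    def _chrom_offsets(self) -> dict:
        if self._index is None:
            idx: dict = {}
            with open(self.path) as fh:
                offset = fh.tell()
                line = fh.readline()
                while line:
                    if line.strip() and not line.startswith("#"):
                        chrom = normalize_chrom(line.split("\t", 1)[0])
                        idx.setdefault(chrom, []).append(offset)
                    offset = fh.tell()
                    line = fh.readline()
            self._index = idx
        return self._index

    def _load(self, chrom: str) -> dict:
        if chrom not in self._by_chrom:
            table: dict = {}
            offsets = self._chrom_offsets().get(chrom, [])
            if offsets:
                with open(self.path) as fh:
                    for off in offsets:
                        fh.seek(off)
                        cols = fh.readline().rstrip("\n").split("\t")
                        c, pos, ref, alt, af = cols[:5]
                        af = float(af)
                        if not 0.0 <= af <= 1.0:
                            raise FilterError(
                                f"{self.path}: allele frequency {af} outside [0,1]"
                            )
                        table[(int(pos), ref, alt)] = af
            self._by_chrom[chrom] = table
        return self._by_chrom[chrom]

    def lookup(self, chrom: str, pos: int, ref: str, alt: str) -> Optional[float]:
        return self._load(normalize_chrom(chrom)).get((pos, ref, alt))

    @classmethod
    def write(cls, rows: Iterable[tuple], path) -> "AlleleFrequencyTable":
        df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af"])
        df.to_csv(path, sep="\t", index=False, header=False)
        return cls(path)


def filter_aaf(
    variants: Iterable[Variant],
    table: AlleleFrequencyTable,
    max_af: float,
    absent_policy: str = "keep",
) -> list:
    """Rarity screen: keep variants whose population AF is strictly below
    ``max_af``.  Variants absent from the table (novel) follow
    ``absent_policy`` (default keep)."""
    if not 0.0 <= max_af <= 1.0:
        raise ValueError("max_af must be within [0, 1]")
    if absent_policy not in ("keep", "drop"):
        raise ValueError(f"unknown absent_policy {absent_policy!r}")
    out = []
    for v in variants:
        keep = False
        for alt in v.alt or ["."]:
            af = table.lookup(v.chrom, v.pos, v.ref, alt)
            if af is None:
                if absent_policy == "keep":
                    keep = True
                    break
            elif af < max_af:
                keep = True
                break
        if keep:
            out.append(v)
    return out


def filter_novel(
    variants: Iterable[Variant],
    known: Union[set, AlleleFrequencyTable],
    mode: str = "keep_novel",
) -> list:
    """Split on novelty: novel = no rsID and absent from the known set/table."""
    if mode not in ("keep_novel", "keep_known"):
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for v in variants:
        if isinstance(known, AlleleFrequencyTable):
            in_known = any(
                known.lookup(v.chrom, v.pos, v.ref, alt) is not None
                for alt in (v.alt or ["."])
            )
        else:
            in_known = v.id is not None and v.id in known
        novel = v.id is None and not in_known
        if (mode == "keep_novel") == novel:
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# multi-file filters

def _variant_keys(v: Variant) -> set:
    return {(normalize_chrom(v.chrom), v.pos, v.ref, a) for a in (v.alt or ["."])}


def filter_same_variant(case_streams: list) -> list:
    """Keep only variants shared (chrom, pos, ref, alt) across ALL cases."""
    if len(case_streams) < 2:
        raise FilterError("same-variant filter needs at least 2 case files")
    key_sets = []
    for stream in case_streams:
        keys: set = set()
        for v in stream:
            keys |= _variant_keys(v)
        key_sets.append(keys)
    shared = set.intersection(*key_sets)
    return [
        [v for v in stream if _variant_keys(v) & shared] for stream in case_streams
    ]


def filter_same_gene(case_streams: list) -> list:
    """Keep variants whose gene context is shared across ALL cases.

    A variant survives iff at least one of its annotated gene symbols is
    carried by some variant in every case stream."""
    if len(case_streams) < 2:
        raise FilterError("same-gene filter needs at least 2 case files")
    gene_sets = []
    for stream in case_streams:
        genes: set = set()
        for v in stream:
            if not v.annotations:
                raise UnannotatedInputError(
                    f"{v.chrom}:{v.pos} has no gene annotations; run gene "
                    "annotation before the same-gene filter"
                )
            genes |= {a.gene for a in v.annotations}
        gene_sets.append(genes)
    shared = set.intersection(*gene_sets) if gene_sets else set()
    return [
        [v for v in stream if {a.gene for a in v.annotations} & shared]
        for stream in case_streams
    ]
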