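"""Post-filter fine annotation: isoform IDs, protein domains, expression.

These stages run on the small surviving variant set, where the per-variant
cost of the extra lookups is acceptable: RefSeq accessions and a REF/ISO
reference-isoform tag, protein-domain context from a flat UniProt-style
table, and tissue-expression filtering with a derived tissue-specificity
score for prioritization.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import pandas as pd

from .gene_model import Transcript
from .vcf_io import Variant


class ExtendedAnnotationError(Exception):
    pass


# ---------------------------------------------------------------------------
# Isoform Context

def annotate_isoform_ids(variants: Iterable[Variant], transcripts: Iterable[Transcript]) -> list:
    """Tag each in-line annotation with its RefSeq accession and REF/ISO.

    REF marks the gene's reference isoform, ISO any alternate isoform, so a
    report search for "REF" isolates reference-isoform rows.  Transcripts
    absent from the table are tagged "unknown" with a warning.
    """
    by_id = {tx.tx_id: tx for tx in transcripts}
    variants = list(variants)
    for v in variants:
        for ann in v.annotations:
            tx = by_id.get(ann.tx_id)
            if tx is None:
                warnings.warn(
                    f"transcript {ann.tx_id!r} not in transcript table; "
                    "isoform tag set to 'unknown'",
                    stacklevel=2,
                )
                ann.iso_tag = "unknown"
                continue
            ann.refseq_id = tx.refseq_id
            ann.iso_tag = "REF" if tx.is_reference_isoform else "ISO"
    return variants


# ---------------------------------------------------------------------------
# Protein Context

class ProteinDomainTable:
    """transcript/protein id -> [(domain name, aa_start, aa_end)], 1-based
    inclusive amino-acid intervals.  Loaded from a TSV with columns
    tx_id, domain, aa_start, aa_end."""

    def __init__(self, domains: Dict[str, List[tuple]]):
        for tx_id, ivals in domains.items():
            for name, s, e in ivals:
                if s > e:
                    raise ExtendedAnnotationError(
                        f"{tx_id}: domain {name!r} aa_start {s} > aa_end {e}"
                    )
        self.domains = domains

    @classmethod
    def load(cls, path) -> "ProteinDomainTable":
        df = pd.read_csv(
            path,
            sep="\t",
            names=["tx_id", "domain", "aa_start", "aa_end"],
            comment="#",
        )
        out: Dict[str, List[tuple]] = {}
        for row in df.itertuples(index=False):
            out.setdefault(str(row.tx_id), []).append(
                (str(row.domain), int(row.aa_start), int(row.aa_end))
            )
        return cls(out)

    def lookup(self, tx_id: str, aa_pos: int) -> Optional[str]:
        for name, s, e in self.domains.get(tx_id, []):
            if s <= aa_pos <= e:  # boundaries inclusive
                return name
        return None


_AA_POS = re.compile(r"^p\.[A-Za-z*]+(\d+)")


def protein_position(protein_change: Optional[str]) -> Optional[int]:
    """Amino-acid position from a p.R141H-style change string."""
    if not protein_change:
        return None
    m = _AA_POS.match(protein_change)
    return int(m.group(1)) if m else None


def annotate_protein_domains(
    variants: Iterable[Variant], domains: ProteinDomainTable
) -> list:
    """Attach the containing domain name to coding annotations."""
    variants = list(variants)
    for v in variants:
        for ann, fn in zip(v.annotations, v.functional or [None] * len(v.annotations)):
            if fn is None:
                continue
            aa = protein_position(fn.protein_change)
            if aa is None:
                continue
            hit = domains.lookup(ann.tx_id, aa)
            if hit is not None:
                ann.domain = hit
    return variants


# ---------------------------------------------------------------------------
# Gene Expression

class ExpressionTable:
    """gene symbol -> tissue -> expression value (arbitrary units, >= 0).

    Loaded from a TSV whose first column is the gene symbol and remaining
    columns are tissues (header row required)."""

    def __init__(self, table: Dict[str, Dict[str, float]]):
        for gene, per in table.items():
            for tissue, val in per.items():
                if val < 0:
                    raise ExtendedAnnotationError(
                        f"{gene}/{tissue}: negative expression value {val}"
                    )
        self.table = table

    @classmethod
    def load(cls, path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        table = {
            str(gene): {str(t): float(v) for t, v in row.items()}
            for gene, row in df.iterrows()
        }
        return cls(table)

    def tissues(self) -> List[str]:
        ts: List[str] = []
        for per in self.table.values():
            for t in per:
                if t not in ts:
                    ts.append(t)
        return ts

    def expression(self, gene: str, tissue: str) -> Optional[float]:
        per = self.table.get(gene)
        if per is None:
            return None
        if tissue not in per:
            raise ExtendedAnnotationError(
                f"unknown tissue {tissue!r}; available: {', '.join(self.tissues())}"
            )
        return per[tissue]

    def specificity(self, gene: str, tissue: str) -> Optional[float]:
        """Tissue-specificity score: expression in the target tissue divided
        by the mean across all tissues.  ~1 for housekeeping profiles,
        large for organ-specific genes."""
        per = self.table.get(gene)
        if per is None:
            return None
        if tissue not in per:
            raise ExtendedAnnotationError(
                f"unknown tissue {tissue!r}; available: {', '.join(self.tissues())}"
            )
        mean = sum(per.values()) / len(per)
        if mean == 0:
            return 0.0
        return per[tissue] / mean


def filter_gene_expression(
    variants: Iterable[Variant],
    table: ExpressionTable,
    tissue: str,
    min_expr: Optional[float] = None,
    max_expr: Optional[float] = None,
    absent_passes: bool = True,
) -> list:
    """Keep variants whose annotated genes satisfy the expression bound(s)
    in the given tissue.  Genes absent from the table pass by default."""
    if min_expr is None and max_expr is None:
        raise ValueError("set min_expr, max_expr, or both (a band)")
    known_tissues = table.tissues()
    if tissue not in known_tissues:
        raise ExtendedAnnotationError(
            f"unknown tissue {tissue!r}; available: {', '.join(known_tissues)}"
        )
    out = []
    for v in variants:
        genes = {a.gene for a in v.annotations}
        keep = False
        for g in genes:
            expr = table.expression(g, tissue)
            if expr is None:
                if absent_passes:
                    keep = True
                    break
                continue
            if min_expr is not None and expr < min_expr:
                continue
            if max_expr is not None and expr > max_expr:
                continue
            keep = True
            break
        if keep:
            out.append(v)
    return out
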