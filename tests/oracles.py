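"""Independent brute-force oracles used to validate the implementation.

Everything here is written as directly as possible from the model
definitions — per-position scans, naive set algebra, plain rule loops —
deliberately sharing no logic with the package's interval indexes, codon
reconstruction or view-based inheritance filters.
"""

from __future__ import annotations

from Bio.Seq import Seq

from varkin.vcf_io import Zygosity

# ---------------------------------------------------------------------------
# per-base region classifier (scans one transcript at a time)


def classify_position(tx, pos, promoter_bp, splice_bp):
    """Region label of one genomic position for one transcript, or None."""
    plus = tx.strand == "+"
    coding = tx.cds_start < tx.cds_end

    for s, e in tx.exons:
        if s <= pos <= e:
            if coding and tx.cds_start <= pos <= tx.cds_end:
                return "exon"
            if coding:
                before_cds = pos < tx.cds_start
            else:
                before_cds = pos <= tx.cds_start
            if plus:
                return "utr5" if before_cds else "utr3"
            return "utr3" if before_cds else "utr5"

    for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
        if e1 < pos < s2:
            ilen = s2 - 1 - e1
            w_d = min(splice_bp, ilen)
            if plus:
                if pos <= e1 + w_d:
                    return "splice_donor"
                w_a = min(splice_bp, ilen - w_d)
                if w_a and pos >= s2 - w_a:
                    return "splice_acceptor"
            else:
                if pos >= s2 - w_d:
                    return "splice_donor"
                w_a = min(splice_bp, ilen - w_d)
                if w_a and pos <= e1 + w_a:
                    return "splice_acceptor"
            return "intron"

    if promoter_bp > 0:
        if tx.tx_start - promoter_bp <= pos < tx.tx_start:
            return "promoter_up" if plus else "promoter_down"
        if tx.tx_end < pos <= tx.tx_end + promoter_bp:
            return "promoter_down" if plus else "promoter_up"
    return None


def brute_force_labels(transcripts, chrom, pos, promoter_bp, splice_bp):
    """Set of (tx_id, region) labels at a position across all transcripts."""
    out = set()
    for tx in transcripts:
        if tx.chrom.removeprefix("chr") != str(chrom).removeprefix("chr"):
            continue
        label = classify_position(tx, pos, promoter_bp, splice_bp)
        if label is not None:
            out.add((tx.tx_id, label))
    return out


# ---------------------------------------------------------------------------
# codon substitution oracle (Biopython translation)


def classify_substitution(sense_codon, offset, sense_alt):
    """Expected mutation type for substituting one base of a sense codon."""
    before = str(Seq(sense_codon).translate())
    after_codon = sense_codon[:offset] + sense_alt + sense_codon[offset + 1 :]
    after = str(Seq(after_codon).translate())
    if before == after:
        return "synonymous"
    if after == "*":
        return "nonsense"
    if before == "*":
        return "stoploss"
    return "missense"


# ---------------------------------------------------------------------------
# trio truth tables (child affected; roles fixed per model)

CARRIER = (Zygosity.HET, Zygosity.HOM_ALT)


def ad_truth(child, father, mother):
    """Autosomal dominant, complete penetrance; father affected, mother not."""
    return child in CARRIER and father in CARRIER and mother not in CARRIER


def ad_denovo_truth(child, father, mother):
    """De novo dominant: both unaffected parents homozygous reference."""
    return (
        child in CARRIER
        and father is Zygosity.HOM_REF
        and mother is Zygosity.HOM_REF
    )


def ar_hom_truth(child, father, mother):
    """Recessive homozygous path: carrier parents, homozygous child."""
    return (
        child is Zygosity.HOM_ALT
        and father is Zygosity.HET
        and mother is Zygosity.HET
    )


# ---------------------------------------------------------------------------
# naive end-to-end enumerator for the planted-recovery fixtures
#
# Re-derives, from the raw simulated VCF records and the transcript table,
# the set of variant keys that should survive annotation + the inheritance
# model, applying the same rules as the pipeline but via flat loops.


def naive_zygosity(call):
    ad = call.allele_depths
    if ad and len(ad) >= 2 and sum(ad) > 0:
        f = sum(ad[1:]) / sum(ad)
        if f < 0.15:
            return Zygosity.HOM_REF
        if f > 0.85:
            return Zygosity.HOM_ALT
        return Zygosity.HET
    gt = call.gt
    if gt is None:
        return Zygosity.MISSING
    if all(a == 0 for a in gt):
        return Zygosity.HOM_REF
    if all(a > 0 for a in gt):
        return Zygosity.HOM_ALT if len(set(gt)) == 1 else Zygosity.HET
    return Zygosity.HET


def _collect(vcfs_by_ind):
    """key -> {individual: (zygosity, alt_fraction)} over raw variant lists."""
    table = {}
    for ind, variants in vcfs_by_ind.items():
        for v in variants:
            key = (v.chrom.removeprefix("chr"), v.pos, v.ref, ",".join(v.alt))
            call = next(iter(v.calls.values()))
            ad = call.allele_depths
            f = sum(ad[1:]) / sum(ad) if ad and sum(ad) > 0 else None
            table.setdefault(key, {})[ind] = (naive_zygosity(call), f)
    return table


def _zyg(table, key, ind):
    return table[key].get(ind, (Zygosity.HOM_REF, None))[0]


def _carries(table, key, ind):
    return _zyg(table, key, ind) in CARRIER


def genic_genes(transcripts, chrom, pos, promoter_bp=500, splice_bp=5):
    """Gene symbols whose transcripts give this position any region label."""
    genes = set()
    for tx in transcripts:
        if tx.chrom.removeprefix("chr") != str(chrom).removeprefix("chr"):
            continue
        if classify_position(tx, pos, promoter_bp, splice_bp) is not None:
            genes.add(tx.gene)
    return genes


def enumerate_survivors(model, members, vcfs_by_ind, transcripts):
    """Surviving variant keys under one inheritance model.

    ``members``: list of dicts with iid/sex ('1'/'2')/affected (bool)/
    father/mother (ids or None).  Only genic variants (any region label
    under default parameters) are considered, mirroring the mandatory
    annotation step that discards wholly intergenic variants.
    """
    table = _collect(vcfs_by_ind)
    by_id = {m["iid"]: m for m in members}
    affected = [m["iid"] for m in members if m["affected"]]
    unaffected = [m["iid"] for m in members if not m["affected"]]

    genic = {}
    for key in table:
        genes = genic_genes(transcripts, key[0], key[1])
        if genes:
            genic[key] = genes

    is_x = lambda key: key[0].upper() == "X"
    male = lambda iid: by_id[iid]["sex"] == "1"

    def dominant(key, de_novo, x):
        if x != is_x(key):
            return False
        if not all(_carries(table, key, a) for a in affected):
            return False
        if de_novo:
            return all(_zyg(table, key, u) is Zygosity.HOM_REF for u in unaffected)
        if any(_carries(table, key, u) for u in unaffected):
            return False
        for a in affected:
            parents = [
                p
                for p in (by_id[a]["father"], by_id[a]["mother"])
                if p is not None and p in vcfs_by_ind
            ]
            if not parents:
                continue
            if not any(by_id[p]["affected"] and _carries(table, key, p) for p in parents):
                return False
        return True

    def recessive_hom(key, x):
        if x != is_x(key):
            return False
        for a in affected:
            if x and male(a):
                if not _carries(table, key, a):
                    return False
            elif _zyg(table, key, a) is not Zygosity.HOM_ALT:
                return False
        for u in unaffected:
            if x and male(u):
                if _carries(table, key, u):
                    return False
            elif _zyg(table, key, u) is Zygosity.HOM_ALT:
                return False
        for a in affected:
            fa, mo = by_id[a]["father"], by_id[a]["mother"]
            for p in (fa, mo):
                if p is None or p not in vcfs_by_ind:
                    continue
                if x:
                    if p == fa and male(a):
                        continue
                    if not _carries(table, key, p):
                        return False
                elif _zyg(table, key, p) is not Zygosity.HET:
                    return False
        return True

    def chet_keys(x):
        pairing = [a for a in affected if not (x and male(a))]
        if not pairing:
            return set()
        by_gene = {}
        for key, genes in genic.items():
            if x != is_x(key):
                continue
            for g in genes:
                by_gene.setdefault(g, []).append(key)
        out = set()
        for g, keys in by_gene.items():
            cands = []
            for key in keys:
                if not all(_zyg(table, key, a) is Zygosity.HET for a in pairing):
                    continue
                if any(_zyg(table, key, u) is Zygosity.HOM_ALT for u in unaffected):
                    continue
                if x and any(male(u) and _carries(table, key, u) for u in unaffected):
                    continue
                cands.append(key)
            fa, mo = by_id[pairing[0]]["father"], by_id[pairing[0]]["mother"]
            both = fa in vcfs_by_ind and mo in vcfs_by_ind if fa and mo else False
            for i, k1 in enumerate(sorted(cands)):
                for k2 in sorted(cands)[i + 1 :]:
                    if both:
                        fa1, fa2 = _carries(table, k1, fa), _carries(table, k2, fa)
                        mo1, mo2 = _carries(table, k1, mo), _carries(table, k2, mo)
                        if (fa1 and fa2) or (mo1 and mo2):
                            continue
                        if not ((fa1 and mo2) or (fa2 and mo1)):
                            continue
                    out.add(k1)
                    out.add(k2)
        return out

    survivors = set()
    for key in genic:
        if model == "AD" and dominant(key, de_novo=False, x=False):
            survivors.add(key)
        elif model == "AD_denovo" and dominant(key, de_novo=True, x=False):
            survivors.add(key)
        elif model in ("AR_HOM", "AR_CHET") and recessive_hom(key, x=False):
            survivors.add(key)
        elif model == "XLD" and dominant(key, de_novo=False, x=True):
            survivors.add(key)
        elif model == "XLR" and recessive_hom(key, x=True):
            survivors.add(key)
        elif model == "mosaic":
            for a in affected:
                info = table[key].get(a)
                if info and info[1] is not None and 0.10 <= info[1] <= 0.35:
                    survivors.add(key)
                    break
    if model in ("AR_HOM", "AR_CHET"):
        survivors |= chet_keys(x=False)
    elif model == "XLR":
        survivors |= chet_keys(x=True)
    return survivors
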