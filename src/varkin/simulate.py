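"""Self-contained synthetic test universes for the pipeline.

Generates a toy genome FASTA, a refGene-dialect gene map with isoforms,
allele-frequency / protein-domain / tissue-expression tables, and
pedigree-linked family VCFs with one causal variant (or compound-het pair)
planted under a chosen inheritance model among several hundred background
variants drawn from Hardy-Weinberg founder genotypes and Mendelian
transmission.  Everything is a pure function of the seed: the same
SimulationSpec produces byte-identical files.

Study-condition defaults: 500 background variants per individual, mean
read depth 30 with +/-3 integer jitter, mosaic alternate-allele fraction
0.20, background population frequencies 5-45% (so a <1% rarity screen
removes essentially all background), planted variants absent from the
allele-frequency table and without rsIDs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core_annotation import GenomeSequence, _classify_snv
from .gene_model import Transcript, load_gene_map
from .vcf_io import (
    SampleCall,
    Variant,
    new_header,
    sort_variants,
    write_vcf,
)

MODELS = ("AD", "AD_denovo", "AR_HOM", "AR_CHET", "XLD", "XLR", "mosaic")

_BASES = "ACGT"


class SimulationError(Exception):
    pass


@dataclass
class SimulationSpec:
    seed: int = 0
    chromosomes: List[Tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 120_000), ("chr2", 120_000), ("chrX", 120_000)]
    )
    n_genes: int = 12
    isoforms_per_gene: int = 2
    n_background_variants: int = 500
    model: str = "AR_CHET"
    planted_gene: Optional[str] = None
    planted_mutation_type: str = "missense"
    mosaic_fraction: float = 0.20
    mean_depth: int = 30
    depth_noise: int = 3

    def __post_init__(self):
        if self.model not in MODELS:
            raise SimulationError(f"unknown model {self.model!r}; choose from {MODELS}")
        names = [c for c, _ in self.chromosomes]
        if not any(n in ("X", "chrX") for n in names):
            raise SimulationError("spec must include a chromosome named X/chrX")


@dataclass
class BackgroundSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    af: float
    rsid: Optional[str]


@dataclass
class Universe:
    directory: Path
    genome_path: Path
    gene_map_path: Path
    af_path: Path
    domain_path: Path
    expression_path: Path
    transcripts: List[Transcript]
    sites: List[BackgroundSite]
    chrom_order: List[str]

    def genome(self) -> GenomeSequence:
        return GenomeSequence(self.genome_path)


@dataclass
class GroundTruth:
    model: str
    family_id: str
    gene: str
    keys: List[Tuple[str, int, str, str]]
    zygosities: Dict[str, Dict[str, str]]  # key-string -> individual -> zygosity

    def to_json(self) -> dict:
        return {
            "model": self.model,
            "family_id": self.family_id,
            "gene": self.gene,
            "keys": [list(k) for k in self.keys],
            "zygosities": self.zygosities,
        }


# ---------------------------------------------------------------------------
# universe

def generate_universe(spec: SimulationSpec, outdir) -> Universe:
    """Write genome, gene map and annotation tables; return their handles."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    # genome
    seqs: Dict[str, str] = {}
    for chrom, length in spec.chromosomes:
        idx = rng.integers(0, 4, size=length)
        seqs[chrom] = "".join(_BASES[i] for i in idx)
    genome_path = outdir / "genome.fa"
    with open(genome_path, "w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    for stale in (outdir / "genome.fa.fai",):
        if stale.exists():
            stale.unlink()

    # genes: round-robin over chromosomes, fixed exon/intron geometry
    chrom_names = [c for c, _ in spec.chromosomes]
    lengths = dict(spec.chromosomes)
    rows = []
    transcripts_meta = []
    per_chrom_counts = {c: 0 for c in chrom_names}
    n_exons, exon_len, intron_len = 4, 150, 400
    span = n_exons * exon_len + (n_exons - 1) * intron_len
    for gi in range(spec.n_genes):
        chrom = chrom_names[gi % len(chrom_names)]
        slot = per_chrom_counts[chrom]
        per_chrom_counts[chrom] += 1
        n_on_chrom = (spec.n_genes + len(chrom_names) - 1) // len(chrom_names)
        spacing = max(span + 2000, (lengths[chrom] - 10_000) // max(1, n_on_chrom))
        tx_start = 3000 + slot * spacing
        if tx_start + span + 600 > lengths[chrom]:
            raise SimulationError(
                f"genes do not fit on {chrom}: need {tx_start + span + 600}, "
                f"have {lengths[chrom]}"
            )
        strand = "+" if gi % 2 == 0 else "-"
        exons = []
        s = tx_start
        for _ in range(n_exons):
            exons.append((s, s + exon_len - 1))
            s += exon_len + intron_len
        tx_end = exons[-1][1]
        cds_start = exons[0][0] + 30
        cds_end = exons[-1][1] - 30
        cds_len = sum(
            max(0, min(e, cds_end) - max(s_, cds_start) + 1) for s_, e in exons
        )
        cds_end -= cds_len % 3
        gene = f"GENE{gi + 1}"
        transcripts_meta.append((gene, chrom, strand, tx_start, tx_end, cds_start, cds_end, exons))
        # reference isoform (all exons) first, then exon-skipping isoforms
        iso_defs = [exons]
        if spec.isoforms_per_gene > 1 and n_exons >= 3:
            skipped = [exons[0], exons[1], exons[3]] if n_exons == 4 else exons[:-1]
            for _ in range(spec.isoforms_per_gene - 1):
                iso_defs.append(skipped)
        for ii, iso_exons in enumerate(iso_defs[: spec.isoforms_per_gene]):
            name = f"NM_{1000 + gi * 10 + ii:06d}"
            exon_starts = ",".join(str(s_ - 1) for s_, _ in iso_exons) + ","
            exon_ends = ",".join(str(e) for _, e in iso_exons) + ","
            rows.append(
                "\t".join(
                    [
                        "0",
                        name,
                        chrom,
                        strand,
                        str(tx_start - 1),
                        str(tx_end),
                        str(cds_start - 1),
                        str(cds_end),
                        str(len(iso_exons)),
                        exon_starts,
                        exon_ends,
                        "0",
                        gene,
                        "cmpl",
                        "cmpl",
                        ",".join("0" for _ in iso_exons) + ",",
                    ]
                )
            )
    gene_map_path = outdir / "genes.refgene.tsv"
    gene_map_path.write_text("\n".join(rows) + "\n")
    transcripts = load_gene_map(gene_map_path)

    # background variant sites (common population variants)
    used: set = set()
    sites: List[BackgroundSite] = []
    genome = GenomeSequence(genome_path)
    i = 0
    while len(sites) < spec.n_background_variants:
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        pos = int(rng.integers(1000, lengths[chrom] - 1000))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = genome.fetch(chrom, pos, pos)
        if ref == "N":
            continue
        alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        af = round(float(rng.uniform(0.05, 0.45)), 4)
        rsid = f"rs{10000 + i}" if rng.random() < 0.8 else None
        sites.append(BackgroundSite(chrom, pos, ref, alt, af, rsid))
        i += 1
    af_path = outdir / "af_table.tsv"
    with open(af_path, "w") as fh:
        for s in sorted(sites, key=lambda s: (chrom_names.index(s.chrom), s.pos)):
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.af}\n")

    # protein domains: one domain per gene's reference transcript
    domain_path = outdir / "domains.tsv"
    with open(domain_path, "w") as fh:
        for tx in transcripts:
            if tx.is_reference_isoform:
                fh.write(f"{tx.tx_id}\tDOM_{tx.gene}\t10\t60\n")

    # tissue expression: housekeeping profile everywhere except the default
    # planted genes, which are strongly kidney-specific
    tissues = ["kidney", "liver", "brain"]
    planted_genes = {_default_target_gene(transcripts, x=False),
                     _default_target_gene(transcripts, x=True)}
    expression_path = outdir / "expression.tsv"
    with open(expression_path, "w") as fh:
        fh.write("gene\t" + "\t".join(tissues) + "\n")
        genes_seen = []
        for tx in transcripts:
            if tx.gene in genes_seen:
                continue
            genes_seen.append(tx.gene)
            if tx.gene in planted_genes:
                vals = [200.0, 8.0, 8.0]
            else:
                base = float(rng.uniform(30, 70))
                vals = [round(base + float(rng.uniform(-5, 5)), 1) for _ in tissues]
            fh.write(tx.gene + "\t" + "\t".join(str(v) for v in vals) + "\n")

    return Universe(
        directory=outdir,
        genome_path=genome_path,
        gene_map_path=gene_map_path,
        af_path=af_path,
        domain_path=domain_path,
        expression_path=expression_path,
        transcripts=transcripts,
        sites=sites,
        chrom_order=chrom_names,
    )


def _default_target_gene(transcripts: List[Transcript], x: bool) -> str:
    for tx in transcripts:
        on_x = tx.chrom.lstrip("chr").upper().endswith("X") or tx.chrom in ("X", "chrX")
        if tx.is_reference_isoform and on_x == x:
            return tx.gene
    raise SimulationError("no suitable target gene in universe")


# ---------------------------------------------------------------------------
# family structures per model

def _family_members(model: str) -> List[dict]:
    """(id, sex, affected, father, mother) per model; sexes fixed so X-linked
    models are well-posed."""
    FA = dict(iid="FA", sex="1", fa="0", mo="0")
    MO = dict(iid="MO", sex="2", fa="0", mo="0")
    if model == "AD":
        return [
            {**FA, "pheno": "2"},
            {**MO, "pheno": "1"},
            dict(iid="C1", sex="1", fa="FA", mo="MO", pheno="2"),
        ]
    if model in ("AD_denovo", "mosaic"):
        return [
            {**FA, "pheno": "1"},
            {**MO, "pheno": "1"},
            dict(iid="C1", sex="1", fa="FA", mo="MO", pheno="2"),
        ]
    if model in ("AR_HOM", "AR_CHET"):
        return [
            {**FA, "pheno": "1"},
            {**MO, "pheno": "1"},
            dict(iid="C1", sex="1", fa="FA", mo="MO", pheno="2"),
            dict(iid="C2", sex="2", fa="FA", mo="MO", pheno="2"),
        ]
    if model == "XLD":
        return [
            {**FA, "pheno": "1"},
            {**MO, "pheno": "2"},
            dict(iid="C1", sex="2", fa="FA", mo="MO", pheno="2"),
        ]
    if model == "XLR":
        return [
            {**FA, "pheno": "1"},
            {**MO, "pheno": "1"},
            dict(iid="C1", sex="1", fa="FA", mo="MO", pheno="2"),
            dict(iid="C2", sex="1", fa="FA", mo="MO", pheno="1"),
        ]
    raise SimulationError(f"unknown model {model!r}")


# planted genotype plans: individual -> allele count (autosome: 0/1/2,
# X male: 0 or 1 haploid copy)
def _planted_plan(model: str, mosaic: bool = False) -> List[Dict[str, int]]:
    if model == "AD":
        return [dict(FA=1, MO=0, C1=1)]
    if model == "AD_denovo":
        return [dict(FA=0, MO=0, C1=1)]
    if model == "AR_HOM":
        return [dict(FA=1, MO=1, C1=2, C2=2)]
    if model == "AR_CHET":
        return [dict(FA=1, MO=0, C1=1, C2=1), dict(FA=0, MO=1, C1=1, C2=1)]
    if model == "XLD":
        return [dict(FA=0, MO=1, C1=1)]
    if model == "XLR":
        return [dict(FA=0, MO=1, C1=1, C2=0)]  # C1 hemizygous alt
    if model == "mosaic":
        return [dict(FA=0, MO=0, C1=1)]  # sub-het fraction in C1
    raise SimulationError(model)


def _find_coding_snvs(
    tx: Transcript, genome: GenomeSequence, wanted: str, count: int
) -> List[Tuple[int, str, str]]:
    """(pos, ref, alt) tuples in distinct codons classifying as ``wanted``."""
    cp = tx.cds_positions()
    out: List[Tuple[int, str, str]] = []
    used_codons: set = set()
    for idx in range(9, len(cp) - 9):
        codon = idx // 3
        if codon in used_codons:
            continue
        pos = cp[idx]
        ref = genome.fetch(tx.chrom, pos, pos)
        for alt in _BASES:
            if alt == ref:
                continue
            fn = _classify_snv(tx, pos, ref, alt, genome)
            if fn.mutation_type == wanted:
                out.append((pos, ref, alt))
                used_codons.add(codon)
                break
        if len(out) >= count:
            return out
    raise SimulationError(
        f"could not find {count} {wanted!r} site(s) in {tx.tx_id}"
    )


# ---------------------------------------------------------------------------
# family simulation

def simulate_family(
    spec: SimulationSpec, universe: Universe, outdir, family_id: str = "F1"
) -> Tuple[List[Path], Path, GroundTruth]:
    """Write per-individual VCFs, a PED file and the ground truth.

    Founder background genotypes are drawn from the allele-frequency table
    under Hardy-Weinberg; offspring receive one random allele per parent
    (X-aware: sons take a single maternal X allele).  Planted genotypes are
    written exactly as the model dictates; allele depths are integer draws
    around the mean depth, with heterozygous calls split evenly and the
    mosaic call computed to hit the target fraction exactly when the depth
    noise is zero.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 104_729)
    genome = universe.genome()
    members = _family_members(spec.model)
    ids = [m["iid"] for m in members]
    sex = {m["iid"]: m["sex"] for m in members}

    x_target = spec.model in ("XLD", "XLR")
    target_gene = spec.planted_gene or _default_target_gene(universe.transcripts, x=x_target)
    target_tx = next(
        tx
        for tx in universe.transcripts
        if tx.gene == target_gene and tx.is_reference_isoform
    )
    n_planted = 2 if spec.model == "AR_CHET" else 1
    wanted = spec.planted_mutation_type
    planted_sites = _find_coding_snvs(target_tx, genome, wanted, n_planted)
    planted_positions = {(s[0]) for s in planted_sites}
    plans = _planted_plan(spec.model)

    # background genotypes: allele-count per individual per site
    genos: Dict[Tuple[str, int], Dict[str, int]] = {}
    ploidy = {}
    for site in universe.sites:
        if (site.chrom, site.pos) in (
            {(target_tx.chrom, p) for p in planted_positions}
        ):
            continue
        on_x = site.chrom.lstrip("chr").upper() == "X"
        per: Dict[str, int] = {}
        pl: Dict[str, int] = {}
        founders = [m for m in members if m["fa"] == "0"]
        for m in founders:
            if on_x and sex[m["iid"]] == "1":
                per[m["iid"]] = int(rng.random() < site.af)
                pl[m["iid"]] = 1
            else:
                per[m["iid"]] = int(rng.random() < site.af) + int(rng.random() < site.af)
                pl[m["iid"]] = 2
        for m in members:
            if m["fa"] == "0":
                continue
            fa_g, mo_g = per[m["fa"]], per[m["mo"]]
            mo_allele = _draw_allele(rng, mo_g, pl[m["mo"]])
            if on_x and sex[m["iid"]] == "1":
                per[m["iid"]] = mo_allele
                pl[m["iid"]] = 1
            else:
                fa_allele = _draw_allele(rng, fa_g, pl[m["fa"]])
                per[m["iid"]] = fa_allele + mo_allele
                pl[m["iid"]] = 2
        genos[(site.chrom, site.pos)] = per
        ploidy[(site.chrom, site.pos)] = pl

    # assemble per-individual variant lists
    per_indiv: Dict[str, List[Variant]] = {i: [] for i in ids}
    for site in universe.sites:
        key = (site.chrom, site.pos)
        if key not in genos:
            continue
        for iid in ids:
            g = genos[key][iid]
            if g == 0:
                continue
            per_indiv[iid].append(
                _make_record(
                    site.chrom,
                    site.pos,
                    site.rsid,
                    site.ref,
                    site.alt,
                    iid,
                    g,
                    ploidy[key][iid],
                    spec,
                    rng,
                )
            )

    truth_z: Dict[str, Dict[str, str]] = {}
    keys = []
    for (pos, ref, alt), plan in zip(planted_sites, plans):
        chrom = target_tx.chrom
        keys.append((chrom, pos, ref, alt))
        kstr = f"{chrom}:{pos}:{ref}:{alt}"
        truth_z[kstr] = {}
        on_x = chrom.lstrip("chr").upper() == "X"
        for iid in ids:
            g = plan.get(iid, 0)
            pl = 1 if (on_x and sex[iid] == "1") else 2
            truth_z[kstr][iid] = _zyg_name(g, pl, spec.model == "mosaic" and iid == "C1")
            if g == 0:
                continue
            mosaic_here = spec.model == "mosaic" and iid == "C1"
            per_indiv[iid].append(
                _make_record(
                    chrom, pos, None, ref, alt, iid, g, pl, spec, rng,
                    mosaic_fraction=spec.mosaic_fraction if mosaic_here else None,
                    qual=60.0,  # planted calls are well-supported
                )
            )

    # write VCFs + PED
    vcf_paths = []
    ped_lines = []
    for m in members:
        iid = m["iid"]
        variants = sort_variants(per_indiv[iid], universe.chrom_order)
        header = new_header([iid], universe.chrom_order)
        path = outdir / f"{family_id}_{iid}.vcf"
        write_vcf(header, variants, path)
        vcf_paths.append(path)
        ped_lines.append(
            f"{family_id}\t{iid}\t{m['fa']}\t{m['mo']}\t{m['sex']}\t{m['pheno']}\t{path.name}"
        )
    ped_path = outdir / "family.ped"
    ped_path.write_text("\n".join(ped_lines) + "\n")

    truth = GroundTruth(
        model=spec.model,
        family_id=family_id,
        gene=target_gene,
        keys=keys,
        zygosities=truth_z,
    )
    (outdir / "ground_truth.json").write_text(json.dumps(truth.to_json(), indent=2) + "\n")
    return vcf_paths, ped_path, truth


def _draw_allele(rng, geno: int, ploidy: int) -> int:
    if ploidy == 1:
        return geno
    if geno == 0:
        return 0
    if geno == 2:
        return 1
    return int(rng.random() < 0.5)


def _zyg_name(g: int, ploidy: int, mosaic: bool) -> str:
    if mosaic:
        return "HET"
    if g == 0:
        return "HOM_REF"
    if g == ploidy:
        return "HOM_ALT"
    return "HET"


def _make_record(
    chrom: str,
    pos: int,
    rsid: Optional[str],
    ref: str,
    alt: str,
    sample: str,
    geno: int,
    ploidy: int,
    spec: SimulationSpec,
    rng,
    mosaic_fraction: Optional[float] = None,
    qual: Optional[float] = None,
) -> Variant:
    noise = int(rng.integers(-spec.depth_noise, spec.depth_noise + 1)) if spec.depth_noise else 0
    depth = max(4, spec.mean_depth + noise)
    if mosaic_fraction is not None:
        alt_d = int(round(depth * mosaic_fraction))
    elif ploidy == 1 or geno == ploidy:
        alt_d = depth
    else:
        alt_d = depth // 2
    ref_d = depth - alt_d
    if ploidy == 1:
        gt = "1"
    else:
        gt = "0/1" if geno == 1 else "1/1"
    if qual is None:
        qual = float(int(rng.integers(5, 90)))
    call = SampleCall({"GT": gt, "AD": f"{ref_d},{alt_d}", "DP": str(depth), "GQ": "99"})
    return Variant(
        chrom=chrom,
        pos=pos,
        id=rsid,
        ref=ref,
        alt=[alt],
        qual=qual,
        filter_field="PASS",
        info={},
        format_keys=["GT", "AD", "DP", "GQ"],
        calls={sample: call},
    )


# ---------------------------------------------------------------------------
# one-call convenience: universe + family + ready-to-run pipeline config

def simulate_model_directory(
    model: str, seed: int, outdir, n_background: int = 500, **spec_kwargs
) -> dict:
    """Generate a complete, ready-to-run analysis directory for one model.

    Returns a dict with universe, truth, and the written config path."""
    spec = SimulationSpec(
        seed=seed, model=model, n_background_variants=n_background, **spec_kwargs
    )
    outdir = Path(outdir)
    universe = generate_universe(spec, outdir)
    vcfs, ped, truth = simulate_family(spec, universe, outdir)
    from .pipeline import default_model_config, write_config

    config = default_model_config(model, outdir)
    config_path = write_config(config, outdir / "config.yaml")
    return {
        "spec": spec,
        "universe": universe,
        "vcf_paths": vcfs,
        "ped_path": ped,
        "truth": truth,
        "config_path": config_path,
    }
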