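"""Annotate a single variant: gene context, functional change, zygosity.

Builds a toy universe (genome + gene map), takes one exonic SNV from the
planted-site finder, and runs the three mandatory annotators on it.
"""

import tempfile
from pathlib import Path

from varkin import (
    GeneMapParams,
    SampleCall,
    Variant,
    annotate_functions,
    annotate_genes,
    assign_zygosity,
    build_region_map,
)
from varkin.core_annotation import GenomeSequence
from varkin.simulate import SimulationSpec, generate_universe

with tempfile.TemporaryDirectory() as tmp:
    universe = generate_universe(SimulationSpec(seed=0, n_background_variants=10), tmp)
    genome = GenomeSequence(universe.genome_path)
    rmap = build_region_map(universe.transcripts, GeneMapParams(promoter_bp=500, splice_bp=5))

    tx = universe.transcripts[0]            # reference isoform of GENE1
    pos = tx.cds_positions()[30]            # a coding base (c.31)
    ref = genome.fetch(tx.chrom, pos, pos)
    alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
    v = Variant(tx.chrom, pos, None, ref, [alt], 60.0, "PASS", {},
                ["GT", "AD", "DP"],
                {"S1": SampleCall({"GT": "0/1", "AD": "14,15", "DP": "29"})})

    (v,) = annotate_genes([v], rmap)
    annotate_functions([v], genome)
    zyg = assign_zygosity(v)

    print(f"variant {v.chrom}:{v.pos} {v.ref}>{v.alt[0]}")
    for ann, fn in zip(v.annotations, v.functional):
        print(f"  {ann.gene} {ann.tx_id:<12} {ann.region:<8} "
              f"{fn.cdna_change:<12} {fn.protein_change or '-':<8} {fn.mutation_type}")
    print(f"  zygosity: {zyg['S1'].value} (alt fraction 15/29 = {15/29:.2f})")

# One line per overlapping isoform: the variant is exonic in both isoforms
# of GENE1, and the codon substitution is classified independently per
# transcript; the alt-allele base count places the sample in the HET band.
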