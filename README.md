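# varkin

Inheritance-aware annotation and filtering of family VCF files.

When a Mendelian disorder segregates in a family, the causal variant is a
needle in a haystack of tens of thousands of exome calls per individual.
`varkin` finds it by combining three things: (i) VCF-preserving core
annotation — gene context, codon-level functional change, and zygosity
recomputed from raw allele base counts; (ii) a battery of chainable
filters (genomic location, call quality, read depth, population rarity,
novelty, mutation type, and cross-file same-variant / same-gene filters);
and (iii) trait-penetrance models that exploit the pedigree itself:
autosomal dominant (including de novo), autosomal recessive with both
homozygous and compound-heterozygous paths, X-linked dominant and
recessive with proper hemizygous-male handling, and mosaicism via an
allele-fraction window.  A provenance-hashed pipeline engine chains the
stages, emits valid VCF at every step, resumes without recomputation, and
renders an interactive HTML/TSV report.  A synthetic-data module builds
complete toy universes (genome, gene map with isoforms, population
frequencies, family VCFs) with planted causal variants for every model,
so the whole system is testable offline.

## The models

Zygosity is assigned from base counts alone: with alternate-allele
fraction *f* = alt/(ref+alt), a sample is HOM_REF for *f* < 0.15, HET for
0.15 ≤ *f* ≤ 0.85, HOM_ALT for *f* > 0.85 (configurable; GT is the
fallback when depths are absent).

Under complete penetrance the models reduce to genotype constraints over
the pedigree, applied per variant key (chrom, pos, ref, alt):

- **AD** — every affected carries the allele ({HET, HOM} ↦ {HET, HOM});
  no unaffected carries it; when an affected's parents are genotyped, an
  *affected* parent must also carry it.  In **de novo** mode the variant
  must instead be absent (HOM_REF) from all unaffected controls.
- **AR, homozygous path** — {HET/HET} ↦ HOM: affecteds are HOM_ALT,
  genotyped parents are HET carriers, no unaffected control is HOM_ALT.
- **AR, compound-heterozygous path** — {HET1/HET2} ↦ {HET1+HET2}: two
  distinct variants in one gene, each HET in every affected, of opposite
  parental origin, with no single parent carrying both (such a parent
  would be an unaffected compound heterozygote).
- **XD / XR** — the same logic on the X chromosome; a male carries only
  one X, so any alt-carrying male call counts as hemizygous (treated as
  homozygous, exempt from compound-het pairing), and an unaffected male
  carrier eliminates a recessive candidate outright.
- **Mosaic** — post-zygotic mutations appear at sub-heterozygous allele
  fractions; a variant survives if *f* lies in a closed window (default
  0.10–0.35) in at least one affected sample.

Per-transcript annotations are stored *in line*: one VCF line per variant
always, with pipe-delimited, index-aligned INFO arrays (`VK_GENE`,
`VK_TX`, `VK_REGION`, `VK_CDNA`, `VK_MUT`, `VK_PROT`, …) carrying one
element per overlapping transcript.

## Worked example

`examples/03_compound_het_quad.py` simulates a quad (two affected
siblings, two carrier parents) with 500 background variants per
individual and a compound-het pair planted in one gene, then runs the
full pipeline:

```
planted compound-het gene: GENE1
  planted variant chr1:3039 A>C
  planted variant chr1:3042 A>G
stage 1 sort             836 ->   836 variants
stage 2 add_genes        836 ->    94 variants
stage 3 add_function      94 ->    94 variants
stage 4 add_zygosity      94 ->    94 variants
stage 5 inheritance       94 ->     6 variants

report rows mentioning the planted gene:
  chr1  3039  .  GENE1  exon  c.10A>C  p.I4L  missense
  chr1  3042  .  GENE1  exon  c.13A>G  p.R5G  missense
```

Gene annotation discards wholly intergenic calls (836 → 94 across the
four files); the autosomal recessive filter reduces the rest to the
planted pair (each variant appears once per overlapping isoform in the
report, tagged with its partner key in the compound-het gene).  The other
examples cover single-variant annotation, filter chaining, the mosaic
window, and resume semantics; each prints what its numbers mean.

A thin CLI wraps the same machinery:

```
varkin simulate --model AR_CHET --seed 1 --out sim_dir
varkin run sim_dir/config.yaml
varkin resume sim_dir/config.yaml
```

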