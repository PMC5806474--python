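# Methods

## Scope and design

`varkin` analyses small-family sequencing studies: one single-sample VCF
per individual, linked by a PED pedigree, annotated against a reference
genome FASTA and a refGene-style transcript table, and filtered down to
candidate causal variants under an explicit inheritance model.  The
guiding constraint is VCF preservation: every stage consumes and emits
valid VCF so results can be extracted, inspected or diffed at any point,
and unknown INFO/FORMAT keys pass through verbatim.  Foreign annotations
from other tools are ignored (left untouched, never consumed); the
package's own `VK_*` keys from a previous run are recognized and
regenerated rather than duplicated, so annotation is idempotent.

## Coordinates and the gene map

All internal coordinates are 1-based inclusive (the VCF convention);
UCSC's 0-based half-open refGene coordinates are converted once at load.
Chromosome names are compared after stripping any `chr` prefix so VCF,
gene map and FASTA dialects interoperate.

A transcript is expanded into disjoint region intervals:

- exonic bases inside the CDS are `exon`; exonic bases outside it are
  `utr5`/`utr3` by strand.  Non-coding transcripts (encoded, as in
  refGene, by `cds_start == cds_end`) need no special case: all their
  exonic bases fall on one side of the empty CDS point and receive UTR
  labels from the same carving.
- the first `splice_bp` intronic bases after an exon (in transcription
  direction) are `splice_donor`, the last before the next exon
  `splice_acceptor`; the remainder is `intron`.  Splice windows are
  carved out of the intron — exonic bases keep their exon label — which
  is what makes the `c.N+1` numbering of donor-site variants come out
  right.  Defaults: 5 bp essential splice windows.  In pathological
  introns shorter than two windows, the donor takes precedence and the
  acceptor truncates.
- `promoter_up` spans `promoter_bp` (default 500) bases 5' of the
  transcription start, `promoter_down` the same 3' of the transcription
  end, both strand-aware and clipped at position 1.

Disabled region classes are simply absent from the map, so positions
covered only by them look intergenic.  Queries return *all* overlapping
(transcript, region) pairs across genes and isoforms; by construction a
position matches at most one region class per transcript.  A cache key
(`region_map_cache_key`) digests the gene-map file plus parameters so
pre-built maps can be recognized.

cDNA labels are simplified HGVS: `c.N` for coding bases counted in
transcription direction, `c.N+k`/`c.M-k` for intronic bases (nearest
exon boundary wins, ties to the donor side), `c.-k` 5' of the CDS and
`c.*k` 3' of it.  For positions upstream of the transcript the count
continues in genomic bases, so a promoter variant 167 bp upstream of a
UTR-less transcription start is `c.-167`.  Indel labels use a plain
`c.NdelXX`/`c.NinsXX` form without 3'-shifting normalization — full
HGVS normalization is out of proportion for this package and is a
documented limitation.

## Functional classification

For an exonic SNV the reference codon is reconstructed from the CDS
coordinate map and the genome FASTA (reverse-complemented for minus
strand transcripts), the alternate base substituted, and both codons
translated with the standard nuclear code: same residue → synonymous,
alt codon is a stop → nonsense, ref codon was the stop → stoploss,
otherwise missense.  Exonic indels are frameshift when the length delta
is not a multiple of 3, inframe otherwise.  Everything non-exonic is
`noncoding`, but keeps its region and cDNA offset label so splice-site
and promoter hits remain selectable by the mutation-type filter and
searchable in the report.  Two SNVs in one codon are classified
independently (no MNV merging).  If the VCF REF base disagrees with the
FASTA, the annotation is flagged unreliable and a warning emitted —
data are never silently dropped.  Multi-allelic records are classified
per alternate allele and the most severe class is kept per transcript
(severity: frameshift > nonsense > stoploss > missense > inframe >
synonymous > noncoding); a record survives per-allele filters if any
allele passes.

## Zygosity from base counts

Caller GT fields are treated as low-confidence; zygosity is recomputed
from allele depths: *f* = alt/(ref+alt) with HOM_REF below 0.15, HET in
[0.15, 0.85], HOM_ALT above.  The thresholds are configuration, not
biology: they separate the ordinary HET band (~0.5) from the mosaic
window (0.10–0.35) that the mosaicism filter later selects, while
keeping 0.5 comfortably HET.  Zero or missing depths fall back to GT;
no GT means MISSING.  The result is persisted per sample as a `VKZ`
FORMAT value so downstream stages and resumed runs see it.

## Filters

Thresholds follow the conventions their parameters are written in: call
quality is strict (`qual > 20` drops a variant at exactly 20), allele
frequency is strict (`af < 0.01` drops exactly 1%), read depth is
non-strict (`dp >= min_dp`).  Missing QUAL/DP fail their filters
(conservative, configurable).  Variants absent from the frequency table
are novel and pass the rarity screen by default.  The frequency table
loads lazily one chromosome at a time, bounding memory on large tables.
Same-variant matching is on (chrom, pos, ref, alt) across all case
files; same-gene matching is on gene symbol (not transcript), so
isoform differences cannot break sharing.  All filters are contractions
and idempotent, and single-file predicate filters commute.

## Inheritance models

Filtering operates on a per-family genotype view keyed by variant.  Two
missingness conventions matter: a record absent from an individual's
single-sample VCF means homozygous reference (single-sample VCFs list
non-reference sites only), while an explicit `./.` call is MISSING and
non-informative in controls (it neither rescues nor eliminates),
configurable.  Parents are consulted only when present in the pedigree
*and* genotyped; singleton affecteds degrade to carrier-presence rules,
matching studies that run without parental data.

The dominant filter implements complete penetrance (unaffected carriers
eliminate; an `incomplete_penetrance` flag relaxes this).  The
recessive compound-het path groups HET candidates per gene and accepts
a pair when, with both parents genotyped, one member is paternal and
one maternal and no single parent carries both; with ungenotyped
parents any two affected-shared HETs in a gene qualify, with origin
recorded as unknown.  Parental origin is inferred from genotype
presence, not read-backed phasing.  Unaffected HET carriers are always
permitted in recessive models; homozygous occurrence in a control
eliminates.  On the X chromosome, males are hemizygous: any
alt-carrying call counts as carrying, affected males are exempt from
compound-het pairing, a father never transmits X to a son, and an
unaffected male carrier refutes a recessive candidate.
Pseudoautosomal regions are not special-cased (treated as X) — a known
limitation.  The mosaic window is closed on both ends ("10–35%" read
as an inclusive interval).

## Pipeline engine

The stage list is validated before execution: the three core annotators
must precede any stage that consumes their outputs (mutation-type needs
functional annotation; same-gene, inheritance and extended annotation
need gene context; dominant/recessive models need zygosity), while
purely positional filters such as the rarity screen may legally run
before annotation.  Each stage writes per-individual VCFs into its own
directory, appending a provenance header
`##VK_STAGE=<index>:<name>:<hash>` where the hash digests the stage
name, canonicalized parameters, the content digests of the resource
files the stage reads, and the upstream hash (with the input VCFs and
pedigree digested at the root).  Resume compares expected and recorded
hashes stage by stage: matching stages are skipped by reloading their
outputs, the first mismatch and everything downstream re-runs, and a
corrupted intermediate triggers a re-run with a warning.  Per-stage
hashing was chosen over whole-config matching as the stronger contract:
it localizes invalidation to exactly the affected suffix.

The report consolidates all remaining variants across files into one
row per (variant, transcript annotation) with chromosome, position,
rsID, gene, gene context, cDNA and protein change, functional change,
REF/ISO isoform tag, protein domain, inheritance tag with compound-het
partner keys, and per-individual zygosity cells for cases and controls.
The HTML is static with embedded client-side sorting and substring
search (searching "REF" isolates reference-isoform rows); the TSV is
its machine-readable twin.  A plotting helper renders the per-stage
variant-count waterfall.

## Extended annotation

Isoform context tags each annotation with its RefSeq accession and
REF/ISO flag; the reference isoform is the explicitly marked one or,
absent a marker, the first transcript per gene in map order.  Protein
domains come from a flat TSV (transcript id, domain, aa interval,
boundaries inclusive); the amino-acid position is parsed from the
`p.` change string.  Coordinate-system mismatches between external
domain resources and the internal translation (signal peptides, isoform
offsets) are not reconciled — fixtures and documentation sidestep this.
Expression filtering keeps variants whose annotated genes satisfy a
min/max bound in a chosen tissue; genes absent from the table pass by
default.  Organ specificity is exposed as a derived score (expression
in the target tissue over the mean across tissues, ~1 for housekeeping
profiles) reported for prioritization, not auto-filtered.

## Synthetic data

The simulator emulates the inputs of a small exome study.  Defaults are
the study conditions used throughout the tests: three 120 kb
chromosomes (one X), 12 genes with two isoforms (4 exons of 150 bp,
400 bp introns, CDS trimmed to a codon multiple), 500 background
variants per individual with population frequencies uniform in 5–45%
(so a <1% rarity screen removes essentially all background, mirroring
the sharp reductions such screens produce on real exomes — no numeric
reduction is asserted as an external fact), mean depth 30 with ±3
integer jitter, call qualities uniform in 5–90 with planted calls fixed
at 60, and a mosaic fraction of 0.20.  Founder genotypes are drawn
under Hardy-Weinberg from the frequency table; offspring receive one
random allele per parent, X-aware (sons take a single maternal X
allele, written as a haploid GT).  Planted variants are chosen by
scanning the target gene's CDS for sites whose substitution classifies
as the requested mutation type, are absent from the frequency table and
carry no rsID.  Heterozygous depths split evenly; mosaic depths are
computed to hit the target fraction exactly when depth noise is zero.
All randomness flows through one integer-seeded generator, so a spec is
reproducible byte-for-byte.

What the simulator does *not* model — sequencing error, coverage
dropout, caller artifacts, population structure, recombination,
pseudoautosomal X — bounds what passing tests show: they verify the
logic of annotation and inheritance filtering, not robustness to messy
real-world call sets.

## Verification strategy and problem sizes

Every non-trivial component is checked against an independent oracle:
region queries against a per-base classifier scanning each transcript
(ten random gene maps, every position of every chromosome); codon
classification against Biopython translation over all 64 codons × 3
positions × 4 bases on both strands (1,536 cases); dominant, de novo
and recessive trio decisions against hand-coded truth tables over all
27 zygosity combinations; each filter against its direct predicate on
1,000 random variants and the multi-file filters against set-algebra
oracles over four files; and, end to end, planted-variant recovery for
all seven models at 500 background variants per individual with exact
survivor-set equality against a brute-force enumerator that re-applies
the rules in flat loops.  These sizes keep the full suite and the
acceptance script in the seconds range while leaving every filter real
work to do.  Case-study counts printed for patient cohorts elsewhere
are not reproducible from desk-scale synthetic data and are not
asserted.
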