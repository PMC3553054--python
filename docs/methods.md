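# Methods

This note records the models, conventions and numerical choices behind
`gbskit`, and what the synthetic-data validation does and does not
demonstrate.

## In silico digestion

Recognition patterns are IUPAC strings scanned on the forward strand only
with a regex lookahead, so overlapping degenerate matches each produce a cut
(physical digestion can cut either of two overlapping sites). This is
lossless exactly for degenerate-palindromic patterns; non-palindromic
patterns are rejected rather than silently half-scanned. Bundled enzymes
follow REBASE conventions: ApeKI `GCWGC` cut offset 1, PstI `CTGCAG` offset
5, MseI `TTAA` offset 1. Matches spanning an `N` in the subject never fire.
Coordinates are 0-based half-open everywhere except at the VCF and GFF3
boundaries.

Fragments tile each chromosome exactly. The fraction of fragments in the
amplifiable size window (default 100–400 bp) is computed over *internal*
fragments only: a terminal fragment has a chromosome end on one side, cannot
receive adapters at both ends and is never sequenced in GBS. Terminal
fragments still appear in totals and histograms. Methylation sensitivity is
not modelled, so digest counts are maxima relative to a real (partially
methylated) template.

Selective-base subsetting keeps internal fragments whose insert, read from
either cut end, begins with the 1–2 selective bases. Both ends are eligible
because adapter ligation does not orient fragments; consequently a
dinucleotide retains ~2/16 of fragments rather than 1/16.

## Read model and processing

A read is `barcode + remnant + insert[ + distal remnant + common adapter]`.
Barcode matching is exact; the sample sheet must be prefix-free, which makes
longest-prefix matching unambiguous and mismatch tolerance unnecessary at
desk scale. The remnant check enforces the IUPAC remnant (ApeKI: `C[AT]GC`).
The barcode is removed; the remnant stays — it is genomic sequence needed
for mapping.

Adapter clipping scans for a remnant match followed by adapter evidence: at
least 5 exact bases of the adapter prefix (`AGATCGGAAGAGC`) mid-read, or an
adapter-prefix run of any length flush at the read end. The end-anchored
rule exists because a fragment window ending 1–4 bases short of the read
length otherwise leaves unclippable adapter bases that shift reverse-strand
placements and fabricate heterozygous sites; the behaviour mirrors
cutadapt's anchored-tail trimming. Clipping is idempotent. Reads shorter
than 25 bases or containing `N` are then discarded; "grooming" is
interpreted as FASTQ format validation plus these rules, with no quality
trimming (phred+33 assumed).

## Mapping

The built-in mapper serves desk-scale references: a canonical k-mer index
(k=31) seeded at read offsets 0, k and 2k on both strands, each candidate
extended by direct comparison allowing ≤2 substitutions, no gaps. Three
disjoint seeds guarantee by pigeonhole that any ≤2-substitution read of
length ≥3k keeps a clean seed. A read placing at more than one location is
discarded as ambiguous — never emitted — and reads shorter than k go
unmapped. Indel discovery therefore requires the SAM import path, which
keeps primary, mapped records with MAPQ ≥ 20 (the operationalization of
"unique location"; BWA's uniqueness annotations are aligner-specific) and
preserves I/D cigar runs.

## Genotype calling and filters

Pileups convert cigar I/D runs to indel events anchored at the preceding
matched base (VCF left-anchoring); a read supporting an insertion
contributes the combined `anchor+insert` allele rather than the plain
anchor base. Per sample and site:

- depth < `min_depth` (default 2) → missing;
- two alleles each with ≥2 reads and minor fraction ≥0.2 → heterozygous;
- otherwise homozygous for the majority allele (count ties break toward the
  reference), with a lone second-allele read ignored as sequencing error —
  at GBS depths of 2–10, treating every stray read as evidence would flood
  the matrix with false heterozygotes.

Site filters follow: genotypes under the depth floor are masked missing,
then sites are dropped when the missing fraction exceeds
`max_missing_fraction` (default 0.5) or the minor allele frequency over
non-missing diploid calls falls below `min_maf` (default 0, i.e. off).
Filtering is idempotent. Heterozygote correction replaces every het call
with missing and drops sites that become monomorphic; it is exposed as an
explicit stage because a third of heterozygous GBS calls failed independent
Sanger validation in the motivating experiment, plausibly from paralogous
collapse. Imputation is out of scope; `export_fastphase` writes the matrix
in fastPHASE inp layout for external imputation.

## Effect annotation

GFF3 gene models collapse to one isoform per gene (longest CDS, SnpEff-like)
via gffutils. Categories: splice site (first/last 2 intron bases, SnpEff's
convention), 5'/3' UTR (exonic minus CDS, orientation-aware), exon, intron
within genes; within a 5 kb strand-aware flank of the nearest gene span
boundary (inclusive at exactly 5,000 bp), upstream/downstream as sub-labels
of the intergenic compartment; intergenic otherwise. One category per SNP
via the priority SPLICE > UTR > EXON > INTRON, overlapping genes resolved to
the highest-priority category and then the smallest gene id. Coding effects
splice the CDS in transcription order, reverse-complement minus-strand
genes, apply the first segment's phase, and translate reference vs alternate
codons with the standard genetic code; CDS models whose length is not a
multiple of 3 are flagged partial and excluded. Multi-allelic SNPs report
the worst effect (stop gain > nonsynonymous > synonymous).

## Diversity and trees

Distances are p-distances over genotype calls: differing shared non-missing
sites divided by shared sites, a heterozygote counting 0.5 against either
homozygote and genotypes compared allele-set-wise at multi-allelic sites.
p-distance is the minimal defensible choice where the distance model of the
original PHYLIP-based analysis is unspecified. Neighbor joining is the
classic Saitou–Nei agglomeration; Q-ties break toward the lexicographically
smallest label pair (merged nodes carry their smaller child label), making
output order-independent, and negative branch lengths are clamped to zero
with the deficit moved to the sibling (Kuhner–Felsenstein). Bootstrap
resamples SNP sites with replacement, runs NJ per replicate, and keeps
bipartitions in >50% of replicates (majority rule guarantees compatibility);
supports label internal nodes of the consensus topology, whose branch
lengths are intentionally not assigned. All resampling flows from one seed.

## Synthetic GBS experiments

The generator emulates the structural properties the pipeline depends on:

- **Reference**: random ACGT contigs with concrete recognition-site
  instances planted at exponential spacing (default mean 250 bp, so most
  fragments fall inside the 100–400 bp window; minimum gap one site length
  + 3 bp); spurious matches are removed by rejection resampling, so a
  digest recovers exactly the planted sites.
- **Truth variants**: biallelic SNPs and 1–5 bp indels placed only in
  "capture zones" — inside internal fragments, clear of both recognition
  sites, within read reach of a cut end, at least 55 bp apart (so no read
  spans more than two substitutions, the mapper's tolerance), and only in
  fragments whose insert is ≥64 bp (so any covering read keeps a clean seed
  k-mer). Per sample, genotypes draw from configurable class fractions
  (default 55% hom-ref / 40% hom-alt / 5% het, echoing the observed
  53.3/33.6/4.9 split); an all-reference cohort draw is redrawn because an
  unobserved variant is undiscoverable by construction.
- **Reads**: per sample × internal fragment, depth ~ Poisson(`mean_depth`),
  each read from a random end and strand, `barcode + genomic + adapter`
  truncated to 100 bp, uniform substitution errors across the read.
  Read-through windows cover the full distal recognition site so that the
  junction reads remnant-then-adapter, matching the clipper's model of the
  library chemistry. Per-read provenance (sample, fragment, end, reference
  start, cigar) supports truth SAM emission for the import path.
- **Selective amplification**: fragments are restricted to the selective
  subset while the total read budget is held constant, so retained
  fragments receive proportionally deeper coverage — the mechanism by which
  selective primers raise depth without more sequencing.

**Depth convention.** `mean_depth` is the Poisson mean per fragment; because
reads enter from both cut ends, the mean depth *per variant locus* is about
half that. End-to-end validations quote locus depth (the convention used for
GBS coverage figures) and set `mean_depth` to twice it.

**What passing tests show — and don't.** On error-free reads the pipeline
returns exactly the planted sites with every called genotype equal to truth,
and with 1% substitution error at locus depth 8 it recovers ≥95% of sites
with ≥99% genotype concordance. The generator does not model PCR
duplicates, fragment amplification bias beyond Poisson (a per-fragment
weight hook exists), quality-score error profiles, organellar contamination,
or methylation; real-data performance additionally depends on aligner
behaviour in repetitive genomes, which the unique-mapping filter mitigates
but synthetic contigs barely exercise.

## Validation against published tables

The bundled pilot tables (eight-cultivar read accounting, Sanger validation
counts, selective-amplification run statistics) are inputs; every derived
figure — the 5,535,843 read total, the 98.4%/97.4% validation rates and
376/384 overall, the +38.4% and +9.5% SNP gains, +37% depth gain, and the
18.7%/14.5% reductions at 384-plex — is recomputed by the accounting,
concordance and comparison operations at test/script run time.

## Problem sizes

Synthetic validations use 2 × 30 kb contigs (~240 internal fragments), 8
samples, 200 SNPs and ~16–33 k reads; digestion property checks use ≤50 kb
contigs and a 400 kb genome for the enzyme-ordering check. These sizes give
fragment statistics and coverage distributions indistinguishable in form
from larger genomes while keeping the whole suite fast on one CPU.
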