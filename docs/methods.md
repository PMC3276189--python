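# Methods

## The screening design being modeled

A recessive ENU screen crosses a mutagenized C57BL/6J (B6) G0 male to
FVB/NJ females; G1 males carry one mutagenized B6 chromosome set over an
FVB set. G1 × FVB produces G2 females, half of them carriers, and G2
females are backcrossed to their G1 father so a recessive lesion can
become homozygous in G3 embryos (expected in 1/4 of embryos from carrier
mothers, with complete penetrance assumed throughout). Because the causal
allele sits on B6 DNA while the genomic background segregates B6/FVB,
affected embryos are homozygous B6 around the lesion — the basis of
linkage mapping — and a candidate lesion must be absent from both
unmutagenized parental strains and from the public polymorphism catalog.

## Filter cascade

For each variant site the six multiplexed samples each contribute a
genotype (hom-ref / het / hom-alt / no-call) and a read depth. A site is
*eligible* when the mutant is hom-alt at callable depth. Eligible sites
partition as: in the known-site catalog (allele-specific key match by
default; a position-only mode exists because catalog records do not
always carry the same alt); else alt seen in either background strain at
callable depth; else remaining. Catalog membership takes precedence in
the attribution, but the remaining set equals "in neither" regardless of
filter order, and growing the catalog can only shrink it.

Choices that were genuinely open:

- **Callable depth ≥ 8.** The sequencing experiment's own coverage rule
  ("more than 8-fold") is ambiguous about strictness; we read it as
  at-least-8 and expose `min_depth`.
- **Parental consistency is a soft filter.** A recessive candidate should
  be het in both parents; a confidently hom-ref parent is Mendelian
  evidence against it. But a parent below callable depth (or uncalled)
  must not veto a true candidate — real screens have retained the causal
  gene through exactly this situation — so candidates are labeled
  CONSISTENT / LOW_COVERAGE / INCONSISTENT and only `strict_parental`
  drops the inconsistent ones.
- **Uncallable backgrounds.** A site uncallable in both background
  strains cannot be excluded by them; it stays remaining with a
  `low_background_coverage` flag rather than being silently dropped.

## Functional annotation

One of five classes per SNV — replacement, silent, UTR, intronic,
intergenic — by severity precedence across all overlapping transcripts
(coding in any transcript means coding). Within a CDS the affected codon
is rebuilt from the reference with strand-aware complementation and
translated with the standard genetic code; stop codons print `*`
(e.g. `L159*`). UTR covers exonic-but-not-CDS positions of coding
transcripts and all exons of non-coding transcripts. Intronic variants
within 2 bp of an exon edge carry a near-splice flag; the class itself is
unchanged because the five-class scheme has no splice category. When
overlapping coding transcripts disagree (different frames), the most
severe call wins and ties go to the first transcript in input order, so
results are deterministic. A variant whose stated ref allele contradicts
the reference FASTA is a hard data-integrity error naming the site.

## Segregation tests

Genotypes collapse to the dichotomy hom-alt vs not (matching how such
pedigrees are reported); embryos with unknown genotype, and embryos with
phenotypes that are neither mutant nor wild type ("abnormal"), are
excluded from the table and tallied separately. Under the null the
genotype is independent of phenotype and each embryo is hom-alt with
probability 1/4 (carrier backcross). Two exact computations ship because
more than one defensible formalization of "probability of a pattern at
least this concordant" exists and published per-pedigree probabilities of
this kind rarely state their formula:

- **Binomial product tail.** Discordance is hom-alt in a wild type
  (probability 1/4) or non-hom-alt in a mutant (probability 3/4); the
  reported p is P(total discordance ≤ observed), the tail of a two-group
  Poisson-binomial, summed exactly.
- **One-sided Fisher.** The hypergeometric tail of the 2×2 table with
  margins fixed, toward greater concordance.

Both are computed in log space from `gammaln` log-factorials with
`logsumexp` accumulation; the result carries `log10_p` alongside the
(possibly underflowing) float p, and agrees with exact big-integer
rational arithmetic to better than 1e-12 relative error at pedigree sizes
well past anything a mouse room produces. Anti-monotonicity holds: adding
a concordant embryo never increases either probability, and the fully
concordant pattern minimizes both at fixed group sizes.

## RFLP assay design

For each enzyme the ref-allele and alt-allele flanks are scanned, on both
strands via the IUPAC-aware reverse complement, for recognition-site
matches in windows overlapping the variant position; GAIN means only the
alt allele has a site, LOSS only the ref. Windows extending past the
given flank are not scanned, so callers should provide at least one motif
length minus one base on each side. The default table is HaeIII (GGCC),
MluCI (AATT), SfcI (CTRYAG) and MboI (GATC) — the enzymes that genotyped
the package's worked example — and is user-extensible via TSV. (Where a
source lists "MobI", a nonexistent enzyme, MboI is presumed.)

## Simulator

### Transmission genetics

Chromosomes are haplotype mosaics over origins {mutagenized-B6, FVB};
each meiosis draws a Poisson number of crossovers (default 0.5 per
chromosome, i.e. a 50 cM chromosome) at uniform positions without
interference. The G0 male's ENU load is split between his two homologues
and one recombinant gamete founds the G1, conditioned on transmitting the
causal mutation (a line only exists when it did). G2 carrier females are
drawn by rejection; G3 litters are Poisson-sized (mean 8). Phenotype is
mutant iff homozygous causal (complete penetrance); otherwise a small
spontaneous abnormality rate (0.02) produces the "abnormal" class that
segregation tests must ignore.

### The targeted region and its variants

Only the capture target is materialized as sequence: a 400 kb region
mid-chromosome, standing in for the exome of a mapped interval, with ~12
generated multi-exon genes (random strands, CDS lengths a multiple of 3)
over a random reference. The emitted FASTA uses `chrN:start-end`
sub-region headers (samtools-faidx convention) so all coordinates stay
absolute. Variant sites are drawn inside the capture footprint (exons
± 100 bp padding, the splice-site padding of such array designs):

- 30 ENU point mutations on the G1's mutagenized haplotype, one of them
  the causal replacement lesion (position chosen so the annotator calls
  it REPLACEMENT);
- 400 strain polymorphisms (80% FVB-private — the reference is B6-like —
  of which 58% are also in the known-site catalog, matching the observed
  share of catalog eliminations);
- 100 extra catalog-only records;
- 10 artifact sites (systematic spurious calls) when `error_rate > 0`.

### Observation model

Per sample and site, depth is negative-binomial (mean 30, dispersion 40 —
modest overdispersion; the left tail below 8 reads is ~4e-5, chosen so
that under default conditions the causal site is essentially always
callable, as in a well-powered capture experiment; lower the mean or
dispersion to exercise the low-coverage code paths). Zero depth is a
no-call. Heterozygotes are subject to binomial allele sampling (a het can
be miscalled hom when one allele drops out at low depth — the mechanism
behind the retained-despite-inconsistent-parent scenario), and an
optional per-call miscall rate (default 0.001) randomizes the genotype.
`error_rate=0` gives fully error-free calls and disables artifact sites.
A site enters the emitted VCF when any sample shows the alt allele; the
truth table records every variant's origin and true genotypes.

### Linkage mapping

`genome_scan` models the low-density SNP panel (15 informative markers
per chromosome, evenly spaced, typed in 4 affected embryos): a
chromosome qualifies when all affecteds are homozygous B6 over a
contiguous marker run, and its interval extends from the run to the
nearest discordant flanking markers. `refine_interval` models the
follow-up fine mapping screens perform during stock maintenance: dense
markers (every 100 kb) typed in *all* affected embryos, with the interval
taken as the outer span of shared homozygosity — an interior window where
a single embryo is discordant (a double-crossover island) must not
truncate the candidate region. The coarse scan assigns the chromosome;
the refined interval feeds the interval filter. Under default error-free
conditions the scan reports the causal chromosome in ≈97–99% of runs and
the refined interval contains the causal site in every detected run the
test batches have measured.

### Fixture mode

`fixture_from_tables` lays out any per-line, per-class composition table
as concrete variants on a four-cassette mini-genome (spacer / UTR exon /
intron / poly-GGC CDS / intron / UTR exon / spacer): second-codon-base
substitutions are replacements, third-base substitutions silent, so the
annotator must re-derive every class from coordinates. Catalog membership
is realized in the known-site file, background status as hom-alt calls in
the FVB sample (catalog sites are *also* present in a background strain,
exercising the precedence rule), and the mapped interval covers the first
two cassettes so the region table's inside/outside split is realized
positionally. All calls sit at depth 30 with het parents; infeasible
compositions raise. Closure is the point: running the pipeline on the
fixture must reproduce the input table exactly, which is how the bundled
four-line worked example (2043 sites → 48 remaining → 15 replacement →
1/2/2/1 in-interval candidates) is regenerated from first principles.

## What the synthetic data does and does not show

The generator reproduces the screen's *structure* — Mendelian
transmission with linkage, the six-sample comparative design, coverage
variation, het allele dropout, the distinction between strain
polymorphism and induced mutation — so passing tests demonstrate that the
filtering logic, the mapping logic and the statistics behave correctly
under that structure. It does not model read-level errors, mapping bias
around indels or segmental duplications, capture-efficiency variation
along GC content, contamination, or incomplete penetrance; conclusions
about performance on real sequencing data are correspondingly limited.
Problem sizes in the shipped tests (a 400 kb region, ~550 variant sites,
~50 embryos, 200-screen batches) were chosen as comfortable desk-scale
defaults.

## Numerical and determinism notes

All randomness flows from one `numpy` Generator per simulated screen;
identical config + seed gives byte-identical output files. The cascade
sorts sites by (chrom, pos, alt) so input order never matters. Interval
and gene-model coordinates are 0-based half-open internally; VCF and GFF3
surfaces are 1-based. Probabilities are exact in log space; the only
floating-point comparisons in the package are against explicit
tolerances in tests, never inside the pipeline. Degenerate inputs fail
loudly: empty pedigrees, ref-allele mismatches, infeasible fixture
compositions, missing annotations and malformed gene models all raise
with the offending record named.
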