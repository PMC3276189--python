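# enuscan

Finding the causal point mutation behind a mouse forward-genetic screen is
slow when done by fine mapping and Sanger sequencing alone. `enuscan`
implements the computational side of a faster strategy: sequence the exome
of the linkage-mapped chromosome for **six multiplexed samples at once** —
the affected embryo (*m/m*), its two carrier parents (*+/m*), one
unmutagenized individual from each background strain (C57BL/6J and
FVB/NJ), and a known heterozygous positive control — and let comparative
filtering separate the newly induced lesion from pre-existing strain
variation and sequencing artifacts.

The package is aimed at mouse geneticists running recessive ENU
(*N*-ethyl-*N*-nitrosourea) screens, and at anyone who wants a fully
ground-truthed synthetic test bed for trio-plus-background variant
filtering.

## What it computes

**Filter cascade.** Every SNV that is homozygous alt in the mutant at
callable depth (≥ 8 reads by default) is assigned exactly one elimination
category:

1. `IN_DBSNP` — the (chrom, pos, alt) key is in the known-polymorphism
   catalog;
2. `IN_BACKGROUND_NOT_DBSNP` — the alt allele is called in either
   background strain at callable depth;
3. `REMAINING` — in neither: the candidate pool for the causal mutation.

The three counts partition the homozygous total per functional class
(replacement / silent / UTR / intronic / intergenic, assigned by a
built-in codon-aware annotator), and the `REMAINING` set is further
narrowed to the linkage-mapped interval. Parental genotypes act as a soft
consistency check: a recessive candidate should be *+/m* in both parents,
but a parent with poor coverage is flagged `LOW_COVERAGE`, not discarded.

**Segregation testing.** For a candidate site genotyped across the
breeding pedigree, genotypes collapse to hom-alt vs not, and two exact
tail probabilities quantify how unlikely the observed phenotype–genotype
concordance is under the Mendelian null (each backcross embryo hom-alt
with probability 1/4):

- binomial product: P(total discordance ≤ observed) with per-embryo
  discordance probabilities 3/4 (mutant phenotype) and 1/4 (wild type);
- one-sided Fisher: the hypergeometric tail of the 2×2 table, e.g.
  1/C(258,57) for a perfectly concordant pedigree of 57 mutants and 201
  wild types.

Both are evaluated in log space (no underflow at any realistic pedigree
size). RFLP assay design finds restriction enzymes whose IUPAC
recognition site the variant creates or destroys on either strand.

**Simulator.** A generative model of the whole screen — G0 mutagenized
B6 male × FVB, G1 carrier × FVB, G2 females backcrossed to their G1
father — with Poisson-crossover meiosis, ENU mutations, strain-private
and dbSNP-shared polymorphisms, a negative-binomial depth model and
optional call errors. It emits every input file the pipeline reads (VCF,
GFF3, FASTA, BED, TSV) with a complete truth table, plus a deterministic
fixture mode that lays out any published composition table as actual
coordinates so the pipeline must re-derive the printed counts.

## Worked example

Simulate a screen, then run the full filter pipeline on its emitted
files:

```
$ enuscan simulate --seed 17 -o demo/sim
causal  chr15:45021354:T:C      g06     S71G
...
$ enuscan filter --vcf demo/sim/multiplex.vcf --roles demo/sim/roles.tsv \
    --genes demo/sim/genes.gff3 --ref demo/sim/reference.fa \
    --dbsnp demo/sim/dbsnp.vcf --interval demo/sim/interval.bed -o demo/out
```

`demo/out/interval_candidates.tsv` then contains the surviving
candidates, the seeded lesion among them with consistent parental
genotypes:

```
#chrom  pos       ref alt class        gene aa_change consistency mutant_gt ...
chr15   45002302  T   A   REPLACEMENT  g01  L7*       CONSISTENT  HOM_ALT
chr15   45021354  T   C   REPLACEMENT  g06  S71G      CONSISTENT  HOM_ALT
...
```

The segregation test on the emitted pedigree (12 mutant and 39 wild-type
embryos, fully concordant) prints

```
$ enuscan segregate --pedigree demo/sim/pedigree.tsv --method both
n_discordant    0
p_binomial      7.99226e-13
p_fisher        6.29908e-12
```

i.e. the candidate co-segregates far beyond chance: the binomial product
is (1/4)^12 (3/4)^39 and the Fisher tail is 1/C(51,12).

The bundled worked-example tables (the four-line screen the package ships
as data) rebuild deterministically:

```
$ enuscan fixture -o demo/fx
AB5   eligible=744    remaining=12   control=PASS
M2    eligible=221    remaining=15   control=PASS
X5    eligible=1001   remaining=14   control=PASS
Y1    eligible=77     remaining=7    control=PASS
```

— 2043 eligible homozygous sites across the four lines, of which 48
remain after the two comparative filters (15 of them replacement
variants, narrowed to 1/2/2/1 candidates per line by the mapped
intervals).

## Layout

- `src/enuscan/model.py` — domain types (sites, calls, gene models,
  intervals, pedigree records)
- `src/enuscan/io.py` — VCF / BED12 / GFF3 / FASTA / TSV readers and
  writers
- `src/enuscan/annotate.py` — functional classification and amino-acid
  effects
- `src/enuscan/cascade.py` — the dbSNP/background partition, coverage,
  interval and parental filters
- `src/enuscan/segregation.py`, `src/enuscan/rflp.py` — exact
  co-segregation tests and restriction-assay design
- `src/enuscan/simulate.py`, `src/enuscan/fixture.py` — the screen
  simulator, linkage scan and table-driven fixture builder
- `src/enuscan/pipeline.py`, `src/enuscan/cli.py` — orchestration and the
  `enuscan` command

See `docs/methods.md` for the models, defaults and their rationale.
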