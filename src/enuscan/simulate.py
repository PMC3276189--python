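"""Ground-truthed simulation of a recessive ENU mutagenesis screen.

The generator reproduces the screen's breeding design: a mutagenized
C57BL/6J (B6) G0 male is crossed to FVB/NJ, G1 carrier males are crossed
to FVB/NJ again, and G2 females are backcrossed to their G1 fathers so a
recessive ENU lesion can become homozygous in G3 embryos. Chromosomes are
transmitted as recombinant mosaics (Poisson crossovers, uniform positions,
no interference), so the causal allele co-segregates with B6 DNA around
its locus and a low-density marker panel can map the linked chromosome
from a handful of affected embryos.

Variation inside the targeted exome region comes in five flavours with
known truth: ENU-induced point mutations (on the G1's mutagenized B6
haplotype, one of them causal), B6- and FVB-private strain polymorphisms,
polymorphisms shared with the known-site catalog (dbSNP), and sequencing
artifacts. Observed genotypes are derived from truth through a
negative-binomial depth model, binomial allele sampling of heterozygotes,
and an optional per-genotype miscall rate; setting ``error_rate=0``
switches the generator to error-free calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import io as eio
from .annotate import classify_variant
from .io import ReferenceSequence
from .model import (
    AnnotatedVariant,
    FunctionalClass,
    Genotype,
    GeneModel,
    KnownSiteIndex,
    MappedInterval,
    MultiplexCallSet,
    MultiplexSite,
    PedGenotype,
    PedigreeRecord,
    Phenotype,
    Role,
    SampleCall,
    VariantSite,
)

log = logging.getLogger(__name__)

# haplotype origins
B6MUT = "B6mut"  # the G1 male's mutagenized B6 chromosome
B6BG = "B6"  # unmutagenized background B6
FVB = "FVB"

# truth-table variant origins
ORIGIN_ENU = "ENU"
ORIGIN_B6 = "B6_PRIVATE"
ORIGIN_FVB = "FVB_PRIVATE"
ORIGIN_DBSNP = "DBSNP_SHARED"
ORIGIN_ERROR = "ERROR"

_BASES = "ACGT"

Hap = Tuple[Tuple[int, int, str], ...]  # (start, end, origin) segments


@dataclass(frozen=True)
class ScreenConfig:
    """Study conditions of one simulated screen.

    Lengths are bp; ``recomb_rate`` is expected crossovers per meiosis per
    chromosome (0.5 = 50 cM). The targeted exome region sits mid-way along
    the causal chromosome and is the only part of the genome with
    materialized sequence, gene models and variant sites; linkage markers
    span every chromosome. The depth model is negative-binomial with the
    given mean and dispersion (size) parameter; ``error_rate`` is the
    per-call miscall probability (0 disables all call errors, including
    artifact sites).
    """

    seed: int = 1
    n_chromosomes: int = 19
    chrom_length_bp: int = 100_000_000
    recomb_rate: float = 0.5
    n_markers_per_chrom: int = 15
    region_length_bp: int = 400_000
    region_offset_frac: float = 0.45
    causal_chrom: Optional[int] = None
    n_genes: int = 12
    n_enu_mutations: int = 30
    enu_spectrum: Optional[Mapping[str, float]] = None  # e.g. {"A>G": 2.0, ...}
    n_strain_polymorphisms: int = 400
    fraction_in_dbsnp: float = 0.58
    fraction_fvb: float = 0.8
    n_dbsnp_extra: int = 100
    n_error_sites: int = 10
    error_rate: float = 0.001
    depth_mean: float = 30.0
    depth_dispersion: float = 40.0
    n_litters: int = 6
    litter_size_mean: float = 8.0
    abnormal_rate: float = 0.02
    n_scan_embryos: int = 4
    fine_marker_spacing_bp: int = 100_000

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes", "chrom_length_bp", "n_markers_per_chrom",
            "region_length_bp", "n_genes", "n_enu_mutations",
            "n_strain_polymorphisms", "n_dbsnp_extra", "n_error_sites",
            "n_litters", "n_scan_embryos",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("fraction_in_dbsnp", "fraction_fvb", "error_rate",
                     "abnormal_rate", "region_offset_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.causal_chrom is not None and not (
            0 <= self.causal_chrom < self.n_chromosomes
        ):
            raise ValueError("causal_chrom outside chromosome range")
        region_end = (
            int(self.region_offset_frac * self.chrom_length_bp)
            + self.region_length_bp
        )
        if region_end > self.chrom_length_bp:
            raise ValueError("targeted region extends past chromosome end")

    @property
    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def region_start(self) -> int:
        return int(self.region_offset_frac * self.chrom_length_bp)


@dataclass(frozen=True)
class TrueVariant:
    """A variant site with its ground-truth origin and genotypes."""

    site: VariantSite
    origin: str
    carrier_origins: FrozenSet[str]
    causal: bool = False
    true_genotypes: Mapping[Role, Genotype] = field(default_factory=dict)


@dataclass(frozen=True)
class MarkerPanel:
    """Linkage-panel marker positions per chromosome (all informative)."""

    positions: Mapping[str, Tuple[int, ...]]
    chrom_lengths: Mapping[str, int]

    def name(self, chrom: str, idx: int) -> str:
        return f"{chrom}_M{idx + 1}"


@dataclass(frozen=True)
class LinkedRegion:
    """One chromosome passing the shared-homozygosity scan."""

    chrom: str
    interval: MappedInterval
    run_start: int  # index of first marker of the shared run
    run_length: int


@dataclass
class SimulatedScreen:
    """Everything the generator knows about one simulated line."""

    config: ScreenConfig
    causal: TrueVariant
    causal_annotation: AnnotatedVariant
    region: MappedInterval
    genes: List[GeneModel]
    ref: ReferenceSequence
    known: KnownSiteIndex
    truth: List[TrueVariant]
    callset: MultiplexCallSet
    control_site: VariantSite
    pedigree: List[PedigreeRecord]
    panel: MarkerPanel
    affected_marker_genotypes: Dict[str, np.ndarray]
    affected_genomes: List["Genome"]
    n_embryos: int
    n_mutant: int

    def emit(self, outdir) -> Dict[str, Path]:
        """Write all pipeline input files; returns name -> path."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        cfg = self.config
        paths = {
            "vcf": out / "multiplex.vcf",
            "roles": out / "roles.tsv",
            "dbsnp": out / "dbsnp.vcf",
            "genes": out / "genes.gff3",
            "reference": out / "reference.fa",
            "interval": out / "interval.bed",
            "pedigree": out / "pedigree.tsv",
            "truth": out / "truth.tsv",
        }
        lengths = {c: cfg.chrom_length_bp for c in cfg.chrom_names}
        eio.write_variant_calls(self.callset, paths["vcf"], contig_lengths=lengths)
        eio.write_roles(self.callset.sample_ids(), paths["roles"])
        _write_known_vcf(self.known, paths["dbsnp"], lengths)
        eio.write_gene_models_gff3(self.genes, paths["genes"])
        eio.write_fasta(self.ref, paths["reference"])
        scan = genome_scan(self.panel, self.affected_marker_genotypes)
        mapped = self.region
        if scan:
            best = max(scan, key=lambda r: r.run_length)
            mapped = refine_interval(self, best.chrom) or best.interval
        eio.write_mapped_interval(mapped, paths["interval"])
        eio.write_pedigree(self.pedigree, paths["pedigree"])
        _write_truth(self.truth, paths["truth"])
        return paths


# ---------------------------------------------------------------------------
# Haplotype mechanics
# ---------------------------------------------------------------------------


def uniform_hap(length: int, origin: str) -> Hap:
    return ((0, length, origin),)


def origin_at(hap: Hap, pos: int) -> str:
    for start, end, origin in hap:
        if start <= pos < end:
            return origin
    raise ValueError(f"position {pos} outside haplotype")


def meiosis(
    hap_a: Hap, hap_b: Hap, length: int, recomb_rate: float, rng: np.random.Generator
) -> Hap:
    """One recombinant gamete: Poisson crossovers, uniform positions."""
    n_x = rng.poisson(recomb_rate)
    cuts = sorted(int(c) for c in rng.integers(1, length, size=n_x))
    current = int(rng.integers(2))
    haps = (hap_a, hap_b)
    bounds = [0] + cuts + [length]
    segments: List[Tuple[int, int, str]] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if lo >= hi:
            current ^= 1
            continue
        for s, e, o in haps[current]:
            a, b = max(s, lo), min(e, hi)
            if a < b:
                if segments and segments[-1][1] == a and segments[-1][2] == o:
                    segments[-1] = (segments[-1][0], b, o)
                else:
                    segments.append((a, b, o))
        current ^= 1
    return tuple(segments)


Genome = List[Tuple[Hap, Hap]]  # one (maternal, paternal) pair per chromosome


def _gamete(genome: Genome, cfg: ScreenConfig, rng: np.random.Generator) -> List[Hap]:
    return [
        meiosis(h1, h2, cfg.chrom_length_bp, cfg.recomb_rate, rng)
        for h1, h2 in genome
    ]


def _b6_dosage(genome: Genome, chrom_idx: int, pos: int) -> int:
    """Copies of mutagenized-B6 origin at a position (pedigree genomes)."""
    h1, h2 = genome[chrom_idx]
    return (origin_at(h1, pos) == B6MUT) + (origin_at(h2, pos) == B6MUT)


# ---------------------------------------------------------------------------
# Region content: reference, gene models, variant sites
# ---------------------------------------------------------------------------


def _random_reference(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=length)])


def _generate_genes(
    rng: np.random.Generator, chrom: str, region_start: int, region_length: int,
    n_genes: int,
) -> List[GeneModel]:
    genes: List[GeneModel] = []
    cursor = region_start
    region_end = region_start + region_length
    for i in range(n_genes):
        cursor += int(rng.integers(1500, 4000))
        utr5 = int(rng.integers(80, 250))
        utr3 = int(rng.integers(80, 250))
        n_cds_exons = int(rng.integers(1, 4))
        cds_len = 3 * int(rng.integers(60, 180))
        chunk = cds_len // n_cds_exons
        chunks = [chunk] * (n_cds_exons - 1) + [cds_len - chunk * (n_cds_exons - 1)]
        introns = [int(rng.integers(300, 1200)) for _ in range(n_cds_exons - 1)]
        exons: List[Tuple[int, int]] = []
        pos = cursor
        for j, c in enumerate(chunks):
            ex_start = pos
            ex_len = c
            if j == 0:
                ex_len += utr5
            if j == n_cds_exons - 1:
                ex_len += utr3
            exons.append((ex_start, ex_start + ex_len))
            pos = ex_start + ex_len
            if j < n_cds_exons - 1:
                pos += introns[j]
        if pos > region_end - 500:
            break
        cds_start = exons[0][0] + utr5
        cds_end = exons[-1][1] - utr3
        strand = "+" if rng.integers(2) == 0 else "-"
        gene_id = f"g{i + 1:02d}"
        genes.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=f"{gene_id}.t1",
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
        cursor = pos
    return genes


CAPTURE_PAD = 100  # bp of padding around each targeted exon


def _capture_footprint(
    genes: Sequence[GeneModel], region_start: int, region_end: int
) -> np.ndarray:
    """Sorted unique 0-based positions covered by padded-exon capture."""
    chunks = [
        np.arange(max(region_start, s - CAPTURE_PAD), min(region_end, e + CAPTURE_PAD))
        for g in genes
        for s, e in g.exons
    ]
    return np.unique(np.concatenate(chunks))


_DEFAULT_ALTS = {b: [a for a in _BASES if a != b] for b in _BASES}


def _draw_alt(
    ref_base: str, rng: np.random.Generator, spectrum: Optional[Mapping[str, float]]
) -> str:
    alts = _DEFAULT_ALTS[ref_base]
    if not spectrum:
        return alts[int(rng.integers(3))]
    weights = np.array([spectrum.get(f"{ref_base}>{a}", 0.0) for a in alts])
    if weights.sum() <= 0:
        return alts[int(rng.integers(3))]
    return alts[int(rng.choice(3, p=weights / weights.sum()))]


def _pick_causal(
    rng: np.random.Generator,
    genes: Sequence[GeneModel],
    ref: ReferenceSequence,
    chrom: str,
    causal_class: FunctionalClass = FunctionalClass.REPLACEMENT,
) -> Tuple[VariantSite, AnnotatedVariant]:
    coding = [g for g in genes if g.is_coding]
    if not coding:
        raise ValueError("no coding gene available for the causal lesion")
    for _ in range(1000):
        gene = coding[int(rng.integers(len(coding)))]
        intervals = gene.cds_intervals()
        s, e = intervals[int(rng.integers(len(intervals)))]
        pos0 = int(rng.integers(s, e))
        ref_base = ref.base(chrom, pos0)
        for alt in rng.permutation(_DEFAULT_ALTS[ref_base]):
            site = VariantSite(chrom, pos0 + 1, ref_base, str(alt))
            ann = classify_variant(site, genes, ref)
            if ann.func_class is causal_class:
                return site, ann
    raise RuntimeError("could not place a causal lesion of the requested class")


# ---------------------------------------------------------------------------
# Observed-genotype model
# ---------------------------------------------------------------------------

_CALLED = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)


def _observe(
    truth: Genotype, cfg: ScreenConfig, rng: np.random.Generator, artifact: bool
) -> Tuple[Genotype, int]:
    k, m = cfg.depth_dispersion, cfg.depth_mean
    depth = int(rng.negative_binomial(k, k / (k + m)))
    if depth == 0:
        return Genotype.NO_CALL, 0
    geno = truth
    if artifact and cfg.error_rate > 0 and rng.random() < 0.5:
        # systematic mismapping artifact: spurious alt call
        geno = Genotype.HET if rng.random() < 0.5 else Genotype.HOM_ALT
    elif geno is Genotype.HET:
        alt_reads = int(rng.binomial(depth, 0.5))
        if alt_reads == 0:
            geno = Genotype.HOM_REF
        elif alt_reads == depth:
            geno = Genotype.HOM_ALT
    if cfg.error_rate > 0 and rng.random() < cfg.error_rate:
        others = [g for g in _CALLED if g is not geno]
        geno = others[int(rng.integers(2))]
    return geno, depth


# ---------------------------------------------------------------------------
# The screen
# ---------------------------------------------------------------------------


def simulate_screen(config: ScreenConfig) -> SimulatedScreen:
    """Simulate one mutant line end to end; fully determined by the config."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    chroms = cfg.chrom_names
    causal_chrom_idx = (
        cfg.causal_chrom
        if cfg.causal_chrom is not None
        else int(rng.integers(cfg.n_chromosomes))
    )
    chrom = chroms[causal_chrom_idx]
    region_start = cfg.region_start
    region_end = region_start + cfg.region_length_bp
    region = MappedInterval(chrom, region_start, region_end)

    seq = _random_reference(rng, cfg.region_length_bp)
    ref = ReferenceSequence({chrom: seq}, {chrom: region_start})
    genes = _generate_genes(
        rng, chrom, region_start, cfg.region_length_bp, cfg.n_genes
    )

    causal_site, causal_ann = _pick_causal(rng, genes, ref, chrom)

    # Variant sites are ascertained only inside the capture footprint:
    # exons padded by 100 bp (splice-site padding of the array design).
    footprint = _capture_footprint(genes, region_start, region_end)
    n_other = (
        cfg.n_enu_mutations - 1
        + cfg.n_strain_polymorphisms
        + cfg.n_dbsnp_extra
        + cfg.n_error_sites
        + 1  # positive-control site
    )
    if n_other + 1 > len(footprint):
        raise ValueError("capture footprint too small for requested variant load")
    drawn = rng.choice(len(footprint), size=n_other + 1, replace=False)
    pool = [int(footprint[i]) for i in drawn]
    pool = [p for p in pool if p != causal_site.pos - 1][:n_other]

    def take(n: int) -> List[int]:
        taken, rest = pool[:n], pool[n:]
        pool[:] = rest
        return taken

    def make_site(pos0: int, spectrum=None) -> VariantSite:
        ref_base = ref.base(chrom, pos0)
        return VariantSite(chrom, pos0 + 1, ref_base, _draw_alt(ref_base, rng, spectrum))

    enu_sites = [causal_site] + [
        make_site(p, cfg.enu_spectrum) for p in take(cfg.n_enu_mutations - 1)
    ]
    strain_sites = [make_site(p) for p in take(cfg.n_strain_polymorphisms)]
    dbsnp_extra = [make_site(p) for p in take(cfg.n_dbsnp_extra)]
    error_sites = (
        [make_site(p) for p in take(cfg.n_error_sites)] if cfg.error_rate > 0 else []
    )
    control_site = make_site(take(1)[0])

    # G0 transmission: which ENU mutations reach the G1 male
    transmitted = _transmit_from_g0(enu_sites, causal_site, cfg, rng)

    known = KnownSiteIndex()
    variants: List[TrueVariant] = []
    for site in transmitted:
        variants.append(
            TrueVariant(site, ORIGIN_ENU, frozenset({B6MUT}), causal=site is causal_site)
        )
    for site in strain_sites:
        is_fvb = rng.random() < cfg.fraction_fvb
        in_dbsnp = rng.random() < cfg.fraction_in_dbsnp
        carriers = frozenset({FVB}) if is_fvb else frozenset({B6MUT, B6BG})
        origin = ORIGIN_DBSNP if in_dbsnp else (ORIGIN_FVB if is_fvb else ORIGIN_B6)
        if in_dbsnp:
            known.add(site.chrom, site.pos, site.alt_allele)
        variants.append(TrueVariant(site, origin, carriers))
    for site in dbsnp_extra:
        known.add(site.chrom, site.pos, site.alt_allele)
    for site in error_sites:
        variants.append(TrueVariant(site, ORIGIN_ERROR, frozenset()))

    # ---- pedigree ------------------------------------------------------
    g1: Genome = [
        (uniform_hap(cfg.chrom_length_bp, FVB), uniform_hap(cfg.chrom_length_bp, B6MUT))
        for _ in chroms
    ]
    causal_pos0 = causal_site.pos - 1

    def carrier_g2() -> Genome:
        while True:
            paternal = _gamete(g1, cfg, rng)
            if origin_at(paternal[causal_chrom_idx], causal_pos0) == B6MUT:
                return [
                    (uniform_hap(cfg.chrom_length_bp, FVB), p) for p in paternal
                ]

    mothers = [carrier_g2() for _ in range(cfg.n_litters)]
    embryos: List[Tuple[str, str, Genome, Phenotype]] = []
    litters = list(enumerate(mothers, 1))
    extra = 0
    while True:
        embryos.clear()
        eid = 0
        for litter_no, mother in litters:
            size = max(1, int(rng.poisson(cfg.litter_size_mean)))
            for _ in range(size):
                eid += 1
                genome = [
                    (m, p)
                    for m, p in zip(_gamete(mother, cfg, rng), _gamete(g1, cfg, rng))
                ]
                dosage = _b6_dosage(genome, causal_chrom_idx, causal_pos0)
                if dosage == 2:
                    phen = Phenotype.MUTANT
                elif rng.random() < cfg.abnormal_rate:
                    phen = Phenotype.ABNORMAL
                else:
                    phen = Phenotype.WILD_TYPE
                embryos.append((f"E{eid:04d}", f"L{litter_no:02d}", genome, phen))
        n_mut = sum(1 for e in embryos if e[3] is Phenotype.MUTANT)
        if n_mut >= max(1, cfg.n_scan_embryos) or extra >= 20:
            break
        extra += 1
        litters.append((len(litters) + 1, carrier_g2()))

    mutants = [e for e in embryos if e[3] is Phenotype.MUTANT]
    if not mutants:
        raise RuntimeError("no affected embryo produced; increase n_litters")
    proband_id, proband_litter, proband, _ = mutants[0]
    mother_genome = litters[int(proband_litter[1:]) - 1][1]

    b6_sample: Genome = [
        (uniform_hap(cfg.chrom_length_bp, B6BG), uniform_hap(cfg.chrom_length_bp, B6BG))
        for _ in chroms
    ]
    fvb_sample: Genome = [
        (uniform_hap(cfg.chrom_length_bp, FVB), uniform_hap(cfg.chrom_length_bp, FVB))
        for _ in chroms
    ]
    control_sample: Genome = [
        (uniform_hap(cfg.chrom_length_bp, B6BG), uniform_hap(cfg.chrom_length_bp, FVB))
        for _ in chroms
    ]

    sample_genomes: Dict[Role, Genome] = {
        Role.MUTANT: proband,
        Role.MOTHER: mother_genome,
        Role.FATHER: g1,
        Role.BACKGROUND_1: b6_sample,
        Role.BACKGROUND_2: fvb_sample,
        Role.POSITIVE_CONTROL: control_sample,
    }
    sample_ids = {
        Role.MUTANT: "mutant",
        Role.MOTHER: "mother",
        Role.FATHER: "father",
        Role.BACKGROUND_1: "bg_b6",
        Role.BACKGROUND_2: "bg_fvb",
        Role.POSITIVE_CONTROL: "control",
    }

    def true_genotype(genome: Genome, variant: TrueVariant) -> Genotype:
        pos0 = variant.site.pos - 1
        h1, h2 = genome[causal_chrom_idx]
        copies = sum(
            origin_at(h, pos0) in variant.carrier_origins for h in (h1, h2)
        )
        return (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[copies]

    truth: List[TrueVariant] = []
    sites: List[MultiplexSite] = []
    for variant in variants:
        genos = {r: true_genotype(g, variant) for r, g in sample_genomes.items()}
        tv = TrueVariant(
            variant.site, variant.origin, variant.carrier_origins,
            variant.causal, genos,
        )
        truth.append(tv)
        calls = {}
        for role in Role:
            geno, depth = _observe(
                genos[role], cfg, rng, artifact=variant.origin == ORIGIN_ERROR
            )
            calls[role] = SampleCall(sample_ids[role], role, geno, max(depth, 0))
        if any(c.genotype in (Genotype.HET, Genotype.HOM_ALT) for c in calls.values()):
            sites.append(MultiplexSite(variant.site, calls))

    # positive-control heterozygote at its own lesion site
    control_truth = {r: Genotype.HOM_REF for r in Role}
    control_truth[Role.POSITIVE_CONTROL] = Genotype.HET
    calls = {
        role: SampleCall(
            sample_ids[role], role,
            *_observe(control_truth[role], cfg, rng, artifact=False),
        )
        for role in Role
    }
    sites.append(MultiplexSite(control_site, calls))

    causal_truth = next(t for t in truth if t.causal)
    callset = MultiplexCallSet("sim", sites)

    # ---- pedigree records and marker genotypes -------------------------
    pedigree = []
    for embryo_id, litter_id, genome, phen in embryos:
        dosage = _b6_dosage(genome, causal_chrom_idx, causal_pos0)
        geno = (PedGenotype.HOM_REF, PedGenotype.HET, PedGenotype.HOM_ALT)[dosage]
        pedigree.append(PedigreeRecord(embryo_id, litter_id, phen, geno))

    panel = MarkerPanel(
        positions={
            c: tuple(
                (i + 1) * cfg.chrom_length_bp // (cfg.n_markers_per_chrom + 1)
                for i in range(cfg.n_markers_per_chrom)
            )
            for c in chroms
        },
        chrom_lengths={c: cfg.chrom_length_bp for c in chroms},
    )
    scan_embryos = mutants[: cfg.n_scan_embryos]
    affected_genotypes = {
        c: np.array(
            [
                [
                    _b6_dosage(genome, ci, pos)
                    for pos in panel.positions[c]
                ]
                for _, _, genome, _ in scan_embryos
            ],
            dtype=int,
        )
        for ci, c in enumerate(chroms)
    }

    return SimulatedScreen(
        config=cfg,
        causal=causal_truth,
        causal_annotation=causal_ann,
        region=region,
        genes=genes,
        ref=ref,
        known=known,
        truth=truth,
        callset=callset,
        control_site=control_site,
        pedigree=pedigree,
        panel=panel,
        affected_marker_genotypes=affected_genotypes,
        affected_genomes=[genome for _, _, genome, _ in mutants],
        n_embryos=len(embryos),
        n_mutant=len(mutants),
    )


def _transmit_from_g0(
    enu_sites: Sequence[VariantSite],
    causal_site: VariantSite,
    cfg: ScreenConfig,
    rng: np.random.Generator,
) -> List[VariantSite]:
    """Segregate the G0 male's ENU load through one meiosis.

    Mutations are assigned to one of the G0's two (both B6) homologues;
    the gamete that founds the G1 line carries a recombinant subset. The
    draw is conditioned on the causal mutation being transmitted, since
    a line only exists when its lesion reached the pedigree.
    """
    assignment = {s.key: int(rng.integers(2)) for s in enu_sites}
    hap_a = uniform_hap(cfg.chrom_length_bp, "G0A")
    hap_b = uniform_hap(cfg.chrom_length_bp, "G0B")
    labels = ("G0A", "G0B")
    for _ in range(200):
        gamete = meiosis(hap_a, hap_b, cfg.chrom_length_bp, cfg.recomb_rate, rng)
        carried = [
            s
            for s in enu_sites
            if origin_at(gamete, s.pos - 1) == labels[assignment[s.key]]
        ]
        if any(s is causal_site for s in carried):
            return carried
    raise RuntimeError("causal mutation repeatedly untransmitted")


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------


def genome_scan(
    panel: MarkerPanel, affected: Mapping[str, np.ndarray]
) -> List[LinkedRegion]:
    """Shared-homozygosity scan over the linkage panel.

    Reports every chromosome carrying a contiguous marker run at which all
    affected embryos are homozygous for mutagenized-strain (B6) DNA; the
    interval extends from the run's outermost markers to the nearest
    flanking non-concordant marker, or to the chromosome end. Per
    chromosome the longest run wins (leftmost on ties). An empty list
    means the line is unmapped.
    """
    regions: List[LinkedRegion] = []
    for chrom, positions in panel.positions.items():
        geno = np.asarray(affected[chrom])
        if geno.ndim != 2 or geno.shape[1] != len(positions):
            raise ValueError(f"{chrom}: genotype matrix does not match panel")
        shared = (geno == 2).all(axis=0)
        best = _longest_run(shared)
        if best is None:
            continue
        start_idx, run_len = best
        interval = _run_interval(
            panel, chrom, positions, start_idx, run_len
        )
        regions.append(LinkedRegion(chrom, interval, start_idx, run_len))
    return regions


def _longest_run(shared: np.ndarray) -> Optional[Tuple[int, int]]:
    best: Optional[Tuple[int, int]] = None  # (start_idx, length)
    i = 0
    while i < len(shared):
        if shared[i]:
            j = i
            while j + 1 < len(shared) and shared[j + 1]:
                j += 1
            if best is None or (j - i + 1) > best[1]:
                best = (i, j - i + 1)
            i = j + 1
        else:
            i += 1
    return best


def _run_interval(
    panel: Optional[MarkerPanel],
    chrom: str,
    positions: Sequence[int],
    start_idx: int,
    run_len: int,
) -> MappedInterval:
    end_idx = start_idx + run_len - 1
    length = panel.chrom_lengths[chrom] if panel else positions[-1] + 1
    if start_idx > 0:
        start = positions[start_idx - 1]
        prox = panel.name(chrom, start_idx - 1) if panel else None
    else:
        start, prox = 0, None
    if end_idx < len(positions) - 1:
        end = positions[end_idx + 1] + 1
        dist = panel.name(chrom, end_idx + 1) if panel else None
    else:
        end, dist = length, None
    return MappedInterval(chrom, start, end, prox, dist)


def refine_interval(
    screen: "SimulatedScreen", chrom: str, spacing: Optional[int] = None
) -> Optional[MappedInterval]:
    """Fine-map the linked interval with dense markers over all affecteds.

    Models the marker genotyping done during stock maintenance after the
    coarse panel has assigned a chromosome: evenly spaced informative
    markers (``fine_marker_spacing_bp`` apart) are typed in every affected
    embryo, and the interval spans from the first to the last marker of
    shared B6 homozygosity, extended to the flanking discordant markers.
    The span is a conservative outer bound: an interior window where a
    single embryo is discordant (a double-crossover island) does not
    truncate the candidate region. None when no marker is shared
    (unmapped at this density).
    """
    cfg = screen.config
    spacing = spacing or cfg.fine_marker_spacing_bp
    try:
        ci = cfg.chrom_names.index(chrom)
    except ValueError as exc:
        raise ValueError(f"unknown chromosome {chrom}") from exc
    positions = list(range(spacing, cfg.chrom_length_bp, spacing))
    dosage = np.array(
        [
            [_b6_dosage(genome, ci, pos) for pos in positions]
            for genome in screen.affected_genomes
        ],
        dtype=int,
    )
    shared = np.flatnonzero((dosage == 2).all(axis=0))
    if shared.size == 0:
        return None
    start_idx, run_len = int(shared[0]), int(shared[-1] - shared[0] + 1)
    fine_panel = MarkerPanel(
        positions={chrom: tuple(positions)},
        chrom_lengths={chrom: cfg.chrom_length_bp},
    )
    return _run_interval(fine_panel, chrom, positions, start_idx, run_len)


# ---------------------------------------------------------------------------
# Emission helpers
# ---------------------------------------------------------------------------


def _write_known_vcf(known: KnownSiteIndex, path, lengths: Mapping[str, int]) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("source", "enuscan-knownsites")
    chroms = sorted({c for c, _, _ in known})
    for c in chroms:
        header.contigs.add(c, length=lengths.get(c))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c, pos, alt in known:
            ref = next(b for b in _BASES if b != alt)
            rec = out.new_record(contig=c, start=pos - 1, alleles=(ref, alt))
            out.write(rec)


def _write_truth(truth: Sequence[TrueVariant], path) -> None:
    roles = list(Role)
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tpos\tref\talt\torigin\tcausal\t"
            + "\t".join(r.value.lower() for r in roles)
            + "\n"
        )
        for t in sorted(truth, key=lambda t: t.site.key):
            genos = "\t".join(t.true_genotypes[r].value for r in roles)
            fh.write(
                f"{t.site.chrom}\t{t.site.pos}\t{t.site.ref_allele}\t"
                f"{t.site.alt_allele}\t{t.origin}\t{int(t.causal)}\t{genos}\n"
            )
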