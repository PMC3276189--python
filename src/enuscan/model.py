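"""Core domain types for the multiplex ENU-screen pipeline.

The unit of analysis is one mutant line sequenced as a six-sample multiplex:
the affected embryo, its two (obligate carrier) parents, one individual from
each unmutagenized background strain, and a known heterozygous positive
control. All internal coordinates are 0-based half-open; VCF surfaces are
1-based (``VariantSite.pos`` keeps the VCF convention because that is the
key users see in every report).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Tuple

_DNA = frozenset("ACGT")


class Role(str, enum.Enum):
    """The six roles of a multiplexed capture experiment."""

    MUTANT = "MUTANT"
    MOTHER = "MOTHER"
    FATHER = "FATHER"
    BACKGROUND_1 = "BACKGROUND_1"
    BACKGROUND_2 = "BACKGROUND_2"
    POSITIVE_CONTROL = "POSITIVE_CONTROL"


class Genotype(str, enum.Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    NO_CALL = "NO_CALL"


class FunctionalClass(str, enum.Enum):
    """Exhaustive, mutually exclusive functional classes for an SNV.

    Ordered by decreasing severity; the ordering resolves conflicts between
    overlapping transcripts (a variant coding in any transcript is coding).
    """

    REPLACEMENT = "REPLACEMENT"
    SILENT = "SILENT"
    UTR = "UTR"
    INTRONIC = "INTRONIC"
    INTERGENIC = "INTERGENIC"

    @property
    def severity(self) -> int:
        """Smaller is more severe (REPLACEMENT = 0)."""
        return _SEVERITY[self]


_SEVERITY = {
    FunctionalClass.REPLACEMENT: 0,
    FunctionalClass.SILENT: 1,
    FunctionalClass.UTR: 2,
    FunctionalClass.INTRONIC: 3,
    FunctionalClass.INTERGENIC: 4,
}


class Category(str, enum.Enum):
    """Elimination category of an eligible homozygous variant."""

    IN_DBSNP = "IN_DBSNP"
    IN_BACKGROUND_NOT_DBSNP = "IN_BACKGROUND_NOT_DBSNP"
    REMAINING = "REMAINING"


class Consistency(str, enum.Enum):
    """Parental-genotype support for a recessive candidate."""

    CONSISTENT = "CONSISTENT"
    INCONSISTENT = "INCONSISTENT"
    LOW_COVERAGE = "LOW_COVERAGE"


class Phenotype(str, enum.Enum):
    WILD_TYPE = "WILD_TYPE"
    MUTANT = "MUTANT"
    ABNORMAL = "ABNORMAL"


class PedGenotype(str, enum.Enum):
    """Genotype of a pedigree embryo at one candidate site (RFLP assay)."""

    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True, order=True)
class VariantSite:
    """A biallelic SNV site. ``pos`` is 1-based as in VCF."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("ref_allele", "alt_allele"):
            a = getattr(self, name)
            if len(a) != 1 or a not in _DNA:
                raise ValueError(f"{name} must be a single base in ACGT, got {a!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele and alt_allele must differ")

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt_allele)


@dataclass(frozen=True)
class SampleCall:
    """One sample's genotype call and read depth at one site."""

    sample_id: str
    role: Role
    genotype: Genotype
    depth: int

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.genotype is not Genotype.NO_CALL and self.depth < 1:
            raise ValueError("a called genotype requires depth >= 1")


@dataclass(frozen=True)
class MultiplexSite:
    """A variant site with exactly one call per multiplex role."""

    site: VariantSite
    calls: Mapping[Role, SampleCall]

    def __post_init__(self) -> None:
        if set(self.calls) != set(Role):
            missing = sorted(r.value for r in set(Role) - set(self.calls))
            raise ValueError(f"site {self.site.key} missing roles: {missing}")
        for role, call in self.calls.items():
            if call.role is not role:
                raise ValueError(f"call for role {role} tagged {call.role}")

    def call(self, role: Role) -> SampleCall:
        return self.calls[role]


@dataclass
class MultiplexCallSet:
    """All multiplex calls for one mutant line."""

    line_id: str
    sites: list[MultiplexSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [s.site.key for s in self.sites]
        if len(keys) != len(set(keys)):
            seen, dups = set(), set()
            for k in keys:
                (dups if k in seen else seen).add(k)
            raise ValueError(f"duplicate (chrom,pos,alt) keys: {sorted(dups)}")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[MultiplexSite]:
        return iter(self.sites)

    def sample_ids(self) -> dict[Role, str]:
        if not self.sites:
            return {}
        return {r: c.sample_id for r, c in self.sites[0].calls.items()}

    def sorted(self) -> "MultiplexCallSet":
        return MultiplexCallSet(
            self.line_id, sorted(self.sites, key=lambda s: s.site.key)
        )

    def find(self, site: VariantSite) -> Optional[MultiplexSite]:
        for s in self.sites:
            if s.site.key == site.key:
                return s
        return None


@dataclass(frozen=True)
class GeneModel:
    """One transcript: exon structure plus CDS bounds, 0-based half-open.

    ``cds_start == cds_end`` marks a non-coding transcript.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError("at least one exon required")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"empty exon [{start},{end})")
            if prev_end is not None and start < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = end
        if self.cds_start > self.cds_end:
            raise ValueError("cds_start > cds_end")
        if self.is_coding and not (
            self.tx_start <= self.cds_start and self.cds_end <= self.tx_end
        ):
            raise ValueError("CDS interval outside exon span")

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start

    def contains(self, pos0: int) -> bool:
        return self.tx_start <= pos0 < self.tx_end

    def in_exon(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.exons)

    def in_cds(self, pos0: int) -> bool:
        return (
            self.is_coding
            and self.cds_start <= pos0 < self.cds_end
            and self.in_exon(pos0)
        )

    def cds_intervals(self) -> list[Tuple[int, int]]:
        """Exonic slices of the CDS, genomic order."""
        out = []
        for s, e in self.exons:
            a, b = max(s, self.cds_start), min(e, self.cds_end)
            if a < b:
                out.append((a, b))
        return out

    def splice_distance(self, pos0: int) -> Optional[int]:
        """Distance (bp) from an intronic position to the nearest exon edge.

        Returns None for exonic or non-overlapping positions.
        """
        if not self.contains(pos0) or self.in_exon(pos0):
            return None
        dist = None
        for s, e in self.exons:
            for edge in (s, e - 1):
                d = abs(pos0 - edge)
                dist = d if dist is None else min(dist, d)
        return dist


class KnownSiteIndex:
    """Exact-key membership index over known polymorphisms (a dbSNP subset).

    Keys are (chrom, 1-based pos, alt). Insertion is idempotent. A
    position-only lookup mode supports matching records whose alt allele is
    unknown or differs.
    """

    def __init__(self, records: Iterable[Tuple[str, int, str]] = ()) -> None:
        self._keys: set[Tuple[str, int, str]] = set()
        self._positions: set[Tuple[str, int]] = set()
        for chrom, pos, alt in records:
            self.add(chrom, pos, alt)

    def add(self, chrom: str, pos: int, alt: str) -> None:
        self._keys.add((chrom, pos, alt))
        self._positions.add((chrom, pos))

    def contains(
        self, chrom: str, pos: int, alt: str, allele_specific: bool = True
    ) -> bool:
        if allele_specific:
            return (chrom, pos, alt) in self._keys
        return (chrom, pos) in self._positions

    def __contains__(self, key: Tuple[str, int, str]) -> bool:
        return key in self._keys

    def __len__(self) -> int:
        return len(self._keys)

    def __iter__(self) -> Iterator[Tuple[str, int, str]]:
        return iter(sorted(self._keys))


@dataclass(frozen=True)
class MappedInterval:
    """Chromosomal interval linked to the phenotype, 0-based half-open."""

    chrom: str
    start: int
    end: int
    proximal_marker: Optional[str] = None
    distal_marker: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval [{self.start},{self.end})")

    def contains_site(self, site: VariantSite) -> bool:
        return site.chrom == self.chrom and self.start <= site.pos - 1 < self.end


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant site with its functional annotation.

    Amino-acid fields are populated exactly for coding classes; ``aa_pos``
    is the 1-based codon index and stop codons are written ``*`` (so a
    nonsense lesion reads e.g. L159*).
    """

    site: VariantSite
    func_class: FunctionalClass
    gene_id: Optional[str] = None
    aa_ref: Optional[str] = None
    aa_alt: Optional[str] = None
    aa_pos: Optional[int] = None
    near_splice: bool = False

    def __post_init__(self) -> None:
        coding = self.func_class in (
            FunctionalClass.REPLACEMENT,
            FunctionalClass.SILENT,
        )
        if (self.gene_id is None) != (self.func_class is FunctionalClass.INTERGENIC):
            raise ValueError("gene_id must be None iff class is INTERGENIC")
        have_aa = all(x is not None for x in (self.aa_ref, self.aa_alt, self.aa_pos))
        if coding != have_aa:
            raise ValueError("aa fields populated iff class is coding")
        if coding:
            if (self.aa_ref != self.aa_alt) != (
                self.func_class is FunctionalClass.REPLACEMENT
            ):
                raise ValueError("REPLACEMENT iff aa_ref != aa_alt")

    @property
    def aa_change(self) -> str:
        """Compact amino-acid change notation, e.g. ``L159*``; '.' if non-coding."""
        if self.aa_ref is None:
            return "."
        return f"{self.aa_ref}{self.aa_pos}{self.aa_alt}"


@dataclass(frozen=True)
class PedigreeRecord:
    """One genotyped embryo from the breeding pedigree."""

    embryo_id: str
    litter_id: str
    phenotype: Phenotype
    genotype: PedGenotype
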