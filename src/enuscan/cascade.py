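"""The two-stage comparative filter for candidate recessive mutations.

A causative ENU lesion must be homozygous in the affected embryo at
callable depth, absent from the known-polymorphism catalog (dbSNP), and
absent from both unmutagenized background strains. Eligible homozygous
variants are partitioned into three mutually exclusive categories —
IN_DBSNP, IN_BACKGROUND_NOT_DBSNP, REMAINING — tabulated per functional
class, and the REMAINING set is optionally narrowed by functional class
and by the linkage-mapped interval. Parental genotypes act as a soft
consistency check by default: a recessive candidate should be
heterozygous in both parents, but a parent with poor coverage must not
cost a true candidate, so inconsistent sites are flagged rather than
dropped unless ``strict_parental`` is set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .model import (
    AnnotatedVariant,
    Category,
    Consistency,
    FunctionalClass,
    Genotype,
    KnownSiteIndex,
    MappedInterval,
    MultiplexCallSet,
    Role,
    SampleCall,
    VariantSite,
)

log = logging.getLogger(__name__)

DEFAULT_MIN_DEPTH = 8


@dataclass(frozen=True)
class CascadeOptions:
    """Tunable thresholds of the cascade.

    min_depth
        Callable-site depth threshold (reads); a genotype below it is
        treated as uncallable.
    strict_parental
        Drop candidates whose parental genotypes are Mendelian-impossible
        for a recessive causal site (default: flag only).
    require_class
        Restrict the candidate list to one functional class.
    interval
        Restrict the candidate list to the linkage-mapped interval.
    dbsnp_allele_specific
        Match the known-site catalog on (chrom, pos, alt) rather than
        position alone.
    """

    min_depth: int = DEFAULT_MIN_DEPTH
    strict_parental: bool = False
    require_class: Optional[FunctionalClass] = None
    interval: Optional[MappedInterval] = None
    dbsnp_allele_specific: bool = True

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass(frozen=True)
class Candidate:
    """A REMAINING variant with its parental-consistency evidence."""

    variant: AnnotatedVariant
    consistency: Consistency
    genotypes: Mapping[Role, SampleCall]
    low_background_coverage: bool = False

    @property
    def site(self) -> VariantSite:
        return self.variant.site


@dataclass
class CandidateSet:
    """Ordered surviving candidates for one line."""

    line_id: str
    candidates: list[Candidate] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def sites(self) -> list[VariantSite]:
        return [c.site for c in self.candidates]


class FilterSummary:
    """Per-class x per-category counts of eligible homozygous variants.

    The machine form of the published filtering table: for every class,
    total = IN_DBSNP + IN_BACKGROUND_NOT_DBSNP + REMAINING.
    """

    def __init__(self, line_id: str) -> None:
        self.line_id = line_id
        self._counts: dict[Tuple[FunctionalClass, Category], int] = {
            (fc, cat): 0 for fc in FunctionalClass for cat in Category
        }

    def increment(self, func_class: FunctionalClass, category: Category) -> None:
        self._counts[(func_class, category)] += 1

    def count(self, func_class: FunctionalClass, category: Category) -> int:
        return self._counts[(func_class, category)]

    def total(self, func_class: Optional[FunctionalClass] = None) -> int:
        classes = [func_class] if func_class else list(FunctionalClass)
        return sum(self._counts[(fc, c)] for fc in classes for c in Category)

    def category_total(self, category: Category) -> int:
        return sum(self._counts[(fc, category)] for fc in FunctionalClass)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FilterSummary)
            and self.line_id == other.line_id
            and self._counts == other._counts
        )

    def __add__(self, other: "FilterSummary") -> "FilterSummary":
        out = FilterSummary(f"{self.line_id}+{other.line_id}" if self.line_id else other.line_id)
        for key in out._counts:
            out._counts[key] = self._counts[key] + other._counts[key]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fc in FunctionalClass:
            rows.append(
                {
                    "line": self.line_id,
                    "functional_class": fc.value,
                    "total_homozygous": self.total(fc),
                    "in_dbsnp": self.count(fc, Category.IN_DBSNP),
                    "in_background_not_dbsnp": self.count(
                        fc, Category.IN_BACKGROUND_NOT_DBSNP
                    ),
                    "remaining": self.count(fc, Category.REMAINING),
                }
            )
        return pd.DataFrame(rows)


def partition_variant(
    v: AnnotatedVariant,
    calls: Mapping[Role, SampleCall],
    known: KnownSiteIndex,
    opts: CascadeOptions = CascadeOptions(),
) -> Optional[Category]:
    """Categorize one annotated variant; None when not eligible.

    Eligibility requires the mutant to be HOM_ALT at callable depth.
    dbSNP membership takes precedence over background-strain presence
    (the second column of the published table is "in background strains,
    *not* in dbSNP"); the REMAINING set is independent of that ordering.
    """
    mutant = calls[Role.MUTANT]
    if mutant.genotype is not Genotype.HOM_ALT or mutant.depth < opts.min_depth:
        return None
    site = v.site
    if known.contains(
        site.chrom, site.pos, site.alt_allele, allele_specific=opts.dbsnp_allele_specific
    ):
        return Category.IN_DBSNP
    for role in (Role.BACKGROUND_1, Role.BACKGROUND_2):
        call = calls[role]
        if (
            call.genotype in (Genotype.HET, Genotype.HOM_ALT)
            and call.depth >= opts.min_depth
        ):
            return Category.IN_BACKGROUND_NOT_DBSNP
    return Category.REMAINING


def backgrounds_uncallable(
    calls: Mapping[Role, SampleCall], opts: CascadeOptions
) -> bool:
    """True when neither background strain is callable at the site."""
    return all(
        calls[r].genotype is Genotype.NO_CALL or calls[r].depth < opts.min_depth
        for r in (Role.BACKGROUND_1, Role.BACKGROUND_2)
    )


def parental_consistency(
    mother: SampleCall, father: SampleCall, opts: CascadeOptions = CascadeOptions()
) -> Consistency:
    """Judge whether parental genotypes fit a recessive causal candidate.

    CONSISTENT: both parents heterozygous at callable depth. LOW_COVERAGE:
    either parent uncallable (the benefit of the doubt a poorly covered
    parent earns). INCONSISTENT: a confidently called non-het parent.
    """
    calls = (mother, father)
    if all(
        c.genotype is Genotype.HET and c.depth >= opts.min_depth for c in calls
    ):
        return Consistency.CONSISTENT
    if any(
        c.genotype is Genotype.NO_CALL or c.depth < opts.min_depth for c in calls
    ):
        return Consistency.LOW_COVERAGE
    return Consistency.INCONSISTENT


def interval_filter(cands: CandidateSet, interval: MappedInterval) -> CandidateSet:
    """Keep candidates inside the linkage-mapped interval."""
    kept = [c for c in cands if interval.contains_site(c.site)]
    return CandidateSet(cands.line_id, kept)


def run_cascade(
    callset: MultiplexCallSet,
    annotations: Sequence[AnnotatedVariant],
    known: KnownSiteIndex,
    opts: CascadeOptions = CascadeOptions(),
) -> Tuple[CandidateSet, FilterSummary]:
    """Partition, tabulate and filter one line's multiplex calls.

    Returns the candidate set (REMAINING variants surviving the requested
    filters, ordered by chromosome and position) and the per-class
    filtering summary of all eligible homozygous variants.
    """
    ann_by_key = {a.site.key: a for a in annotations}
    missing = [s.site.key for s in callset if s.site.key not in ann_by_key]
    if missing:
        raise ValueError(f"annotation missing for sites: {missing[:5]}")

    summary = FilterSummary(callset.line_id)
    candidates: list[Candidate] = []
    n_eligible = 0
    for ms in sorted(callset.sites, key=lambda s: s.site.key):
        ann = ann_by_key[ms.site.key]
        category = partition_variant(ann, ms.calls, known, opts)
        if category is None:
            continue
        n_eligible += 1
        summary.increment(ann.func_class, category)
        if category is not Category.REMAINING:
            continue
        consistency = parental_consistency(
            ms.calls[Role.MOTHER], ms.calls[Role.FATHER], opts
        )
        if opts.strict_parental and consistency is Consistency.INCONSISTENT:
            continue
        candidates.append(
            Candidate(
                variant=ann,
                consistency=consistency,
                genotypes=dict(ms.calls),
                low_background_coverage=backgrounds_uncallable(ms.calls, opts),
            )
        )

    cands = CandidateSet(callset.line_id, candidates)
    log.info(
        "%s: %d eligible homozygous sites; %d in dbSNP, %d in background, %d remaining",
        callset.line_id,
        n_eligible,
        summary.category_total(Category.IN_DBSNP),
        summary.category_total(Category.IN_BACKGROUND_NOT_DBSNP),
        summary.category_total(Category.REMAINING),
    )
    if opts.require_class is not None:
        cands = CandidateSet(
            cands.line_id,
            [c for c in cands if c.variant.func_class is opts.require_class],
        )
        log.info("%s: %d candidates after class filter", callset.line_id, len(cands))
    if opts.interval is not None:
        cands = interval_filter(cands, opts.interval)
        log.info("%s: %d candidates inside mapped interval", callset.line_id, len(cands))
    return cands, summary


@dataclass(frozen=True)
class ControlReport:
    """Outcome of the positive-control heterozygote check."""

    passed: bool
    reason: str
    genotype: Optional[Genotype] = None
    depth: Optional[int] = None


def positive_control_check(
    callset: MultiplexCallSet,
    control_site: VariantSite,
    opts: CascadeOptions = CascadeOptions(),
) -> ControlReport:
    """Verify the known het control line is recovered at its lesion site."""
    ms = callset.find(control_site)
    if ms is None:
        return ControlReport(False, "not covered")
    call = ms.calls[Role.POSITIVE_CONTROL]
    if call.genotype is Genotype.HET and call.depth >= opts.min_depth:
        return ControlReport(True, "control heterozygote recovered", call.genotype, call.depth)
    return ControlReport(
        False,
        f"control genotype {call.genotype.value} at depth {call.depth}",
        call.genotype,
        call.depth,
    )


def write_candidates(cands: CandidateSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tpos\tref\talt\tclass\tgene\taa_change\tconsistency\t"
            "mutant_gt\tmutant_dp\tmother_gt\tmother_dp\tfather_gt\tfather_dp\t"
            "low_bg_coverage\n"
        )
        for c in cands:
            v, s = c.variant, c.site
            gt = {r: c.genotypes[r] for r in Role}
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\t"
                f"{v.func_class.value}\t{v.gene_id or '.'}\t{v.aa_change}\t"
                f"{c.consistency.value}\t"
                f"{gt[Role.MUTANT].genotype.value}\t{gt[Role.MUTANT].depth}\t"
                f"{gt[Role.MOTHER].genotype.value}\t{gt[Role.MOTHER].depth}\t"
                f"{gt[Role.FATHER].genotype.value}\t{gt[Role.FATHER].depth}\t"
                f"{int(c.low_background_coverage)}\n"
            )


def write_summary(summaries: Iterable[FilterSummary], path) -> None:
    frames = [s.to_frame() for s in summaries]
    df = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
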