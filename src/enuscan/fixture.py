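"""Deterministic fixture screens laid out from published-count tables.

Given per-line, per-class compositions (total homozygous, in dbSNP, in
background strains) and the mapped-region split of the remaining
replacement variants, this builds a synthetic mini-genome per line in
which every composition is realized by actual coordinates: functional
classes arise from real gene models over a constructed reference (the
annotator must re-derive them), dbSNP membership from a real known-site
catalog, and background status from background-sample genotype calls.
Running the annotate + cascade + interval pipeline on the fixture must
therefore reproduce the input tables exactly.

The mini-genome tiles four identical gene cassettes; the mapped interval
covers the first two, so replacement variants can be placed inside or
outside it as the region table dictates. CDS exons are poly-GGC (glycine)
tracts: a substitution at a codon's second base is always a replacement,
at its third base always silent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Tuple

from .io import ReferenceSequence
from .model import (
    FunctionalClass,
    Genotype,
    GeneModel,
    KnownSiteIndex,
    MappedInterval,
    MultiplexCallSet,
    MultiplexSite,
    Role,
    SampleCall,
    VariantSite,
)

Composition = Tuple[int, int, int]  # (total, in_dbsnp, in_background)

# cassette geometry (bp)
_SPACER = 60
_UTR = 120
_INTRON = 60
_CDS = 360  # 120 GGC codons
_CASSETTE = _SPACER + _UTR + _INTRON + _CDS + _INTRON + _UTR + _SPACER  # 840
_N_CASSETTES = 4
_N_INSIDE = 2  # cassettes covered by the mapped interval

_ALT_OF = {"A": "G", "C": "T", "G": "A", "T": "C"}


@dataclass
class LineFixture:
    """One line's fixture: inputs plus the composition it must reproduce."""

    line_id: str
    callset: MultiplexCallSet
    genes: List[GeneModel]
    ref: ReferenceSequence
    known: KnownSiteIndex
    interval: MappedInterval
    control_site: VariantSite
    expected: Dict[FunctionalClass, Composition]
    expected_within_region: int


def _cassette_sequence() -> str:
    spacer = ("ACGT" * (_SPACER // 4 + 1))[:_SPACER]
    utr = ("TACG" * (_UTR // 4 + 1))[:_UTR]
    intron = ("TTAA" * (_INTRON // 4 + 1))[:_INTRON]
    cds = "GGC" * (_CDS // 3)
    return spacer + utr + intron + cds + intron + utr + spacer


def _cassette_gene(line_id: str, idx: int, chrom: str) -> GeneModel:
    base = idx * _CASSETTE
    e1 = (base + _SPACER, base + _SPACER + _UTR)
    cds_start = e1[1] + _INTRON
    e2 = (cds_start, cds_start + _CDS)
    e3_start = e2[1] + _INTRON
    e3 = (e3_start, e3_start + _UTR)
    gene_id = f"{line_id}_g{idx + 1}"
    return GeneModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        chrom=chrom,
        strand="+",
        exons=(e1, e2, e3),
        cds_start=e2[0],
        cds_end=e2[1],
    )


def _class_pools(genes: List[GeneModel]) -> Dict[FunctionalClass, List[int]]:
    """0-based positions per functional class, cassette order (inside first)."""
    pools: Dict[FunctionalClass, List[int]] = {fc: [] for fc in FunctionalClass}
    for idx, g in enumerate(genes):
        base = idx * _CASSETTE
        e1, e2, e3 = g.exons
        cds = range(e2[0], e2[1])
        pools[FunctionalClass.REPLACEMENT] += [p for p in cds if (p - e2[0]) % 3 == 1]
        pools[FunctionalClass.SILENT] += [p for p in cds if (p - e2[0]) % 3 == 2]
        pools[FunctionalClass.UTR] += list(range(e1[0], e1[1])) + list(
            range(e3[0], e3[1])
        )
        # keep > 2 bp off exon edges so no near-splice flag muddies reports
        pools[FunctionalClass.INTRONIC] += list(range(e1[1] + 3, e2[0] - 3)) + list(
            range(e2[1] + 3, e3[0] - 3)
        )
        # leading spacer; position 0 of cassette 1 is reserved for the control
        lead = range(base + (1 if idx == 0 else 0), base + _SPACER)
        pools[FunctionalClass.INTERGENIC] += list(lead)
    return pools


def fixture_from_tables(
    filter_counts: Mapping[str, Mapping[FunctionalClass, Composition]],
    region_splits: Mapping[str, Tuple[int, int]],
    depth: int = 30,
) -> List[LineFixture]:
    """Build one deterministic fixture per line from composition tables.

    ``filter_counts[line][class] = (total, in_dbsnp, in_background)``;
    ``region_splits[line] = (remaining_replacement, within_mapped_region)``.
    Raises ``ValueError`` for infeasible compositions.
    """
    fixtures = []
    for line_id in filter_counts:
        fixtures.append(
            _build_line(
                line_id,
                filter_counts[line_id],
                region_splits.get(line_id),
                depth,
            )
        )
    return fixtures


def _build_line(
    line_id: str,
    comps: Mapping[FunctionalClass, Composition],
    split: Tuple[int, int] | None,
    depth: int,
) -> LineFixture:
    chrom = f"fx_{line_id}"
    seq = _cassette_sequence() * _N_CASSETTES
    ref = ReferenceSequence({chrom: seq})
    genes = [_cassette_gene(line_id, i, chrom) for i in range(_N_CASSETTES)]
    pools = _class_pools(genes)
    interval = MappedInterval(
        chrom, 0, _N_INSIDE * _CASSETTE, proximal_marker=None, distal_marker=None
    )

    for fc, (total, dbsnp, bg) in comps.items():
        if min(total, dbsnp, bg) < 0 or dbsnp + bg > total:
            raise ValueError(f"{line_id}/{fc.value}: infeasible composition")
        if total > len(pools[fc]):
            raise ValueError(
                f"{line_id}/{fc.value}: {total} variants exceed fixture capacity "
                f"{len(pools[fc])}"
            )

    repl_total, repl_dbsnp, repl_bg = comps.get(FunctionalClass.REPLACEMENT, (0, 0, 0))
    repl_remaining = repl_total - repl_dbsnp - repl_bg
    if split is None:
        split = (repl_remaining, repl_remaining)
    if split[0] != repl_remaining:
        raise ValueError(
            f"{line_id}: region table lists {split[0]} remaining replacement "
            f"variants but filter table implies {repl_remaining}"
        )
    n_within = split[1]
    if not 0 <= n_within <= repl_remaining:
        raise ValueError(f"{line_id}: infeasible mapped-region split {split}")

    known = KnownSiteIndex()
    sites: List[MultiplexSite] = []
    sample_ids = {r: f"{line_id}_{r.value.lower()}" for r in Role}

    def add_site(pos0: int, category: str) -> None:
        ref_base = seq[pos0]
        site = VariantSite(chrom, pos0 + 1, ref_base, _ALT_OF[ref_base])
        genos = {
            Role.MUTANT: Genotype.HOM_ALT,
            Role.MOTHER: Genotype.HET,
            Role.FATHER: Genotype.HET,
            Role.BACKGROUND_1: Genotype.HOM_REF,
            Role.BACKGROUND_2: Genotype.HOM_REF,
            Role.POSITIVE_CONTROL: Genotype.HOM_REF,
        }
        if category == "dbsnp":
            known.add(site.chrom, site.pos, site.alt_allele)
            # dbSNP sites are real strain polymorphisms: also seen in a
            # background strain, which must not demote them from IN_DBSNP
            genos[Role.BACKGROUND_2] = Genotype.HOM_ALT
        elif category == "background":
            genos[Role.BACKGROUND_2] = Genotype.HOM_ALT
        calls = {
            r: SampleCall(sample_ids[r], r, g, depth) for r, g in genos.items()
        }
        sites.append(MultiplexSite(site, calls))

    inside_cap = {
        fc: sum(1 for p in pools[fc] if p < interval.end) for fc in FunctionalClass
    }
    for fc in FunctionalClass:
        total, dbsnp, bg = comps.get(fc, (0, 0, 0))
        remaining = total - dbsnp - bg
        pool = pools[fc]
        if fc is FunctionalClass.REPLACEMENT and remaining:
            # remaining replacement variants obey the mapped-region split;
            # eliminated ones fill the inside pool first
            n_inside_other = dbsnp + bg
            if n_inside_other + n_within > inside_cap[fc]:
                raise ValueError(f"{line_id}: mapped-region capacity exceeded")
            inside = [p for p in pool if p < interval.end]
            outside = [p for p in pool if p >= interval.end]
            if remaining - n_within > len(outside):
                raise ValueError(f"{line_id}: outside-region capacity exceeded")
            order = (
                inside[: n_inside_other + n_within]
                + outside[: remaining - n_within]
            )
            categories = (
                ["dbsnp"] * dbsnp
                + ["background"] * bg
                + ["remaining"] * n_within
                + ["remaining"] * (remaining - n_within)
            )
        else:
            order = pool[:total]
            categories = (
                ["dbsnp"] * dbsnp + ["background"] * bg + ["remaining"] * remaining
            )
        for pos0, category in zip(order, categories):
            add_site(pos0, category)

    # positive-control heterozygote on the reserved first spacer base
    control_base = seq[0]
    control_site = VariantSite(chrom, 1, control_base, _ALT_OF[control_base])
    control_calls = {
        r: SampleCall(
            sample_ids[r],
            r,
            Genotype.HET if r is Role.POSITIVE_CONTROL else Genotype.HOM_REF,
            depth,
        )
        for r in Role
    }
    sites.append(MultiplexSite(control_site, control_calls))

    callset = MultiplexCallSet(line_id, sites)
    expected = {
        fc: comps.get(fc, (0, 0, 0)) for fc in FunctionalClass
    }
    return LineFixture(
        line_id=line_id,
        callset=callset,
        genes=genes,
        ref=ref,
        known=known,
        interval=interval,
        control_site=control_site,
        expected=expected,
        expected_within_region=n_within,
    )
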