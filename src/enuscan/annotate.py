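"""Functional classification of SNVs against transcript models.

Each variant receives exactly one of five classes — REPLACEMENT, SILENT,
UTR, INTRONIC, INTERGENIC — by precedence over all overlapping transcripts
(a variant inside any transcript's CDS is coding). For coding variants the
affected codon is rebuilt from the reference with strand-aware
complementation and translated with the standard genetic code; stop codons
are written ``*``. UTR means exonic-but-not-CDS of a coding transcript and
every exon of a non-coding transcript. Intronic variants within 2 bp of an
exon boundary carry a near-splice flag (the class list itself has no
splice category).
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

from .io import ReferenceSequence
from .model import (
    AnnotatedVariant,
    FunctionalClass,
    GeneModel,
    MultiplexCallSet,
    VariantSite,
)

SPLICE_WINDOW = 2  # bp from an exon edge that flags an intronic variant

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class AnnotationError(ValueError):
    """Raised when a variant contradicts the reference or gene models."""


def classify_variant(
    v: VariantSite,
    genes: Sequence[GeneModel],
    ref_seq: ReferenceSequence,
) -> AnnotatedVariant:
    """Assign the functional class and amino-acid effect of one SNV.

    Raises :class:`AnnotationError` when the reference base at the site
    does not equal the variant's ref allele.
    """
    pos0 = v.pos - 1
    ref_base = ref_seq.base(v.chrom, pos0)
    if ref_base != v.ref_allele:
        raise AnnotationError(
            f"reference mismatch at {v.chrom}:{v.pos}: "
            f"FASTA has {ref_base}, variant claims {v.ref_allele}"
        )

    best: Optional[AnnotatedVariant] = None
    for model in genes:
        if model.chrom != v.chrom or not model.contains(pos0):
            continue
        if model.in_cds(pos0):
            ann = _annotate_coding(v, model, ref_seq)
        elif model.in_exon(pos0):
            ann = AnnotatedVariant(v, FunctionalClass.UTR, gene_id=model.gene_id)
        else:
            d = model.splice_distance(pos0)
            ann = AnnotatedVariant(
                v,
                FunctionalClass.INTRONIC,
                gene_id=model.gene_id,
                near_splice=d is not None and d <= SPLICE_WINDOW,
            )
        if best is None or ann.func_class.severity < best.func_class.severity:
            best = ann
    if best is None:
        best = AnnotatedVariant(v, FunctionalClass.INTERGENIC)
    return best


def _annotate_coding(
    v: VariantSite, model: GeneModel, ref_seq: ReferenceSequence
) -> AnnotatedVariant:
    pos0 = v.pos - 1
    # Spliced CDS positions in coding (5'->3') order.
    genomic = [p for s, e in model.cds_intervals() for p in range(s, e)]
    if model.strand == "-":
        genomic.reverse()
    cds_index = genomic.index(pos0)
    codon_idx = cds_index // 3
    codon_pos = genomic[codon_idx * 3 : codon_idx * 3 + 3]
    if len(codon_pos) < 3:
        raise AnnotationError(
            f"{model.transcript_id}: CDS length not a multiple of 3 at "
            f"{v.chrom}:{v.pos}"
        )

    def coding_base(p: int, allele: Optional[str] = None) -> str:
        b = allele if allele is not None else ref_seq.base(v.chrom, p)
        return b.translate(_COMPLEMENT) if model.strand == "-" else b

    ref_codon = "".join(coding_base(p) for p in codon_pos)
    alt_codon = "".join(
        coding_base(p, v.alt_allele if p == pos0 else None) for p in codon_pos
    )
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    func = (
        FunctionalClass.SILENT if aa_ref == aa_alt else FunctionalClass.REPLACEMENT
    )
    return AnnotatedVariant(
        v,
        func,
        gene_id=model.gene_id,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        aa_pos=codon_idx + 1,
    )


def annotate_all(
    callset: MultiplexCallSet,
    genes: Sequence[GeneModel],
    ref_seq: ReferenceSequence,
) -> list[AnnotatedVariant]:
    """Annotate every site of a call set, preserving input order."""
    return [classify_variant(s.site, genes, ref_seq) for s in callset]


def write_annotations(anns: Iterable[AnnotatedVariant], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\tclass\tgene\taa_change\tnear_splice\n")
        for a in anns:
            fh.write(
                f"{a.site.chrom}\t{a.site.pos}\t{a.site.ref_allele}\t"
                f"{a.site.alt_allele}\t{a.func_class.value}\t{a.gene_id or '.'}\t"
                f"{a.aa_change}\t{int(a.near_splice)}\n"
            )
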