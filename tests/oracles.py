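"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result from first principles with a
different algorithm (and, for probabilities, different arithmetic) than
the implementation under test.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import List, Optional, Sequence, Tuple

from Bio.Seq import Seq

# ---------------------------------------------------------------------------
# Functional annotation: exhaustive positional classification
# ---------------------------------------------------------------------------

_SEVERITY_ORDER = ["REPLACEMENT", "SILENT", "UTR", "INTRONIC", "INTERGENIC"]
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def classify_oracle(
    chrom: str,
    pos1: int,
    alt: str,
    genes,
    fetch,
) -> Tuple[str, Optional[str], Optional[str], Optional[str], Optional[int]]:
    """(class, gene_id, aa_ref, aa_alt, aa_pos) by whole-protein translation.

    ``fetch(chrom, start0, end0)`` returns reference sequence. For every
    transcript the position's compartment is found by explicit per-exon
    scanning; coding effects come from translating the complete ref and
    alt CDS proteins and locating the changed residue.
    """
    pos0 = pos1 - 1
    per_tx = []
    for g in genes:
        if g.chrom != chrom:
            continue
        tx_start, tx_end = g.exons[0][0], g.exons[-1][1]
        if not (tx_start <= pos0 < tx_end):
            continue
        exonic = False
        for s, e in g.exons:
            if s <= pos0 < e:
                exonic = True
        coding = g.cds_end > g.cds_start
        in_cds = exonic and coding and g.cds_start <= pos0 < g.cds_end
        if not exonic:
            per_tx.append(("INTRONIC", g.gene_id, None, None, None))
            continue
        if not in_cds:
            per_tx.append(("UTR", g.gene_id, None, None, None))
            continue
        # whole-CDS translation for both alleles
        cds_pos: List[int] = []
        for s, e in g.exons:
            for p in range(s, e):
                if g.cds_start <= p < g.cds_end:
                    cds_pos.append(p)
        ref_cds = "".join(fetch(chrom, p, p + 1) for p in cds_pos)
        idx = cds_pos.index(pos0)
        alt_cds = ref_cds[:idx] + alt + ref_cds[idx + 1 :]
        if g.strand == "-":
            ref_cds = "".join(_COMP[b] for b in reversed(ref_cds))
            alt_cds = "".join(_COMP[b] for b in reversed(alt_cds))
        ref_prot = str(Seq(ref_cds).translate())
        alt_prot = str(Seq(alt_cds).translate())
        diffs = [i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
        if diffs:
            i = diffs[0]
            per_tx.append(("REPLACEMENT", g.gene_id, ref_prot[i], alt_prot[i], i + 1))
        else:
            # silent: codon index still reportable
            if g.strand == "-":
                i = (len(cds_pos) - 1 - idx) // 3
            else:
                i = idx // 3
            per_tx.append(("SILENT", g.gene_id, ref_prot[i], ref_prot[i], i + 1))
    if not per_tx:
        return ("INTERGENIC", None, None, None, None)
    best_rank = min(_SEVERITY_ORDER.index(t[0]) for t in per_tx)
    for t in per_tx:  # first transcript attaining the most severe class
        if _SEVERITY_ORDER.index(t[0]) == best_rank:
            return t
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Segregation probabilities: exact rational arithmetic
# ---------------------------------------------------------------------------


def p_binomial_oracle(n_mut: int, n_wt: int, n_discordant: int) -> Fraction:
    """P(total discordance <= observed) as an exact Fraction.

    Each MUTANT embryo is discordant with probability 3/4, each WILD_TYPE
    with probability 1/4, independently.
    """
    total = Fraction(0)
    for d1 in range(0, min(n_discordant, n_mut) + 1):
        for d2 in range(0, min(n_discordant - d1, n_wt) + 1):
            total += (
                Fraction(comb(n_mut, d1) * 3**d1, 4**n_mut)
                * Fraction(comb(n_wt, d2) * 3 ** (n_wt - d2), 4**n_wt)
            )
    return total


def p_fisher_oracle(
    mut_hom: int, mut_not: int, wt_hom: int, wt_not: int
) -> Fraction:
    """One-sided hypergeometric tail toward concordance, exact Fraction."""
    n = mut_hom + mut_not + wt_hom + wt_not
    k_hom = mut_hom + wt_hom
    n_mut = mut_hom + mut_not
    denom = comb(n, n_mut)
    total = 0
    for j in range(mut_hom, min(k_hom, n_mut) + 1):
        if n_mut - j <= n - k_hom:
            total += comb(k_hom, j) * comb(n - k_hom, n_mut - j)
    return Fraction(total, denom)


# ---------------------------------------------------------------------------
# RFLP: exhaustive window scan with an independent IUPAC table
# ---------------------------------------------------------------------------

_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _revcomp_iupac(motif: str) -> str:
    comp = {
        "A": "T", "C": "G", "G": "C", "T": "A",
        "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
        "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
    }
    return "".join(comp[c] for c in reversed(motif))


def rflp_oracle(flank: str, offset: int, ref: str, alt: str, motif: str) -> Optional[str]:
    """GAIN/LOSS/None by enumerating every window on both alleles/strands."""
    assert flank[offset] == ref

    def has_site(seq: str) -> bool:
        for m in (motif, _revcomp_iupac(motif)):
            L = len(m)
            for i in range(0, len(seq) - L + 1):
                if not (i <= offset < i + L):
                    continue  # must overlap the variant
                if all(seq[i + k] in _IUPAC_SETS[m[k]] for k in range(L)):
                    return True
        return False

    alt_seq = flank[:offset] + alt + flank[offset + 1 :]
    in_ref, in_alt = has_site(flank), has_site(alt_seq)
    if in_alt and not in_ref:
        return "GAIN"
    if in_ref and not in_alt:
        return "LOSS"
    return None
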