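"""Exact genotype-phenotype co-segregation tests for backcross pedigrees.

Under the screen's breeding design a candidate recessive allele behaves
like a het x het (carrier backcross) draw in every embryo: homozygous
mutant with probability 1/4, otherwise 3/4. Genotypes are collapsed to
the published dichotomy, HOM_ALT vs not; MUTANT embryos are concordant
when HOM_ALT and WILD_TYPE embryos when not. Two exact null computations
are shipped, because more than one defensible formalization exists:

* ``BINOMIAL_PRODUCT`` — probability, under independent Mendelian draws,
  of a segregation pattern at least as concordant as observed (tail over
  total discordance counts <= observed).
* ``FISHER_EXACT`` — one-sided hypergeometric tail of the 2x2
  phenotype x genotype table with margins fixed.

Both are evaluated in log-space (gammaln-based log factorials), so
pedigrees up to tens of thousands of embryos do not underflow; results
carry log10 alongside the (possibly denormal) probability.

ABNORMAL-phenotype and UNKNOWN-genotype embryos are excluded from the
tests and tallied separately.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy.special import gammaln, logsumexp

from .model import PedGenotype, PedigreeRecord, Phenotype

_LOG_QUARTER = math.log(0.25)
_LOG_THREE_QUARTERS = math.log(0.75)


class NullModel(str, enum.Enum):
    """Mendelian null for the expected homozygote fraction (1/4)."""

    INTERCROSS_14 = "INTERCROSS_14"


class Method(str, enum.Enum):
    BINOMIAL_PRODUCT = "BINOMIAL_PRODUCT"
    FISHER_EXACT = "FISHER_EXACT"
    BOTH = "BOTH"


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 phenotype x collapsed-genotype counts plus exclusions."""

    mutant_hom_alt: int
    mutant_not_hom_alt: int
    wild_type_hom_alt: int
    wild_type_not_hom_alt: int
    n_abnormal: int = 0
    n_unknown: int = 0

    @property
    def n_discordant(self) -> int:
        return self.mutant_not_hom_alt + self.wild_type_hom_alt

    @property
    def n_mutant(self) -> int:
        return self.mutant_hom_alt + self.mutant_not_hom_alt

    @property
    def n_wild_type(self) -> int:
        return self.wild_type_hom_alt + self.wild_type_not_hom_alt

    @property
    def n(self) -> int:
        return self.n_mutant + self.n_wild_type


@dataclass(frozen=True)
class SegregationResult:
    counts: ConcordanceTable
    n_discordant: int
    p_binomial: Optional[float]
    p_fisher: Optional[float]
    log10_p_binomial: Optional[float]
    log10_p_fisher: Optional[float]
    method_notes: str


def concordance_counts(records: Iterable[PedigreeRecord]) -> ConcordanceTable:
    """Tally the 2x2 table; ABNORMAL and UNKNOWN records sit outside it."""
    mut_hom = mut_not = wt_hom = wt_not = abnormal = unknown = 0
    for r in records:
        if r.genotype is PedGenotype.UNKNOWN:
            unknown += 1
            continue
        if r.phenotype is Phenotype.ABNORMAL:
            abnormal += 1
            continue
        hom = r.genotype is PedGenotype.HOM_ALT
        if r.phenotype is Phenotype.MUTANT:
            mut_hom, mut_not = mut_hom + hom, mut_not + (not hom)
        else:
            wt_hom, wt_not = wt_hom + hom, wt_not + (not hom)
    return ConcordanceTable(mut_hom, mut_not, wt_hom, wt_not, abnormal, unknown)


def _log_choose(n: int, k) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _log_p_binomial_tail(table: ConcordanceTable) -> float:
    """log P(total discordance <= observed) under independent 1/4-3/4 draws.

    A MUTANT embryo is discordant (not HOM_ALT) with probability 3/4; a
    WILD_TYPE embryo is discordant (HOM_ALT) with probability 1/4. The
    tail sums the two-group Poisson-binomial over all splits of the
    discordance budget.
    """
    n_mut, n_wt, d = table.n_mutant, table.n_wild_type, table.n_discordant
    terms = []
    for d1 in range(0, min(d, n_mut) + 1):
        for d2 in range(0, min(d - d1, n_wt) + 1):
            terms.append(
                _log_choose(n_mut, d1)
                + d1 * _LOG_THREE_QUARTERS
                + (n_mut - d1) * _LOG_QUARTER
                + _log_choose(n_wt, d2)
                + d2 * _LOG_QUARTER
                + (n_wt - d2) * _LOG_THREE_QUARTERS
            )
    return float(logsumexp(terms))


def _log_p_fisher_tail(table: ConcordanceTable) -> float:
    """log one-sided hypergeometric tail toward greater concordance.

    With margins fixed, concordance increases with the MUTANT & HOM_ALT
    cell, so the tail is P(X >= observed) for X hypergeometric.
    """
    n_total = table.n
    k_hom = table.mutant_hom_alt + table.wild_type_hom_alt
    n_mut = table.n_mutant
    x = table.mutant_hom_alt
    lo = max(0, n_mut - (n_total - k_hom))
    hi = min(k_hom, n_mut)
    denom = _log_choose(n_total, n_mut)
    terms = [
        _log_choose(k_hom, j) + _log_choose(n_total - k_hom, n_mut - j) - denom
        for j in range(x, hi + 1)
    ]
    if not terms:  # x above support: more concordant than any table
        return -math.inf
    return float(logsumexp(terms))


def segregation_test(
    records: Sequence[PedigreeRecord],
    null_model: NullModel = NullModel.INTERCROSS_14,
    method: Method = Method.BOTH,
) -> SegregationResult:
    """Probability that the observed co-segregation arose by chance.

    Raises ``ValueError("empty pedigree")`` when no record has a known
    genotype and a non-ABNORMAL phenotype.
    """
    null_model = NullModel(null_model)
    table = concordance_counts(records)
    if table.n == 0:
        raise ValueError("empty pedigree")

    p_bin = log10_bin = p_fis = log10_fis = None
    if method in (Method.BINOMIAL_PRODUCT, Method.BOTH):
        lp = _log_p_binomial_tail(table)
        p_bin, log10_bin = math.exp(lp), lp / math.log(10)
    if method in (Method.FISHER_EXACT, Method.BOTH):
        lp = _log_p_fisher_tail(table)
        p_fis, log10_fis = math.exp(lp), lp / math.log(10)

    notes = (
        f"null={null_model.value}; n={table.n} "
        f"(mutant {table.n_mutant}, wild-type {table.n_wild_type}); "
        f"discordant={table.n_discordant}; "
        f"excluded: {table.n_abnormal} abnormal, {table.n_unknown} unknown genotype"
    )
    return SegregationResult(
        counts=table,
        n_discordant=table.n_discordant,
        p_binomial=p_bin,
        p_fisher=p_fis,
        log10_p_binomial=log10_bin,
        log10_p_fisher=log10_fis,
        method_notes=notes,
    )


def write_segregation(result: SegregationResult, path) -> None:
    t = result.counts
    with open(path, "w") as fh:
        fh.write("#field\tvalue\n")
        rows = [
            ("mutant_hom_alt", t.mutant_hom_alt),
            ("mutant_not_hom_alt", t.mutant_not_hom_alt),
            ("wild_type_hom_alt", t.wild_type_hom_alt),
            ("wild_type_not_hom_alt", t.wild_type_not_hom_alt),
            ("n_abnormal_excluded", t.n_abnormal),
            ("n_unknown_excluded", t.n_unknown),
            ("n_discordant", result.n_discordant),
            ("p_binomial", result.p_binomial),
            ("p_fisher", result.p_fisher),
            ("log10_p_binomial", result.log10_p_binomial),
            ("log10_p_fisher", result.log10_p_fisher),
            ("method_notes", result.method_notes),
        ]
        for k, v in rows:
            fh.write(f"{k}\t{v}\n")
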