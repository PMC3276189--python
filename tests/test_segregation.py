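import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import p_binomial_oracle, p_fisher_oracle

from enuscan.datasets import (
    load_reported_segregation_counts,
    pedigree_from_counts,
)
from enuscan.model import PedGenotype, PedigreeRecord, Phenotype
from enuscan.segregation import (
    Method,
    concordance_counts,
    segregation_test,
)


def _pedigree(mut_hom=0, mut_not=0, wt_hom=0, wt_not=0, abnormal=0, unknown=0):
    return pedigree_from_counts(wt_not, wt_hom, mut_not, mut_hom) + [
        PedigreeRecord(f"A{i}", "L9", Phenotype.ABNORMAL, PedGenotype.HET)
        for i in range(abnormal)
    ] + [
        PedigreeRecord(f"U{i}", "L9", Phenotype.WILD_TYPE, PedGenotype.UNKNOWN)
        for i in range(unknown)
    ]


class TestClosedForms:
    def test_single_concordant_mutant_embryo(self):
        r = segregation_test(_pedigree(mut_hom=1))
        assert math.isclose(r.p_binomial, 0.25, rel_tol=1e-12)

    def test_three_embryo_fully_concordant_product(self):
        r = segregation_test(_pedigree(mut_hom=2, wt_not=1))
        assert math.isclose(r.p_binomial, 3 / 64, rel_tol=1e-12)

    def test_fully_concordant_fisher_is_one_over_choose(self):
        r = segregation_test(_pedigree(mut_hom=57, wt_not=201))
        expected = 1 / math.comb(258, 57)
        assert math.isclose(r.p_fisher, expected, rel_tol=1e-12)
        # and the binomial product is (1/4)^57 (3/4)^201
        lg = 57 * math.log10(1 / 4) + 201 * math.log10(3 / 4)
        assert math.isclose(r.log10_p_binomial, lg, rel_tol=1e-12)

    def test_empty_pedigree_raises(self):
        with pytest.raises(ValueError, match="empty pedigree"):
            segregation_test(_pedigree(abnormal=3, unknown=2))


class TestConcordanceCounts:
    def test_discordant_tally_with_mixed_evidence(self):
        # 51 concordant mutants, 4 het mutants, 159 concordant wild types,
        # 2 hom wild types: six discordant embryos in total
        t = concordance_counts(_pedigree(mut_hom=51, mut_not=4, wt_hom=2, wt_not=159))
        assert (t.mutant_hom_alt, t.mutant_not_hom_alt) == (51, 4)
        assert (t.wild_type_hom_alt, t.wild_type_not_hom_alt) == (2, 159)
        assert t.n_discordant == 6

    def test_all_concordant_has_zero_discordance(self):
        assert concordance_counts(_pedigree(mut_hom=10, wt_not=30)).n_discordant == 0

    def test_counts_equal_naive_recount_on_random_pedigrees(self):
        import numpy as np

        rng = np.random.default_rng(21)
        phens = [Phenotype.MUTANT, Phenotype.WILD_TYPE, Phenotype.ABNORMAL]
        genos = list(PedGenotype)
        for _ in range(20):
            recs = [
                PedigreeRecord(
                    f"E{i}", "L1",
                    phens[rng.integers(3)], genos[rng.integers(4)],
                )
                for i in range(300)
            ]
            t = concordance_counts(recs)
            naive = {"mh": 0, "mn": 0, "wh": 0, "wn": 0, "ab": 0, "uk": 0}
            for r in recs:
                if r.genotype is PedGenotype.UNKNOWN:
                    naive["uk"] += 1
                elif r.phenotype is Phenotype.ABNORMAL:
                    naive["ab"] += 1
                elif r.phenotype is Phenotype.MUTANT:
                    naive["mh" if r.genotype is PedGenotype.HOM_ALT else "mn"] += 1
                else:
                    naive["wh" if r.genotype is PedGenotype.HOM_ALT else "wn"] += 1
            assert (
                t.mutant_hom_alt, t.mutant_not_hom_alt,
                t.wild_type_hom_alt, t.wild_type_not_hom_alt,
                t.n_abnormal, t.n_unknown,
            ) == tuple(naive.values())


class TestAgainstBigIntegerOracle:
    @given(
        mut_hom=st.integers(0, 120), mut_not=st.integers(0, 10),
        wt_hom=st.integers(0, 10), wt_not=st.integers(0, 260),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_both_engines_match_exact_rational_arithmetic(
        self, mut_hom, mut_not, wt_hom, wt_not
    ):
        if mut_hom + mut_not + wt_hom + wt_not == 0:
            return
        r = segregation_test(_pedigree(mut_hom, mut_not, wt_hom, wt_not))
        exact_bin = p_binomial_oracle(mut_hom + mut_not, wt_hom + wt_not,
                                      mut_not + wt_hom)
        exact_fis = p_fisher_oracle(mut_hom, mut_not, wt_hom, wt_not)
        assert math.isclose(r.p_binomial, float(exact_bin), rel_tol=1e-12)
        assert math.isclose(r.p_fisher, float(exact_fis), rel_tol=1e-12)

    def test_published_pedigree_sizes_are_handled_exactly(self):
        """The six candidate pedigrees, checked against exact fractions."""
        for (line, cand), c in load_reported_segregation_counts().items():
            r = segregation_test(
                _pedigree(
                    mut_hom=c["mutant_hom_alt"], mut_not=c["mutant_not_hom_alt"],
                    wt_hom=c["wild_type_hom_alt"], wt_not=c["wild_type_not_hom_alt"],
                )
            )
            exact_bin = p_binomial_oracle(
                c["mutant_hom_alt"] + c["mutant_not_hom_alt"],
                c["wild_type_hom_alt"] + c["wild_type_not_hom_alt"],
                c["mutant_not_hom_alt"] + c["wild_type_hom_alt"],
            )
            exact_fis = p_fisher_oracle(
                c["mutant_hom_alt"], c["mutant_not_hom_alt"],
                c["wild_type_hom_alt"], c["wild_type_not_hom_alt"],
            )
            assert math.isclose(r.p_binomial, float(exact_bin), rel_tol=1e-12), line
            assert math.isclose(r.p_fisher, float(exact_fis), rel_tol=1e-12), line
            assert 0 < r.p_binomial <= 1 and 0 < r.p_fisher <= 1


class TestProperties:
    def test_adding_a_concordant_embryo_never_raises_either_p(self):
        for base in [
            dict(mut_hom=5, wt_not=10),
            dict(mut_hom=20, mut_not=2, wt_hom=1, wt_not=50),
            dict(mut_hom=1),
        ]:
            r0 = segregation_test(_pedigree(**base))
            grown_m = dict(base, mut_hom=base.get("mut_hom", 0) + 1)
            grown_w = dict(base, wt_not=base.get("wt_not", 0) + 1)
            for grown in (grown_m, grown_w):
                r1 = segregation_test(_pedigree(**grown))
                assert r1.log10_p_binomial <= r0.log10_p_binomial + 1e-12
                assert r1.log10_p_fisher <= r0.log10_p_fisher + 1e-12

    def test_perfect_concordance_minimizes_both_p(self):
        n_mut, n_wt = 8, 20
        best = segregation_test(_pedigree(mut_hom=n_mut, wt_not=n_wt))
        for d_m in range(0, n_mut + 1):
            for d_w in range(0, n_wt + 1, 5):
                if d_m == 0 and d_w == 0:
                    continue
                r = segregation_test(
                    _pedigree(
                        mut_hom=n_mut - d_m, mut_not=d_m,
                        wt_hom=d_w, wt_not=n_wt - d_w,
                    )
                )
                assert r.p_binomial >= best.p_binomial
                assert r.p_fisher >= best.p_fisher

    def test_abnormal_and_unknown_records_never_move_the_probabilities(self):
        r0 = segregation_test(_pedigree(mut_hom=12, wt_not=30))
        r1 = segregation_test(_pedigree(mut_hom=12, wt_not=30, abnormal=7, unknown=4))
        assert r1.p_binomial == r0.p_binomial
        assert r1.p_fisher == r0.p_fisher
        assert r1.counts.n_abnormal == 7 and r1.counts.n_unknown == 4

    def test_log_space_survives_very_large_pedigrees(self):
        r = segregation_test(
            _pedigree(mut_hom=2500, wt_not=7500), method=Method.BOTH
        )
        # the float probability underflows but the log stays exact
        expected = 2500 * math.log10(1 / 4) + 7500 * math.log10(3 / 4)
        assert math.isclose(r.log10_p_binomial, expected, rel_tol=1e-12)
        assert r.log10_p_fisher < -900

    def test_method_selection_reports_only_what_was_asked(self):
        ped = _pedigree(mut_hom=3, wt_not=5)
        b = segregation_test(ped, method=Method.BINOMIAL_PRODUCT)
        assert b.p_binomial is not None and b.p_fisher is None
        f = segregation_test(ped, method=Method.FISHER_EXACT)
        assert f.p_fisher is not None and f.p_binomial is None
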