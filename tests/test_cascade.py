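import numpy as np
import pytest

from enuscan.annotate import annotate_all
from enuscan.cascade import (
    CandidateSet,
    CascadeOptions,
    interval_filter,
    parental_consistency,
    partition_variant,
    positive_control_check,
    run_cascade,
)
from enuscan.model import (
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
from enuscan.simulate import ORIGIN_ENU, ORIGIN_ERROR, B6BG, FVB

SITE = VariantSite("chr1", 100, "A", "G")
ANN = AnnotatedVariant(SITE, FunctionalClass.INTERGENIC)


def _calls(mutant=("HOM_ALT", 30), mother=("HET", 30), father=("HET", 30),
           bg1=("HOM_REF", 30), bg2=("HOM_REF", 30), control=("HOM_REF", 30)):
    spec = {
        Role.MUTANT: mutant, Role.MOTHER: mother, Role.FATHER: father,
        Role.BACKGROUND_1: bg1, Role.BACKGROUND_2: bg2,
        Role.POSITIVE_CONTROL: control,
    }
    return {
        r: SampleCall(r.value.lower(), r, Genotype(g), d) for r, (g, d) in spec.items()
    }


class TestPartition:
    def test_dbsnp_takes_precedence_over_background(self):
        known = KnownSiteIndex([SITE.key])
        calls = _calls(bg2=("HOM_ALT", 40))  # present in FVB as well
        assert partition_variant(ANN, calls, known) is Category.IN_DBSNP

    def test_heterozygous_mutant_is_not_eligible(self):
        assert partition_variant(ANN, _calls(mutant=("HET", 30)), KnownSiteIndex()) is None
        assert (
            partition_variant(ANN, _calls(mutant=("HOM_ALT", 5)), KnownSiteIndex())
            is None
        )

    def test_background_call_must_be_callable(self):
        calls = _calls(bg2=("HET", 5))  # alt seen but below callable depth
        assert partition_variant(ANN, calls, KnownSiteIndex()) is Category.REMAINING
        calls = _calls(bg1=("HET", 9))
        assert (
            partition_variant(ANN, calls, KnownSiteIndex())
            is Category.IN_BACKGROUND_NOT_DBSNP
        )

    def test_position_only_dbsnp_matching_mode(self):
        known = KnownSiteIndex([("chr1", 100, "T")])  # different alt
        assert partition_variant(ANN, _calls(), known) is Category.REMAINING
        loose = CascadeOptions(dbsnp_allele_specific=False)
        assert partition_variant(ANN, _calls(), known, loose) is Category.IN_DBSNP

    def test_partition_agrees_with_generator_truth_labels(self):
        """Every eligible variant of a high-coverage error-free screen lands
        in the category its ground-truth origin dictates."""
        from enuscan.simulate import ScreenConfig, simulate_screen

        screen = simulate_screen(
            ScreenConfig(seed=13, error_rate=0.0, depth_mean=60, depth_dispersion=60)
        )
        anns = annotate_all(screen.callset, screen.genes, screen.ref)
        ann_by_key = {a.site.key: a for a in anns}
        truth_by_key = {t.site.key: t for t in screen.truth}
        checked = 0
        for ms in screen.callset:
            if ms.site.key not in truth_by_key:
                continue  # the positive-control site
            t = truth_by_key[ms.site.key]
            got = partition_variant(ann_by_key[ms.site.key], ms.calls, screen.known)
            if t.true_genotypes[Role.MUTANT] is not Genotype.HOM_ALT:
                assert got is None
                continue
            if screen.known.contains(*ms.site.key):
                expected = Category.IN_DBSNP
            elif t.carrier_origins & {B6BG, FVB}:
                expected = Category.IN_BACKGROUND_NOT_DBSNP
            else:
                assert t.origin in (ORIGIN_ENU, ORIGIN_ERROR)
                expected = Category.REMAINING
            assert got is expected, (ms.site.key, t.origin)
            checked += 1
        assert checked > 50  # enough eligible homozygous sites were exercised


class TestParentalConsistency:
    def test_both_parents_het_at_depth_is_consistent(self):
        c = _calls(mother=("HET", 30), father=("HET", 25))
        assert (
            parental_consistency(c[Role.MOTHER], c[Role.FATHER])
            is Consistency.CONSISTENT
        )

    def test_poorly_covered_parent_is_flagged_not_contradicted(self):
        # one parent at depth 2: cannot be called het, retained with a flag
        c = _calls(mother=("HET", 30), father=("HOM_REF", 2))
        assert (
            parental_consistency(c[Role.MOTHER], c[Role.FATHER])
            is Consistency.LOW_COVERAGE
        )
        c = _calls(father=("NO_CALL", 0))
        assert (
            parental_consistency(c[Role.MOTHER], c[Role.FATHER])
            is Consistency.LOW_COVERAGE
        )

    def test_confident_hom_ref_parent_is_inconsistent(self):
        c = _calls(mother=("HOM_REF", 40))
        assert (
            parental_consistency(c[Role.MOTHER], c[Role.FATHER])
            is Consistency.INCONSISTENT
        )


class TestRunCascade:
    def test_worked_example_replacement_row(self, table_fixtures):
        fx = next(f for f in table_fixtures if f.line_id == "AB5")
        anns = annotate_all(fx.callset, fx.genes, fx.ref)
        cands, summary = run_cascade(fx.callset, anns, fx.known)
        fc = FunctionalClass.REPLACEMENT
        assert summary.total(fc) == 96
        assert summary.count(fc, Category.IN_DBSNP) == 80
        assert summary.count(fc, Category.IN_BACKGROUND_NOT_DBSNP) == 13
        assert summary.count(fc, Category.REMAINING) == 3

    def test_empty_callset_gives_empty_outputs(self):
        cands, summary = run_cascade(MultiplexCallSet("x"), [], KnownSiteIndex())
        assert len(cands) == 0 and summary.total() == 0

    def test_shuffling_input_order_changes_nothing(self, table_fixtures):
        fx = table_fixtures[0]
        anns = annotate_all(fx.callset, fx.genes, fx.ref)
        cands, summary = run_cascade(fx.callset, anns, fx.known)
        rng = np.random.default_rng(0)
        shuffled_sites = list(fx.callset.sites)
        rng.shuffle(shuffled_sites)
        shuffled = MultiplexCallSet(fx.line_id, shuffled_sites)
        cands2, summary2 = run_cascade(shuffled, anns, fx.known)
        assert summary2 == summary
        assert [c.site.key for c in cands2] == [c.site.key for c in cands]

    def test_missing_annotation_is_an_error(self, table_fixtures):
        fx = table_fixtures[0]
        anns = annotate_all(fx.callset, fx.genes, fx.ref)[:-1]
        with pytest.raises(ValueError, match="annotation missing"):
            run_cascade(fx.callset, anns, fx.known)

    def test_remaining_set_is_independent_of_filter_order(self, sim_screen):
        """REMAINING = in neither catalog nor background, however attributed."""
        anns = annotate_all(sim_screen.callset, sim_screen.genes, sim_screen.ref)
        cands, _ = run_cascade(sim_screen.callset, anns, sim_screen.known)
        opts = CascadeOptions()
        neither = []
        for ms in sorted(sim_screen.callset.sites, key=lambda s: s.site.key):
            m = ms.calls[Role.MUTANT]
            if m.genotype is not Genotype.HOM_ALT or m.depth < opts.min_depth:
                continue
            in_dbsnp = sim_screen.known.contains(*ms.site.key)
            in_bg = any(
                ms.calls[r].genotype in (Genotype.HET, Genotype.HOM_ALT)
                and ms.calls[r].depth >= opts.min_depth
                for r in (Role.BACKGROUND_1, Role.BACKGROUND_2)
            )
            if not in_dbsnp and not in_bg:
                neither.append(ms.site.key)
        assert [c.site.key for c in cands] == neither

    def test_growing_known_index_never_grows_remaining(self, sim_screen):
        anns = annotate_all(sim_screen.callset, sim_screen.genes, sim_screen.ref)
        cands, _ = run_cascade(sim_screen.callset, anns, sim_screen.known)
        bigger = KnownSiteIndex(list(sim_screen.known))
        before = {c.site.key for c in cands}
        for key in list(before)[:3]:
            bigger.add(*key)
        cands2, _ = run_cascade(sim_screen.callset, anns, bigger)
        after = {c.site.key for c in cands2}
        assert after <= before and len(after) == len(before) - min(3, len(before))

    def test_strict_parental_drops_inconsistent_only(self, sim_screen):
        anns = annotate_all(sim_screen.callset, sim_screen.genes, sim_screen.ref)
        soft, _ = run_cascade(sim_screen.callset, anns, sim_screen.known)
        strict, _ = run_cascade(
            sim_screen.callset, anns, sim_screen.known,
            CascadeOptions(strict_parental=True),
        )
        dropped = {c.site.key for c in soft} - {c.site.key for c in strict}
        by_key = {c.site.key: c for c in soft}
        assert all(
            by_key[k].consistency is Consistency.INCONSISTENT for k in dropped
        )
        kept_inconsistent = [
            c for c in strict if c.consistency is Consistency.INCONSISTENT
        ]
        assert not kept_inconsistent


class TestIntervalFilter:
    def test_whole_chromosome_interval_is_identity(self, sim_screen):
        anns = annotate_all(sim_screen.callset, sim_screen.genes, sim_screen.ref)
        cands, _ = run_cascade(sim_screen.callset, anns, sim_screen.known)
        whole = MappedInterval(
            sim_screen.causal.site.chrom, 0, sim_screen.config.chrom_length_bp
        )
        assert [c.site.key for c in interval_filter(cands, whole)] == [
            c.site.key for c in cands
        ]

    def test_complement_intervals_partition_candidates(self, sim_screen):
        anns = annotate_all(sim_screen.callset, sim_screen.genes, sim_screen.ref)
        cands, _ = run_cascade(sim_screen.callset, anns, sim_screen.known)
        chrom = sim_screen.causal.site.chrom
        mid = sim_screen.causal.site.pos
        left = interval_filter(cands, MappedInterval(chrom, 0, mid))
        right = interval_filter(
            cands, MappedInterval(chrom, mid, sim_screen.config.chrom_length_bp)
        )
        assert len(left) + len(right) == len(cands)

    def test_worked_example_mapped_region_split(self, table_fixtures):
        fx = next(f for f in table_fixtures if f.line_id == "M2")
        anns = annotate_all(fx.callset, fx.genes, fx.ref)
        cands, _ = run_cascade(
            fx.callset, anns, fx.known,
            CascadeOptions(require_class=FunctionalClass.REPLACEMENT),
        )
        assert len(cands) == 4
        assert len(interval_filter(cands, fx.interval)) == 2


class TestPositiveControl:
    def test_control_het_passes_and_hom_ref_fails(self, table_fixtures):
        fx = table_fixtures[0]
        report = positive_control_check(fx.callset, fx.control_site)
        assert report.passed and report.genotype is Genotype.HET
        wrong_site = VariantSite(
            fx.control_site.chrom, fx.control_site.pos,
            fx.control_site.ref_allele,
            next(
                b for b in "ACGT"
                if b not in (fx.control_site.ref_allele, fx.control_site.alt_allele)
            ),
        )
        report = positive_control_check(fx.callset, wrong_site)
        assert not report.passed and report.reason == "not covered"

    def test_control_recovered_in_simulated_screens(self):
        from enuscan.simulate import ScreenConfig, simulate_screen

        for seed in range(40):
            s = simulate_screen(
                ScreenConfig(seed=3000 + seed, error_rate=0.0, n_litters=3)
            )
            assert positive_control_check(s.callset, s.control_site).passed
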