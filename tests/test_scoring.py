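"""Mutation scores, relative scores and the candidate filter cascade."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from msiscan import (
    MicrosatelliteLocus,
    SampleCall,
    ScoredLocus,
    control_differs_filter,
    dose_dependence_filter,
    intersect_with_msats,
    load_candidate_fixture,
    mutation_score,
    positivity_filter,
    rank_candidates,
    relative_scores,
    run_cascade,
    score_sites,
    select_indels,
)
from msiscan.scoring import ScoreUndefinedError
from test_variants import make_site

from _oracles import brute_force_overlaps


def call(ad, dp=None):
    return SampleCall(genotype=(0, 1), allelic_depths=tuple(ad),
                      total_depth=dp if dp is not None else sum(ad))


def scored(m_control, m_low, m_high, site=None, msat=None):
    site = site or make_site([(0, 0), (0, 1), (0, 1)])
    return ScoredLocus(
        site=site,
        m_control=Fraction(str(m_control)),
        m_low=Fraction(str(m_low)),
        m_high=Fraction(str(m_high)),
        msat=msat,
    )


class TestMutationScore:
    @pytest.mark.parametrize(
        "ad,dp,expected",
        [
            ((40, 60), 100, 60),     # 60% of reads support the variant
            ((25, 0), 25, 0),        # no variant reads
            ((10, 5, 5), 20, 50),    # two alts: variant reads sum
            ((0, 150), 100, 100),    # external VCFs may exceed DP: capped
        ],
    )
    def test_examples(self, ad, dp, expected):
        assert mutation_score(call(ad, dp)) == Fraction(expected)

    @pytest.mark.parametrize(
        "bad",
        [
            SampleCall((0, 1), (0, 10), 0),
            SampleCall((0, 1), (0, 10), None),
            SampleCall((0, 1), None, 30),
        ],
    )
    def test_undefined_score_raises(self, bad):
        with pytest.raises(ScoreUndefinedError):
            mutation_score(bad)

    def test_undefined_loci_excluded_from_scoring(self):
        good = make_site([(0, 0), (0, 1), (0, 1)])
        bad = make_site(
            [(0, 0), (0, 1), (0, 1)], position=2000,
            depths=[(20, 10), (20, 10), (20, 10)],
        )
        object.__setattr__(bad.calls["high"], "total_depth", 0)
        assert [s.site for s in score_sites([good, bad])] == [good]

    def test_scores_are_exact_rationals(self):
        # 1/7 of reads: a float pipeline would round-trip through 14.29
        assert mutation_score(call((6, 1))) == Fraction(100, 7)


class TestRelativeScores:
    @pytest.mark.parametrize(
        "m,expected",
        [
            ((0, "22.73", 60), (Fraction("22.73"), Fraction(60))),
            ((50, 50, 50), (0, 0)),
            ((80, 70, 90), (-10, 10)),
        ],
    )
    def test_examples(self, m, expected):
        assert relative_scores(scored(*m)) == expected


class TestScoreFilters:
    def test_dose_dependence_strict_inequality(self):
        near_tie = scored(0, "13.64", "13.79")   # passes by 0.15 points
        exact_tie = scored(0, 10, 10)
        assert dose_dependence_filter([near_tie, exact_tie]) == [near_tie]

    def test_positivity_examples(self):
        zero_low = scored(0, 0, 12)
        passing = scored("83.33", "85.71", "94.44")
        assert positivity_filter([zero_low, passing]) == [passing]

    def test_positivity_sign_grid_matches_truth_table(self):
        """Exhaustive (-, 0, +)^2 grid for (r_low, r_high) in both modes."""
        for r_low, r_high in itertools.product((-5, 0, 5), repeat=2):
            locus = scored(10, 10 + r_low, 10 + r_high)
            assert (positivity_filter([locus]) == [locus]) is (
                r_low > 0 and r_high > 0
            )
            assert (positivity_filter([locus], require_both=False) == [locus]) is (
                r_low > 0
            )

    def test_random_scores_match_brute_force_predicates(self):
        rng = np.random.default_rng(77)
        loci = [
            scored(*np.round(rng.uniform(0, 100, size=3), 2))
            for _ in range(300)
        ]
        dose_kept = dose_dependence_filter(loci)
        pos_kept = positivity_filter(loci)
        for l in loci:
            assert (l in dose_kept) == (l.m_high - l.m_control > l.m_low - l.m_control)
            assert (l in pos_kept) == (
                l.m_low > l.m_control and l.m_high > l.m_control
            )


class TestMsatIntersection:
    MSAT = MicrosatelliteLocus("s1", 1000, 1014, "AAC", 5)

    def indel_at(self, position, ref="AAAC"):
        return scored(
            0, 20, 60,
            site=make_site([(0, 0), (0, 1), (0, 1)], position=position,
                           ref=ref, alts=(ref[0],)),
        )

    def test_deletion_inside_msat_retained_with_motif(self):
        hit = intersect_with_msats([self.indel_at(1000)], [self.MSAT])
        assert len(hit) == 1
        assert hit[0].msat.notation == "(AAC)5"

    def test_one_bp_left_of_msat_start_removed(self):
        # single-base indel anchored at 999 does not reach base 1000
        assert intersect_with_msats([self.indel_at(999, ref="A")], [self.MSAT]) == []
        # but a ref allele spanning into the repeat does
        assert len(intersect_with_msats([self.indel_at(999)], [self.MSAT])) == 1

    def test_largest_overlap_wins_ties_leftmost(self):
        left = MicrosatelliteLocus("s1", 990, 1001, "CA", 6)
        right = MicrosatelliteLocus("s1", 1002, 1013, "TG", 6)
        locus = self.indel_at(1000, ref="AAAAA")  # spans 1000-1004: 2 vs 3 bp
        assert intersect_with_msats([locus], [left, right])[0].msat == right
        tie_left = MicrosatelliteLocus("s1", 996, 1001, "CA", 3)
        tie_right = MicrosatelliteLocus("s1", 1003, 1008, "TG", 3)
        locus = self.indel_at(1000, ref="AAAA")  # spans 1000-1003: 2 vs 1
        assert intersect_with_msats([locus], [tie_left, tie_right])[0].msat == tie_left

    def test_random_intervals_match_all_pairs_oracle(self):
        rng = np.random.default_rng(123)
        scaffolds = ["s1", "s2"]
        targets = []
        for _ in range(150):
            start = int(rng.integers(1, 5000))
            targets.append(
                MicrosatelliteLocus(
                    scaffolds[int(rng.integers(0, 2))], start, start + 11, "CA", 6
                )
            )
        queries = []
        for i in range(300):
            pos = int(rng.integers(1, 5000))
            ref = "A" * int(rng.integers(1, 6))
            queries.append(self.indel_at(pos, ref=ref))
            queries[-1] = scored(
                0, 20, 60,
                site=make_site([(0, 0), (0, 1), (0, 1)], position=pos,
                               ref=ref, alts=(ref[0] + "T",)),
            )
            object.__setattr__(
                queries[-1].site, "scaffold", scaffolds[int(rng.integers(0, 2))]
            )
        got = intersect_with_msats(queries, targets)
        got_map = {id(q.site): q.msat for q in got}
        want = brute_force_overlaps(
            [(q.site.scaffold, *q.site.ref_span) for q in queries],
            [(t.scaffold, t.start, t.end) for t in targets],
        )
        assert len(got) == len(want)
        for qi, ti in want.items():
            assert got_map[id(queries[qi].site)] == targets[ti]


class TestControlDiffers:
    def test_textbook_pass(self):
        site = make_site(
            [(0, 0), (0, 1), (0, 1)],
            depths=[(30, 0), (22, 8), (10, 20)],
        )
        loci = score_sites([site])
        assert control_differs_filter(loci) == loci

    def test_identical_genotypes_removed_despite_depth_gradient(self):
        site = make_site(
            [(0, 1), (0, 1), (0, 1)],
            depths=[(20, 10), (18, 12), (10, 20)],
        )
        assert control_differs_filter(score_sites([site])) == []

    def test_control_reads_must_be_strictly_fewer(self):
        site = make_site(
            [(0, 0), (0, 1), (1, 1)],
            depths=[(22, 8), (22, 8), (2, 28)],  # low ties the control
        )
        assert control_differs_filter(score_sites([site])) == []

    def test_missing_genotype_removed(self):
        site = make_site([(None, None), (0, 1), (0, 1)],
                         depths=[(30, 0), (20, 10), (10, 20)])
        assert control_differs_filter(score_sites([site])) == []


class TestRanking:
    def test_depth_orders_candidates(self):
        deep = scored(0, 20, 60, site=make_site(
            [(0, 0), (0, 1), (0, 1)], position=10, depths=[(80, 20)] * 3,
        ), msat=TestMsatIntersection.MSAT)
        shallow = scored(0, 20, 60, site=make_site(
            [(0, 0), (0, 1), (0, 1)], position=20, depths=[(15, 5)] * 3,
        ), msat=TestMsatIntersection.MSAT)
        ranked = rank_candidates([shallow, deep])
        assert [c.scored for c in ranked] == [deep, shallow]
        assert [c.rank for c in ranked] == [1, 2]
        assert ranked[0].total_depth_sum == 300

    def test_equal_depth_breaks_tie_on_high_dose_response(self):
        strong = scored(0, 20, 40, site=make_site(
            [(0, 0), (0, 1), (0, 1)], position=10), msat=TestMsatIntersection.MSAT)
        weak = scored(0, 15, 20, site=make_site(
            [(0, 0), (0, 1), (0, 1)], position=20), msat=TestMsatIntersection.MSAT)
        ranked = rank_candidates([weak, strong])
        assert [c.scored for c in ranked] == [strong, weak]


class TestCascade:
    def test_final_set_is_stage_order_invariant(self, small_study):
        indels = select_indels(small_study.sites)
        loci = score_sites(indels)
        msats = small_study.msats
        stages = {
            "dose": dose_dependence_filter,
            "pos": positivity_filter,
            "msat": lambda l: intersect_with_msats(l, msats),
            "ctrl": control_differs_filter,
        }
        reference_set = None
        for order in itertools.permutations(stages):
            current = loci
            for name in order:
                current = stages[name](current)
            result = {(l.site.scaffold, l.site.position) for l in current}
            if reference_set is None:
                reference_set = result
            assert result == reference_set

    def test_trace_counts_non_increasing(self, small_study):
        loci = score_sites(select_indels(small_study.sites))
        _, trace = run_cascade(loci, small_study.msats)
        counts = trace.counts
        assert counts == sorted(counts, reverse=True)
        assert len(trace.stages) == 5

    def test_score_bounds(self, small_study):
        for locus in score_sites(small_study.sites):
            for m in (locus.m_control, locus.m_low, locus.m_high):
                assert 0 <= m <= 100
            for r in (locus.r_low, locus.r_high):
                assert -100 <= r <= 100


class TestPublishedFixture:
    def test_all_rows_pass_score_filters(self):
        """Every published candidate shows a positive, dose-increasing
        relative score: 30 mM response > 10 mM response > 0."""
        table = load_candidate_fixture()
        assert len(table) == 124
        r_low = table["score_10mM"] - table["score_control"]
        r_high = table["score_30mM"] - table["score_control"]
        assert (r_high > r_low).all()
        assert (r_low > 0).all()

    def test_fixture_shape(self):
        table = load_candidate_fixture()
        assert set(table.columns) >= {
            "scaffold", "position", "motif", "repeat_count",
            "score_10mM", "score_30mM", "score_control",
        }
        assert table["motif"].str.len().between(2, 4).all()
        assert table.duplicated(["scaffold", "position"]).sum() == 0
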