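"""Kinase positional categories, domain coverage, disorder and mutations."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from kinophos import (
    KDLabel,
    Kinase,
    KinaseType,
    MutationRecord,
    PhosphoSite,
    PositionalCategory,
    classify_positional,
    disorder_overlap,
    kd_coverage,
    locate_site,
    mutation_join,
    rank_sites,
    select_predominant,
    site_contexts,
)


def make_kinase(length=100, domains=((40, 80),), disorder=(), kid="K1"):
    return Kinase(
        kinase_id=kid, gene_symbol="G", group="GRP", family="FAM",
        kinase_type=KinaseType.ST, sequence="S" * length,
        domain_intervals=list(domains), disordered_intervals=list(disorder),
    )


def profile_for(kinase, positions_ht):
    sites = [
        PhosphoSite(kinase.kinase_id, "S", pos, ht, 0)
        for pos, ht in positions_ht
    ]
    return select_predominant(rank_sites(sites))


class TestLocateSite:
    @pytest.mark.parametrize(
        "pos,expected", [(150, True), (400, True), (401, False), (149, False)]
    )
    def test_inclusive_interval_membership(self, pos, expected):
        assert locate_site(pos, [(150, 400)]) is expected

    def test_multiple_intervals(self):
        assert locate_site(5, [(1, 3), (5, 9)])
        assert not locate_site(4, [(1, 3), (5, 9)])


class TestClassify:
    def test_all_three_inside_is_pikd(self):
        k = make_kinase()
        prof = profile_for(k, [(50, 9), (60, 8), (70, 7), (5, 1)])
        assert classify_positional(prof, k).category == PositionalCategory.PiKD

    def test_all_three_outside_is_pokd(self):
        k = make_kinase()
        prof = profile_for(k, [(5, 9), (10, 8), (90, 7)])
        assert classify_positional(prof, k).category == PositionalCategory.PoKD

    def test_mixed_is_pakd(self):
        k = make_kinase()
        prof = profile_for(k, [(50, 9), (5, 8), (10, 7)])
        assert classify_positional(prof, k).category == PositionalCategory.PaKD

    @pytest.mark.parametrize("positions", [[], [(50, 3)]])
    def test_zero_or_one_site_is_pekd(self, positions):
        k = make_kinase()
        prof = profile_for(k, positions)
        assert classify_positional(prof, k).category == PositionalCategory.PeKD

    def test_two_sites_use_same_rule(self):
        k = make_kinase()
        assert classify_positional(profile_for(k, [(50, 9), (60, 8)]), k).category == PositionalCategory.PiKD
        assert classify_positional(profile_for(k, [(50, 9), (5, 8)]), k).category == PositionalCategory.PaKD

    def test_rank_four_and_below_never_matter(self):
        k = make_kinase()
        base = profile_for(k, [(50, 9), (60, 8), (70, 7)])
        extended = profile_for(k, [(50, 9), (60, 8), (70, 7), (5, 6), (6, 5)])
        assert classify_positional(base, k).category == classify_positional(extended, k).category

    def test_profile_kinase_mismatch_is_error(self):
        k = make_kinase(kid="K1")
        other = make_kinase(kid="K2")
        prof = profile_for(other, [(50, 1), (60, 1)])
        with pytest.raises(ValueError):
            classify_positional(prof, k)

    @given(st.lists(st.tuples(st.integers(1, 100), st.integers(1, 50)),
                    min_size=0, max_size=8, unique_by=lambda t: t[0]))
    def test_categories_partition_every_kinase(self, positions_ht):
        k = make_kinase()
        cat = classify_positional(profile_for(k, positions_ht), k)
        assert cat.category in set(PositionalCategory)
        if len(positions_ht) <= 1:
            assert cat.category == PositionalCategory.PeKD


class TestKDCoverage:
    @pytest.mark.parametrize(
        "length,domains,ratio,label",
        [
            (500, [(1, 375)], 0.75, KDLabel.KD_HIGH),
            (400, [(101, 300)], 0.50, KDLabel.KD_MID),
            (300, [(50, 149)], 100 / 300, KDLabel.KD_LESS),
            (100, [(1, 70)], 0.70, KDLabel.KD_HIGH),       # boundary: 0.70 is High
            (100, [(1, 50)], 0.50, KDLabel.KD_MID),        # boundary: 0.50 is Mid
            (100, [(1, 49)], 0.49, KDLabel.KD_LESS),
        ],
    )
    def test_ratio_and_strata_boundaries(self, length, domains, ratio, label):
        got_ratio, got_label = kd_coverage(make_kinase(length, domains))
        assert got_ratio == pytest.approx(ratio)
        assert got_label == label

    def test_dual_domain_intervals_are_summed(self):
        ratio, label = kd_coverage(make_kinase(100, [(1, 30), (51, 90)]))
        assert ratio == pytest.approx(0.70) and label == KDLabel.KD_HIGH

    def test_no_domain_is_less(self):
        ratio, label = kd_coverage(make_kinase(100, ()))
        assert ratio == 0.0 and label == KDLabel.KD_LESS


class TestDisorderAndMutations:
    def _site(self, pos, kid="K1"):
        return PhosphoSite(kid, "S", pos, 1, 0)

    def test_disorder_overlap_inclusive_edges(self):
        k = make_kinase(disorder=[(10, 30)])
        assert disorder_overlap(self._site(20), k)
        assert disorder_overlap(self._site(10), k)
        assert disorder_overlap(self._site(30), k)
        assert not disorder_overlap(self._site(31), k)

    def test_no_disorder_intervals(self):
        assert not disorder_overlap(self._site(20), make_kinase())

    def test_mutation_join_exact_position_only(self):
        k = make_kinase()
        sites = [self._site(100 - 50)]  # position 50, inside domain
        muts = [MutationRecord("K1", 50, "S", "A"), MutationRecord("K1", 51, "S", "A")]
        tallies = mutation_join(sites, muts, k)
        assert tallies == {"in_domain": 1, "outside_domain": 0}

    def test_two_mutations_at_one_site_count_twice(self):
        k = make_kinase()
        sites = [self._site(5)]  # outside domain
        muts = [MutationRecord("K1", 5, "S", "A"), MutationRecord("K1", 5, "S", "G")]
        assert mutation_join(sites, muts, k) == {"in_domain": 0, "outside_domain": 2}

    def test_site_contexts_flags(self):
        k = make_kinase(disorder=[(1, 10)])
        ctxs = site_contexts([self._site(5), self._site(50)], k,
                             [MutationRecord("K1", 50, "S", "A")])
        assert (ctxs[0].in_domain, ctxs[0].in_disorder, ctxs[0].co_mutated) == (False, True, False)
        assert (ctxs[1].in_domain, ctxs[1].in_disorder, ctxs[1].co_mutated) == (True, False, True)
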