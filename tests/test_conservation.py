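"""Windowed conservation scoring: examples, bounds, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kinophos import (
    ConservationLabel,
    PhosphoSite,
    conservation_score,
    extract_window,
    family_unique_sites,
    label_conservation,
    score_position,
)
from kinophos.conservation import DEFAULT_PROPERTY_GROUPS, ScoringWeights
from kinophos.io import aligned_family_from_rows
from kinophos.model import AMINO_ACIDS, GAP

ALPHABET = AMINO_ACIDS + GAP


class TestExtractWindow:
    def test_interior_window_has_no_padding(self):
        seq = "ABCDEFGHIKLMNPQRSTVW"  # length 20
        win = extract_window(seq, 10, w=5)
        assert win.window == seq[4:15] and len(win.window) == 11
        assert win.center == seq[9]

    def test_left_boundary_pads_with_gaps(self):
        win = extract_window("ABCDEFGHIK", 3, w=5)
        assert win.window.startswith("---") and not win.window.startswith("----")

    def test_first_position_pads_five(self):
        win = extract_window("ABCDEFGHIK", 1, w=5)
        assert win.window[:5] == "-----" and win.center == "A"

    def test_out_of_range_position(self):
        with pytest.raises(ValueError):
            extract_window("ABC", 4)

    @given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=50),
           st.data(), st.integers(1, 7))
    def test_window_length_always_2w_plus_1(self, seq, data, w):
        p = data.draw(st.integers(1, len(seq)))
        assert len(extract_window(seq, p, w=w).window) == 2 * w + 1


def oracle_position_score(ref, chars, w_exact=1.0, w_property=0.5, w_gap=0.0):
    """Independent character-by-character recount of one position."""
    group = {}
    for gname, members in DEFAULT_PROPERTY_GROUPS.items():
        for aa in members:
            group[aa] = gname
    n = len(chars)
    exact = sum(1 for a in chars if a != GAP and a == ref)
    prop = sum(
        1
        for a in chars
        if a != GAP and a != ref and ref in group and a in group and group[a] == group[ref]
    )
    gaps = sum(1 for a in chars if a == GAP)
    if ref == GAP:
        return 0.0
    return min(1.0, max(0.0, (exact * w_exact + prop * w_property + gaps * w_gap) / n))


class TestScorePosition:
    def test_perfect_conservation_scores_one(self):
        assert score_position("S", ["S", "S", "S"]).score == 1.0

    def test_mixed_exact_property_gap(self):
        # 2 exact L + 1 hydrophobic I + 1 gap over n=4: 0.5 + 0.125 + 0 = 0.625
        ps = score_position("L", ["L", "L", "I", "-"])
        assert ps.exact_matches == 2 and ps.property_matches == 1 and ps.gaps == 1
        assert ps.score == pytest.approx(0.625)

    def test_all_gaps_score_zero_under_default_weights(self):
        assert score_position("S", ["-", "-"]).score == 0.0

    def test_empty_comparison_set_is_error(self):
        with pytest.raises(ValueError):
            score_position("S", [])

    def test_gap_reference_contributes_zero(self):
        assert score_position(GAP, ["S", "S"]).score == 0.0

    def test_counts_never_exceed_n(self):
        ps = score_position("A", ["A", "V", "-", "W"])
        assert ps.exact_matches + ps.property_matches + ps.gaps <= ps.n

    def test_scoring_agrees_with_oracle_on_random_positions(self):
        rng = np.random.default_rng(7)
        letters = np.array(list(ALPHABET))
        for _ in range(2000):
            ref = str(rng.choice(letters))
            chars = [str(c) for c in rng.choice(letters, size=rng.integers(1, 9))]
            assert score_position(ref, chars).score == pytest.approx(
                oracle_position_score(ref, chars)
            )

    @given(st.sampled_from(AMINO_ACIDS),
           st.lists(st.sampled_from(ALPHABET), min_size=1, max_size=10),
           st.data())
    def test_exact_match_substitution_never_decreases_score(self, ref, chars, data):
        i = data.draw(st.integers(0, len(chars) - 1))
        improved = list(chars)
        improved[i] = ref
        assert score_position(ref, improved).score >= score_position(ref, chars).score

    @given(st.sampled_from(AMINO_ACIDS),
           st.lists(st.sampled_from(ALPHABET), min_size=1, max_size=10),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, ref, chars, rnd):
        shuffled = list(chars)
        rnd.shuffle(shuffled)
        assert score_position(ref, shuffled).score == score_position(ref, chars).score


def _site(kid, seq, pos):
    return PhosphoSite(kinase_id=kid, residue=seq[pos - 1], position=pos,
                       ht_count=1, lt_count=0)


class TestConservationScore:
    def test_identity_family_scores_exactly_one(self, identity_family):
        # interior site: the full 11-column window lies inside the alignment
        seq = identity_family.ungapped("K0")
        pos = seq.index("S", 6) + 1
        assert 5 < pos <= len(seq) - 5
        r = conservation_score(identity_family, _site("K0", seq, pos))
        assert r.total_score == 1.0
        assert r.label == ConservationLabel.HIGHLY_CONSERVED and not r.unique_flag

    def test_all_gap_comparisons_score_exactly_zero(self):
        # other members are gaps across the query's whole window
        rows = {
            "Q": "AAAAASAAAAA",
            "B": "-----------",
            "C": "-----------",
        }
        # ragged all-gap rows are invalid sequences; append a shared block
        rows = {k: v + "MKT" for k, v in rows.items()}
        af = aligned_family_from_rows("F", rows)
        r = conservation_score(af, _site("Q", rows["Q"].replace("-", ""), 6))
        assert r.total_score == 0.0 and r.unique_flag

    def test_window_beyond_alignment_edges_counts_as_gap_reference(self):
        af = aligned_family_from_rows("F", {"Q": "SAA", "B": "SAA"})
        r = conservation_score(af, _site("Q", "SAA", 1))
        # columns -4..0 fall outside: reference '-' scores 0 there
        assert sum(1 for p in r.positions if p.reference == GAP) >= 4
        assert 0.0 <= r.total_score <= 1.0

    def test_unknown_kinase_is_error(self, identity_family):
        with pytest.raises(KeyError):
            conservation_score(identity_family, _site("KX", "SSS", 1))

    def test_total_is_mean_of_position_scores(self, identity_family):
        seq = identity_family.ungapped("K1")
        r = conservation_score(identity_family, _site("K1", seq, 5))
        assert r.total_score == pytest.approx(
            sum(p.score for p in r.positions) / len(r.positions)
        )

    @given(st.integers(0, 10_000))
    def test_total_score_bounded_on_random_families(self, seed):
        rng = np.random.default_rng(seed)
        n, L = int(rng.integers(2, 6)), int(rng.integers(12, 40))
        rows = {}
        for i in range(n):
            row = rng.choice(list(ALPHABET), size=L)
            if not any(c != GAP for c in row):
                row[0] = "S"
            rows[f"K{i}"] = "".join(row)
        af = aligned_family_from_rows("F", rows)
        seq = af.ungapped("K0")
        stys = [i + 1 for i, c in enumerate(seq) if c in "STY"]
        pos = stys[0] if stys else 1
        site = PhosphoSite("K0", seq[pos - 1], pos, 1, 0) if seq[pos - 1] in "STY" else None
        if site is None:
            return
        r = conservation_score(af, site)
        assert 0.0 <= r.total_score <= 1.0


class TestLabels:
    @pytest.mark.parametrize(
        "score,label,unique",
        [
            (0.80, ConservationLabel.HIGHLY_CONSERVED, False),
            (0.75, ConservationLabel.HIGHLY_CONSERVED, False),
            (0.50, ConservationLabel.INTERMEDIATE, False),
            (0.25, ConservationLabel.LESS_CONSERVED, False),
            (0.10, ConservationLabel.LESS_CONSERVED, False),
            (0.05, ConservationLabel.LESS_CONSERVED, True),
        ],
    )
    def test_threshold_boundaries(self, score, label, unique):
        assert label_conservation(score) == (label, unique)

    def test_score_outside_unit_interval_is_error(self):
        with pytest.raises(ValueError):
            label_conservation(1.2)

    def test_family_unique_filter(self):
        class R:
            def __init__(self, flag):
                self.unique_flag = flag

        rs = [R(True), R(False), R(True)]
        assert len(family_unique_sites(rs)) == 2


class TestWeights:
    def test_property_weight_cannot_exceed_exact(self):
        with pytest.raises(ValueError):
            ScoringWeights(w_exact=0.5, w_property=1.0)

    def test_negative_gap_weight_clamps_at_zero(self):
        w = ScoringWeights(w_gap=-1.0)
        assert score_position("S", ["-", "-", "-"], w).score == 0.0
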