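"""Category and respondent scoring: worked orderings, tie policies,
exhaustive oracle agreement, and structural invariants."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from novascore.errors import EmptyInputError, ValidationError
from novascore.scoring import (
    ScoringPolicy,
    score_category,
    score_matrix,
    score_respondent,
    score_table,
    scores_to_frame,
)

from conftest import oracle_category_points

DEFAULT = ScoringPolicy()
ZERO_CAT = ScoringPolicy(tie_policy="zero_category")
ONE_PAIR = ScoringPolicy(one_pair_policy="one_point")


class TestWorkedOrderings:
    @pytest.mark.parametrize(
        "ratings,points,pairs",
        [
            ((10, 5, 1), 2, 3),  # fully correct G1>G3>G4
            ((10, 1, 5), 1, 2),  # one pairwise ranking wrong (G1>G4>G3)
            ((1, 5, 10), 0, 0),  # fully reversed
            ((5, 5, 5), 0, 0),   # all tied
            ((9, 9, 2), 1, 2),   # tied top pair; two strict pairs remain
        ],
    )
    def test_default_policy(self, ratings, points, pairs):
        cs = score_category(*ratings, DEFAULT)
        assert (cs.points, cs.correct_pairs) == (points, pairs)

    def test_tied_pair_earns_nothing(self):
        # G3 = G4: that pair cannot count, so 2 points are unreachable
        cs = score_category(10, 4, 4, DEFAULT)
        assert cs.points == 1 and cs.correct_pairs == 2

    def test_zero_category_policy_voids_tied_triples(self):
        assert score_category(9, 9, 2, ZERO_CAT).points == 0
        assert score_category(10, 5, 1, ZERO_CAT).points == 2

    def test_one_pair_policy_upgrades_single_correct_pair(self):
        # G3>G4>G1: only the (G3,G4) pair is correct
        assert score_category(1, 10, 5, DEFAULT).points == 0
        assert score_category(1, 10, 5, ONE_PAIR).points == 1


class TestExhaustiveOracle:
    @pytest.mark.parametrize("policy,tie,onep", [
        (DEFAULT, "pair_incorrect", "zero"),
        (ZERO_CAT, "zero_category", "zero"),
        (ONE_PAIR, "pair_incorrect", "one_point"),
    ])
    def test_all_thousand_triples(self, policy, tie, onep):
        for r1, r3, r4 in itertools.product(range(1, 11), repeat=3):
            expected = oracle_category_points(r1, r3, r4, tie, onep)
            assert score_category(r1, r3, r4, policy).points == expected

    def test_translation_invariance(self):
        # shifting all three ratings by a constant never changes the score
        for r1, r3, r4 in itertools.product(range(1, 11), repeat=3):
            for shift in (1, 2, 3):
                if max(r1, r3, r4) + shift <= 10:
                    assert (
                        score_category(r1 + shift, r3 + shift, r4 + shift).points
                        == score_category(r1, r3, r4).points
                    )

    def test_permutation_of_group_assignment_matches_pair_recount(self):
        # relabeling which rating belongs to which group rescores exactly as
        # recomputing the three pairs on the permuted triple
        for triple in itertools.product(range(1, 6), repeat=3):
            for perm in itertools.permutations(triple):
                assert score_category(*perm).points == oracle_category_points(*perm)


@st.composite
def rating_triples(draw):
    return tuple(draw(st.integers(1, 10)) for _ in range(3))


class TestRangeProperties:
    @given(rating_triples())
    @settings(max_examples=200, deadline=None)
    def test_category_points_in_range(self, triple):
        cs = score_category(*triple)
        assert cs.points in {0, 1, 2}
        assert 0 <= cs.correct_pairs <= 3


def _ratings_for(instrument, per_category):
    """Build an item_id->rating map giving each category the same triple."""
    from novascore.instrument import GROUP_ORDER

    out = {}
    for category in instrument.categories:
        triad = instrument.triad(category)
        triple = per_category[category] if isinstance(per_category, dict) else per_category
        for g, r in zip(GROUP_ORDER, triple):
            out[triad[g].item_id] = r
    return out


class TestRespondent:
    def test_all_correct_totals_eight(self, instrument):
        res = score_respondent(_ratings_for(instrument, (9, 6, 3)), instrument)
        assert res.total == 8 and res.n_complete_categories == 4

    def test_all_reversed_totals_zero(self, instrument):
        res = score_respondent(_ratings_for(instrument, (3, 6, 9)), instrument)
        assert res.total == 0

    def test_mixed_categories_sum(self, instrument):
        ratings = _ratings_for(
            instrument,
            {
                "banana": (10, 5, 1),  # 2
                "beef": (10, 5, 1),    # 2
                "corn": (10, 1, 5),    # 1
                "dairy": (7, 7, 7),    # 0
            },
        )
        res = score_respondent(ratings, instrument)
        assert res.total == 5

    def test_missing_rating_voids_category_and_total(self, instrument):
        ratings = _ratings_for(instrument, (9, 6, 3))
        del ratings["banana_fresh"]
        res = score_respondent(ratings, instrument)
        assert res.total is None
        assert res.n_complete_categories == 3
        assert res.points("banana") is None
        assert res.points("beef") == 2

    def test_unknown_item_rejected(self, instrument):
        with pytest.raises(ValidationError, match="unknown item_id"):
            score_respondent({"pizza": 5}, instrument)

    @pytest.mark.parametrize("bad", [0, 11, 5.5, "seven"])
    def test_out_of_contract_rating_rejected(self, instrument, bad):
        ratings = _ratings_for(instrument, (9, 6, 3))
        ratings["banana_fresh"] = bad
        with pytest.raises(ValidationError):
            score_respondent(ratings, instrument)


class TestBatchScoring:
    def _random_table(self, instrument, n, rng, missing_rate=0.0):
        rows = []
        for i in range(n):
            for item in instrument.items:
                if rng.random() < missing_rate:
                    continue
                rows.append((f"r{i}", item.item_id, int(rng.integers(1, 11))))
        return pd.DataFrame(rows, columns=["respondent_id", "item_id", "rating"])

    def test_totals_match_independent_pair_evaluator(self, instrument):
        rng = np.random.default_rng(42)
        table = self._random_table(instrument, 50, rng)
        results = score_table(table, instrument)
        lookup = table.set_index(["respondent_id", "item_id"])["rating"]
        from novascore.instrument import GROUP_ORDER

        for res in results:
            expected = 0
            for category in instrument.categories:
                triad = instrument.triad(category)
                triple = [lookup[(res.respondent_id, triad[g].item_id)] for g in GROUP_ORDER]
                expected += oracle_category_points(*triple)
            assert res.total == expected

    def test_matrix_fast_path_agrees_with_per_respondent_scorer(self, instrument):
        rng = np.random.default_rng(7)
        table = self._random_table(instrument, 40, rng, missing_rate=0.05)
        results = score_table(table, instrument)
        frame = scores_to_frame(results)
        wide = table.pivot(index="respondent_id", columns="item_id", values="rating")
        for item in instrument.item_ids:
            if item not in wide.columns:
                wide[item] = np.nan
        wide = wide.loc[frame["respondent_id"], list(instrument.item_ids)]
        totals = score_matrix(wide.to_numpy(float), instrument)
        assert np.allclose(totals, frame["total"].to_numpy(), equal_nan=True)

    def test_empty_table_is_an_error(self, instrument):
        empty = pd.DataFrame(columns=["respondent_id", "item_id", "rating"])
        with pytest.raises(EmptyInputError):
            score_table(empty, instrument)

    def test_duplicate_rating_rejected(self, instrument):
        table = pd.DataFrame(
            {
                "respondent_id": ["r0", "r0"],
                "item_id": ["banana_fresh", "banana_fresh"],
                "rating": [5, 6],
            }
        )
        with pytest.raises(ValidationError, match="duplicate"):
            score_table(table, instrument)

    def test_input_order_preserved(self, instrument):
        rng = np.random.default_rng(0)
        table = self._random_table(instrument, 5, rng)
        ids = [r.respondent_id for r in score_table(table, instrument)]
        assert ids == [f"r{i}" for i in range(5)]
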