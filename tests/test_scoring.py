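"""Score synthesis rules, scorecards, tertile assignment and placement."""

import itertools

import pandas as pd
import pytest

from rootslope import scoring
from rootslope.scoring import (
    DEFAULT_FOLD_ORDERS,
    DEFAULT_RULES,
    PlacementProfile,
    Position,
    ScoreRuleTable,
    assign_scores,
    combine_pair,
    load_score_fixture,
    property_global,
    recommend_position,
    score_card,
)

# ---------------------------------------------------------------------------
# Rule table
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "a, b, expected",
    [
        (1, 1, 1),  # poor + poor = poor
        (3, 3, 3),  # good + good = good
        (1, 3, 2),  # poor + good = average
        (1, 2, 1),  # poor + average = poor
        (3, 2, 3),  # good + average = good
        (2, 2, 2),  # average + average = average
        (2, 1, 1),  # symmetry of poor + average
    ],
)
def test_pairwise_synthesis_rules(a, b, expected):
    assert combine_pair(a, b) == expected


def test_rule_table_total_and_symmetric():
    for a, b in itertools.product((1, 2, 3), repeat=2):
        assert combine_pair(a, b) in (1, 2, 3)
        assert combine_pair(a, b) == combine_pair(b, a)


def test_rule_table_rejects_out_of_range():
    with pytest.raises(ValueError):
        combine_pair(0, 2)
    with pytest.raises(ValueError):
        combine_pair(1, 4)


def test_rule_table_rejects_asymmetric_or_incomplete():
    with pytest.raises(ValueError, match="symmetric"):
        ScoreRuleTable(
            {(1, 1): 1, (3, 3): 3, (1, 3): 2, (3, 1): 3, (1, 2): 1, (3, 2): 3, (2, 2): 2}
        )
    with pytest.raises(ValueError, match="incomplete"):
        ScoreRuleTable({(1, 1): 1})


# ---------------------------------------------------------------------------
# Ordered fold
# ---------------------------------------------------------------------------


def test_property_global_is_an_ordered_left_fold():
    # non-associativity makes the order observable
    assert property_global([1, 1, 3]) == 2
    assert property_global([1, 3, 1]) == 1
    assert property_global([3, 1, 1]) == 1
    assert property_global([1, 3, 3]) == 3


@pytest.mark.parametrize("s", [1, 2, 3])
def test_property_global_idempotent_on_uniform_inputs(s):
    assert property_global([s, s]) == s
    assert property_global([s, s, s]) == s


def test_property_global_bounded_by_inputs():
    for seq in itertools.product((1, 2, 3), repeat=3):
        g = property_global(list(seq))
        assert min(seq) <= g <= max(seq)


def test_property_global_rejects_wrong_arity():
    with pytest.raises(ValueError):
        property_global([])
    with pytest.raises(ValueError):
        property_global([2])
    with pytest.raises(ValueError):
        property_global([1, 2, 3, 1])


# ---------------------------------------------------------------------------
# Published scorecard reproduction
# ---------------------------------------------------------------------------

EXPECTED_CARDS = {
    # species: (tension, bending, abundance, mechanical, physiological)
    "Agave americana": (1, 3, 2, 3, 1),
    "Artemisia codonocephala": (3, 1, 2, 3, 3),
    "Arthraxon hispidus": (3, 1, 2, 1, 1),
    "Bauhinia championii": (2, 2, 2, 1, 1),
    "Chloris anomala": (3, 1, 1, 3, 2),
    "Ficus tikoua": (2, 1, 1, 1, 1),
    "Jatropha curcas": (1, 3, 1, 3, 2),
    "Pueraria stricta": (3, 3, 2, 3, 3),
    "Rhus chinensis": (1, 3, 2, 1, 1),
}


def test_fixture_scorecards_reproduce_published_table():
    """All 18 composite and 27 global cells of the reference scorecard."""
    fixture = load_score_fixture()
    assert set(fixture.index) == set(EXPECTED_CARDS)
    for sp, row in fixture.iterrows():
        card = score_card(sp, row.to_dict())
        t, b, ga, gm, gp = EXPECTED_CARDS[sp]
        assert card.composite_tension == t, sp
        assert card.composite_bending == b, sp
        assert card.globals_ == (ga, gm, gp), sp


def test_top_global_profile_is_pueraria_and_artemisia():
    """The headline reading: two species attain the best global profile."""
    fixture = load_score_fixture()
    totals = {
        sp: sum(score_card(sp, row.to_dict()).globals_)
        for sp, row in fixture.iterrows()
    }
    best = max(totals.values())
    winners = {sp for sp, v in totals.items() if v == best}
    assert winners == {"Pueraria stricta", "Artemisia codonocephala"}


def test_row_listed_physiological_order_does_not_reproduce_table():
    """The fold is non-associative: the (strain, N, cellulose) order fails."""
    fixture = load_score_fixture()
    row_order = dict(DEFAULT_FOLD_ORDERS)
    row_order["physiological"] = ("eps_ult_phys", "n_concentration", "cellulose")
    mismatches = {
        sp
        for sp, row in fixture.iterrows()
        if score_card(sp, row.to_dict(), fold_orders=row_order).global_physiological
        != EXPECTED_CARDS[sp][4]
    }
    assert mismatches == {"Ficus tikoua", "Pueraria stricta"}


def test_score_card_requires_complete_scores_and_fold_orders():
    fixture = load_score_fixture()
    row = fixture.iloc[0].to_dict()
    incomplete = {k: v for k, v in row.items() if k != "rar"}
    with pytest.raises(ValueError, match="missing trait scores"):
        score_card("x", incomplete)
    with pytest.raises(ValueError, match="fold order"):
        score_card("x", row, fold_orders={"abundance": ("rar", "t_max")})


# ---------------------------------------------------------------------------
# Score assignment
# ---------------------------------------------------------------------------


def _trait_frame(values_by_trait):
    idx = [f"sp{i}" for i in range(len(next(iter(values_by_trait.values()))))]
    base = {t: list(range(1, len(idx) + 1)) for t in scoring.SCORED_TRAITS}
    base.update(values_by_trait)
    return pd.DataFrame(base, index=idx)


def test_tertile_assignment_splits_nine_distinct_values_evenly():
    table = _trait_frame({"rar": [9, 1, 5, 3, 8, 2, 7, 4, 6]})
    scores = assign_scores(table, method="tertile")["rar"]
    assert sorted(scores) == [1, 1, 1, 2, 2, 2, 3, 3, 3]
    assert scores[table["rar"].idxmax()] == 3
    assert scores[table["rar"].idxmin()] == 1


def test_tertile_respects_lower_better_polarity_for_strain():
    table = _trait_frame({"eps_ult": [25.0, 10.0, 15.0, 30.0, 12.0, 18.0, 22.0, 9.0, 20.0]})
    scores = assign_scores(table, method="tertile")
    # smallest ultimate strain (most reversible deformation) scores best
    assert scores.loc[table["eps_ult"].idxmin(), "eps_ult_phys"] == 3
    assert scores.loc[table["eps_ult"].idxmax(), "eps_ult_phys"] == 1
    assert (scores["eps_ult_mech"] == scores["eps_ult_phys"]).all()


def test_tertile_tie_break_is_deterministic():
    table = _trait_frame({"rar": [5.0] * 9})
    s1 = assign_scores(table, method="tertile")["rar"]
    s2 = assign_scores(table.iloc[::-1], method="tertile")["rar"]
    assert (s1.sort_index() == s2.sort_index()).all()


def test_fixture_method_returns_scores_verbatim():
    fixture = load_score_fixture()
    out = assign_scores(pd.DataFrame(), method="fixture", fixture=fixture)
    assert (out == fixture[list(scoring.SCORE_COLUMNS)]).all().all()


def test_assign_scores_errors():
    with pytest.raises(ValueError, match="fixture"):
        assign_scores(pd.DataFrame(), method="fixture")
    with pytest.raises(ValueError, match="missing traits"):
        assign_scores(pd.DataFrame({"rar": [1, 2, 3]}), method="tertile")


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------


def _any_card():
    fixture = load_score_fixture()
    return score_card("Pueraria stricta", fixture.loc["Pueraria stricta"].to_dict())


@pytest.mark.parametrize(
    "sector, depth, expected",
    [
        ("up", "none", Position.top),
        ("down", "none", Position.toe),
        ("none", "deep", Position.middle),
        ("none", "shallow", Position.top_or_toe),
        ("none", "none", Position.unclassified),
        ("up", "deep", Position.top),  # sector bias dominates the cascade
    ],
)
def test_placement_cascade(sector, depth, expected):
    evidence = ["observed trait bias"] if (sector, depth) != ("none", "none") else []
    profile = PlacementProfile(sector_bias=sector, depth_bias=depth, evidence=evidence)
    assert recommend_position(_any_card(), profile) == expected


def test_placement_profile_requires_evidence():
    with pytest.raises(ValueError, match="evidence"):
        PlacementProfile(sector_bias="up", evidence=[])
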