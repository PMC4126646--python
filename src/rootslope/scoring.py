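"""Multi-criteria species scoring for slope-stabilization potential.

Each species receives a 1/2/3 score (poor/average/good) per desirable root
trait.  Trait scores are synthesized into composite scores (tension,
bending) and three property globals (root abundance in soil, root mechanical
resistance, root physiological properties) through a pairwise rule table.
The synthesis operator is *not* an arithmetic product and is
non-associative, so multi-score globals are computed as an ordered left
fold.

The rule table
--------------
``1 ⊗ 1 = 1``, ``3 ⊗ 3 = 3``, ``1 ⊗ 3 = 2``, ``1 ⊗ 2 = 1``, ``3 ⊗ 2 = 3``
and ``2 ⊗ 2 = 2``; the operator is symmetric.  Intuitively a score of 2 acts
as a neutral element and opposite extremes average out.

A shipped fixture (``fixtures/species_scores.csv``) encodes the per-trait
scores of the nine reference species from the Yunnan field study, so the
published scorecard can be reproduced without the unpublished raw data.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Score",
    "ScoreRuleTable",
    "DEFAULT_RULES",
    "TRAIT_POLARITY",
    "SCORED_TRAITS",
    "DEFAULT_FOLD_ORDERS",
    "ScoreCard",
    "PlacementProfile",
    "Position",
    "combine_pair",
    "property_global",
    "assign_scores",
    "score_card",
    "score_cards_frame",
    "recommend_position",
    "load_score_fixture",
]

Score = int
_VALID_SCORES = (1, 2, 3)


class ScoreRuleTable:
    """Symmetric total map (score, score) -> score over {1, 2, 3}."""

    def __init__(self, pairs: Mapping[tuple[int, int], int]):
        table: dict[tuple[int, int], int] = {}
        for (a, b), c in pairs.items():
            self._check(a), self._check(b), self._check(c)
            table[(a, b)] = c
            if (b, a) in pairs and pairs[(b, a)] != c:
                raise ValueError(f"rule table not symmetric at ({a}, {b})")
            table[(b, a)] = c
        for a in _VALID_SCORES:
            for b in _VALID_SCORES:
                if (a, b) not in table:
                    raise ValueError(f"rule table incomplete: missing ({a}, {b})")
        self._table = table

    @staticmethod
    def _check(s: int) -> None:
        if s not in _VALID_SCORES:
            raise ValueError(f"score {s!r} outside {{1, 2, 3}}")

    def __getitem__(self, pair: tuple[int, int]) -> int:
        return self._table[pair]

    def combine(self, a: int, b: int) -> int:
        self._check(a), self._check(b)
        return self._table[(a, b)]


#: 1⊗1=1, 3⊗3=3, 1⊗3=2, 1⊗2=1, 3⊗2=3 plus the neutral pair 2⊗2=2.
DEFAULT_RULES = ScoreRuleTable(
    {
        (1, 1): 1,
        (3, 3): 3,
        (1, 3): 2,
        (1, 2): 1,
        (3, 2): 3,
        (2, 2): 2,
    }
)


def combine_pair(a: Score, b: Score, rules: ScoreRuleTable = DEFAULT_RULES) -> Score:
    """Synthesize two 1/2/3 scores into one via the rule table (symmetric)."""
    return rules.combine(a, b)


def property_global(
    ordered_scores: Sequence[Score], rules: ScoreRuleTable = DEFAULT_RULES
) -> Score:
    """Left-fold 2 or 3 scores with :func:`combine_pair`.

    The operator is non-associative, so the order of ``ordered_scores``
    matters: e.g. fold(1,1,3) = 2 but fold(1,3,1) = 1.
    """
    if not 2 <= len(ordered_scores) <= 3:
        raise ValueError("property_global requires 2 or 3 scores")
    acc = ordered_scores[0]
    for s in ordered_scores[1:]:
        acc = rules.combine(acc, s)
    return acc


# ---------------------------------------------------------------------------
# Trait tables and score assignment
# ---------------------------------------------------------------------------

#: Scored traits and their polarity. ``higher`` means a larger raw value is
#: better for slope stabilization. Ultimate tensile strain is the single
#: lower-is-better trait (short, mostly reversible deformation is desirable);
#: it enters both the mechanical and the physiological property, and the
#: fixture carries one score column per role because the published scorecard
#: assigns them independently.
TRAIT_POLARITY: dict[str, str] = {
    "stems_per_m2": "higher",
    "isv_over_dc": "higher",
    "rar": "higher",
    "rar_fine": "higher",
    "t_max": "higher",
    "rar_coarse": "higher",
    "ei": "higher",
    "eps_ult": "lower",
    "n_concentration": "higher",
    "cellulose": "higher",
}

SCORED_TRAITS = tuple(TRAIT_POLARITY)

#: Score columns a complete score table must carry (eps_ult split by role).
SCORE_COLUMNS = (
    "stems_per_m2",
    "isv_over_dc",
    "rar",
    "rar_fine",
    "t_max",
    "rar_coarse",
    "ei",
    "eps_ult_mech",
    "eps_ult_phys",
    "n_concentration",
    "cellulose",
)

#: Fold orders reproducing the published scorecard. The physiological order
#: is (strain, cellulose, nitrogen) — see docs/methods.md for the derivation;
#: the row-listed order (strain, nitrogen, cellulose) does not reproduce the
#: printed globals for two species because the fold is non-associative.
DEFAULT_FOLD_ORDERS: dict[str, tuple[str, ...]] = {
    "abundance": ("stems_per_m2", "isv_over_dc", "rar"),
    "mechanical": ("composite_tension", "composite_bending", "eps_ult_mech"),
    "physiological": ("eps_ult_phys", "cellulose", "n_concentration"),
}


def _tertile_scores(values: pd.Series, polarity: str) -> pd.Series:
    """Rank species on one trait and cut the ranking into thirds.

    Better performance gets the higher score. Ties get average ranks first;
    a tie straddling a tertile boundary is broken deterministically by
    lexicographic species order (index order after a stable sort).
    """
    sign = 1.0 if polarity == "higher" else -1.0
    # goodness ascending, ties broken lexicographically by species name
    order = (
        (sign * values.astype(float))
        .to_frame("goodness")
        .sort_index(kind="stable")
        .sort_values("goodness", kind="stable")
    )
    n = len(order)
    scores = {}
    for pos, species in enumerate(order.index, start=1):
        scores[species] = int(-(-3 * pos // n))  # ceil(3*pos/n) in {1,2,3}
    return pd.Series(scores).loc[values.index]


def assign_scores(
    table: pd.DataFrame,
    method: str = "tertile",
    fixture: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Map a species × trait table to per-trait 1/2/3 scores.

    Parameters
    ----------
    table
        Species-indexed raw trait values with the columns of
        :data:`SCORED_TRAITS` (``eps_ult`` as a single column) when
        ``method="tertile"``.
    method
        ``"tertile"`` ranks species per trait (respecting polarity) and cuts
        into thirds; ``"fixture"`` returns the supplied score table
        verbatim after validation.
    fixture
        Species-indexed table of 1/2/3 scores with the columns of
        :data:`SCORE_COLUMNS`; required for ``method="fixture"``.
    """
    if method == "fixture":
        if fixture is None:
            raise ValueError("method='fixture' requires a fixture score table")
        missing = [c for c in SCORE_COLUMNS if c not in fixture.columns]
        if missing:
            raise ValueError(f"fixture missing score columns: {missing}")
        out = fixture[list(SCORE_COLUMNS)].astype(int)
        bad = ~out.isin(_VALID_SCORES)
        if bad.any().any():
            raise ValueError("fixture contains scores outside {1, 2, 3}")
        return out
    if method != "tertile":
        raise ValueError(f"unknown scoring method {method!r}")

    missing = [t for t in SCORED_TRAITS if t not in table.columns]
    if missing:
        raise ValueError(f"trait table missing traits: {missing}")
    scores = pd.DataFrame(index=table.index)
    for trait in SCORED_TRAITS:
        col = _tertile_scores(table[trait].astype(float), TRAIT_POLARITY[trait])
        if trait == "eps_ult":
            scores["eps_ult_mech"] = col
            scores["eps_ult_phys"] = col
        else:
            scores[trait] = col
    return scores[list(SCORE_COLUMNS)]


# ---------------------------------------------------------------------------
# Score cards
# ---------------------------------------------------------------------------


@dataclass
class ScoreCard:
    """Per-species scorecard: trait scores, composites, property globals."""

    species: str
    trait_scores: dict[str, Score]
    composite_tension: Score
    composite_bending: Score
    global_abundance: Score
    global_mechanical: Score
    global_physiological: Score
    provenance: str = "assigned"

    @property
    def globals_(self) -> tuple[Score, Score, Score]:
        return (
            self.global_abundance,
            self.global_mechanical,
            self.global_physiological,
        )


def score_card(
    species: str,
    trait_scores: Mapping[str, Score],
    rules: ScoreRuleTable = DEFAULT_RULES,
    fold_orders: Mapping[str, Sequence[str]] = DEFAULT_FOLD_ORDERS,
    provenance: str = "assigned",
) -> ScoreCard:
    """Build the full scorecard for one species.

    The tension composite combines the fine-root RAR score with the tensile
    strength score; the bending composite combines the coarse-root RAR score
    with the bending rigidity score. The three property globals are ordered
    folds over the components named in ``fold_orders``.
    """
    missing = [c for c in SCORE_COLUMNS if c not in trait_scores]
    if missing:
        raise ValueError(f"{species}: missing trait scores: {missing}")
    for key in ("abundance", "mechanical", "physiological"):
        if key not in fold_orders:
            raise ValueError(f"missing fold order for property {key!r}")

    composite_tension = rules.combine(
        trait_scores["rar_fine"], trait_scores["t_max"]
    )
    composite_bending = rules.combine(
        trait_scores["rar_coarse"], trait_scores["ei"]
    )
    components: dict[str, Score] = dict(trait_scores)
    components["composite_tension"] = composite_tension
    components["composite_bending"] = composite_bending

    def fold(prop: str) -> Score:
        names = fold_orders[prop]
        try:
            seq = [components[n] for n in names]
        except KeyError as err:
            raise ValueError(f"unknown component in fold order {prop!r}: {err}")
        return property_global(seq, rules)

    return ScoreCard(
        species=species,
        trait_scores=dict(trait_scores),
        composite_tension=composite_tension,
        composite_bending=composite_bending,
        global_abundance=fold("abundance"),
        global_mechanical=fold("mechanical"),
        global_physiological=fold("physiological"),
        provenance=provenance,
    )


def score_cards_frame(cards: Iterable[ScoreCard]) -> pd.DataFrame:
    """Tabulate scorecards, one row per species (published-table layout)."""
    rows = []
    for c in cards:
        row = {"species": c.species, **c.trait_scores}
        row.update(
            composite_tension=c.composite_tension,
            composite_bending=c.composite_bending,
            global_abundance=c.global_abundance,
            global_mechanical=c.global_mechanical,
            global_physiological=c.global_physiological,
            provenance=c.provenance,
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("species")


def load_score_fixture() -> pd.DataFrame:
    """Shipped per-trait 1/2/3 scores for the nine reference species."""
    ref = importlib.resources.files("rootslope") / "fixtures" / "species_scores.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, index_col="species")


# ---------------------------------------------------------------------------
# Placement on a hotspot
# ---------------------------------------------------------------------------


class Position(str, Enum):
    top = "top"
    middle = "middle"
    toe = "toe"
    top_or_toe = "top_or_toe"
    unclassified = "unclassified"


@dataclass
class PlacementProfile:
    """Trait biases relevant to where on a hotspot a species acts best.

    ``sector_bias`` records whether desirable traits concentrate in the
    upslope or downslope root sector; ``depth_bias`` whether they
    concentrate deep or shallow. Biases must be backed by at least one
    evidence statement (a human-readable trait-level observation).
    """

    sector_bias: str = "none"  # up | down | none
    depth_bias: str = "none"  # deep | shallow | none
    evidence: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sector_bias not in ("up", "down", "none"):
            raise ValueError(f"bad sector_bias {self.sector_bias!r}")
        if self.depth_bias not in ("deep", "shallow", "none"):
            raise ValueError(f"bad depth_bias {self.depth_bias!r}")
        if (self.sector_bias != "none" or self.depth_bias != "none") and not self.evidence:
            raise ValueError("trait biases require at least one evidence entry")


def recommend_position(card: ScoreCard, profile: PlacementProfile) -> Position:
    """Recommend where on an unstable hotspot to plant a species.

    Rule cascade: roots biased upslope have the best chance of crossing the
    potential shear plane when the plant sits at the top of the slope
    (downslope bias: the toe). Deep-concentrated desirable traits reinforce
    the shear zone at depth in the middle of the hotspot; shallow
    concentration suits the top or the toe, where the shear plane nears the
    surface. Total function: anything else is unclassified.
    """
    if profile.sector_bias == "up":
        return Position.top
    if profile.sector_bias == "down":
        return Position.toe
    if profile.depth_bias == "deep":
        return Position.middle
    if profile.depth_bias == "shallow":
        return Position.top_or_toe
    return Position.unclassified
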