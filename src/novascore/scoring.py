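"""Knowledge scoring from healthiness ratings.

Within each category the respondent's three ratings (r1 for the G1 item, r3
for G3, r4 for G4) are compared pairwise. The three ordered pairs that a
knowledgeable respondent should satisfy strictly are::

    r1 > r3,   r1 > r4,   r3 > r4

All three correct earns 2 points for the category; exactly two correct earns
1 point; one or zero correct earns nothing. The total over the four default
categories therefore ranges from 0 to 8.

Tie handling is explicit policy. Under the default ``pair_incorrect`` policy
a tie makes only that pair incorrect (so e.g. ratings 9/9/2 still earn one
point from the two strict pairs against the G4 item); under ``zero_category``
any tie among the three ratings voids the whole category. A second policy
axis, ``one_pair_policy``, controls whether a single correct pair earns one
point instead of zero; the default awards nothing, reserving 1 point for
exactly-two-correct configurations. Neither variant changes the worked
orderings G1>G3>G4 -> 2, G1>G4>G3 -> 1, G4>G3>G1 -> 0.

Missing ratings never score: a category with any missing rating is
incomplete, and under the default missing policy a respondent's total is
reported only when every category is complete. No imputation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ValidationError
from .instrument import GROUP_ORDER, Instrument, NovaGroup

__all__ = [
    "ScoringPolicy",
    "CategoryScore",
    "ScoreResult",
    "score_category",
    "score_respondent",
    "score_table",
    "score_matrix",
    "scores_to_frame",
]

TIE_POLICIES = ("pair_incorrect", "zero_category")
ONE_PAIR_POLICIES = ("zero", "one_point")
MISSING_POLICIES = ("total_requires_all", "prorate_never")


@dataclass(frozen=True)
class ScoringPolicy:
    """Tie, single-pair and missing-data policy for the scorer.

    Defaults implement the minimal reading of the published rule: ties void
    only the tied pair, a single correct pair earns nothing, and a total is
    reported only for fully complete respondents.
    """

    tie_policy: str = "pair_incorrect"
    one_pair_policy: str = "zero"
    missing_policy: str = "total_requires_all"

    def __post_init__(self) -> None:
        if self.tie_policy not in TIE_POLICIES:
            raise ValidationError(f"unknown tie_policy {self.tie_policy!r}")
        if self.one_pair_policy not in ONE_PAIR_POLICIES:
            raise ValidationError(f"unknown one_pair_policy {self.one_pair_policy!r}")
        if self.missing_policy not in MISSING_POLICIES:
            raise ValidationError(f"unknown missing_policy {self.missing_policy!r}")


@dataclass(frozen=True)
class CategoryScore:
    category: str
    points: Optional[int]  # None iff incomplete
    correct_pairs: int
    complete: bool


@dataclass(frozen=True)
class ScoreResult:
    respondent_id: str
    category_scores: tuple[CategoryScore, ...]
    total: Optional[int]
    n_complete_categories: int

    def points(self, category: str) -> Optional[int]:
        for cs in self.category_scores:
            if cs.category == category:
                return cs.points
        raise KeyError(category)


def _check_rating(value, scale, context: str) -> Optional[int]:
    """Validate one rating; returns the int rating or None for missing."""
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    if isinstance(value, (bool, np.bool_)):
        raise ValidationError(f"{context}: rating must be an integer, got {value!r}")
    if isinstance(value, (int, np.integer)):
        iv = int(value)
    elif isinstance(value, (float, np.floating)):
        if float(value) != int(value):
            raise ValidationError(
                f"{context}: rating must be an integer, got {value!r}"
            )
        iv = int(value)
    else:
        raise ValidationError(f"{context}: rating must be an integer, got {value!r}")
    if not scale.contains(iv):
        raise ValidationError(
            f"{context}: rating {iv} outside scale [{scale.min}, {scale.max}]"
        )
    return iv


def _points_from_pairs(correct_pairs: int, any_tie: bool, policy: ScoringPolicy) -> int:
    if policy.tie_policy == "zero_category" and any_tie:
        return 0
    if correct_pairs == 3:
        return 2
    if correct_pairs == 2:
        return 1
    if correct_pairs == 1 and policy.one_pair_policy == "one_point":
        return 1
    return 0


def score_category(
    r1,
    r3,
    r4,
    policy: ScoringPolicy = ScoringPolicy(),
    *,
    category: str = "category",
    scale=None,
) -> CategoryScore:
    """Score one category triad from its three ratings.

    Ratings may be None/NaN (missing), which makes the category incomplete.
    ``scale`` defaults to the 1-10 scale.
    """
    from .instrument import RatingScale

    scale = scale or RatingScale()
    vals = [
        _check_rating(r, scale, f"{category}/{g.value}")
        for r, g in zip((r1, r3, r4), GROUP_ORDER)
    ]
    if any(v is None for v in vals):
        return CategoryScore(category=category, points=None, correct_pairs=0, complete=False)
    v1, v3, v4 = vals
    correct = int(v1 > v3) + int(v1 > v4) + int(v3 > v4)
    any_tie = v1 == v3 or v1 == v4 or v3 == v4
    pts = _points_from_pairs(correct, any_tie, policy)
    return CategoryScore(category=category, points=pts, correct_pairs=correct, complete=True)


def score_respondent(
    ratings: Mapping[str, object],
    instrument: Instrument,
    policy: ScoringPolicy = ScoringPolicy(),
    *,
    respondent_id: str = "respondent",
) -> ScoreResult:
    """Score one respondent from an item_id -> rating mapping."""
    unknown = set(ratings) - set(instrument.item_ids)
    if unknown:
        raise ValidationError(
            f"{respondent_id}: rating(s) for unknown item_id(s) "
            f"{', '.join(sorted(unknown))}"
        )
    cat_scores = []
    for category in instrument.categories:
        triad = instrument.triad(category)
        r = [ratings.get(triad[g].item_id) for g in GROUP_ORDER]
        cat_scores.append(
            score_category(
                *r, policy, category=category, scale=instrument.scale
            )
        )
    n_complete = sum(cs.complete for cs in cat_scores)
    # both missing policies refuse a partial total; neither prorates
    if n_complete == len(cat_scores):
        total: Optional[int] = sum(cs.points for cs in cat_scores)
    else:
        total = None
    return ScoreResult(
        respondent_id=str(respondent_id),
        category_scores=tuple(cat_scores),
        total=total,
        n_complete_categories=n_complete,
    )


def score_matrix(
    ratings: np.ndarray,
    instrument: Instrument,
    policy: ScoringPolicy = ScoringPolicy(),
) -> np.ndarray:
    """Vectorised totals for an (n_respondents, n_items) rating matrix.

    Columns follow ``instrument.items`` order. NaN marks a missing rating;
    rows with any missing rating get a NaN total. This is the fast path the
    simulation studies use; :func:`score_table` is the validated front door.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[1] != len(instrument.items):
        raise ValidationError(
            f"rating matrix must be (n, {len(instrument.items)}), got {ratings.shape}"
        )
    col = {it.item_id: j for j, it in enumerate(instrument.items)}
    totals = np.zeros(ratings.shape[0])
    for category in instrument.categories:
        triad = instrument.triad(category)
        r1 = ratings[:, col[triad[NovaGroup.G1].item_id]]
        r3 = ratings[:, col[triad[NovaGroup.G3].item_id]]
        r4 = ratings[:, col[triad[NovaGroup.G4].item_id]]
        correct = (r1 > r3).astype(int) + (r1 > r4) + (r3 > r4)
        pts = np.where(correct == 3, 2, np.where(correct == 2, 1, 0))
        if policy.one_pair_policy == "one_point":
            pts = np.where(correct == 1, 1, pts)
        if policy.tie_policy == "zero_category":
            any_tie = (r1 == r3) | (r1 == r4) | (r3 == r4)
            pts = np.where(any_tie, 0, pts)
        pts = np.where(np.isnan(r1) | np.isnan(r3) | np.isnan(r4), np.nan, pts)
        totals = totals + pts
    return totals


def score_table(
    responses: "pd.DataFrame | object",
    instrument: Instrument,
    policy: ScoringPolicy = ScoringPolicy(),
) -> list[ScoreResult]:
    """Score every respondent in a long-form ratings table.

    ``responses`` is a DataFrame with columns respondent_id, item_id, rating
    (or a ResponseSet, whose ratings table is used). Respondent order of
    first appearance is preserved.
    """
    ratings = getattr(responses, "ratings", responses)
    if not isinstance(ratings, pd.DataFrame):
        raise ValidationError("responses must be a DataFrame or ResponseSet")
    if ratings.empty:
        raise EmptyInputError("no responses to score")
    required = {"respondent_id", "item_id", "rating"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValidationError(f"responses table missing column(s) {sorted(missing)}")
    dup = ratings.duplicated(["respondent_id", "item_id"])
    if dup.any():
        first = ratings.loc[dup, ["respondent_id", "item_id"]].iloc[0]
        raise ValidationError(
            f"duplicate rating for respondent {first['respondent_id']!r}, "
            f"item {first['item_id']!r}"
        )
    results = []
    order = ratings["respondent_id"].drop_duplicates()
    grouped = dict(tuple(ratings.groupby("respondent_id", sort=False)))
    for rid in order:
        sub = grouped[rid]
        mapping = dict(zip(sub["item_id"], sub["rating"]))
        results.append(
            score_respondent(mapping, instrument, policy, respondent_id=rid)
        )
    return results


def scores_to_frame(results: Iterable[ScoreResult]) -> pd.DataFrame:
    """Tabulate ScoreResults: one row per respondent, one column per category."""
    rows = []
    for res in results:
        row: dict = {"respondent_id": res.respondent_id}
        for cs in res.category_scores:
            row[cs.category] = cs.points if cs.complete else np.nan
        row["total"] = np.nan if res.total is None else res.total
        row["n_complete_categories"] = res.n_complete_categories
        rows.append(row)
    if not rows:
        raise EmptyInputError("no score results to tabulate")
    return pd.DataFrame(rows)
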