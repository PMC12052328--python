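"""CSV reading/writing and the ResponseSet container.

Canonical dialect everywhere: comma separator, period decimal mark, UTF-8,
header row. Brazilian-locale files (semicolon separator, comma decimals)
can be converted on read with ``locale="br"``. Validation reports the
offending row and field so data errors surface at the file boundary, not
deep in the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ValidationError
from .instrument import Instrument
from .scoring import ScoreResult, scores_to_frame

__all__ = [
    "ResponseSet",
    "read_responses",
    "read_covariates",
    "read_recalls",
    "write_scores",
    "write_usual_intake",
]

RATINGS_COLUMNS = ("respondent_id", "item_id", "rating")
COVARIATE_COLUMNS = ("respondent_id", "sex", "age", "education")


@dataclass
class ResponseSet:
    """Ratings plus covariates for a set of respondents.

    ``ratings`` is long form (respondent_id, item_id, rating); ``covariates``
    has one row per respondent (respondent_id, sex, age, education and an
    optional ``group`` label). Every rated respondent must have covariates;
    the reverse is not required.
    """

    ratings: pd.DataFrame
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        missing = set(RATINGS_COLUMNS) - set(self.ratings.columns)
        if missing:
            raise ValidationError(f"ratings table missing column(s) {sorted(missing)}")
        if self.covariates is not None:
            if "respondent_id" not in self.covariates.columns:
                raise ValidationError("covariates table missing respondent_id")
            rated = set(self.ratings["respondent_id"])
            known = set(self.covariates["respondent_id"])
            orphans = rated - known
            if orphans:
                raise ValidationError(
                    f"respondent(s) with ratings but no covariates: "
                    f"{sorted(orphans)[:5]}"
                )

    @property
    def respondent_ids(self) -> list[str]:
        return list(self.ratings["respondent_id"].drop_duplicates())

    def validate_against(self, instrument: Instrument) -> "ResponseSet":
        """Check item ids and rating values against an instrument."""
        known = set(instrument.item_ids)
        unknown = set(self.ratings["item_id"]) - known
        if unknown:
            raise ValidationError(f"unknown item_id(s): {sorted(unknown)[:5]}")
        for row in self.ratings.itertuples(index=False):
            v = row.rating
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            if float(v) != int(v) or not instrument.scale.contains(int(v)):
                raise ValidationError(
                    f"respondent {row.respondent_id!r}, item {row.item_id!r}: "
                    f"rating {v!r} is not an integer in "
                    f"[{instrument.scale.min}, {instrument.scale.max}]"
                )
        return self


def _read_csv(path: Union[str, Path], locale: str = "c") -> pd.DataFrame:
    kwargs = {"sep": ";", "decimal": ","} if locale == "br" else {}
    try:
        df = pd.read_csv(path, encoding="utf-8", **kwargs)
    except FileNotFoundError:
        raise
    except Exception as exc:  # parse errors carry file context
        raise ValidationError(f"{path}: could not parse CSV ({exc})") from exc
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    return df


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing column(s) {missing}; expected header with "
            f"{list(required)}"
        )


def read_responses(
    path: Union[str, Path],
    instrument: Instrument,
    wide: bool = False,
    covariates_path: Union[str, Path, None] = None,
    locale: str = "c",
) -> ResponseSet:
    """Read a ratings CSV (long form by default) into a ResponseSet.

    Wide form has one ``respondent_id`` column plus one column per
    instrument item_id; it is melted to the canonical long form. Ratings are
    validated against the instrument scale with row-level error reporting.
    """
    df = _read_csv(path, locale)
    if wide:
        _require_columns(df, ["respondent_id"], path)
        present = [c for c in df.columns if c in set(instrument.item_ids)]
        if not present:
            raise ValidationError(
                f"{path}: wide form has no instrument item columns"
            )
        df = df.melt(
            id_vars=["respondent_id"],
            value_vars=present,
            var_name="item_id",
            value_name="rating",
        ).sort_values(["respondent_id"], kind="stable", ignore_index=True)
    _require_columns(df, RATINGS_COLUMNS, path)
    dup = df.duplicated(["respondent_id", "item_id"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"{path}: duplicate (respondent_id, item_id) at data row {i + 1}: "
            f"({df.iloc[i]['respondent_id']!r}, {df.iloc[i]['item_id']!r})"
        )
    for i, row in enumerate(df.itertuples(index=False)):
        v = row.rating
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        try:
            ok = float(v) == int(float(v)) and instrument.scale.contains(int(float(v)))
        except (TypeError, ValueError):
            ok = False
        if not ok:
            raise ValidationError(
                f"{path}: data row {i + 1}, field 'rating': {v!r} is not an "
                f"integer in [{instrument.scale.min}, {instrument.scale.max}]"
            )
    df = df.astype({"respondent_id": str, "item_id": str})
    cov = read_covariates(covariates_path, locale) if covariates_path else None
    return ResponseSet(ratings=df, covariates=cov)


def read_covariates(path: Union[str, Path], locale: str = "c") -> pd.DataFrame:
    df = _read_csv(path, locale)
    _require_columns(df, COVARIATE_COLUMNS, path)
    if df["respondent_id"].duplicated().any():
        dup = df.loc[df["respondent_id"].duplicated(), "respondent_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate respondent_id {dup!r}")
    return df.astype({"respondent_id": str})


def read_recalls(path: Union[str, Path], locale: str = "c") -> pd.DataFrame:
    from .usual_intake import validate_recalls

    df = _read_csv(path, locale)
    _require_columns(df, ["respondent_id", "occasion", "upf_percent"], path)
    df = df.astype({"respondent_id": str})
    return validate_recalls(df)


def write_scores(path: Union[str, Path], results: list[ScoreResult]) -> pd.DataFrame:
    """Write a scores CSV: respondent_id, per-category points, total."""
    frame = scores_to_frame(results)
    frame.to_csv(path, index=False)
    return frame


def write_usual_intake(path: Union[str, Path], usual: pd.DataFrame) -> None:
    cols = ["respondent_id", "n_recalls", "person_mean", "usual_estimate", "shrinkage_lambda"]
    usual[cols].to_csv(path, index=False)
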