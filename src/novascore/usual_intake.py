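"""Usual ultra-processed-food intake from repeated 24-hour recalls.

A single 24-hour recall is a noisy snapshot of a person's long-run (usual)
diet: day-to-day variation inflates the spread of observed person means and
attenuates associations with covariates. With 1-3 recalls per person the
classical remedy is to decompose total variance into between- and
within-person components and shrink each person's mean toward the cohort
grand mean in proportion to how noisy it is::

    lambda_i = var_between / (var_between + var_within / n_i)
    usual_i  = grand_mean + lambda_i * (person_mean_i - grand_mean)

Variance components come from the one-way random-effects analysis of
variance, by method of moments, with the standard effective replicate count
n0 = (N - sum(n_i^2)/N) / (k - 1) for unbalanced designs. A negative
moment estimate of the between-person variance is truncated to zero (and
flagged), the usual practice.

This is deliberately the shrinkage core only — a documented simplification
of full usual-intake machinery such as the Multiple Source Method, which
additionally models covariates, transforms the response, and handles
episodically consumed foods. UPF share of energy is near-continuous, so the
untransformed shrinkage estimator is an adequate per-person deattenuator
here; the attenuation it can still leave in regressions is discussed in the
methods document.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError, IdentifiabilityError, ValidationError

__all__ = [
    "VarianceComponents",
    "validate_recalls",
    "variance_components",
    "estimate_usual",
]

RECALL_COLUMNS = ("respondent_id", "occasion", "upf_percent")


@dataclass(frozen=True)
class VarianceComponents:
    """One-way random-effects decomposition of recall variance.

    Units: grand_mean in % of energy; variances in %^2.
    """

    grand_mean: float
    var_between: float
    var_within: float
    n_respondents: int
    mean_recalls_per_respondent: float
    truncated: bool = False  # True if the raw between-variance moment was < 0


def validate_recalls(recalls: pd.DataFrame) -> pd.DataFrame:
    """Check a recall table's schema, ranges and occasion uniqueness."""
    if not isinstance(recalls, pd.DataFrame):
        raise ValidationError("recalls must be a DataFrame")
    if recalls.empty:
        raise EmptyInputError("recall table is empty")
    missing = set(RECALL_COLUMNS) - set(recalls.columns)
    if missing:
        raise ValidationError(f"recall table missing column(s) {sorted(missing)}")
    dup = recalls.duplicated(["respondent_id", "occasion"])
    if dup.any():
        row = recalls.loc[dup].iloc[0]
        raise ValidationError(
            f"duplicate occasion {row['occasion']!r} for respondent "
            f"{row['respondent_id']!r}"
        )
    vals = pd.to_numeric(recalls["upf_percent"], errors="coerce")
    bad = recalls.loc[vals.isna() | (vals < 0) | (vals > 100)]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValidationError(
            f"upf_percent {row['upf_percent']!r} for respondent "
            f"{row['respondent_id']!r} is not a number in [0, 100]"
        )
    return recalls


def variance_components(recalls: pd.DataFrame) -> VarianceComponents:
    """Method-of-moments between/within variance components.

    Requires at least two respondents and at least one respondent with two
    or more recalls, otherwise the within-person variance is unidentifiable.
    """
    recalls = validate_recalls(recalls)
    y = recalls["upf_percent"].astype(float)
    groups = recalls.groupby("respondent_id", sort=False)["upf_percent"]
    n_i = groups.size()
    k = len(n_i)
    if k < 2:
        raise IdentifiabilityError(
            "variance components need at least 2 respondents"
        )
    if (n_i < 2).all():
        raise IdentifiabilityError(
            "no respondent has 2 or more recalls: within-person variance "
            "is unidentifiable"
        )
    N = int(n_i.sum())
    grand_mean = float(y.mean())
    means = groups.mean()
    # pooled within-person variance: SSW / (N - k)
    ssw = float(((y - means.reindex(recalls["respondent_id"]).to_numpy()) ** 2).sum())
    var_within = ssw / (N - k) if N > k else 0.0
    # between mean square and effective replicate count for unbalanced design
    ssb = float((n_i * (means - grand_mean) ** 2).sum())
    msb = ssb / (k - 1)
    n0 = (N - float((n_i**2).sum()) / N) / (k - 1)
    raw_between = (msb - var_within) / n0
    truncated = raw_between < 0
    if truncated:
        warnings.warn(
            "negative between-person variance moment estimate "
            f"({raw_between:.4g}) truncated to 0",
            stacklevel=2,
        )
    return VarianceComponents(
        grand_mean=grand_mean,
        var_between=max(0.0, raw_between),
        var_within=max(0.0, var_within),
        n_respondents=k,
        mean_recalls_per_respondent=N / k,
        truncated=truncated,
    )


def estimate_usual(
    recalls: pd.DataFrame, components: VarianceComponents | None = None
) -> pd.DataFrame:
    """Per-respondent usual-intake estimates by shrinkage toward the grand mean.

    Returns a DataFrame with columns respondent_id, n_recalls, person_mean,
    usual_estimate, shrinkage_lambda, in the respondents' first-appearance
    order. ``components`` defaults to :func:`variance_components` of the same
    table; if supplied it must come from a table covering these respondents.
    """
    recalls = validate_recalls(recalls)
    if components is None:
        components = variance_components(recalls)
    groups = recalls.groupby("respondent_id", sort=False)["upf_percent"]
    out = pd.DataFrame(
        {
            "respondent_id": groups.size().index,
            "n_recalls": groups.size().to_numpy(),
            "person_mean": groups.mean().to_numpy(),
        }
    )
    vb, vw = components.var_between, components.var_within
    if vb == 0.0:
        lam = np.zeros(len(out))
    elif vw == 0.0:
        lam = np.ones(len(out))
    else:
        lam = vb / (vb + vw / out["n_recalls"].to_numpy())
    out["usual_estimate"] = components.grand_mean + lam * (
        out["person_mean"].to_numpy() - components.grand_mean
    )
    out["shrinkage_lambda"] = lam
    return out
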