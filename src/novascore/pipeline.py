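"""End-to-end orchestration of the scoring and validity analyses.

Each public function is one pipeline stage; the CLI and the numbered
analysis scripts are thin wrappers around them. Stages communicate through
plain DataFrames/CSVs so synthetic and user-supplied data are
interchangeable: simulate-mode output passes the same validators as data
read from disk.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .instrument import Instrument, default_instrument
from .io import ResponseSet, write_scores
from .scoring import ScoringPolicy, score_table, scores_to_frame
from .synthetic import (
    CohortScenario,
    cohort_scenario,
    education_students_scenario,
    generate_recalls,
    generate_two_group_study,
    generate_ratings,
    nutrition_students_scenario,
)
from .usual_intake import estimate_usual, variance_components
from .validation import (
    chi_square_2x2,
    mann_whitney,
    ols_adjusted,
    sample_size_two_groups,
    welch_t_from_summary,
)

__all__ = [
    "totals_frame",
    "run_score",
    "run_simulate_two_group",
    "run_simulate_cohort",
    "discriminant_report",
    "convergent_report",
    "write_run_log",
]


def totals_frame(
    responses: ResponseSet,
    instrument: Optional[Instrument] = None,
    policy: ScoringPolicy = ScoringPolicy(),
) -> pd.DataFrame:
    """Per-respondent score table (vectorised), merged with covariates.

    Same numbers as :func:`novascore.scoring.score_table`, computed via the
    matrix fast path; one row per respondent with per-category points,
    total, and any covariate columns.
    """
    instrument = instrument or default_instrument()
    order = [it.item_id for it in instrument.items]
    wide = responses.ratings.pivot(index="respondent_id", columns="item_id", values="rating")
    missing_items = set(order) - set(wide.columns)
    for item in missing_items:  # fully unrated item -> NaN column
        wide[item] = np.nan
    wide = wide.loc[responses.respondent_ids, order]
    mat = wide.to_numpy(dtype=float)
    out = pd.DataFrame({"respondent_id": wide.index})
    from .instrument import NovaGroup

    col = {it.item_id: j for j, it in enumerate(instrument.items)}
    for category in instrument.categories:
        triad = instrument.triad(category)
        sub_ids = [triad[g].item_id for g in (NovaGroup.G1, NovaGroup.G3, NovaGroup.G4)]
        r1, r3, r4 = (mat[:, col[i]] for i in sub_ids)
        correct = (r1 > r3).astype(float) + (r1 > r4) + (r3 > r4)
        pts = np.where(correct == 3, 2.0, np.where(correct == 2, 1.0, 0.0))
        if policy.one_pair_policy == "one_point":
            pts = np.where(correct == 1, 1.0, pts)
        if policy.tie_policy == "zero_category":
            pts = np.where((r1 == r3) | (r1 == r4) | (r3 == r4), 0.0, pts)
        pts = np.where(np.isnan(r1) | np.isnan(r3) | np.isnan(r4), np.nan, pts)
        out[category] = pts
    cat_cols = list(instrument.categories)
    out["n_complete_categories"] = out[cat_cols].notna().sum(axis=1)
    out["total"] = out[cat_cols].sum(axis=1, skipna=False)
    if responses.covariates is not None:
        out = out.merge(responses.covariates, on="respondent_id", how="left")
    return out


def run_score(
    responses: ResponseSet,
    instrument: Optional[Instrument] = None,
    policy: ScoringPolicy = ScoringPolicy(),
    out_path: Union[str, Path, None] = None,
) -> pd.DataFrame:
    """Validated scoring front door: score a ResponseSet, optionally to CSV."""
    instrument = instrument or default_instrument()
    responses.validate_against(instrument)
    results = score_table(responses, instrument, policy)
    frame = scores_to_frame(results)
    if out_path is not None:
        write_scores(out_path, results)
    return frame


def run_simulate_two_group(
    out_dir: Union[str, Path],
    seed: int = 0,
    n_ref: int = 76,
    n_cmp: int = 99,
    instrument: Optional[Instrument] = None,
) -> ResponseSet:
    """Simulate the two-student-group study and write its CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rs = generate_two_group_study(
        nutrition_students_scenario(n=n_ref),
        education_students_scenario(n=n_cmp),
        instrument,
        seed=seed,
    )
    rs.ratings.to_csv(out / "responses.csv", index=False)
    rs.covariates.drop(columns=["knowledge_k"]).to_csv(out / "covariates.csv", index=False)
    rs.covariates[["respondent_id", "knowledge_k"]].to_csv(out / "truth.csv", index=False)
    return rs


def run_simulate_cohort(
    out_dir: Union[str, Path],
    seed: int = 0,
    n: int = 1245,
    instrument: Optional[Instrument] = None,
) -> tuple[ResponseSet, pd.DataFrame, pd.DataFrame]:
    """Simulate the cohort subsample with recalls; returns (responses, recalls, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_ratings, s_recalls = ss.spawn(2)
    scenario = cohort_scenario(n=n)
    rs = generate_ratings(scenario, instrument, seed=s_ratings)
    totals = totals_frame(rs, instrument)
    recalls, truth = generate_recalls(totals, scenario, seed=s_recalls)
    rs.ratings.to_csv(out / "responses.csv", index=False)
    rs.covariates.drop(columns=["knowledge_k"]).to_csv(out / "covariates.csv", index=False)
    recalls.to_csv(out / "recalls.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    return rs, recalls, truth


def _group_frames(scores: pd.DataFrame) -> tuple[str, str, pd.DataFrame, pd.DataFrame]:
    if "group" not in scores.columns:
        raise ValidationError("discriminant analysis needs a 'group' column")
    labels = list(pd.unique(scores["group"]))
    if len(labels) != 2:
        raise ValidationError(f"expected exactly 2 groups, found {labels}")
    a, b = labels
    return a, b, scores[scores["group"] == a], scores[scores["group"] == b]


def discriminant_report(
    scores: pd.DataFrame, categories: Optional[list[str]] = None
) -> dict:
    """Two-group comparison of knowledge scores (per category and total).

    ``scores`` is a totals_frame-style table with a ``group`` column. The
    report mirrors the layout of a discriminant-validity table: mean (SD)
    per group and the Mann-Whitney p-value per row, plus group-comparability
    tests (chi-square on sex and education, Welch t on age) when those
    covariates are present.
    """
    name_a, name_b, ga, gb = _group_frames(scores.dropna(subset=["total"]))
    if categories is None:
        categories = [
            c for c in scores.columns
            if c not in {"respondent_id", "total", "n_complete_categories",
                         "group", "sex", "age", "education", "knowledge_k"}
        ]
    rows = {}
    for name in [*categories, "total"]:
        a_vals, b_vals = ga[name].to_numpy(float), gb[name].to_numpy(float)
        mw = mann_whitney(a_vals, b_vals)
        rows[name] = {
            f"{name_a}_mean": float(np.mean(a_vals)),
            f"{name_a}_sd": float(np.std(a_vals, ddof=1)),
            f"{name_b}_mean": float(np.mean(b_vals)),
            f"{name_b}_sd": float(np.std(b_vals, ddof=1)),
            "U": mw.statistic_value,
            "p_value": mw.p_value,
        }
    report = {
        "groups": {name_a: int(len(ga)), name_b: int(len(gb))},
        "scores": rows,
    }
    comparability = {}
    if "sex" in scores.columns:
        tab = pd.crosstab(scores["sex"], scores["group"])
        if tab.shape == (2, 2):
            res = chi_square_2x2(tab.to_numpy())
            comparability["sex"] = {"chi2": res.statistic_value, "p_value": res.p_value}
    if "education" in scores.columns:
        tab = pd.crosstab(scores["education"], scores["group"])
        if tab.shape == (2, 2):
            res = chi_square_2x2(tab.to_numpy())
            comparability["education"] = {"chi2": res.statistic_value, "p_value": res.p_value}
    if "age" in scores.columns:
        res = welch_t_from_summary(
            ga["age"].mean(), ga["age"].std(ddof=1), len(ga),
            gb["age"].mean(), gb["age"].std(ddof=1), len(gb),
        )
        comparability["age"] = {"t": res.statistic_value, "p_value": res.p_value}
    if comparability:
        report["comparability"] = comparability
    return report


def convergent_report(
    scores: pd.DataFrame,
    recalls: pd.DataFrame,
    categories: Optional[list[str]] = None,
) -> dict:
    """Usual-intake estimation plus adjusted regressions of intake on score.

    One OLS per score measure (each category and the total), each adjusted
    for sex, age and education, mirroring a convergent-validity table.
    Returns the variance components, cohort intake summaries, and the score
    coefficient (with 95% CI) per model.
    """
    comp = variance_components(recalls)
    usual = estimate_usual(recalls, comp)
    merged = scores.merge(usual, on="respondent_id", how="inner")
    if categories is None:
        categories = [
            c for c in scores.columns
            if c not in {"respondent_id", "total", "n_complete_categories",
                         "group", "sex", "age", "education", "knowledge_k"}
        ]
    models = {}
    for name in [*categories, "total"]:
        fit = ols_adjusted(merged, response="usual_estimate", score=name)
        c = fit.coefficients[name]
        models[name] = {
            "score_mean": float(merged[name].mean()),
            "score_sd": float(merged[name].std(ddof=1)),
            "beta": c["estimate"],
            "se": c["se"],
            "ci_low": c["ci_low"],
            "ci_high": c["ci_high"],
            "p_value": c["p_value"],
            "n": fit.n,
        }
    return {
        "variance_components": asdict(comp),
        "usual_intake": {
            "mean": float(usual["usual_estimate"].mean()),
            "sd": float(usual["usual_estimate"].std(ddof=1)),
            "n": int(len(usual)),
        },
        "models": models,
    }


def write_run_log(out_dir: Union[str, Path], config: dict, seed: Optional[int]) -> Path:
    """Write a reproducibility log (seed, config hash, versions) as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    log = {
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "novascore_version": __version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    path = out / "run_log.json"
    path.write_text(json.dumps(log, indent=2, default=str) + "\n", encoding="utf-8")
    return path


def power_report(delta: float, sd1: float, sd2: float, alpha: float = 0.05,
                 power: float = 0.80, nonparametric_are: float = 0.864) -> dict:
    n = sample_size_two_groups(delta, sd1, sd2, alpha, power, nonparametric_are)
    return {
        "n_per_group": n,
        "inputs": {
            "delta": delta, "sd1": sd1, "sd2": sd2,
            "alpha": alpha, "power": power, "nonparametric_are": nonparametric_are,
        },
    }
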