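"""Statistical battery for the discriminant and convergent validity analyses.

Covers the four tests the validation design needs — Mann-Whitney comparison
of knowledge scores between groups, 2x2 chi-square and Welch t checks of
group comparability, covariate-adjusted OLS of usual UPF intake on the
score — plus the nonparametric sample-size planning formula.

The heavy lifting is delegated to scipy.stats and statsmodels; this module
pins down the exact path choices (exact vs tie-corrected asymptotic
Mann-Whitney, Yates continuity correction on by default) and returns small
result records with the numbers a validity report prints.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError, IdentifiabilityError, ValidationError

__all__ = [
    "TestResult",
    "RegressionResult",
    "mann_whitney",
    "chi_square_2x2",
    "welch_t_from_summary",
    "ols_adjusted",
    "sample_size_two_groups",
]


@dataclass(frozen=True)
class TestResult:
    statistic_name: str
    statistic_value: float
    p_value: float
    n: tuple[int, ...]
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class RegressionResult:
    """OLS coefficient table for one response.

    ``coefficients`` maps term name to a dict with estimate, se, p_value,
    ci_low, ci_high. The score term's estimate is in percentage points of
    energy per score point.
    """

    response: str
    coefficients: dict
    n: int
    adjustment_terms: tuple[str, ...] = field(default_factory=tuple)

    def coef(self, term: str) -> float:
        return self.coefficients[term]["estimate"]


def _exact_permutation_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided p by full enumeration of group assignments.

    Enumerates all C(n1+n2, n1) splits of the pooled sample and counts
    splits whose U (for the first group, midranks) is at least as extreme as
    observed, measuring extremity as distance from the null mean n1*n2/2.
    """
    pooled = np.concatenate([a, b])
    n1 = len(a)
    n = len(pooled)
    if math.comb(n, n1) > 2_000_000:
        raise ValidationError(
            f"exact enumeration infeasible for C({n},{n1}) assignments"
        )
    ranks = stats.rankdata(pooled)
    mu = n1 * (n - n1) / 2.0
    d_obs = abs(u_obs - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n1):
        r1 = ranks[list(idx)].sum()
        u1 = r1 - n1 * (n1 + 1) / 2.0
        if abs(u1 - mu) >= d_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def mann_whitney(a, b, exact: bool | None = None) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    The U statistic is for sample ``a``. The p-value is exact (full
    enumeration of assignments) when both samples have at most 10
    observations and there are no ties, or whenever ``exact=True`` forces
    the permutation path; otherwise a normal approximation with
    tie-corrected variance and continuity correction is used.
    ``exact=False`` forces the asymptotic path.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EmptyInputError("Mann-Whitney requires two non-empty samples")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    small = a.size <= 10 and b.size <= 10
    use_exact = exact if exact is not None else (small and not ties)
    u = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").statistic)
    notes = ["midrank ties"] if ties else []
    if use_exact:
        if ties:
            p = _exact_permutation_p(a, b, u)
            notes.append("exact permutation enumeration (ties)")
        else:
            p = float(
                stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            )
            notes.append("exact distribution")
    else:
        p = float(
            stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
        notes.append("normal approximation, tie-corrected variance, continuity correction")
    return TestResult(
        statistic_name="U",
        statistic_value=u,
        p_value=min(1.0, p),
        n=(int(a.size), int(b.size)),
        notes=tuple(notes),
    )


def chi_square_2x2(table, continuity: bool = True) -> TestResult:
    """Pearson chi-square on a 2x2 count table, Yates-corrected by default."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.all(t == np.floor(t)):
            raise ValidationError("table counts must be integers")
        t = t.astype(int)
    if (t < 0).any():
        raise ValidationError("table counts must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("every row and column margin must be positive")
    res = stats.chi2_contingency(t, correction=continuity)
    notes = ("Yates continuity correction",) if continuity else ()
    return TestResult(
        statistic_name="chi2",
        statistic_value=float(res.statistic),
        p_value=float(res.pvalue),
        n=tuple(int(v) for v in t.sum(axis=1)),
        notes=notes,
    )


def welch_t_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> TestResult:
    """Welch two-sample t test from group summaries (Satterthwaite df)."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    return TestResult(
        statistic_name="t",
        statistic_value=float(res.statistic),
        p_value=float(res.pvalue),
        n=(int(n1), int(n2)),
        notes=("Welch-Satterthwaite df",),
    )


def ols_adjusted(
    data: pd.DataFrame,
    response: str = "usual_estimate",
    score: str = "total",
    covariates: tuple[str, ...] = ("sex", "age", "education"),
    categorical: tuple[str, ...] = ("sex", "education"),
) -> RegressionResult:
    """OLS of usual intake on the knowledge score, adjusted for covariates.

    Complete cases only; categorical covariates are expanded to indicator
    columns against their first (sorted) level. Classical standard errors.
    Raises on a rank-deficient design, naming the collinear columns.
    """
    import statsmodels.api as sm

    cols = [response, score, *covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValidationError(f"data missing column(s) {missing}")
    df = data[cols].dropna()
    X = pd.DataFrame(index=df.index)
    X[score] = pd.to_numeric(df[score])
    for cov in covariates:
        if cov in categorical:
            dummies = pd.get_dummies(df[cov].astype(str), prefix=cov, drop_first=True)
            for c in dummies.columns:
                X[c] = dummies[c].astype(float)
        else:
            X[cov] = pd.to_numeric(df[cov])
    n, p = len(df), X.shape[1] + 1
    if n < p + 10:
        raise ValidationError(
            f"need at least {p + 10} complete cases for {p} parameters, got {n}"
        )
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # name columns whose removal restores full rank
        collinear = []
        base = Xc.to_numpy()
        for j, name in enumerate(Xc.columns):
            reduced = np.delete(base, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(name)
        raise ValidationError(f"rank-deficient design; collinear term(s): {collinear}")
    fit = sm.OLS(pd.to_numeric(df[response]), Xc).fit()
    ci = fit.conf_int(alpha=0.05)
    coefficients = {
        term: {
            "estimate": float(fit.params[term]),
            "se": float(fit.bse[term]),
            "p_value": float(fit.pvalues[term]),
            "ci_low": float(ci.loc[term, 0]),
            "ci_high": float(ci.loc[term, 1]),
        }
        for term in Xc.columns
    }
    return RegressionResult(
        response=response,
        coefficients=coefficients,
        n=n,
        adjustment_terms=tuple(c for c in X.columns if c != score),
    )


def sample_size_two_groups(
    delta: float,
    sd1: float,
    sd2: float,
    alpha: float = 0.05,
    power: float = 0.80,
    nonparametric_are: float = 0.864,
) -> int:
    """Per-group n to detect a mean difference with a Mann-Whitney test.

    Normal-approximation two-sample formula with unequal SDs,

        n = ceil( (z_{1-alpha/2} + z_power)^2 (sd1^2 + sd2^2) / delta^2
                  / ARE )

    inflated by the worst-case asymptotic relative efficiency of the
    Mann-Whitney test versus the t test (0.864). Set
    ``nonparametric_are=1`` for plain t-test planning.
    """
    if delta <= 0 or sd1 <= 0 or sd2 <= 0:
        raise ValidationError("delta and both SDs must be positive")
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ValidationError("alpha and power must lie in (0, 1)")
    if not (0 < nonparametric_are <= 1):
        raise ValidationError("ARE must lie in (0, 1]")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    n = (z_a + z_b) ** 2 * (sd1**2 + sd2**2) / delta**2 / nonparametric_are
    if not np.isfinite(n):
        raise IdentifiabilityError("sample-size formula produced a non-finite value")
    return max(1, math.ceil(n))
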