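"""Inferential layer: ANCOVA, stage t-test, chi-square, partial correlations, FDR.

Group comparisons adjust for age, sex and education via a linear model; the
EBM stage itself is compared with a plain pooled-variance t-test because its
covariates were already removed upstream.  Partial correlations between
cognitive scores and clinical chemistry use the residualize-then-correlate
definition, and multiplicity is handled per analysis family with
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "PartialCorrResult",
    "ancova_compare",
    "two_sample_t",
    "chi_square_2x2",
    "partial_correlation",
    "bh_fdr",
    "compare_family",
    "correlation_family",
]


@dataclass
class ComparisonResult:
    variable: str
    adjusted_means: dict[str, float]
    statistic: float                   # F for the group term
    p_value: float
    p_fdr: float | None = None


@dataclass
class PartialCorrResult:
    x: str
    y: str
    r: float
    p_value: float
    n: int
    p_fdr: float | None = None


def ancova_compare(
    outcome: np.ndarray,
    group: np.ndarray,
    covariates: pd.DataFrame,
    variable: str = "outcome",
) -> ComparisonResult:
    """Group comparison of one outcome adjusting for age/sex/education.

    Linear model ``outcome ~ group + age + sex + education``; the group term
    is tested by its partial F, and adjusted means evaluate the fit for each
    group at the grand covariate means.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(outcome, dtype=float),
            "group": np.asarray(group),
            "age": covariates["age"].to_numpy(float),
            "sex": covariates["sex"].to_numpy(float),
            "education": covariates["education"].to_numpy(float),
        }
    )
    if df["group"].nunique() < 2:
        raise ValueError("need at least 2 groups")
    model = ols("y ~ C(group) + age + sex + education", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient ANCOVA design")
    table = anova_lm(model, typ=3)
    F = float(table.loc["C(group)", "F"])
    p = float(table.loc["C(group)", "PR(>F)"])
    means = {}
    cov_means = df[["age", "sex", "education"]].mean()
    for g in sorted(df["group"].unique()):
        pred = pd.DataFrame(
            {"group": [g], "age": [cov_means["age"]], "sex": [cov_means["sex"]],
             "education": [cov_means["education"]]}
        )
        means[str(g)] = float(model.predict(pred).iloc[0])
    return ComparisonResult(variable, means, F, p)


def two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    df = len(a) + len(b) - 2
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def chi_square_2x2(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 contingency table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | None = None,
    labels: tuple[str, str] = ("x", "y"),
) -> PartialCorrResult:
    """Partial Pearson correlation of x and y given linear covariates.

    Computed as the Pearson correlation of the OLS residuals of each
    variable on (intercept + covariates), with the p-value from the t
    transform at df = n - k - 2; with no covariates it reduces to the
    plain Pearson r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None or covariates.shape[1] == 0:
        if n < 4:
            raise ValueError("too few observations")
        r, p = stats.pearsonr(x, y)
        return PartialCorrResult(labels[0], labels[1], float(r), float(p), n)
    k = covariates.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > n_covariates + 2 (n={n}, covariates={k})")
    X = np.column_stack([np.ones(n), covariates.to_numpy(float)])
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("constant residuals; partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrResult(labels[0], labels[1], r, p, n)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def compare_family(
    outcomes: pd.DataFrame, group: np.ndarray, covariates: pd.DataFrame
) -> list[ComparisonResult]:
    """ANCOVA for every column of ``outcomes`` with one shared FDR family."""
    results = [
        ancova_compare(outcomes[c].to_numpy(), group, covariates, variable=c)
        for c in outcomes.columns
    ]
    adj = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, adj):
        r.p_fdr = float(q)
    return results


def correlation_family(
    scores: pd.DataFrame,
    clinical: pd.DataFrame,
    covariates: pd.DataFrame,
) -> list[PartialCorrResult]:
    """Partial correlations of every score x clinical pair, one FDR family."""
    results = []
    for s in scores.columns:
        for c in clinical.columns:
            results.append(
                partial_correlation(
                    scores[s].to_numpy(), clinical[c].to_numpy(), covariates,
                    labels=(s, c),
                )
            )
    adj = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, adj):
        r.p_fdr = float(q)
    return results
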