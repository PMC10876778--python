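"""Clinical and ROI-level statistics.

Group comparisons of demographic/clinical variables follow a Shapiro–Wilk
normality gate (alpha 0.05 per group): both groups normal -> pooled
two-sample t-test, otherwise Mann–Whitney U.  Sex tables use the Pearson
chi-square without continuity correction.  ROI–clinical correlations use
Pearson when both variables pass the gate and Spearman otherwise, with an
uncorrected flag at p < 0.05 and a Bonferroni flag at alpha / 7 (seven
clinical scales).  The covariate-adjusted sensitivity check is an ordinary
least-squares model ``roi ~ group + covariates`` with a single-df F-test of
the group term.

Missing values are removed pairwise; every result reports the n actually
used and which test was chosen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "compare_groups",
    "compare_sex",
    "roi_clinical_correlation",
    "roi_glm_sensitivity",
    "compare_clinical_table",
    "TestResult",
    "CorrelationResult",
    "GroupTermResult",
]

NORMALITY_ALPHA = 0.05
N_CLINICAL_SCALES = 7


@dataclass
class TestResult:
    test: str
    statistic: float
    p: float
    n_a: int
    n_b: int


@dataclass
class CorrelationResult:
    method: str
    coefficient: float
    p: float
    n: int
    significant_uncorrected: bool
    significant_corrected: bool
    corrected_threshold: float


@dataclass
class GroupTermResult:
    f_statistic: float
    p: float
    df_num: int
    df_den: int
    covariates_used: list[str]


def _is_normal(x: np.ndarray) -> bool:
    """Shapiro–Wilk gate; undefined (constant) samples count as non-normal."""
    if np.ptp(x) == 0:
        logger.info("Shapiro-Wilk undefined for constant sample; treating as non-normal")
        return False
    return stats.shapiro(x).pvalue > NORMALITY_ALPHA


def _clean(x) -> np.ndarray:
    x = np.asarray(x, float)
    return x[np.isfinite(x)]


def compare_groups(values, groups) -> TestResult:
    """Normality-gated two-group comparison of one numeric variable.

    Pooled two-sample t-test when Shapiro–Wilk p > 0.05 in both groups,
    Mann–Whitney U otherwise.  Missing values are dropped per group.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(labels)}")
    a = _clean(values[groups == labels[0]])
    b = _clean(values[groups == labels[1]])
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 non-missing values per group")
    if _is_normal(a) and _is_normal(b):
        res = stats.ttest_ind(a, b, equal_var=True)
        return TestResult("t-test", float(res.statistic), float(res.pvalue), len(a), len(b))
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult("mann-whitney-u", float(res.statistic), float(res.pvalue), len(a), len(b))


def compare_sex(counts: np.ndarray) -> TestResult:
    """Pearson chi-square (no continuity correction) on a 2x2 count table."""
    counts = np.asarray(counts, float)
    if counts.shape != (2, 2) or (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be a 2x2 table of nonnegative integers")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero marginal")
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return TestResult("pearson-chi2", float(chi2), float(p), int(counts[0].sum()), int(counts[1].sum()))


def roi_clinical_correlation(
    roi_values,
    clinical_values,
    alpha: float = 0.05,
    n_comparisons: int = N_CLINICAL_SCALES,
) -> CorrelationResult:
    """Normality-gated ROI–clinical correlation with Bonferroni flags.

    Pearson when both variables pass the Shapiro–Wilk gate, Spearman
    otherwise.  Flags significance uncorrected (p < alpha) and corrected
    (p < alpha / n_comparisons).  Pairs with missing values are dropped.
    """
    x = np.asarray(roi_values, float)
    y = np.asarray(clinical_values, float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("need at least 4 complete pairs")
    thr = alpha / n_comparisons
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.info("constant vector in correlation; returning p = 1")
        return CorrelationResult("degenerate", 0.0, 1.0, len(x), False, False, thr)
    if _is_normal(x) and _is_normal(y):
        r, p = stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = stats.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(method, float(r), float(p), len(x), p < alpha, p < thr, thr)


def roi_glm_sensitivity(roi_values, group, covariates: pd.DataFrame) -> GroupTermResult:
    """OLS ``roi ~ group + covariates`` with an F-test of the group term.

    Group may be any two-level labelling; covariate columns that are
    collinear with the rest of the design are dropped with a warning.  For
    a single-df group term F equals the squared t of its coefficient.
    """
    roi = np.asarray(roi_values, float)
    group = np.asarray(group)
    labels = pd.unique(group)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(labels)}")
    g = (group == labels[1]).astype(float)
    cov = covariates.astype(float).reset_index(drop=True)

    ok = np.isfinite(roi) & np.isfinite(cov.to_numpy()).all(axis=1)
    roi, g, cov = roi[ok], g[ok], cov.loc[ok]

    X = pd.DataFrame({"intercept": np.ones(len(roi)), "group": g})
    used = []
    for col in cov.columns:
        trial = pd.concat([X, cov[[col]]], axis=1).to_numpy()
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            X[col] = cov[col].to_numpy()
            used.append(col)
        else:
            logger.warning("dropping collinear covariate %r", col)
    fit = sm.OLS(roi, X.to_numpy()).fit()
    tval = fit.tvalues[1]
    return GroupTermResult(
        f_statistic=float(tval**2),
        p=float(fit.pvalues[1]),
        df_num=1,
        df_den=int(fit.df_resid),
        covariates_used=used,
    )


def compare_clinical_table(
    table: pd.DataFrame, group_col: str = "group", variables: list[str] | None = None
) -> pd.DataFrame:
    """Gate-selected group comparison of every numeric column of a table."""
    if variables is None:
        variables = [
            c for c in table.columns
            if c != group_col and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows = []
    for var in variables:
        res = compare_groups(table[var].to_numpy(float), table[group_col].to_numpy())
        rows.append(
            {"variable": var, "test": res.test, "statistic": res.statistic,
             "p": res.p, "n_a": res.n_a, "n_b": res.n_b}
        )
    return pd.DataFrame(rows).set_index("variable")
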