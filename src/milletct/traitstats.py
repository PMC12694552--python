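"""Population-level trait statistics: descriptive summaries, normality
assessment and the Pearson correlation matrix.

Conventions follow common statistics-package output: sample SD (n-1),
adjusted Fisher-Pearson skewness G1, bias-corrected excess kurtosis G2,
Shapiro-Wilk for the formal normality test, plus the pragmatic screening
rule that treats a trait as near-normal when |skewness| < 3 and
|kurtosis| < 10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import DomainError


@dataclass
class TraitSummary:
    trait_name: str
    n: int
    minimum: float
    maximum: float
    mean: float
    sd: float
    cv_percent: float
    skewness: float
    kurtosis: float
    shapiro_p: float
    normal_flag: bool


def summarize_trait(values, name: str) -> TraitSummary:
    """Descriptive summary of one trait vector (missing values dropped)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        raise DomainError(f"{name}: need >=3 finite values, got {v.size}")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if mean <= 0:
        raise DomainError(f"{name}: CV undefined for non-positive mean")
    g1 = float(stats.skew(v, bias=False))
    g2 = float(stats.kurtosis(v, fisher=True, bias=False))
    shapiro_p = float(stats.shapiro(v).pvalue)
    return TraitSummary(
        trait_name=name,
        n=int(v.size),
        minimum=float(v.min()),
        maximum=float(v.max()),
        mean=mean,
        sd=sd,
        cv_percent=100.0 * sd / mean,
        skewness=g1,
        kurtosis=g2,
        shapiro_p=shapiro_p,
        normal_flag=(abs(g1) < 3.0) and (abs(g2) < 10.0),
    )


@dataclass
class NormalityDecision:
    trait_name: str
    shapiro_p: float
    shapiro_reject: bool      # formal test rejects normality at alpha
    rule_normal: bool         # |skew| < 3 and |kurtosis| < 10
    alpha: float


def normality_assessment(summary: TraitSummary, alpha: float = 0.05) -> NormalityDecision:
    """Report both the Shapiro-Wilk verdict at ``alpha`` and the
    skewness/kurtosis screening rule as separate fields."""
    return NormalityDecision(
        trait_name=summary.trait_name,
        shapiro_p=summary.shapiro_p,
        shapiro_reject=summary.shapiro_p < alpha,
        rule_normal=summary.normal_flag,
        alpha=alpha,
    )


def correlation_matrix(trait_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix with two-sided t-test p-values.

    Rows with any missing value are dropped (complete cases). Zero-variance
    columns get NaN correlations (flagged by the NaN itself) and p = NaN.
    Returns (r_matrix, p_matrix), both p x p with unit/zero diagonals.
    """
    df = trait_table.select_dtypes(include=[np.number]).dropna(axis=0)
    if len(df) < 3:
        raise DomainError("need >=3 complete cases for correlations")
    cols = list(df.columns)
    x = df.to_numpy(dtype=float)
    n = x.shape[0]
    sd = x.std(axis=0, ddof=1)
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.outer(sd, sd)
    r[np.isinf(r)] = np.nan
    np.fill_diagonal(r, np.where(sd > 0, 1.0, np.nan))
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rr * np.sqrt((n - 2) / (1.0 - rr**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rr), 1.0)] = 0.0
    p[np.isnan(rr)] = np.nan
    np.fill_diagonal(p, 0.0)
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def summary_table(trait_table: pd.DataFrame) -> pd.DataFrame:
    """Per-trait summary rows for every numeric column."""
    rows = []
    for col in trait_table.select_dtypes(include=[np.number]).columns:
        s = summarize_trait(trait_table[col], col)
        rows.append({
            "Trait": s.trait_name, "N": s.n,
            "Minimum": s.minimum, "Maximum": s.maximum,
            "Mean": s.mean, "SD": s.sd, "CV (%)": s.cv_percent,
            "Skewness": s.skewness, "Kurtosis": s.kurtosis,
            "Shapiro p": s.shapiro_p, "Normal (rule)": s.normal_flag,
        })
    return pd.DataFrame(rows)
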