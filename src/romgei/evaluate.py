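"""Calibration summaries for scan output: genomic inflation, empirical
type-I error, and QQ data.

The genomic inflation factor is the ratio of the median observed test
statistic to the median of its null chi-square distribution (obtained
from the quantile function, never a hard-coded constant).  Empirical
type-I error is reported as the rejection rate divided by the nominal
level, with a binomial standard error on the same ratio scale — the
convention used when rates at genome-wide thresholds are tabulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvalSummary",
    "genomic_inflation",
    "genomic_inflation_from_pvalues",
    "empirical_t1e",
    "t1e_from_counts",
    "qq_points",
    "summarize",
    "per_replicate_inflation",
]


@dataclass
class EvalSummary:
    """Calibration metrics of one strategy/test combination."""

    lambda_gc: float
    t1e_ratio: float
    t1e_se: float
    n_tests: int
    alpha: float
    df: int
    qq: np.ndarray  # (m, 2) sorted (expected, observed) -log10 p pairs


def genomic_inflation(statistics: np.ndarray, df: int) -> float:
    """median(observed statistics) / median(chi-square with df)."""
    statistics = np.asarray(statistics, dtype=float)
    statistics = statistics[np.isfinite(statistics)]
    if statistics.size == 0:
        raise ValueError("no finite statistics")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(np.median(statistics) / stats.chi2.ppf(0.5, df))


def genomic_inflation_from_pvalues(pvalues: np.ndarray, df: int) -> float:
    """Inflation from p-values via the inverse chi-square quantile."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    return genomic_inflation(stats.chi2.isf(p, df), df)


def empirical_t1e(pvalues: np.ndarray, alpha: float) -> tuple[float, float]:
    """Rejection rate over ``alpha`` with binomial SE on the ratio scale."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    if p.size < 1 / alpha:
        warnings.warn(
            f"only {p.size} tests for alpha={alpha}; the empirical rate is unstable",
            stacklevel=2,
        )
    return t1e_from_counts(int((p <= alpha).sum()), p.size, alpha)


def t1e_from_counts(n_exceed: int, n_tests: int, alpha: float) -> tuple[float, float]:
    """Ratio and SE from the exceedance count directly."""
    phat = n_exceed / n_tests
    se = np.sqrt(phat * (1.0 - phat) / n_tests) / alpha
    return phat / alpha, float(se)


def qq_points(pvalues: np.ndarray, thin: int | None = None) -> np.ndarray:
    """Sorted (expected, observed) -log10 p pairs.

    Expected quantiles are -log10((i - 0.5)/n).  With ``thin`` set, the
    bulk (expected -log10 p < 2) is down-sampled to about that many
    points while the tail is kept exactly.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    n = p.size
    if n == 0:
        raise ValueError("no finite p-values")
    obs = -np.log10(np.sort(p)[::-1])  # ascending in -log10 p
    exp = -np.log10((np.arange(n, 0, -1) - 0.5) / n)
    pairs = np.column_stack([exp, obs])
    if thin is not None and n > thin:
        bulk = exp < 2.0
        keep = np.flatnonzero(bulk)
        if keep.size > thin:
            keep = keep[np.linspace(0, keep.size - 1, thin).astype(int)]
        sel = np.sort(np.concatenate([keep, np.flatnonzero(~bulk)]))
        pairs = pairs[sel]
    return pairs


def summarize(
    pvalues: np.ndarray,
    df: int,
    alpha: float = 0.01,
    statistics: np.ndarray | None = None,
    thin: int | None = 2000,
) -> EvalSummary:
    """One-stop calibration summary for a vector of test results."""
    p = np.asarray(pvalues, dtype=float)
    mask = np.isfinite(p)
    p = p[mask]
    if statistics is not None:
        lam = genomic_inflation(np.asarray(statistics, dtype=float)[mask], df)
    else:
        lam = genomic_inflation_from_pvalues(p, df)
    ratio, se = empirical_t1e(p, alpha)
    return EvalSummary(
        lambda_gc=lam,
        t1e_ratio=ratio,
        t1e_se=se,
        n_tests=p.size,
        alpha=alpha,
        df=df,
        qq=qq_points(p, thin=thin),
    )


def per_replicate_inflation(
    results: pd.DataFrame,
    statistic: str = "T_I",
    df: int | None = None,
    replicate_col: str = "replicate",
) -> pd.DataFrame:
    """Per-replicate genomic inflation table (one row per replicate),
    as used for violin-style summaries across simulation replicates."""
    if df is None:
        df_col = {"T_I": "df_I", "T_J": "df_J"}[statistic]
        df = int(results[df_col].iloc[0])
    rows = [
        {replicate_col: rep, "lambda_gc": genomic_inflation(sub[statistic].to_numpy(), df)}
        for rep, sub in results.groupby(replicate_col)
    ]
    return pd.DataFrame(rows)
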