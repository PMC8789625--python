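"""Psychometric validation screens for a cohort of WoMAB outcomes.

Covers the standard normative-study checks: skewness/kurtosis screening for
normality, the inter-test correlation matrix with Bonferroni correction, and
between-sex t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .battery import BASE_OUTCOMES

__all__ = [
    "NormalityReport",
    "CorrelationReport",
    "SexDifference",
    "normality_screen",
    "correlation_matrix",
    "sex_difference_tests",
]

#: screening thresholds: |skewness| > 1 or |kurtosis| > 3 flags a violation
SKEW_THRESHOLD = 1.0
KURTOSIS_THRESHOLD = 3.0


@dataclass(frozen=True)
class NormalityReport:
    outcome_id: str
    skewness: float
    kurtosis: float
    violated: bool
    zero_variance: bool = False
    excess_kurtosis: bool = True

    @property
    def recommended_method(self) -> str:
        return "spearman" if self.violated else "pearson"


def normality_screen(
    cohort: pd.DataFrame,
    outcomes: Sequence[str] = BASE_OUTCOMES,
    *,
    excess_kurtosis: bool = True,
) -> list[NormalityReport]:
    """Skewness/kurtosis screen per outcome.

    A distribution is flagged as violating normality when |skewness| > 1 or
    |kurtosis| > 3.  Kurtosis is excess kurtosis by default (normal = 0);
    ``excess_kurtosis=False`` reports raw kurtosis (normal = 3) against the
    same threshold.  Zero-variance outcomes are flagged and excluded from
    downstream correlations.
    """
    reports = []
    for oid in outcomes:
        x = cohort[oid].dropna().to_numpy(dtype=float)
        if x.size < 3:
            raise ValueError(f"{oid}: need at least 3 observations, got {x.size}")
        if np.ptp(x) == 0:
            reports.append(NormalityReport(oid, 0.0, float("nan"), violated=False,
                                           zero_variance=True,
                                           excess_kurtosis=excess_kurtosis))
            continue
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, fisher=excess_kurtosis, bias=False))
        violated = abs(skew) > SKEW_THRESHOLD or abs(kurt) > KURTOSIS_THRESHOLD
        reports.append(NormalityReport(oid, skew, kurt, violated,
                                       excess_kurtosis=excess_kurtosis))
    return reports


@dataclass(frozen=True)
class CorrelationReport:
    pair: tuple[str, str]
    method: str
    r: float
    p: float
    n: int
    alpha: float
    alpha_adjusted: float
    significant_raw: bool
    significant_bonferroni: bool


def correlation_matrix(
    cohort: pd.DataFrame,
    outcomes: Sequence[str] = BASE_OUTCOMES,
    *,
    alpha: float = 0.05,
    bonferroni: bool = True,
    method: str = "auto",
) -> list[CorrelationReport]:
    """All unordered outcome-pair correlations with Bonferroni adjustment.

    ``method='auto'`` runs the normality screen first and uses Spearman for
    any pair involving a flagged outcome, Pearson otherwise.  The adjusted
    threshold is alpha / C(k, 2); with the eight base outcomes that is
    .05 / 28 = .002 (approximately).  Constant columns are skipped with a
    warning.
    """
    outcomes = list(outcomes)
    n_pairs = comb(len(outcomes), 2)
    alpha_adj = alpha / n_pairs if bonferroni else alpha
    if method == "auto":
        screen = {r.outcome_id: r for r in normality_screen(cohort, outcomes)}
    reports = []
    for i, a in enumerate(outcomes):
        for b in outcomes[i + 1:]:
            sub = cohort[[a, b]].dropna()
            if len(sub) < 4:
                warnings.warn(f"pair ({a}, {b}): fewer than 4 complete observations, skipped",
                              stacklevel=2)
                continue
            x, y = sub[a].to_numpy(float), sub[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(f"pair ({a}, {b}): constant column, skipped", stacklevel=2)
                continue
            if method == "auto":
                use = ("spearman" if screen[a].violated or screen[b].violated
                       else "pearson")
            else:
                use = method
            if use == "pearson":
                r, p = stats.pearsonr(x, y)
            elif use == "spearman":
                res = stats.spearmanr(x, y)
                r, p = res.statistic, res.pvalue
            else:
                raise ValueError(f"unknown correlation method {use!r}")
            reports.append(CorrelationReport(
                pair=(a, b), method=use, r=float(r), p=float(p), n=len(sub),
                alpha=alpha, alpha_adjusted=alpha_adj,
                significant_raw=bool(p < alpha),
                significant_bonferroni=bool(p < alpha_adj)))
    return reports


@dataclass(frozen=True)
class SexDifference:
    outcome_id: str
    t: float
    df: float
    p: float
    mean_male: float
    mean_female: float
    direction: str  # "m>f", "f>m" or "none"


def sex_difference_tests(
    cohort: pd.DataFrame,
    outcomes: Sequence[str] = BASE_OUTCOMES,
    *,
    welch: bool = False,
) -> list[SexDifference]:
    """Two-sample male-vs-female t-tests per outcome.

    Pooled-variance by default (df = n - 2, the convention of normative
    reports); ``welch=True`` switches to the unequal-variance test.
    """
    sex = cohort["sex"].astype(str).str.strip().str.lower().str[0]
    males = cohort[sex == "m"]
    females = cohort[sex == "f"]
    if males.empty or females.empty:
        raise ValueError("both sexes must be represented in the cohort")
    out = []
    for oid in outcomes:
        m = males[oid].dropna().to_numpy(float)
        f = females[oid].dropna().to_numpy(float)
        res = stats.ttest_ind(m, f, equal_var=not welch)
        df = float(res.df) if welch else float(m.size + f.size - 2)
        direction = "none" if res.pvalue >= 0.05 else ("m>f" if m.mean() > f.mean() else "f>m")
        out.append(SexDifference(oid, t=float(res.statistic), df=df,
                                 p=float(res.pvalue),
                                 mean_male=float(m.mean()), mean_female=float(f.mean()),
                                 direction=direction))
    return out
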