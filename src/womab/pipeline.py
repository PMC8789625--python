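"""Re-derivation of Equivalent-Score norms on an arbitrary cohort.

This module re-runs the whole normative procedure on a cohort table:

1. for each raw outcome, an ordinary least-squares model on transformed
   demographic predictors is selected (one age form x one education form,
   chosen by maximized log-likelihood, then backward elimination at
   alpha = .05) and refitted with the retained terms only;
2. raw scores are adjusted by subtracting the fitted, mean-centered
   demographic effects;
3. a nonparametric interval estimate of the population 5th-centile cutoff is
   obtained from binomial order-statistic tolerance limits (outer oTL at 95%
   confidence, inner iTL);
4. adjusted scores are partitioned into five Equivalent-Score levels: ES 0
   up to the oTL, ES 4 above the sample median, and the two intermediate
   thresholds at the sample quantiles whose cumulative normal areas split
   the z-interval [-1.645, 0] into three equal widths;
5. per-participant Average Equivalent Scores (AES) are computed over the
   five T and the five WM/S outcomes, with their own tolerance limits.

A power routine for multiple linear regression (noncentral F) reproduces the
minimum-sample-size calculation used to plan such normative studies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .battery import OUTCOME_COLUMNS
from .published import (AES_T_CONSTITUENTS, AES_WMS_CONSTITUENTS,
                        Demographics, TRANSFORMS, normalize_sex)

__all__ = [
    "AGE_FORMS",
    "EDUCATION_FORMS",
    "FittedTerm",
    "NormativeModel",
    "NormativeReport",
    "PowerSpec",
    "select_model",
    "adjust_cohort",
    "tolerance_limit_ranks",
    "es_thresholds",
    "build_norms",
    "compute_aes",
    "min_sample_size",
]

#: candidate age transforms (identity plus the published nonlinear forms)
AGE_FORMS = ("rawAge", "ln100minusAge", "ageCubed", "reciprocalAge", "lnAge")
#: candidate education transforms
EDUCATION_FORMS = ("rawEducation", "reciprocalEducation")

_ALL_TRANSFORMS = dict(TRANSFORMS)
_ALL_TRANSFORMS["rawEducation"] = lambda age, edu: float(edu)

#: cumulative normal areas of the ES1/ES2 and ES2/ES3 thresholds -- the
#: points splitting the z-range [z(.05), 0] into three equal widths
_Z5 = stats.norm.ppf(0.05)
ES_INNER_AREAS = tuple(stats.norm.cdf([_Z5 * 2 / 3, _Z5 / 3]))


def _transform_column(kind: str, age: np.ndarray, edu: np.ndarray) -> np.ndarray:
    fn = _ALL_TRANSFORMS[kind]
    return np.array([fn(a, e) for a, e in zip(age, edu)], dtype=float)


def _sex_code(sex: Iterable[str]) -> np.ndarray:
    # +1 female / -1 male, matching the published "+offset if female" convention
    return np.array([1.0 if normalize_sex(s) == "f" else -1.0 for s in sex])


@dataclass
class FittedTerm:
    """One retained demographic predictor of a normative regression."""

    kind: str          # transform identifier ("sex" for the sex contrast)
    coefficient: float  # OLS slope on the transformed predictor
    center: float       # cohort mean of the transformed predictor
    beta: float         # standardized coefficient
    t: float
    p: float

    def to_dict(self) -> dict:
        return vars(self).copy()


@dataclass
class NormativeModel:
    """Fitted normative machinery for one outcome.

    ``adjustment(age, education, sex)`` is the quantity *added* to a raw
    score: minus the fitted, mean-centered demographic effects.
    """

    outcome_id: str
    n: int
    terms: list[FittedTerm] = field(default_factory=list)
    resid_sd: float = float("nan")
    adjusted_sample: np.ndarray | None = None  # ascending
    oTL_rank: int | None = None
    iTL_rank: int | None = None
    oTL: float | None = None
    iTL: float | None = None
    es_bounds: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.terms

    @property
    def sex_term(self) -> FittedTerm | None:
        return next((t for t in self.terms if t.kind == "sex"), None)

    @property
    def sex_offset(self) -> float:
        """Published-style +female/-male offset (0 when sex not retained)."""
        st = self.sex_term
        return 0.0 if st is None else -st.coefficient

    def adjustment(self, age: float, education: float, sex: str) -> float:
        adj = 0.0
        code = 1.0 if normalize_sex(sex) == "f" else -1.0
        for term in self.terms:
            x = code if term.kind == "sex" else _ALL_TRANSFORMS[term.kind](age, education)
            adj -= term.coefficient * (x - term.center)
        return adj

    def adjust(self, raw: float, demo: Demographics) -> float:
        return raw + self.adjustment(demo.age, demo.education, demo.sex)

    def es(self, adjusted: float, *, es_zero_inclusive: bool = True) -> int:
        if self.es_bounds is None:
            raise ValueError(f"{self.outcome_id}: no ES thresholds derived")
        b = self.es_bounds
        if (adjusted <= b[0]) if es_zero_inclusive else (adjusted < b[0]):
            return 0
        for level in (1, 2, 3):
            if adjusted <= b[level]:
                return level
        return 4

    def to_dict(self) -> dict:
        return {
            "outcome_id": self.outcome_id,
            "n": self.n,
            "terms": [t.to_dict() for t in self.terms],
            "resid_sd": self.resid_sd,
            "oTL_rank": self.oTL_rank,
            "iTL_rank": self.iTL_rank,
            "oTL": self.oTL,
            "iTL": self.iTL,
            "es_bounds": None if self.es_bounds is None else list(map(float, self.es_bounds)),
            "adjusted_sample": (None if self.adjusted_sample is None
                                else list(map(float, self.adjusted_sample))),
            "flags": list(self.flags),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NormativeModel":
        m = cls(outcome_id=d["outcome_id"], n=int(d["n"]),
                terms=[FittedTerm(**t) for t in d["terms"]],
                resid_sd=float(d["resid_sd"]),
                oTL_rank=d["oTL_rank"], iTL_rank=d["iTL_rank"],
                oTL=d["oTL"], iTL=d["iTL"],
                es_bounds=None if d["es_bounds"] is None else np.asarray(d["es_bounds"], float),
                flags=list(d.get("flags", [])))
        if d.get("adjusted_sample") is not None:
            m.adjusted_sample = np.asarray(d["adjusted_sample"], float)
        return m


def _fit_ols(y: np.ndarray, columns: dict[str, np.ndarray]):
    X = sm.add_constant(pd.DataFrame(columns), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear predictors)")
    return sm.OLS(y, X).fit()


def select_model(
    cohort: pd.DataFrame,
    outcome_id: str,
    age_forms: Sequence[str] = AGE_FORMS,
    education_forms: Sequence[str] = EDUCATION_FORMS,
    alpha: float = 0.05,
    include_sex: bool = True,
) -> NormativeModel:
    """Select and fit the demographic regression for one raw outcome.

    Every pair (one age form, one education form) is fitted jointly with the
    sex contrast; the pair with the highest log-likelihood wins, and terms
    are then removed by backward elimination until all remaining predictors
    are significant at ``alpha``.  The winning model is refitted with the
    retained terms only.  An all-nonsignificant screen yields an empty model
    (adjusted = raw).
    """
    data = cohort.dropna(subset=[outcome_id])
    y = data[outcome_id].to_numpy(dtype=float)
    age = data["age"].to_numpy(dtype=float)
    edu = data["education"].to_numpy(dtype=float)
    n = len(y)
    n_candidates = 2 + (1 if include_sex else 0)
    if n < n_candidates + 3:
        raise ValueError(f"{outcome_id}: cohort too small ({n}) for {n_candidates} candidate terms")
    if np.ptp(y) == 0:
        model = NormativeModel(outcome_id=outcome_id, n=n, resid_sd=0.0)
        model.flags.append("zero residual variance: constant outcome, empty model")
        return model

    sex = _sex_code(data["sex"]) if include_sex else None

    def columns_for(kinds: Sequence[str]) -> dict[str, np.ndarray]:
        cols = {}
        for kind in kinds:
            cols[kind] = sex.copy() if kind == "sex" else _transform_column(kind, age, edu)
        return cols

    # 1. choose the transform pair by maximized log-likelihood of the full model
    best = None
    for a_form, e_form in product(age_forms, education_forms):
        kinds = [a_form, e_form] + (["sex"] if include_sex else [])
        try:
            res = _fit_ols(y, columns_for(kinds))
        except ValueError:
            continue
        if best is None or res.llf > best[1]:
            best = (kinds, res.llf)
    if best is None:
        raise ValueError(f"{outcome_id}: every candidate design was rank-deficient")
    kinds = list(best[0])

    # 2. backward elimination at alpha
    while kinds:
        res = _fit_ols(y, columns_for(kinds))
        pvals = res.pvalues.drop("const")
        worst = pvals.idxmax()
        if pvals[worst] > alpha:
            kinds.remove(worst)
        else:
            break

    model = NormativeModel(outcome_id=outcome_id, n=n)
    if not kinds:
        model.resid_sd = float(np.std(y, ddof=1))
        return model

    res = _fit_ols(y, columns_for(kinds))
    sd_y = np.std(y, ddof=1)
    for kind in kinds:
        x = columns_for([kind])[kind]
        model.terms.append(FittedTerm(
            kind=kind,
            coefficient=float(res.params[kind]),
            center=float(np.mean(x)),
            beta=float(res.params[kind] * np.std(x, ddof=1) / sd_y),
            t=float(res.tvalues[kind]),
            p=float(res.pvalues[kind]),
        ))
    model.resid_sd = float(np.sqrt(res.mse_resid))
    return model


def adjust_cohort(model: NormativeModel, cohort: pd.DataFrame) -> np.ndarray:
    """Adjusted scores for every cohort row (NaN where the outcome is missing).

    adjusted_i = raw_i - sum_k b_k (t_k(x_i) - mean t_k), with sex as a
    centered contrast, so the cohort-mean adjustment is zero by construction.
    """
    raw = cohort[model.outcome_id].to_numpy(dtype=float)
    age = cohort["age"].to_numpy(dtype=float)
    edu = cohort["education"].to_numpy(dtype=float)
    adj = np.zeros_like(raw)
    for term in model.terms:
        if term.kind == "sex":
            x = _sex_code(cohort["sex"])
        else:
            x = _transform_column(term.kind, age, edu)
        adj -= term.coefficient * (x - term.center)
    return raw + adj


def tolerance_limit_ranks(n: int, p: float = 0.05, conf: float = 0.95) -> tuple[int, int]:
    """Order-statistic ranks of the outer and inner tolerance limits.

    The outer limit is the largest order statistic a such that, with
    confidence ``conf``, the population ``p``-th centile exceeds it:
    the largest a with P[Binomial(n, p) <= a-1] <= 1-conf.  The inner limit
    is the smallest b with P[Binomial(n, p) <= b-1] >= conf.  Ranks are
    1-based on the ascending sort.
    """
    if n < 1:
        raise ValueError("n must be positive")
    # largest k with cdf(k) <= 1-conf, via the quantile function
    k = int(stats.binom.ppf(1 - conf, n, p))  # smallest k with cdf(k) >= 1-conf
    if stats.binom.cdf(k, n, p) > (1 - conf) + 1e-12:
        k -= 1
    a = k + 1
    if a < 1:
        raise ValueError(
            f"n={n} is too small for an outer tolerance limit at p={p}, conf={conf}: "
            f"P[Binomial({n},{p})=0] = {stats.binom.cdf(0, n, p):.4g} > {1-conf}")
    b = int(stats.binom.ppf(conf, n, p)) + 1
    if b > n:
        raise ValueError(f"n={n} too small for an inner tolerance limit")
    return a, b


def es_thresholds(adjusted: np.ndarray, oTL: float,
                  strategy: str = "rank") -> np.ndarray:
    """Four upper bounds partitioning adjusted scores into ES levels 0-4.

    ES 0 ends at the outer tolerance limit, ES 4 starts above the sample
    median, and the ES1/ES2 and ES2/ES3 bounds sit at the quantiles whose
    cumulative normal areas (~13.6% and ~29.2%) split [z(.05), 0] into three
    equal z-widths.  ``strategy='rank'`` reads those quantiles off the
    sample; ``strategy='normal'`` evaluates them on a fitted normal curve.
    """
    x = np.sort(np.asarray(adjusted, dtype=float))
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("empty adjusted sample")
    if strategy == "rank":
        inner = np.quantile(x, ES_INNER_AREAS)
        median = float(np.median(x))
    elif strategy == "normal":
        mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        z = np.array([_Z5 * 2 / 3, _Z5 / 3])
        inner = mu + sd * z
        median = mu
    else:
        raise ValueError(f"unknown ES threshold strategy {strategy!r}")
    bounds = np.array([oTL, inner[0], inner[1], median], dtype=float)
    monotone = np.maximum.accumulate(bounds)
    if np.unique(monotone).size < 4:
        warnings.warn(
            "ES thresholds collapsed: fewer distinct adjusted values than ES bins",
            stacklevel=2)
    return monotone


@dataclass
class NormativeReport:
    """Bundle of fitted normative models plus the AES composites."""

    models: dict[str, NormativeModel]
    aes: pd.DataFrame | None = None          # per-participant AES_T / AES_WMS
    aes_limits: dict[str, dict] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    def norm_table(self) -> pd.DataFrame:
        """Norm sheet: one row per outcome (oTL, iTL, five ES intervals)."""
        rows = []
        for oid, m in self.models.items():
            row = {"outcome": oid, "n": m.n, "oTL": m.oTL, "iTL": m.iTL}
            if m.es_bounds is not None:
                b = m.es_bounds
                row.update({
                    "ES0": f"<= {b[0]:.3g}",
                    "ES1": f"{b[0]:.3g} - {b[1]:.3g}",
                    "ES2": f"{b[1]:.3g} - {b[2]:.3g}",
                    "ES3": f"{b[2]:.3g} - {b[3]:.3g}",
                    "ES4": f"> {b[3]:.3g}",
                })
            rows.append(row)
        for scale, lim in self.aes_limits.items():
            rows.append({"outcome": scale, "n": lim.get("n"),
                         "oTL": lim.get("oTL"), "iTL": lim.get("iTL")})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "models": {k: m.to_dict() for k, m in self.models.items()},
            "aes_limits": self.aes_limits,
            "errors": dict(self.errors),
        }


def _score_es_frame(report_models: Mapping[str, NormativeModel],
                    cohort: pd.DataFrame, *, es_zero_inclusive: bool = True) -> pd.DataFrame:
    """Per-participant ES levels under freshly derived norms."""
    out = {}
    for oid, model in report_models.items():
        if model.es_bounds is None:
            continue
        adjusted = adjust_cohort(model, cohort)
        out[oid] = [
            model.es(a, es_zero_inclusive=es_zero_inclusive) if not math.isnan(a) else np.nan
            for a in adjusted
        ]
    return pd.DataFrame(out, index=cohort.index)


def compute_aes(es_frame: pd.DataFrame, p: float = 0.05, conf: float = 0.95
                ) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Average Equivalent Scores per participant plus their tolerance limits.

    A participant enters a composite only with all five constituent ESs
    present; others yield NaN.  Limits are order-statistic tolerance limits
    on the observed AES sample.
    """
    aes = pd.DataFrame(index=es_frame.index)
    for name, constituents in (("AES_T", AES_T_CONSTITUENTS),
                               ("AES_WMS", AES_WMS_CONSTITUENTS)):
        cols = [c for c in constituents if c in es_frame.columns]
        if len(cols) == len(constituents):
            block = es_frame[list(constituents)]
            aes[name] = block.mean(axis=1).where(block.notna().all(axis=1))
        else:
            aes[name] = np.nan
    limits: dict[str, dict] = {}
    for name in ("AES_T", "AES_WMS"):
        sample = np.sort(aes[name].dropna().to_numpy())
        entry: dict = {"n": int(sample.size)}
        try:
            a, b = tolerance_limit_ranks(sample.size, p, conf)
            entry.update({"oTL_rank": a, "iTL_rank": b,
                          "oTL": float(sample[a - 1]), "iTL": float(sample[b - 1])})
        except ValueError as exc:
            entry["error"] = str(exc)
        limits[name] = entry
    return aes, limits


def build_norms(
    cohort: pd.DataFrame,
    outcomes: Sequence[str] = OUTCOME_COLUMNS,
    *,
    p: float = 0.05,
    conf: float = 0.95,
    alpha: float = 0.05,
    es_strategy: str = "rank",
) -> NormativeReport:
    """Run the full normative derivation on a cohort table.

    Per-outcome failures are recorded in ``report.errors`` without aborting
    the remaining outcomes.
    """
    report = NormativeReport(models={})
    for oid in outcomes:
        try:
            model = select_model(cohort, oid, alpha=alpha)
            data = cohort.dropna(subset=[oid])
            adjusted = np.sort(adjust_cohort(model, data))
            model.adjusted_sample = adjusted
            a, b = tolerance_limit_ranks(adjusted.size, p, conf)
            model.oTL_rank, model.iTL_rank = a, b
            model.oTL = float(adjusted[a - 1])
            model.iTL = float(adjusted[b - 1])
            model.es_bounds = es_thresholds(adjusted, model.oTL, strategy=es_strategy)
            report.models[oid] = model
        except (ValueError, KeyError) as exc:
            report.errors[oid] = str(exc)
    es_frame = _score_es_frame(report.models, cohort)
    if not es_frame.empty:
        report.aes, report.aes_limits = compute_aes(es_frame, p, conf)
    return report


@dataclass(frozen=True)
class PowerSpec:
    """Power-analysis specification for a multiple linear regression F test."""

    f2: float = 0.10
    u: int = 3
    alpha: float = 0.05
    power: float = 0.90

    def __post_init__(self) -> None:
        if not self.f2 > 0:
            raise ValueError("f2 must be positive")
        if self.u < 1:
            raise ValueError("u must be at least 1")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")


def regression_power(f2: float, u: int, v: int, alpha: float) -> float:
    """Power of the regression F test with noncentrality f2 * (u + v + 1)."""
    lam = f2 * (u + v + 1)
    fcrit = stats.f.ppf(1 - alpha, u, v)
    return float(stats.ncf.sf(fcrit, u, v, lam))


def min_sample_size(spec: PowerSpec, v_max: int = 1_000_000) -> int:
    """Minimum N = u + v + 1 reaching the target power.

    Searches the smallest denominator df v at which the noncentral-F power
    of the overall regression test reaches ``spec.power``.
    """
    for v in range(1, v_max + 1):
        if regression_power(spec.f2, spec.u, v, spec.alpha) >= spec.power:
            return spec.u + v + 1
    raise ValueError(f"target power {spec.power} unreachable within v <= {v_max}")
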