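"""Model/Results front-end for deriving Equivalent-Score norms.

`NormingModel` holds a cohort table and the derivation settings; `fit()`
runs the whole pipeline (per-outcome demographic regression, adjusted
scores, tolerance limits, ES partition, AES composites) and returns a
`NormingResults` carrying the fitted normative models, a printable summary,
publication-style tables and individual scoring.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .battery import OUTCOME_COLUMNS
from .pipeline import (NormativeModel, NormativeReport, adjust_cohort,
                       build_norms)
from .published import (AES_T_CONSTITUENTS, AES_WMS_CONSTITUENTS,
                        Demographics)

__all__ = ["NormingModel", "NormingResults"]

_SCHEMA_VERSION = 1


class NormingModel:
    """Equivalent-Score norming of a cohort of raw WoMAB outcomes.

    Parameters
    ----------
    cohort
        One row per participant with ``age``, ``education``, ``sex`` and raw
        outcome columns.
    outcomes
        Outcome columns to norm (default: the full battery).
    p, conf
        Centile and confidence of the nonparametric tolerance limits
        (default: 5th centile at 95% confidence).
    alpha
        Retention threshold of the demographic regressions.
    es_strategy
        'rank' (sample quantiles) or 'normal' (fitted-normal areas) for the
        intermediate ES thresholds.
    """

    def __init__(self, cohort: pd.DataFrame,
                 outcomes: Sequence[str] = OUTCOME_COLUMNS, *,
                 p: float = 0.05, conf: float = 0.95, alpha: float = 0.05,
                 es_strategy: str = "rank"):
        required = {"age", "education", "sex"}
        missing = required - set(cohort.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        self.cohort = cohort.reset_index(drop=True)
        self.outcomes = [o for o in outcomes if o in cohort.columns]
        if not self.outcomes:
            raise ValueError("no outcome columns found in the cohort table")
        self.p, self.conf, self.alpha = p, conf, alpha
        self.es_strategy = es_strategy

    @classmethod
    def from_csv(cls, path, **kwargs) -> "NormingModel":
        from .io import read_cohort
        return cls(read_cohort(path).data, **kwargs)

    def fit(self) -> "NormingResults":
        report = build_norms(self.cohort, self.outcomes, p=self.p,
                             conf=self.conf, alpha=self.alpha,
                             es_strategy=self.es_strategy)
        return NormingResults(self, report)


class NormingResults:
    """Fitted normative models for one cohort."""

    def __init__(self, model: NormingModel, report: NormativeReport):
        self.model = model
        self.report = report
        self.models: Mapping[str, NormativeModel] = report.models

    # -- tables -----------------------------------------------------------

    def norm_table(self) -> pd.DataFrame:
        """Norm sheet (oTL, iTL, five ES intervals; AES rows carry TLs only)."""
        return self.report.norm_table()

    def coefficient_table(self) -> pd.DataFrame:
        rows = []
        for oid, m in self.models.items():
            for term in m.terms:
                rows.append({"outcome": oid, "term": term.kind,
                             "coef": term.coefficient, "center": term.center,
                             "beta": term.beta, "t": term.t, "p": term.p})
            if m.is_empty:
                rows.append({"outcome": oid, "term": "(none retained)"})
        return pd.DataFrame(rows)

    def adjustment_grids(self, ages: Sequence[int] = (35, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85),
                         educations: Sequence[int] = (5, 8, 11, 13, 16, 18),
                         decimals: int = 2) -> dict[str, pd.DataFrame]:
        """Adjustment-factor grids on the standard age/education lattice."""
        from .published import round_half_away
        grids: dict[str, pd.DataFrame] = {}
        for oid, m in self.models.items():
            dec = decimals + 1 if oid.startswith("DSR") else decimals
            uses_edu = any(t.kind in ("reciprocalEducation", "rawEducation")
                           for t in m.terms)
            sexes = ["m", "f"] if m.sex_term is not None else [None]
            for sex in sexes:
                key = oid if sex is None else f"{oid}_{sex.upper()}"
                rows = {}
                for edu in (educations if uses_edu else ["adjustment"]):
                    e = edu if isinstance(edu, int) else 10
                    rows[edu] = [round_half_away(m.adjustment(a, e, sex or "m"), dec)
                                 for a in ages]
                df = pd.DataFrame.from_dict(rows, orient="index", columns=list(ages))
                df.columns.name = "age"
                grids[key] = df
        return grids

    # -- individual scoring ----------------------------------------------

    def adjusted_scores(self) -> pd.DataFrame:
        """Adjusted scores of the fitted cohort, one column per outcome."""
        out = {}
        for oid, m in self.models.items():
            out[oid] = adjust_cohort(m, self.model.cohort)
        return pd.DataFrame(out, index=self.model.cohort.index)

    def score(self, raw_scores: Mapping[str, float], demo: Demographics) -> dict:
        """ES profile of one subject under the freshly derived norms."""
        outcomes = {}
        for oid, raw in raw_scores.items():
            if oid not in self.models or raw is None:
                continue
            m = self.models[oid]
            adjusted = m.adjust(float(raw), demo)
            outcomes[oid] = {"raw": float(raw), "adjusted": adjusted,
                             "es": m.es(adjusted) if m.es_bounds is not None else None}

        def composite(names):
            if all(n in outcomes and outcomes[n]["es"] is not None for n in names):
                return sum(outcomes[n]["es"] for n in names) / len(names)
            return None

        return {"outcomes": outcomes,
                "aes_t": composite(AES_T_CONSTITUENTS),
                "aes_wms": composite(AES_WMS_CONSTITUENTS)}

    # -- reporting / persistence ------------------------------------------

    def summary(self) -> str:
        lines = ["Equivalent-Score norming results",
                 "=" * 48,
                 f"cohort n = {len(self.model.cohort)}; outcomes = {len(self.models)}",
                 f"tolerance limits: p = {self.model.p}, conf = {self.model.conf}; "
                 f"ES strategy = {self.model.es_strategy}", ""]
        for oid, m in self.models.items():
            lines.append(f"{oid} (n={m.n})")
            if m.is_empty:
                lines.append("  no significant demographic predictors; adjusted = raw")
            for term in m.terms:
                lines.append(
                    f"  {term.kind:<22} b={term.coefficient:>12.6g}  beta={term.beta:>7.3f}"
                    f"  t={term.t:>7.2f}  p={term.p:.4g}")
            if m.oTL is not None:
                lines.append(f"  oTL={m.oTL:.3f} (rank {m.oTL_rank})  "
                             f"iTL={m.iTL:.3f} (rank {m.iTL_rank})")
            if m.es_bounds is not None:
                b = ", ".join(f"{x:.3f}" for x in m.es_bounds)
                lines.append(f"  ES upper bounds: [{b}]")
            for flag in m.flags:
                lines.append(f"  ! {flag}")
            lines.append("")
        for scale, lim in self.report.aes_limits.items():
            if "oTL" in lim:
                lines.append(f"{scale}: oTL={lim['oTL']:.2f} iTL={lim['iTL']:.2f} "
                             f"(n={lim['n']})")
            else:
                lines.append(f"{scale}: {lim.get('error', 'unavailable')}")
        for oid, err in self.report.errors.items():
            lines.append(f"{oid}: ERROR {err}")
        return "\n".join(lines)

    def save(self, path) -> None:
        from .io import serialize_report
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(serialize_report(self.report))
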