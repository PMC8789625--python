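"""Individual scoring against the published WoMAB norms.

The normative study modelled each raw outcome on demographic predictors
(age and education transforms, plus sex where significant) and published,
for each outcome, an adjustment equation of the form

    adjusted = raw + sum_k b_k * (t_k(x) - mean(t_k))  [+/- sex offset]

together with nonparametric tolerance limits (oTL, iTL) for the population
5th-centile cutoff and four thresholds partitioning adjusted scores into the
five Equivalent-Score levels (ES 0 "abnormal" ... ES 4 "high-end normal").
This module ships those constants as a versioned JSON resource and applies
them exactly; it never re-estimates anything (see :mod:`womab.pipeline` for
re-derivation on a new cohort).

Printed coefficients are used verbatim — the cubic-age coefficients are
rounded in print, so regenerated adjustment grids are guaranteed to match
the published ones only to within 0.01.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Callable, Mapping

import pandas as pd

from .battery import OUTCOME_COLUMNS, TEST_SPECS, TestId

__all__ = [
    "Demographics",
    "PublishedEquation",
    "NormTableRow",
    "OutcomeScore",
    "ESProfile",
    "AES_T_CONSTITUENTS",
    "AES_WMS_CONSTITUENTS",
    "load_norms",
    "published_adjust",
    "adjustment_factor",
    "published_es",
    "score_patient",
    "regenerate_grids",
    "round_half_away",
]

_RESOURCE = "published_norms_v1.json"

#: theoretical raw ranges of the eight base outcomes
_RAW_MAX = {
    "DOT_T": TEST_SPECS[TestId.DOT].t_max, "DOT_WM": TEST_SPECS[TestId.DOT].wm_max,
    "ICT_T": TEST_SPECS[TestId.ICT].t_max, "ICT_WM": TEST_SPECS[TestId.ICT].wm_max,
    "FDS_T": TEST_SPECS[TestId.FDS].t_max, "FDS_S": TEST_SPECS[TestId.FDS].wm_max,
    "BDS_T": TEST_SPECS[TestId.BDS].t_max, "BDS_WM": TEST_SPECS[TestId.BDS].wm_max,
}

#: the five constituents of each Average Equivalent Score composite
AES_T_CONSTITUENTS = ("DOT_T", "ICT_T", "FDS_T", "BDS_T", "DSR_T")
AES_WMS_CONSTITUENTS = ("DOT_WM", "ICT_WM", "FDS_S", "BDS_WM", "DSR_WMS")

TRANSFORMS: Mapping[str, Callable[[float, float], float]] = {
    "ln100minusAge": lambda age, edu: math.log(100.0 - age),
    "ageCubed": lambda age, edu: float(age) ** 3,
    "reciprocalEducation": lambda age, edu: 1.0 / edu,
    "rawAge": lambda age, edu: float(age),
    "lnAge": lambda age, edu: math.log(age),
    "reciprocalAge": lambda age, edu: 1.0 / age,
}


def normalize_sex(sex: str) -> str:
    s = str(sex).strip().lower()
    if s in ("m", "male"):
        return "m"
    if s in ("f", "female"):
        return "f"
    raise ValueError(f"sex must be one of m/f/male/female, got {sex!r}")


@dataclass(frozen=True)
class Demographics:
    """Age (years), education (years of schooling) and sex of one subject.

    The transform family uses ln(100 - age), ln(age), 1/age and 1/education,
    so age must lie in [1, 99] and education must be at least 1 year.
    """

    age: int
    education: int
    sex: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", normalize_sex(self.sex))
        if not 1 <= self.age <= 99:
            raise ValueError(f"age {self.age} outside the transform domain [1, 99]")
        if self.education < 1:
            raise ValueError(f"education {self.education} outside the transform domain (>= 1)")

    @property
    def sex_sign(self) -> float:
        """+1 for female, -1 for male (the published offset convention)."""
        return 1.0 if self.sex == "f" else -1.0


@dataclass(frozen=True)
class PublishedEquation:
    outcome_id: str
    terms: tuple[tuple[str, float, float], ...]  # (transform kind, coefficient, centering)
    sex_offset: float


@dataclass(frozen=True)
class NormTableRow:
    outcome_id: str
    oTL: float
    iTL: float
    es_upper_bounds: tuple[float, float, float, float] | None

    def __post_init__(self) -> None:
        if self.oTL > self.iTL:
            raise ValueError(f"{self.outcome_id}: oTL {self.oTL} exceeds iTL {self.iTL}")
        if self.es_upper_bounds is not None:
            b = self.es_upper_bounds
            if not (b[0] < b[1] < b[2] < b[3]):
                raise ValueError(f"{self.outcome_id}: ES bounds not strictly increasing: {b}")
            if b[0] != self.oTL:
                raise ValueError(f"{self.outcome_id}: ES 0 bound {b[0]} must equal oTL {self.oTL}")


@dataclass(frozen=True)
class PublishedNorms:
    schema_version: int
    equations: Mapping[str, PublishedEquation]
    norm_table: Mapping[str, NormTableRow]
    grid_ages: tuple[int, ...]
    grid_educations: tuple[int, ...]


def load_norms() -> PublishedNorms:
    """Load the packaged normative constants (validated on load)."""
    raw = json.loads(resources.files("womab.resources").joinpath(_RESOURCE).read_text())
    if raw.get("schema_version") != 1:
        raise ValueError(f"unsupported norms schema version: {raw.get('schema_version')!r}")
    centers = raw["centering_constants"]
    equations = {}
    for oid, eq in raw["equations"].items():
        terms = tuple((kind, float(coef), float(centers[kind])) for kind, coef in eq["terms"])
        equations[oid] = PublishedEquation(oid, terms, float(eq["sex_offset"]))
    table = {}
    for oid, row in raw["norm_table"].items():
        ub = row["es_upper_bounds"]
        table[oid] = NormTableRow(
            oid, float(row["oTL"]), float(row["iTL"]),
            None if ub is None else tuple(float(x) for x in ub))
    lattice = raw["grid_lattice"]
    return PublishedNorms(1, equations, table,
                          tuple(lattice["ages"]), tuple(lattice["educations"]))


_NORMS = load_norms()


def adjustment_factor(outcome_id: str, demo: Demographics,
                      norms: PublishedNorms = _NORMS) -> float:
    """Demographic adjustment added to the raw score (full precision)."""
    try:
        eq = norms.equations[outcome_id]
    except KeyError:
        raise KeyError(f"no published equation for outcome {outcome_id!r}") from None
    adj = 0.0
    for kind, coef, center in eq.terms:
        adj += coef * (TRANSFORMS[kind](demo.age, demo.education) - center)
    adj += demo.sex_sign * eq.sex_offset
    return adj


def published_adjust(outcome_id: str, raw: float, demo: Demographics,
                     norms: PublishedNorms = _NORMS) -> float:
    """Adjusted score = raw + published demographic adjustment."""
    return raw + adjustment_factor(outcome_id, demo, norms)


def published_es(outcome_id: str, adjusted: float, *,
                 es_zero_inclusive: bool = True,
                 norms: PublishedNorms = _NORMS) -> int:
    """Equivalent-Score level (0-4) of an adjusted score.

    ``es_zero_inclusive`` keeps the norm table's boundary convention
    (adjusted <= oTL -> ES 0); setting it False uses the strict-inequality
    reading (adjusted < oTL) found elsewhere in the ES literature.
    """
    try:
        row = norms.norm_table[outcome_id]
    except KeyError:
        raise KeyError(f"no normative thresholds for outcome {outcome_id!r}") from None
    if row.es_upper_bounds is None:
        raise ValueError(
            f"{outcome_id} carries tolerance limits only; no ES partition is "
            "published for the AES composites")
    b = row.es_upper_bounds
    if adjusted <= b[0] if es_zero_inclusive else adjusted < b[0]:
        return 0
    for level, ub in enumerate(b[1:], start=1):
        if adjusted <= ub:
            return level
    return 4


@dataclass(frozen=True)
class OutcomeScore:
    raw: float
    adjusted: float
    es: int


@dataclass(frozen=True)
class ESProfile:
    """Per-outcome adjusted scores and ES levels plus AES composites."""

    demographics: Demographics
    outcomes: Mapping[str, OutcomeScore]
    aes_t: float | None
    aes_wms: float | None
    errors: Mapping[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "demographics": {"age": self.demographics.age,
                             "education": self.demographics.education,
                             "sex": self.demographics.sex},
            "outcomes": {k: vars(v) for k, v in self.outcomes.items()},
            "aes_t": self.aes_t,
            "aes_wms": self.aes_wms,
            "errors": dict(self.errors),
        }


def _derive_dsr(raw_scores: dict[str, float]) -> dict[str, float]:
    out = dict(raw_scores)
    if "DSR_T" not in out and {"FDS_T", "BDS_T"} <= out.keys():
        if out["FDS_T"]:
            out["DSR_T"] = out["BDS_T"] / out["FDS_T"]
    if "DSR_WMS" not in out and {"FDS_S", "BDS_WM"} <= out.keys():
        if out["FDS_S"]:
            out["DSR_WMS"] = out["BDS_WM"] / out["FDS_S"]
    return out


def score_patient(raw_scores: Mapping[str, float], demo: Demographics, *,
                  es_zero_inclusive: bool = True,
                  norms: PublishedNorms = _NORMS) -> ESProfile:
    """Score one subject: adjust every supplied raw outcome, assign ES
    levels, and form the AES composites.

    DSR ratios are derived from the supplied forward/backward raw scores when
    not given explicitly.  Each AES (mean ES over the five T or the five
    WM/S outcomes) is computed only when all five constituents scored; with
    fewer, partial per-outcome results are still returned and the composite
    is None.  Per-outcome problems are collected in ``errors``, not raised.
    """
    raw_scores = _derive_dsr({k: v for k, v in dict(raw_scores).items()
                              if v is not None and not (isinstance(v, float) and math.isnan(v))})
    outcomes: dict[str, OutcomeScore] = {}
    errors: dict[str, str] = {}
    for oid in OUTCOME_COLUMNS:
        if oid not in raw_scores:
            continue
        raw = float(raw_scores[oid])
        if oid in _RAW_MAX and not (0 <= raw <= _RAW_MAX[oid]):
            errors[oid] = f"raw score {raw} outside theoretical range 0-{_RAW_MAX[oid]}"
            continue
        try:
            adjusted = published_adjust(oid, raw, demo, norms)
            es = published_es(oid, adjusted, es_zero_inclusive=es_zero_inclusive, norms=norms)
        except (KeyError, ValueError) as exc:
            errors[oid] = str(exc)
            continue
        outcomes[oid] = OutcomeScore(raw=raw, adjusted=adjusted, es=es)

    def composite(constituents: tuple[str, ...]) -> float | None:
        if all(c in outcomes for c in constituents):
            return sum(outcomes[c].es for c in constituents) / len(constituents)
        return None

    return ESProfile(demographics=demo, outcomes=outcomes,
                     aes_t=composite(AES_T_CONSTITUENTS),
                     aes_wms=composite(AES_WMS_CONSTITUENTS),
                     errors=errors)


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def regenerate_grids(norms: PublishedNorms = _NORMS) -> dict[str, pd.DataFrame]:
    """Recompute the published adjustment-factor grids from the equations.

    Returns one DataFrame per grid, indexed by education (a single
    ``adjustment`` row for the ratio outcomes, which do not use education)
    with one column per lattice age.  Sex-dependent outcomes get one grid per
    sex, keyed ``<outcome>_M`` / ``<outcome>_F``.  Cells are rounded half
    away from zero to 2 decimals (3 for the ratio outcomes).
    """
    ages, edus = norms.grid_ages, norms.grid_educations
    grids: dict[str, pd.DataFrame] = {}
    for oid, eq in norms.equations.items():
        decimals = 3 if oid.startswith("DSR") else 2
        uses_edu = any(kind == "reciprocalEducation" for kind, _, _ in eq.terms)
        sexes = ["m", "f"] if eq.sex_offset else [None]
        for sex in sexes:
            key = oid if sex is None else f"{oid}_{sex.upper()}"
            rows = {}
            for edu in (edus if uses_edu else [None]):
                vals = []
                for age in ages:
                    demo = Demographics(age=age, education=edu if edu else 10,
                                        sex=sex or "m")
                    adj = adjustment_factor(oid, demo, norms)
                    if sex is None and eq.sex_offset:
                        adj -= demo.sex_sign * eq.sex_offset
                    vals.append(round_half_away(adj, decimals))
                rows[edu if edu else "adjustment"] = vals
            df = pd.DataFrame.from_dict(rows, orient="index", columns=list(ages))
            df.index.name = "education" if uses_edu else None
            df.columns.name = "age"
            grids[key] = df
    return grids
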