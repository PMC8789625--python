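"""Synthetic normative cohorts with the WoMAB study's statistical structure.

The generator emulates a stratified normative sample of healthy Italian
adults (default n = 168, 73 male / 95 female, age 18-86, education 4-21,
with the published age x education x sex cell counts): raw test scores
decline with age, improve with education, show a male advantage on the
backward-span outcomes, and are highly inter-correlated through a shared
latent ability factor.

Per outcome, a raw score is drawn as

    round(clip(intercept + demographic effect + loading * g + eps))

where the demographic effect inverts the published adjustment equation for
that outcome (so re-deriving norms on a synthetic cohort is a genuine
parameter-recovery exercise), g ~ N(0,1) is shared within participant and
eps ~ N(0, sigma^2) is outcome-specific.  Digit-span ratios are always
recomputed from the generated forward/backward raw scores, never sampled.

Trial-level administrations can be emitted whose rescoring reproduces the
tabulated outcomes exactly (the round-trip contract of the scorer).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .battery import (OUTCOME_COLUMNS, TEST_OUTCOME_COLUMNS, TEST_SPECS,
                      OutcomePair, TestId, TestSpec, TrialRecord)
from .published import Demographics, adjustment_factor

__all__ = [
    "StratumCell",
    "OutcomeParams",
    "SyntheticCohortSpec",
    "DEFAULT_SPEC",
    "sample_demographics",
    "generate_outcomes",
    "generate_cohort",
    "generate_trials",
    "trials_for_pair",
]


@dataclass(frozen=True)
class StratumCell:
    """One age-band x education-band x sex cell of the sampling frame."""

    age_range: tuple[int, int]
    education_range: tuple[int, int]
    sex: str
    count: int


# Published stratification: age bands <=35, 36-45, ..., 76-85, >=86 crossed
# with education bands <=5, 6-11, 12-16, >=17; cells give male/female counts.
# Observed sample bounds (age 18-86, education 4-21) close the open bands.
_AGE_BANDS = ((18, 35), (36, 45), (46, 55), (56, 65), (66, 75), (76, 85), (86, 86))
_EDU_BANDS = ((4, 5), (6, 11), (12, 16), (17, 21))
_CELL_COUNTS = {
    (4, 5):   ((0, 0), (0, 0), (0, 1), (3, 1), (4, 8), (4, 6), (0, 0)),
    (6, 11):  ((2, 2), (5, 1), (4, 13), (7, 5), (4, 3), (0, 1), (1, 0)),
    (12, 16): ((9, 11), (3, 4), (2, 6), (4, 1), (1, 1), (0, 1), (0, 0)),
    (17, 21): ((11, 21), (1, 0), (3, 3), (4, 6), (1, 0), (0, 0), (0, 0)),
}


def _default_cells() -> tuple[StratumCell, ...]:
    cells = []
    for edu_band, counts in _CELL_COUNTS.items():
        for age_band, (m, f) in zip(_AGE_BANDS, counts):
            if m:
                cells.append(StratumCell(age_band, edu_band, "m", m))
            if f:
                cells.append(StratumCell(age_band, edu_band, "f", f))
    return tuple(cells)


@dataclass(frozen=True)
class OutcomeParams:
    """Generative parameters for one raw outcome.

    ``shared_frac`` is the fraction of the non-demographic standard
    deviation carried by the shared ability factor; the remainder is
    outcome-specific noise.  When ``loading``/``resid_sd`` are None they are
    derived at generation time from ``target_sd`` and the realized variance
    of the demographic effect.
    """

    intercept: float
    target_sd: float
    shared_frac: float = 0.75
    loading: float | None = None
    resid_sd: float | None = None


#: intercepts / dispersions matching the published sample descriptives
_DEFAULT_OUTCOME_PARAMS: Mapping[str, OutcomeParams] = {
    "DOT_T": OutcomeParams(7.33, 2.45),
    "DOT_WM": OutcomeParams(6.25, 1.48),
    "ICT_T": OutcomeParams(7.29, 2.81),
    "ICT_WM": OutcomeParams(6.32, 1.81),
    "FDS_T": OutcomeParams(9.98, 2.48),
    "FDS_S": OutcomeParams(6.45, 1.34),
    "BDS_T": OutcomeParams(7.07, 2.73),
    "BDS_WM": OutcomeParams(5.02, 1.50),
}

_OUTCOME_RANGES = {
    "DOT_T": (0, TEST_SPECS[TestId.DOT].t_max), "DOT_WM": (0, TEST_SPECS[TestId.DOT].wm_max),
    "ICT_T": (0, TEST_SPECS[TestId.ICT].t_max), "ICT_WM": (0, TEST_SPECS[TestId.ICT].wm_max),
    "FDS_T": (0, TEST_SPECS[TestId.FDS].t_max), "FDS_S": (0, TEST_SPECS[TestId.FDS].wm_max),
    "BDS_T": (0, TEST_SPECS[TestId.BDS].t_max), "BDS_WM": (0, TEST_SPECS[TestId.BDS].wm_max),
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Sampling frame plus generative model of a synthetic normative cohort."""

    cells: tuple[StratumCell, ...] = field(default_factory=_default_cells)
    outcome_params: Mapping[str, OutcomeParams] = field(
        default_factory=lambda: dict(_DEFAULT_OUTCOME_PARAMS))
    enforce_pair_consistency: bool = True

    @property
    def n(self) -> int:
        return sum(c.count for c in self.cells)


DEFAULT_SPEC = SyntheticCohortSpec()


def sample_demographics(spec: SyntheticCohortSpec = DEFAULT_SPEC,
                        seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Draw a demographics table honouring the cell counts exactly.

    Ages and educations are uniform integers within their band (a stated
    simplification: the real joint distribution inside cells is unknown).
    Deterministic for a given (spec, seed).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    for cell in spec.cells:
        if cell.count < 0:
            raise ValueError("cell counts must be non-negative")
        ages = rng.integers(cell.age_range[0], cell.age_range[1] + 1, size=cell.count)
        edus = rng.integers(cell.education_range[0], cell.education_range[1] + 1,
                            size=cell.count)
        for a, e in zip(ages, edus):
            rows.append({"age": int(a), "education": int(e), "sex": cell.sex})
    df = pd.DataFrame(rows)
    df.insert(0, "participant_id", [f"S{i + 1:04d}" for i in range(len(df))])
    return df


def _demographic_effects(outcome_id: str, demographics: pd.DataFrame) -> np.ndarray:
    """Systematic raw-score component: minus the published adjustment."""
    return -np.array([
        adjustment_factor(outcome_id, Demographics(int(r.age), int(r.education), r.sex))
        for r in demographics.itertuples(index=False)
    ])


def _reconcile_pair(t: int, wm: int, spec: TestSpec) -> tuple[int, int]:
    """Project a (T, WM) draw onto the pairs reachable under the stop rule."""
    if t <= 0 or wm <= 0:
        return 0, 0
    wm = int(np.clip(wm, spec.min_length, spec.max_length))
    k = wm - spec.min_length + 1
    t = int(np.clip(t, k, 2 * k))
    return t, wm


def generate_outcomes(demographics: pd.DataFrame,
                      spec: SyntheticCohortSpec = DEFAULT_SPEC,
                      seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Generate the ten raw outcomes for a demographics table.

    Integer test scores are rounded and clipped to their theoretical ranges
    (with a warning if clipping touches more than 10% of an outcome) and,
    by default, projected onto (T, WM) pairs reachable under the two-lists /
    stop-after-double-fail administration so that trial-level records can be
    reconstructed.  DSR columns are derived by division.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(demographics)
    g = rng.standard_normal(n)  # shared ability factor
    cohort = demographics.reset_index(drop=True).copy()
    for oid, params in spec.outcome_params.items():
        effects = _demographic_effects(oid, cohort)
        loading, resid_sd = params.loading, params.resid_sd
        if loading is None or resid_sd is None:
            resid_var = max(params.target_sd ** 2 - np.var(effects),
                            (0.3 * params.target_sd) ** 2)
            loading = params.shared_frac * np.sqrt(resid_var)
            resid_sd = np.sqrt(resid_var - loading ** 2)
        latent = params.intercept + effects + loading * g + rng.normal(0.0, resid_sd, n)
        lo, hi = _OUTCOME_RANGES[oid]
        scores = np.round(latent)
        clipped = np.count_nonzero((scores < lo) | (scores > hi))
        if clipped > 0.10 * n:
            warnings.warn(
                f"{oid}: {clipped}/{n} generated scores clipped to [{lo}, {hi}]; "
                "generative parameters look miscalibrated", stacklevel=2)
        cohort[oid] = np.clip(scores, lo, hi).astype(int)
    if spec.enforce_pair_consistency:
        for test, (t_col, wm_col) in TEST_OUTCOME_COLUMNS.items():
            if t_col not in cohort or wm_col not in cohort:
                continue
            tspec = TEST_SPECS[test]
            pairs = [_reconcile_pair(t, w, tspec)
                     for t, w in zip(cohort[t_col], cohort[wm_col])]
            cohort[t_col] = [p[0] for p in pairs]
            cohort[wm_col] = [p[1] for p in pairs]
    for ratio, num, den in (("DSR_T", "BDS_T", "FDS_T"), ("DSR_WMS", "BDS_WM", "FDS_S")):
        if num in cohort and den in cohort:
            cohort[ratio] = np.where(cohort[den] > 0, cohort[num] / cohort[den], np.nan)
    return cohort.reindex(
        columns=["participant_id", "age", "education", "sex", *OUTCOME_COLUMNS])


def generate_cohort(spec: SyntheticCohortSpec = DEFAULT_SPEC,
                    seed: int = 0) -> pd.DataFrame:
    """Demographics + outcomes in one call, one RNG stream."""
    rng = np.random.default_rng(seed)
    demo = sample_demographics(spec, rng)
    return generate_outcomes(demo, spec, rng)


def trials_for_pair(pair: OutcomePair, spec: TestSpec) -> list[TrialRecord]:
    """Construct a trial list whose scoring reproduces ``pair`` exactly.

    A (T, WM) pair is reachable iff T = 0 = WM, or WM lies within the
    administered lengths and k <= T <= 2k where k = WM - min_length + 1
    (at least one success per length up to the span, at most both lists).
    Successes are front-loaded: the first T - k lengths succeed on both
    lists, the rest on list 1 only; two fails follow the span.
    """
    t, wm = pair.t_score, pair.wm_score
    if t == 0 and wm == 0:
        return [TrialRecord(spec.min_length, 1, False), TrialRecord(spec.min_length, 2, False)]
    if not spec.min_length <= wm <= spec.max_length:
        raise ValueError(f"{spec.test.value}: span {wm} outside administered lengths "
                         f"{spec.min_length}-{spec.max_length}")
    k = wm - spec.min_length + 1
    if not k <= t <= 2 * k:
        raise ValueError(
            f"{spec.test.value}: outcome pair (t={t}, wm={wm}) unreachable under the "
            f"stop rule (needs {k} <= t <= {2 * k})")
    trials = []
    doubles = t - k
    for i in range(k):
        length = spec.min_length + i
        trials.append(TrialRecord(length, 1, True))
        trials.append(TrialRecord(length, 2, i < doubles))
    if wm < spec.max_length:
        trials.append(TrialRecord(wm + 1, 1, False))
        trials.append(TrialRecord(wm + 1, 2, False))
    return trials


def generate_trials(cohort: pd.DataFrame,
                    specs: Mapping[TestId, TestSpec] = TEST_SPECS) -> pd.DataFrame:
    """Emit a long-format trial table reproducing the cohort's raw outcomes.

    Raises if any tabulated (T, WM) pair is unreachable under the stop rule,
    naming the participant and pair.
    """
    rows = []
    for r in cohort.itertuples(index=False):
        for test, (t_col, wm_col) in TEST_OUTCOME_COLUMNS.items():
            t, wm = getattr(r, t_col), getattr(r, wm_col)
            if pd.isna(t) or pd.isna(wm):
                continue
            try:
                trials = trials_for_pair(OutcomePair(int(t), int(wm)), specs[test])
            except ValueError as exc:
                raise ValueError(f"participant {r.participant_id}: {exc}") from exc
            for tr in trials:
                rows.append({
                    "participant_id": r.participant_id, "test": test.value,
                    "length": tr.length, "list_index": tr.list_index,
                    "recalled_exactly": tr.recalled_exactly,
                    "contains_intrusion": tr.contains_intrusion,
                })
    return pd.DataFrame(rows)
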