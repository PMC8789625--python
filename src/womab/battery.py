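"""Trial-level scoring for the WoMAB span tasks.

The battery comprises four auditory-verbal working-memory tests:

* ``DOT`` — Digit Ordering Test (recall digits in ascending order),
* ``ICT`` — Ice Cream Test (track per-flavour counts of customers' orders),
* ``FDS`` / ``BDS`` — forward / backward digit span.

Each test presents two lists per sequence length, lengths increasing by one;
administration stops after both lists of the same length fail.  Two outcomes
are scored per test: ``T`` (total number of correctly recalled sequences,
read as attentive monitoring) and ``WM``/``S`` (number of elements in the
longest correctly recalled sequence, read as working-memory capacity).
Sequences containing intrusions score 0.  The digit-span ratio (DSR) divides
each backward-span outcome by its forward counterpart, on raw scores.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "TestId",
    "TestSpec",
    "TrialRecord",
    "OutcomePair",
    "DsrPair",
    "TEST_SPECS",
    "OUTCOME_COLUMNS",
    "BASE_OUTCOMES",
    "ScoringError",
    "score_administration",
    "compute_dsr",
    "batch_score",
]


class ScoringError(ValueError):
    """Raised when trial records violate the administration protocol."""


class TestId(str, enum.Enum):
    DOT = "DOT"
    ICT = "ICT"
    FDS = "FDS"
    BDS = "BDS"


@dataclass(frozen=True)
class TestSpec:
    """Administration parameters of one span task.

    Start lengths are back-derived from the published outcome ranges so that
    ``t_max = 2 * (max_length - min_length + 1)``.
    """

    test: TestId
    min_length: int
    max_length: int
    lists_per_length: int = 2

    @property
    def n_lengths(self) -> int:
        return self.max_length - self.min_length + 1

    @property
    def t_max(self) -> int:
        return self.lists_per_length * self.n_lengths

    @property
    def wm_max(self) -> int:
        return self.max_length


TEST_SPECS: Mapping[TestId, TestSpec] = {
    TestId.DOT: TestSpec(TestId.DOT, 3, 8),
    TestId.ICT: TestSpec(TestId.ICT, 3, 10),
    TestId.FDS: TestSpec(TestId.FDS, 2, 9),
    TestId.BDS: TestSpec(TestId.BDS, 2, 8),
}

#: outcome column order used in every cohort table
OUTCOME_COLUMNS = (
    "DOT_T", "DOT_WM", "ICT_T", "ICT_WM",
    "FDS_T", "FDS_S", "BDS_T", "BDS_WM",
    "DSR_T", "DSR_WMS",
)
#: the eight non-derived outcomes (ratios excluded)
BASE_OUTCOMES = OUTCOME_COLUMNS[:8]

#: (T column, WM/S column) per test
TEST_OUTCOME_COLUMNS: Mapping[TestId, tuple[str, str]] = {
    TestId.DOT: ("DOT_T", "DOT_WM"),
    TestId.ICT: ("ICT_T", "ICT_WM"),
    TestId.FDS: ("FDS_T", "FDS_S"),
    TestId.BDS: ("BDS_T", "BDS_WM"),
}


@dataclass(frozen=True)
class TrialRecord:
    """Final response for one administered list.

    ``recalled_exactly`` records the (possibly self-corrected) final answer;
    an intrusion forces a score of 0 regardless of the recall flag.
    """

    length: int
    list_index: int
    recalled_exactly: bool
    contains_intrusion: bool = False

    @property
    def success(self) -> bool:
        return self.recalled_exactly and not self.contains_intrusion


@dataclass(frozen=True)
class OutcomePair:
    """Raw (T, WM/S) outcome of one test administration."""

    t_score: int
    wm_score: int

    def __post_init__(self) -> None:
        if (self.t_score == 0) != (self.wm_score == 0):
            raise ValueError(
                f"inconsistent outcome pair (t={self.t_score}, wm={self.wm_score}): "
                "a zero total implies a zero span and vice versa"
            )
        if self.t_score < 0 or self.wm_score < 0:
            raise ValueError("scores are non-negative counts")


@dataclass(frozen=True)
class DsrPair:
    """Digit-span ratios BDS/FDS; NaN marks an undefined ratio (FDS = 0)."""

    dsr_t: float
    dsr_wms: float

    @property
    def t_missing(self) -> bool:
        return math.isnan(self.dsr_t)

    @property
    def wms_missing(self) -> bool:
        return math.isnan(self.dsr_wms)


def _validate_trials(trials: Sequence[TrialRecord], spec: TestSpec) -> None:
    per_length: dict[int, int] = {}
    prev = None
    for tr in trials:
        if not (spec.min_length <= tr.length <= spec.max_length):
            raise ScoringError(
                f"{spec.test.value}: trial length {tr.length} outside the "
                f"administered range {spec.min_length}-{spec.max_length}"
            )
        if tr.list_index not in (1, 2):
            raise ScoringError(f"{spec.test.value}: list_index must be 1 or 2, got {tr.list_index}")
        per_length[tr.length] = per_length.get(tr.length, 0) + 1
        if per_length[tr.length] > spec.lists_per_length:
            raise ScoringError(
                f"{spec.test.value}: more than {spec.lists_per_length} lists "
                f"recorded at length {tr.length}"
            )
        key = (tr.length, tr.list_index)
        if prev is not None and key < prev:
            raise ScoringError(
                f"{spec.test.value}: trials not ordered by ascending length/list "
                f"({key} after {prev})"
            )
        prev = key


def score_administration(trials: Sequence[TrialRecord], spec: TestSpec) -> OutcomePair:
    """Score an ordered trial list into a raw (T, WM/S) pair.

    Two lists of the same length are administered and the task stops after
    both lists of a length fail; trials recorded past that point (e.g. by an
    examiner who kept going) are ignored.  T counts the successes up to the
    stop, WM/S is the longest length among them (0 if none).
    """
    trials = list(trials)
    _validate_trials(trials, spec)

    t_score = 0
    wm_score = 0
    i = 0
    while i < len(trials):
        length = trials[i].length
        block = [tr for tr in trials if tr.length == length]
        for tr in block:
            if tr.success:
                t_score += 1
                wm_score = max(wm_score, length)
        i += len(block)
        # discontinuation: both lists of this length failed
        if len(block) >= spec.lists_per_length and not any(tr.success for tr in block):
            break
    return OutcomePair(t_score=t_score, wm_score=wm_score)


def compute_dsr(fds: OutcomePair, bds: OutcomePair) -> DsrPair:
    """Backward/forward span ratios on raw scores; NaN when FDS is 0.

    Values above 1 are legitimate (observed empirically) and are never
    clamped.
    """
    dsr_t = bds.t_score / fds.t_score if fds.t_score else math.nan
    dsr_wms = bds.wm_score / fds.wm_score if fds.wm_score else math.nan
    return DsrPair(dsr_t=dsr_t, dsr_wms=dsr_wms)


_TRIAL_COLUMNS = ("participant_id", "test", "length", "list_index",
                  "recalled_exactly", "contains_intrusion")


def batch_score(
    cohort_trials: pd.DataFrame,
    demographics: pd.DataFrame | None = None,
    specs: Mapping[TestId, TestSpec] = TEST_SPECS,
) -> pd.DataFrame:
    """Score a long-format trial table into one outcome row per participant.

    Parameters
    ----------
    cohort_trials
        Columns ``participant_id, test, length, list_index, recalled_exactly,
        contains_intrusion``; one row per administered list.
    demographics
        Optional table with ``participant_id, age, education, sex`` merged
        into the output.

    Returns
    -------
    DataFrame with one row per participant: the eight base outcomes plus the
    two DSR ratios (NaN where a test is missing or a ratio is undefined).
    """
    missing = set(_TRIAL_COLUMNS) - set(cohort_trials.columns)
    if missing:
        raise ScoringError(f"trial table missing columns: {sorted(missing)}")
    dup = cohort_trials.duplicated(
        subset=["participant_id", "test", "length", "list_index"])
    if dup.any():
        bad = cohort_trials.loc[dup, ["participant_id", "test"]].drop_duplicates()
        raise ScoringError(
            "duplicate trial records for participant/test pairs: "
            + ", ".join(f"{p}/{t}" for p, t in bad.itertuples(index=False))
        )

    rows = []
    for pid, ptrials in cohort_trials.groupby("participant_id", sort=True):
        row: dict[str, object] = {"participant_id": pid}
        pairs: dict[TestId, OutcomePair] = {}
        for test_name, ttrials in ptrials.groupby("test"):
            test = TestId(str(test_name))
            spec = specs[test]
            ttrials = ttrials.sort_values(["length", "list_index"])
            trials = [
                TrialRecord(int(r.length), int(r.list_index),
                            bool(r.recalled_exactly), bool(r.contains_intrusion))
                for r in ttrials.itertuples(index=False)
            ]
            pairs[test] = score_administration(trials, spec)
        for test, (t_col, wm_col) in TEST_OUTCOME_COLUMNS.items():
            if test in pairs:
                row[t_col] = pairs[test].t_score
                row[wm_col] = pairs[test].wm_score
        if TestId.FDS in pairs and TestId.BDS in pairs:
            dsr = compute_dsr(pairs[TestId.FDS], pairs[TestId.BDS])
            row["DSR_T"] = dsr.dsr_t
            row["DSR_WMS"] = dsr.dsr_wms
        rows.append(row)

    out = pd.DataFrame(rows).reindex(
        columns=["participant_id", *OUTCOME_COLUMNS])
    if demographics is not None:
        out = demographics[["participant_id", "age", "education", "sex"]].merge(
            out, on="participant_id", how="right")
    return out
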