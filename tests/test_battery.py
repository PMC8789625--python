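"""Trial-level scoring: discontinuation rule, intrusions, ratios, batching."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from womab import (TEST_SPECS, OutcomePair, TestId, TrialRecord, batch_score,
                   compute_dsr, score_administration)
from womab.battery import ScoringError


def _trials(*specs):
    """(length, list_index, ok[, intrusion]) shorthand."""
    return [TrialRecord(l, i, ok, *extra) for l, i, ok, *extra in specs]


def oracle_score(trials, spec):
    """Literal reading of the stop rule: walk the ordered trial list, stop as
    soon as both lists of one length have failed, count successes seen."""
    t = wm = 0
    fails_at = {}
    for tr in trials:
        ok = tr.recalled_exactly and not tr.contains_intrusion
        if ok:
            t += 1
            wm = max(wm, tr.length)
        else:
            fails_at[tr.length] = fails_at.get(tr.length, 0) + 1
            if fails_at[tr.length] >= spec.lists_per_length:
                break
    return t, wm


class TestScoreAdministration:
    def test_all_failures_scores_zero(self):
        spec = TEST_SPECS[TestId.DOT]
        pair = score_administration(_trials((3, 1, False), (3, 2, False)), spec)
        assert (pair.t_score, pair.wm_score) == (0, 0)

    def test_perfect_ict_reaches_published_maxima(self):
        spec = TEST_SPECS[TestId.ICT]
        trials = [TrialRecord(l, i, True) for l in range(3, 11) for i in (1, 2)]
        pair = score_administration(trials, spec)
        assert (pair.t_score, pair.wm_score) == (16, 10)

    def test_trials_after_double_fail_are_ignored(self):
        # successes at 3,3,4; both length-5 lists fail; spurious later success
        spec = TEST_SPECS[TestId.DOT]
        trials = _trials((3, 1, True), (3, 2, True), (4, 1, True), (4, 2, False),
                         (5, 1, False), (5, 2, False), (6, 1, True))
        pair = score_administration(trials, spec)
        assert (pair.t_score, pair.wm_score) == (3, 4)

    def test_single_fail_does_not_stop(self):
        # fail on list 2 of length 3 and list 1 of length 4: task continues
        spec = TEST_SPECS[TestId.DOT]
        trials = _trials((3, 1, True), (3, 2, False), (4, 1, False), (4, 2, True),
                         (5, 1, True), (5, 2, False))
        pair = score_administration(trials, spec)
        assert (pair.t_score, pair.wm_score) == (3, 5)

    def test_intrusion_scores_zero(self):
        spec = TEST_SPECS[TestId.BDS]
        trials = _trials((2, 1, True, True), (2, 2, True, True))
        pair = score_administration(trials, spec)
        assert (pair.t_score, pair.wm_score) == (0, 0)

    @pytest.mark.parametrize("bad", [
        _trials((2, 1, True)),                                   # below DOT range
        _trials((9, 1, True)),                                   # above DOT range
        _trials((3, 1, True), (3, 2, True), (3, 1, False)),      # 3 lists at a length
        _trials((4, 1, True), (3, 1, True)),                     # unordered
    ])
    def test_protocol_violations_rejected(self, bad):
        with pytest.raises(ScoringError):
            score_administration(bad, TEST_SPECS[TestId.DOT])

    @given(data=st.data())
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_literal_stop_rule_oracle(self, data):
        test = data.draw(st.sampled_from(list(TestId)))
        spec = TEST_SPECS[test]
        n_lengths = data.draw(st.integers(1, spec.n_lengths))
        trials = []
        for length in range(spec.min_length, spec.min_length + n_lengths):
            for idx in (1, 2):
                trials.append(TrialRecord(
                    length, idx,
                    data.draw(st.booleans()),
                    data.draw(st.booleans())))
        # optionally truncate mid-administration
        trials = trials[:data.draw(st.integers(1, len(trials)))]
        pair = score_administration(trials, spec)
        assert (pair.t_score, pair.wm_score) == oracle_score(trials, spec)
        # structural invariants of any administration
        counted_lengths = {tr.length for tr in trials}
        assert pair.wm_score == 0 or pair.wm_score in counted_lengths
        assert pair.t_score >= (1 if pair.wm_score else 0)


class TestDsr:
    def test_identity_ratio(self):
        pair = compute_dsr(OutcomePair(10, 6), OutcomePair(10, 6))
        assert (pair.dsr_t, pair.dsr_wms) == (1.0, 1.0)

    def test_direct_division(self):
        pair = compute_dsr(OutcomePair(10, 6), OutcomePair(7, 3))
        assert pair.dsr_t == pytest.approx(0.70)
        assert pair.dsr_wms == pytest.approx(0.50)

    def test_zero_denominator_is_missing_not_error(self):
        pair = compute_dsr(OutcomePair(0, 0), OutcomePair(2, 2))
        assert pair.t_missing and pair.wms_missing
        assert math.isnan(pair.dsr_t)

    def test_ratios_above_one_not_clamped(self):
        pair = compute_dsr(OutcomePair(10, 6), OutcomePair(12, 7))
        assert pair.dsr_t > 1


class TestBatchScore:
    @staticmethod
    def _trial_rows(pid, test, rows):
        return [{"participant_id": pid, "test": test, "length": l,
                 "list_index": i, "recalled_exactly": ok, "contains_intrusion": False}
                for l, i, ok in rows]

    def test_one_participant_four_tests(self):
        rows = []
        for test in ("DOT", "ICT", "FDS", "BDS"):
            spec = TEST_SPECS[TestId(test)]
            rows += self._trial_rows("p1", test, [(spec.min_length, 1, True),
                                                  (spec.min_length, 2, False),
                                                  (spec.min_length + 1, 1, False),
                                                  (spec.min_length + 1, 2, False)])
        out = batch_score(pd.DataFrame(rows))
        assert len(out) == 1
        assert out.loc[0, "DOT_T"] == 1 and out.loc[0, "DOT_WM"] == 3
        assert out.loc[0, "DSR_T"] == 1.0  # both spans scored 1 success

    def test_missing_bds_propagates_to_dsr(self):
        rows = []
        for test in ("DOT", "ICT", "FDS"):
            spec = TEST_SPECS[TestId(test)]
            rows += self._trial_rows("p1", test, [(spec.min_length, 1, True),
                                                  (spec.min_length, 2, False)])
        out = batch_score(pd.DataFrame(rows))
        assert pd.isna(out.loc[0, "BDS_T"])
        assert pd.isna(out.loc[0, "DSR_T"]) and pd.isna(out.loc[0, "DSR_WMS"])

    def test_duplicate_records_rejected(self):
        rows = self._trial_rows("p1", "DOT", [(3, 1, True), (3, 1, True)])
        with pytest.raises(ScoringError, match="duplicate"):
            batch_score(pd.DataFrame(rows))
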