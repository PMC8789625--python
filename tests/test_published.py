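"""Published equations, norm-table thresholds and individual ES scoring."""

import math

import numpy as np
import pytest

from womab import (Demographics, load_norms, published_adjust, published_es,
                   regenerate_grids, score_patient)
from womab.published import adjustment_factor, round_half_away

from printed_grids import AGES, PRINTED_GRIDS

NORMS = load_norms()


class TestAdjustment:
    @pytest.mark.parametrize("outcome,age,edu,sex,printed", [
        ("DOT_T", 35, 5, "m", 1.08),
        ("DOT_T", 85, 5, "m", 3.42),
        ("ICT_T", 85, 18, "f", 1.68),
        ("ICT_WM", 35, 5, "m", 0.48),
        ("FDS_S", 85, 18, "m", 1.06),
        ("FDS_T", 35, 16, "f", -1.15),
        ("BDS_WM", 35, 5, "m", -0.21),
        ("BDS_T", 35, 5, "f", 0.78),
        ("DSR_T", 35, 10, "m", -0.074),
        ("DSR_WMS", 35, 10, "m", -0.015),
    ])
    def test_printed_spot_cells(self, outcome, age, edu, sex, printed):
        adj = adjustment_factor(outcome, Demographics(age, edu, sex))
        assert adj == pytest.approx(printed, abs=0.01)

    def test_adjusted_equals_raw_plus_factor(self):
        demo = Demographics(35, 5, "m")
        assert published_adjust("DOT_T", 7, demo) == pytest.approx(8.08, abs=0.005)

    @pytest.mark.parametrize("outcome", ["DOT_T", "ICT_T", "FDS_T"])
    def test_centering_identity(self, outcome):
        # at the (non-integer) point where every transform hits its sample
        # mean, the adjustment vanishes and adjusted == raw
        demo = Demographics(100 - math.exp(3.862482), 1 / 0.101788, "m")
        assert published_adjust(outcome, 9.0, demo) == pytest.approx(9.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [
        dict(age=0, education=10, sex="m"),
        dict(age=100, education=10, sex="f"),
        dict(age=50, education=0, sex="m"),
        dict(age=50, education=10, sex="x"),
    ])
    def test_demographics_outside_transform_domain_rejected(self, bad):
        with pytest.raises(ValueError):
            Demographics(**bad)

    def test_unknown_outcome_rejected(self):
        with pytest.raises(KeyError):
            published_adjust("MMSE", 28, Demographics(50, 10, "m"))


class TestGridFidelity:
    """The regenerated grids must reproduce every printed cell within 0.01."""

    def test_full_grid_diff(self):
        grids = regenerate_grids()
        mismatches = []
        n_checked = 0
        for key, rows in PRINTED_GRIDS.items():
            regenerated = grids[key]
            for row_key, printed_row in rows.items():
                for age, printed in zip(AGES, printed_row):
                    if printed is None:
                        continue
                    n_checked += 1
                    got = float(regenerated.loc[row_key, age])
                    if abs(got - printed) > 0.01 + 1e-9:
                        mismatches.append((key, row_key, age, printed, got))
        assert n_checked > 600
        assert not mismatches, f"cells off by more than 0.01: {mismatches}"

    def test_grid_monotone_in_age_and_education(self):
        # adjustments grow with age and shrink with education in every grid
        for key, grid in regenerate_grids().items():
            arr = grid.to_numpy(dtype=float)
            assert (np.diff(arr, axis=1) >= -1e-12).all(), key
            if grid.shape[0] > 1:
                assert (np.diff(arr, axis=0) <= 1e-12).all(), key

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(0.125, 2) == 0.13
        assert round_half_away(-0.125, 2) == -0.13
        assert round_half_away(1.005, 2) == 1.01


class TestEquivalentScores:
    @pytest.mark.parametrize("adjusted,expected", [
        (3.27, 0),   # boundary belongs to ES 0 as printed
        (3.28, 1),
        (5.00, 2),
        (7.35, 3),
        (7.36, 4),
    ])
    def test_dot_t_interval_lookup(self, adjusted, expected):
        assert published_es("DOT_T", adjusted) == expected

    def test_strict_cutoff_convention_flag(self):
        assert published_es("DOT_T", 3.27, es_zero_inclusive=False) == 1
        assert published_es("DOT_T", 3.26, es_zero_inclusive=False) == 0

    def test_aes_rows_carry_limits_only(self):
        with pytest.raises(ValueError, match="tolerance limits only"):
            published_es("AES_T", 2.0)

    @pytest.mark.parametrize("outcome", list(NORMS.equations))
    def test_step_function_non_decreasing_and_surjective(self, outcome):
        row = NORMS.norm_table[outcome]
        lo, hi = row.es_upper_bounds[0] - 1, row.es_upper_bounds[3] + 1
        levels = [published_es(outcome, a) for a in np.linspace(lo, hi, 400)]
        assert all(b >= a for a, b in zip(levels, levels[1:]))
        assert set(levels) == {0, 1, 2, 3, 4}

    def test_norm_table_internally_consistent(self):
        for row in NORMS.norm_table.values():
            assert row.oTL <= row.iTL
            if row.es_upper_bounds is not None:
                assert list(row.es_upper_bounds) == sorted(row.es_upper_bounds)
                assert row.es_upper_bounds[0] == row.oTL


class TestScorePatient:
    demo = Demographics(48, 12, "f")

    def _raw_for_adjusted(self, outcome, target):
        return target - adjustment_factor(outcome, self.demo)

    def test_constant_top_profile_gives_aes_four(self):
        raws = {}
        for outcome in NORMS.equations:
            top = NORMS.norm_table[outcome].es_upper_bounds[3] + 0.5
            raws[outcome] = self._raw_for_adjusted(outcome, top)
        profile = score_patient(raws, self.demo)
        assert all(s.es == 4 for s in profile.outcomes.values())
        assert profile.aes_t == 4.0 and profile.aes_wms == 4.0

    def test_aes_is_mean_of_five_constituents(self):
        # ES levels (0, 0, 1, 1, 1) over the T scale -> AES-T = 0.6,
        # the smallest composite observed in the normative sample
        targets = {"DOT_T": 0, "ICT_T": 0, "FDS_T": 1, "BDS_T": 1, "DSR_T": 1}
        raws = {}
        for outcome, level in targets.items():
            b = NORMS.norm_table[outcome].es_upper_bounds
            adjusted = b[0] - 0.1 if level == 0 else (b[0] + b[1]) / 2
            raws[outcome] = self._raw_for_adjusted(outcome, adjusted)
        profile = score_patient(raws, self.demo)
        assert [profile.outcomes[o].es for o in targets] == list(targets.values())
        assert profile.aes_t == pytest.approx(0.6)
        assert profile.aes_wms is None  # no WM/S outcomes supplied

    def test_dsr_derived_from_span_raws(self):
        profile = score_patient({"FDS_T": 10, "BDS_T": 7, "FDS_S": 6, "BDS_WM": 3},
                                self.demo)
        assert profile.outcomes["DSR_T"].raw == pytest.approx(0.7)
        assert profile.outcomes["DSR_WMS"].raw == pytest.approx(0.5)

    def test_invariant_to_outcome_ordering(self):
        raws = {"DOT_T": 7, "ICT_T": 8, "FDS_T": 10, "BDS_T": 6, "DSR_T": 0.6}
        fwd = score_patient(raws, self.demo)
        rev = score_patient(dict(reversed(list(raws.items()))), self.demo)
        assert fwd.outcomes == rev.outcomes and fwd.aes_t == rev.aes_t

    def test_out_of_range_raw_collected_not_raised(self):
        profile = score_patient({"DOT_T": 13, "ICT_T": 8}, self.demo)
        assert "DOT_T" in profile.errors and "theoretical range" in profile.errors["DOT_T"]
        assert "ICT_T" in profile.outcomes
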