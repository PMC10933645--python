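"""Composite scoring, compliance, descriptives and lag-pair construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emanet import (CompositeSpec, TrueModel, build_lag_pairs, compliance,
                    descriptives, score_composites, simulate_panel)

from conftest import make_panel


def _composite_value(panel, name, person="a", day=1, slot="AM"):
    df = panel.data
    row = df[(df.person == person) & (df.day == day) & (df.slot == slot)
             & (df.variable == name)]
    return row["value"].iloc[0]


class TestComposites:
    @pytest.mark.parametrize("values,reverse,expected", [
        ((80, 60, 20, 60), ("i3",), 70.0),   # reverse: 100-20=80 -> mean 70
        ((10, 30), (), 20.0),                # two-item rumination mean
        ((50, 50, 50, 50), (), 50.0),
    ])
    def test_mean_of_reverse_corrected_items(self, values, reverse, expected):
        items = tuple(f"i{k + 1}" for k in range(len(values)))
        panel = make_panel([("a", 1, "AM", it, float(v))
                            for it, v in zip(items, values)])
        spec = CompositeSpec("comp", items=items, reverse=reverse)
        scored = score_composites(panel, [spec])
        assert _composite_value(scored, "comp") == pytest.approx(expected)

    def test_below_min_answered_scores_missing(self):
        panel = make_panel([("a", 1, "AM", "i1", 40.0),
                            ("a", 1, "AM", "i2", np.nan),
                            ("a", 1, "AM", "i3", np.nan),
                            ("a", 1, "AM", "i4", np.nan)])
        spec = CompositeSpec("comp", items=("i1", "i2", "i3", "i4"),
                             min_answered=3)
        scored = score_composites(panel, [spec])
        assert np.isnan(_composite_value(scored, "comp"))

    def test_default_requires_all_items(self):
        panel = make_panel([("a", 1, "AM", "i1", 40.0),
                            ("a", 1, "AM", "i2", np.nan)])
        scored = score_composites(panel, [CompositeSpec("c", ("i1", "i2"))])
        assert np.isnan(_composite_value(scored, "c"))

    def test_unknown_item_rejected(self):
        panel = make_panel([("a", 1, "AM", "i1", 40.0)])
        with pytest.raises(ValueError, match="unknown items"):
            score_composites(panel, [CompositeSpec("c", ("i1", "ghost"))])

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_identical_items_and_double_reverse_identity(self, v, w):
        panel = make_panel([("a", 1, "AM", "i1", v), ("a", 1, "AM", "i2", v),
                            ("a", 1, "AM", "j", w)])
        specs = [CompositeSpec("same", ("i1", "i2")),
                 CompositeSpec("rev2", ("j",), reverse=())]
        scored = score_composites(panel, specs)
        assert _composite_value(scored, "same") == pytest.approx(v)
        # reversing twice is the identity
        once = 100.0 - w
        assert 100.0 - once == pytest.approx(w)


class TestCompliance:
    def _full_panel(self, n_answered, persons=("a",)):
        rows = []
        for p in persons:
            count = 0
            for d in range(1, 10):
                for s in ("AM", "PM"):
                    if count < n_answered:
                        rows.append((p, d, s, "x", 50.0))
                        count += 1
                    else:
                        rows.append((p, d, s, "x", np.nan))
        return make_panel(rows)

    def test_all_occasions_answered(self):
        rep = compliance(self._full_panel(18))
        assert rep.rate == pytest.approx(1.0)

    def test_half_answered_many_persons(self):
        persons = tuple(f"p{i}" for i in range(62))
        rep = compliance(self._full_panel(9, persons))
        assert rep.rate == pytest.approx(0.5)

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            compliance(self._full_panel(18), expected_occasions=0)

    def test_bernoulli_completion_recovers_rate(self):
        tm = TrueModel.study_preset()  # compliance 0.85 / 0.793
        panel = simulate_panel(tm, seed=5)
        rep = compliance(panel, variables=["anger"], expected_occasions=18)
        assert abs(rep.rate - 0.85) < 0.03
        rep_task = compliance(panel, variables=["response_inhibition"],
                              expected_occasions=18)
        assert abs(rep_task.rate - 0.793) < 0.03


class TestDescriptives:
    def test_constant_variable(self):
        rows = [(p, d, s, "x", 50.0) for p in "abcd" for d in (1, 2)
                for s in ("AM", "PM")]
        table = descriptives(make_panel(rows), ["x"])
        row = table.iloc[0]
        assert row["mean"] == pytest.approx(50.0)
        assert row["sd"] == pytest.approx(0.0)
        assert row["am_pm_p"] > 0.05

    def test_forced_am_pm_separation(self):
        rows = []
        for i in range(20):
            for d in (1, 2):
                rows.append((f"p{i}", d, "AM", "x", 10.0 + 0.01 * i))
                rows.append((f"p{i}", d, "PM", "x", 20.0 + 0.01 * i))
        table = descriptives(make_panel(rows), ["x"])
        row = table.iloc[0]
        assert row["am_mean"] == pytest.approx(10.0, abs=0.2)
        assert row["pm_mean"] == pytest.approx(20.0, abs=0.2)
        assert row["am_pm_p"] < 0.05

    def test_generator_without_slot_effect_is_calibrated_null(self):
        # no AM/PM mean difference in the generative model: the comparison
        # should reject at ~ the nominal 5% rate across replications
        tm = TrueModel.study_preset()
        rejections = []
        for seed in range(15):
            table = descriptives(simulate_panel(tm, seed), tm.nodes)
            rejections.extend(table["am_pm_p"] < 0.05)
        rate = np.mean(rejections)
        assert rate < 0.15

    def test_absent_variable_rejected(self, two_person_panel):
        with pytest.raises(ValueError, match="ghost"):
            descriptives(two_person_panel, ["ghost"])


class TestLagPairs:
    def test_complete_person_yields_nine_rows(self):
        rows = [("a", d, s, "x", float(40 + d + (5 if s == "PM" else 0)))
                for d in range(1, 10) for s in ("AM", "PM")]
        lags = build_lag_pairs(make_panel(rows), ["x"])
        assert len(lags.pairs) == 9

    def test_am_only_person_yields_zero_rows(self):
        rows = [("a", d, "AM", "x", 50.0) for d in range(1, 10)]
        lags = build_lag_pairs(make_panel(rows), ["x"])
        assert len(lags.pairs) == 0

    def test_missing_am_day_still_counts_toward_person_mean(self):
        # day 1: AM missing, PM=60 -> no lag row, but PM feeds the mean;
        # day 2: AM=40, PM=50 -> one lag row
        rows = [("a", 1, "PM", "x", 60.0),
                ("a", 2, "AM", "x", 40.0), ("a", 2, "PM", "x", 50.0)]
        lags = build_lag_pairs(make_panel(rows), ["x"])
        assert len(lags.pairs) == 1
        m_hat = (60.0 + 40.0 + 50.0) / 3
        row = lags.pairs.iloc[0]
        assert row["m_x"] == pytest.approx(m_hat)
        assert row["c_x"] == pytest.approx(40.0 - m_hat)
        assert row["y_x"] == pytest.approx(50.0)

    def test_rows_never_cross_days_and_centering_sums_to_zero(self, rng):
        # distinctive values encode (day, slot) so pairing can be audited
        # AM of day d is d, PM of day d is 10-d: same person mean (5), and
        # the AM/PM pairing of each row can be audited exactly
        rows = []
        for p in ("a", "b", "c"):
            for d in range(1, 10):
                rows.append((p, d, "AM", "x", float(d)))
                rows.append((p, d, "PM", "x", float(10 - d)))
        lags = build_lag_pairs(make_panel(rows), ["x"])
        raw_am = lags.pairs["c_x"] + lags.pairs["m_x"]
        assert np.allclose(lags.pairs["y_x"], 10.0 - raw_am)
        # centered predictors average zero within person (complete data)
        assert np.allclose(lags.pairs.groupby("person")["c_x"].mean(), 0.0,
                           atol=1e-12)

    def test_person_with_zero_observations_rejected(self):
        rows = [("a", 1, "AM", "x", 50.0), ("a", 1, "PM", "x", 55.0),
                ("b", 1, "AM", "x", np.nan)]
        with pytest.raises(ValueError, match="zero observations"):
            build_lag_pairs(make_panel(rows), ["x"])
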