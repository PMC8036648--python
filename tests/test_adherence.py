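"""Cohort alignment, phase summaries and weekly adherence curves."""

import numpy as np
import pandas as pd
import pytest

import perimon as pm
from perimon.adherence import CohortTimeline, align_weeks, phase_summary, weekly_curves


def _timeline(rows, meta_rows):
    return CohortTimeline(pd.DataFrame(rows), pd.DataFrame(meta_rows))


def _days(pid, start, n, wear=16.0, answered=1, bp=0):
    d0 = pd.Timestamp(start)
    return [
        {
            "participant_id": pid,
            "date": (d0 + pd.Timedelta(days=i)).date().isoformat(),
            "wear_h": wear,
            "answered": answered,
            "bp_count": bp,
        }
        for i in range(n)
    ]


class TestAlignWeeks:
    def test_postpartum_week_starts_at_delivery(self):
        tl = _timeline(
            _days("A", "2020-01-01", 12),
            [{"participant_id": "A", "enrollment_gw": 38.0, "delivery_date": "2020-01-04"}],
        )
        df = align_weeks(tl)
        day3 = df[df.date == pd.Timestamp("2020-01-07")].iloc[0]  # 3 days after delivery
        assert day3.phase == "postpartum" and day3.week == 1
        day7 = df[df.date == pd.Timestamp("2020-01-11")].iloc[0]
        assert day7.week == 2

    def test_censored_participant_all_pregnancy(self):
        tl = _timeline(
            _days("A", "2020-01-01", 14),
            [{"participant_id": "A", "enrollment_gw": 20.0, "delivery_date": ""}],
        )
        df = align_weeks(tl)
        assert (df.phase == "pregnancy").all()

    def test_gestational_week_arithmetic(self):
        tl = _timeline(
            _days("A", "2020-01-01", 20),
            [{"participant_id": "A", "enrollment_gw": 13.0, "delivery_date": ""}],
        )
        df = align_weeks(tl)
        day14 = df.iloc[14]
        assert day14.week == 15


class TestPhaseSummary:
    def test_hand_arithmetic_across_participants(self):
        rows = _days("A", "2020-01-01", 5, wear=16.0) + _days("B", "2020-01-01", 5, wear=18.0)
        tl = _timeline(
            rows,
            [
                {"participant_id": "A", "enrollment_gw": 13.0, "delivery_date": ""},
                {"participant_id": "B", "enrollment_gw": 14.0, "delivery_date": ""},
            ],
        )
        s = phase_summary(tl)["pregnancy"]
        assert s.mean_wear_h == pytest.approx(17.0)
        assert s.sd_wear_h == pytest.approx(np.sqrt(2.0))

    def test_full_answering_is_100pct(self):
        tl = _timeline(
            _days("A", "2020-01-01", 10, answered=1),
            [{"participant_id": "A", "enrollment_gw": 13.0, "delivery_date": ""}],
        )
        assert phase_summary(tl)["pregnancy"].answer_rate_pct == 100.0

    def test_empty_phase_flagged_absent(self):
        tl = _timeline(
            _days("A", "2020-01-01", 5),
            [{"participant_id": "A", "enrollment_gw": 13.0, "delivery_date": ""}],
        )
        s = phase_summary(tl)["postpartum"]
        assert s.mean_wear_h is None and s.n_days == 0

    def test_phase_answered_counts_sum_to_total(self):
        cfg = pm.CohortSimConfig(n_participants=30, seed=4)
        rec, meta, _ = pm.simulate_cohort(cfg)
        s = phase_summary(CohortTimeline(rec, meta))
        assert s["pregnancy"].answered_days + s["postpartum"].answered_days == int(
            rec["answered"].sum()
        )

    def test_wear_out_of_range_rejected(self):
        rows = _days("A", "2020-01-01", 2, wear=25.0)
        with pytest.raises(ValueError, match="wear_h"):
            _timeline(rows, [{"participant_id": "A", "enrollment_gw": 13.0, "delivery_date": ""}])


class TestWeeklyCurves:
    def test_flat_cohort_flat_curve(self):
        rows = _days("A", "2020-01-06", 14, wear=15.0) + _days("B", "2020-01-06", 14, wear=15.0)
        tl = _timeline(
            rows,
            [
                {"participant_id": "A", "enrollment_gw": 13.0, "delivery_date": ""},
                {"participant_id": "B", "enrollment_gw": 13.0, "delivery_date": ""},
            ],
        )
        curves = weekly_curves(tl)
        assert all(w.mean_wear_h == 15.0 and w.sd_wear_h == 0.0 for w in curves)

    def test_exclusion_lowers_bp_rate(self):
        rows = _days("A", "2020-01-06", 14, bp=0) + _days("B", "2020-01-06", 14, bp=3)
        tl = _timeline(
            rows,
            [
                {"participant_id": "A", "enrollment_gw": 13.0, "delivery_date": ""},
                {"participant_id": "B", "enrollment_gw": 13.0, "delivery_date": ""},
            ],
        )
        full = {(w.phase, w.week): w.bp_per_week for w in weekly_curves(tl)}
        excl = {(w.phase, w.week): w.bp_per_week for w in weekly_curves(tl, exclude_ids=["B"])}
        assert all(excl[k] <= full[k] for k in excl)

    def test_exclusion_leaves_others_untouched(self):
        rows = _days("A", "2020-01-06", 14, wear=12.0) + _days("B", "2020-01-06", 14, wear=20.0)
        tl = _timeline(
            rows,
            [
                {"participant_id": "A", "enrollment_gw": 13.0, "delivery_date": ""},
                {"participant_id": "B", "enrollment_gw": 13.0, "delivery_date": ""},
            ],
        )
        excl = weekly_curves(tl, exclude_ids=["B"])
        assert all(w.mean_wear_h == 12.0 for w in excl)

    def test_n_contributing_nonincreasing_after_followup_end(self):
        rows = _days("A", "2020-01-06", 28) + _days("B", "2020-01-06", 14)
        tl = _timeline(
            rows,
            [
                {"participant_id": "A", "enrollment_gw": 13.0, "delivery_date": ""},
                {"participant_id": "B", "enrollment_gw": 13.0, "delivery_date": ""},
            ],
        )
        curves = [w for w in weekly_curves(tl) if w.phase == "pregnancy"]
        ns = [w.n_contributing for w in sorted(curves, key=lambda w: w.week)]
        assert ns == sorted(ns, reverse=True)

    def test_simulated_wear_decline_slope_recovered(self):
        cfg = pm.CohortSimConfig(
            n_participants=60,
            wear_pregnancy_slope=-0.15,
            wear_participant_sd=1.0,
            wear_day_sd=1.0,
            enrollment_gw_sd=0.0,
            postpartum_weeks=0.0,
            seed=8,
        )
        rec, meta, _ = pm.simulate_cohort(cfg)
        curves = [
            w for w in weekly_curves(CohortTimeline(rec, meta)) if w.phase == "pregnancy"
        ]
        weeks = np.array([w.week for w in curves], dtype=float)
        means = np.array([w.mean_wear_h for w in curves])
        good = np.array([w.n_contributing for w in curves]) >= 30
        slope = np.polyfit(weeks[good], means[good], 1)[0]
        assert slope == pytest.approx(-0.15, abs=0.05)
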