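"""Cohort feasibility analytics: wear time, questionnaire answers, BP rates.

A cohort timeline holds one daily record per participant (wear hours,
answered-questionnaire flag, blood-pressure measurement count) plus
enrollment gestational age and delivery date.  Days are aligned on
gestational week during pregnancy and on weeks since delivery
postpartum (the delivery day opens postpartum week 1), so trajectories
from participants enrolled at different gestational ages aggregate on
a common axis.

Phase summaries weight participants equally: each participant's daily
mean is computed first and the cohort mean ± SD is taken across
participants, matching the "average across participants" framing of
feasibility reporting.  A day-weighted alternative is available by
flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortTimeline", "WeeklyAdherence", "align_weeks", "phase_summary", "weekly_curves"]


@dataclass
class CohortTimeline:
    """Daily adherence records plus per-participant metadata.

    ``records``: columns participant_id, date, wear_h, answered, bp_count.
    ``meta``: columns participant_id, enrollment_gw, delivery_date
    (empty/NaN delivery_date = censored before delivery).
    """

    records: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"participant_id", "date", "wear_h", "answered", "bp_count"}
        if not need.issubset(self.records.columns):
            raise ValueError(f"records missing columns {sorted(need - set(self.records.columns))}")
        need_m = {"participant_id", "enrollment_gw", "delivery_date"}
        if not need_m.issubset(self.meta.columns):
            raise ValueError(f"meta missing columns {sorted(need_m - set(self.meta.columns))}")
        bad = (self.records["wear_h"] < 0) | (self.records["wear_h"] > 24)
        if bad.any():
            raise ValueError("wear_h outside [0, 24]")


@dataclass
class WeeklyAdherence:
    """Cohort aggregate for one gestational or postpartum week."""

    phase: str  # "pregnancy" | "postpartum"
    week: int
    mean_wear_h: float
    sd_wear_h: float
    answer_rate_pct: float
    bp_per_week: float
    n_contributing: int


def align_weeks(timeline: CohortTimeline) -> pd.DataFrame:
    """Attach phase and week index to every participant-day.

    Pregnancy days carry the gestational week (enrollment_gw plus
    elapsed weeks, floored); days on or after the delivery date carry
    the postpartum week, starting at 1 on the delivery day.  Censored
    participants (no delivery date) stay in the pregnancy phase
    throughout.
    """
    rec = timeline.records.copy()
    rec["date"] = pd.to_datetime(rec["date"])
    meta = timeline.meta.copy()
    meta["delivery_date"] = pd.to_datetime(meta["delivery_date"], errors="coerce")
    df = rec.merge(meta, on="participant_id", how="left", validate="many_to_one")
    first_day = df.groupby("participant_id")["date"].transform("min")
    days_in = (df["date"] - first_day).dt.days
    post = df["delivery_date"].notna() & (df["date"] >= df["delivery_date"])
    gest_week = np.floor(df["enrollment_gw"] + days_in / 7.0).astype(int)
    pp_week = ((df["date"] - df["delivery_date"]).dt.days // 7 + 1).where(post)
    df["phase"] = np.where(post, "postpartum", "pregnancy")
    df["week"] = pd.array(np.where(post, pp_week, gest_week), dtype="Int64")
    return df


@dataclass
class PhaseSummary:
    """Per-phase adherence descriptives (participant-equal weighting)."""

    phase: str
    n_participants: int
    n_days: int
    mean_wear_h: float | None
    sd_wear_h: float | None
    answer_rate_pct: float | None
    bp_per_week: float | None
    answered_days: int


def phase_summary(
    timeline: CohortTimeline, day_weighted: bool = False
) -> dict[str, PhaseSummary]:
    """Wear / answer-rate / BP descriptives for pregnancy and postpartum.

    With the default participant-equal weighting the wear mean ± SD is
    taken across participant-level daily means; ``day_weighted=True``
    pools all days instead.  The answer rate is answered days over
    observed days and the BP rate is total measurements over observed
    weeks, both cohort-level.
    """
    df = align_weeks(timeline)
    out: dict[str, PhaseSummary] = {}
    for phase in ("pregnancy", "postpartum"):
        sub = df[df["phase"] == phase]
        if sub.empty:
            out[phase] = PhaseSummary(phase, 0, 0, None, None, None, None, 0)
            continue
        if day_weighted:
            mean_w = float(sub["wear_h"].mean())
            sd_w = float(sub["wear_h"].std(ddof=1)) if len(sub) > 1 else 0.0
        else:
            per = sub.groupby("participant_id")["wear_h"].mean()
            mean_w = float(per.mean())
            sd_w = float(per.std(ddof=1)) if len(per) > 1 else 0.0
        answered = int(sub["answered"].sum())
        out[phase] = PhaseSummary(
            phase=phase,
            n_participants=sub["participant_id"].nunique(),
            n_days=len(sub),
            mean_wear_h=mean_w,
            sd_wear_h=sd_w,
            answer_rate_pct=100.0 * answered / len(sub),
            bp_per_week=float(sub["bp_count"].sum()) / (len(sub) / 7.0),
            answered_days=answered,
        )
    return out


def weekly_curves(
    timeline: CohortTimeline, exclude_ids: list[str] | None = None
) -> list[WeeklyAdherence]:
    """Per-week cohort curves, optionally excluding outlier participants.

    Exclusion removes the listed participants before averaging (as is
    done when a single participant's self-measurement pattern dominates
    a weekly mean); other participants' contributions are unchanged.
    """
    df = align_weeks(timeline)
    if exclude_ids:
        df = df[~df["participant_id"].isin(exclude_ids)]
    out: list[WeeklyAdherence] = []
    for (phase, week), sub in df.groupby(["phase", "week"], observed=True):
        if pd.isna(week):
            continue
        per = sub.groupby("participant_id")["wear_h"].mean()
        out.append(
            WeeklyAdherence(
                phase=str(phase),
                week=int(week),
                mean_wear_h=float(per.mean()),
                sd_wear_h=float(per.std(ddof=1)) if len(per) > 1 else 0.0,
                answer_rate_pct=100.0 * float(sub["answered"].mean()),
                bp_per_week=float(sub["bp_count"].sum()) / (len(sub) / 7.0),
                n_contributing=int(sub["participant_id"].nunique()),
            )
        )
    out.sort(key=lambda w: (w.phase != "pregnancy", w.week))
    return out
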