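"""Actigraphy analytics: non-wear, sleep summaries, and daily activity.

Sleep/wake is classified per 1-min epoch by a center-weighted moving
average of activity counts compared against a fixed threshold — a
transparent stand-in in the style of classical count-based actigraphy
scorers, with the weights rescaled to the activity-count range of
wrist devices reporting tens of counts per active minute.  Sleep onset
is the first sustained sleep run inside the externally supplied bed
window; total sleep time (TST), wake after sleep onset (WASO) and
sleep efficiency (SE = 100·TST / time in bed) follow from the scored
epochs.

Non-wear is a sustained run of zero counts (≥ 60 min): genuine sleep
produces occasional small position-shift movements, so hour-long exact
zeros indicate an off-wrist device.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SleepSummary",
    "DailyActivity",
    "detect_nonwear",
    "score_epochs",
    "score_sleep",
    "daily_activity",
]

NONWEAR_MIN_RUN = 60  # epochs (minutes) of exact zeros
# moving-average sleep classifier: weights for epochs t-4 .. t+2, threshold 1
SLEEP_WEIGHTS = np.array([0.01, 0.01, 0.02, 0.04, 0.20, 0.04, 0.02])
SLEEP_WEIGHTS_CENTER = 4  # index of a_t in the weight vector
SLEEP_THRESHOLD = 1.0
ONSET_RUN_EPOCHS = 10
SEDENTARY_COUNTS = 10.0  # counts/min below which a worn awake epoch is sedentary


@dataclass
class SleepSummary:
    """One night's sleep metrics over the supplied bed window."""

    bed_start_min: float
    bed_end_min: float
    tst_min: float
    se_pct: float
    waso_min: float
    sleep_onset_latency_min: float
    valid: bool
    sleep_mask: np.ndarray | None = None  # per bed-window epoch, True = asleep


@dataclass
class DailyActivity:
    """One calendar day of wear / activity accounting (hours)."""

    steps: int
    wear_h: float
    sedentary_h: float
    active_h: float


def detect_nonwear(counts: np.ndarray, min_run: int = NONWEAR_MIN_RUN) -> np.ndarray:
    """Boolean wear mask over 1-min epochs.

    Runs of at least ``min_run`` consecutive exact-zero counts are
    marked non-wear (mask False).
    """
    counts = np.asarray(counts, dtype=float)
    worn = np.ones(len(counts), dtype=bool)
    zero = counts == 0
    n = len(counts)
    i = 0
    while i < n:
        if zero[i]:
            j = i
            while j < n and zero[j]:
                j += 1
            if j - i >= min_run:
                worn[i:j] = False
            i = j
        else:
            i += 1
    return worn


def wear_hours_per_day(counts: np.ndarray, min_run: int = NONWEAR_MIN_RUN) -> np.ndarray:
    """Daily wear hours (24 − non-wear) from a multi-day epoch series."""
    worn = detect_nonwear(counts, min_run)
    n_days = len(counts) // 1440
    return np.array([worn[d * 1440 : (d + 1) * 1440].sum() / 60.0 for d in range(n_days)])


def score_epochs(counts: np.ndarray) -> np.ndarray:
    """Per-epoch sleep (True) / wake (False) from activity counts.

    The weighted moving average D_t = Σ w_k · a_{t+k} over the window
    t−4 … t+2 is compared against a fixed threshold; D_t below the
    threshold scores sleep.
    """
    counts = np.asarray(counts, dtype=float)
    pad_l, pad_r = SLEEP_WEIGHTS_CENTER, len(SLEEP_WEIGHTS) - SLEEP_WEIGHTS_CENTER - 1
    padded = np.pad(counts, (pad_l, pad_r), mode="edge")
    d = np.convolve(padded, SLEEP_WEIGHTS[::-1], mode="valid")
    return d < SLEEP_THRESHOLD


def _bed_window_mask(clock_min: np.ndarray, bed_start: float, bed_end: float) -> np.ndarray:
    if bed_end >= bed_start:
        return (clock_min >= bed_start) & (clock_min < bed_end)
    return (clock_min >= bed_start) | (clock_min < bed_end)


def score_sleep(
    epochs: pd.DataFrame,
    bed_start_min: float,
    bed_end_min: float,
    day: int = 0,
) -> SleepSummary:
    """Sleep summary for the night whose bed window starts on ``day``.

    ``epochs`` must carry ``timestamp_min`` (minutes from series start,
    1-min spacing) and ``counts``.  The bed window is given as clock
    minutes after midnight and may cross midnight.  A window with more
    than 20% of its epochs missing is flagged invalid.
    """
    tib = (bed_end_min - bed_start_min) % 1440.0
    if tib == 0:
        tib = 1440.0
    start_abs = day * 1440.0 + bed_start_min
    end_abs = start_abs + tib
    ts = epochs["timestamp_min"].to_numpy(dtype=float)
    m = (ts >= start_abs) & (ts < end_abs)
    n_expected = int(round(tib))
    if m.sum() < 0.8 * n_expected:
        return SleepSummary(bed_start_min, bed_end_min, 0.0, 0.0, 0.0, 0.0, valid=False)
    counts = epochs.loc[m, "counts"].to_numpy(dtype=float)
    asleep = score_epochs(counts)

    # sleep onset: first run of >= ONSET_RUN_EPOCHS sleep epochs
    onset = None
    run = 0
    for i, s in enumerate(asleep):
        run = run + 1 if s else 0
        if run >= ONSET_RUN_EPOCHS:
            onset = i - ONSET_RUN_EPOCHS + 1
            break
    if onset is None:
        return SleepSummary(
            bed_start_min, bed_end_min, 0.0, 0.0, 0.0, tib, valid=True, sleep_mask=asleep
        )
    sleep_idx = np.flatnonzero(asleep[onset:]) + onset
    last = sleep_idx[-1]
    tst = float(len(sleep_idx))
    waso = float(np.sum(~asleep[onset : last + 1]))
    return SleepSummary(
        bed_start_min=bed_start_min,
        bed_end_min=bed_end_min,
        tst_min=tst,
        se_pct=100.0 * tst / tib,
        waso_min=waso,
        sleep_onset_latency_min=float(onset),
        valid=True,
        sleep_mask=asleep,
    )


def daily_activity(
    epochs: pd.DataFrame,
    day: int,
    sleep: SleepSummary | None = None,
    sedentary_counts: float = SEDENTARY_COUNTS,
) -> DailyActivity:
    """Wear / sedentary / active accounting for one calendar day.

    Sedentary hours are worn, awake epochs with counts below the
    sedentary threshold; active hours are the remaining worn awake
    epochs.  Epochs inside the scored sleep period (onset to final
    awakening) are excluded from both.
    """
    ts = epochs["timestamp_min"].to_numpy(dtype=float)
    m = (ts >= day * 1440.0) & (ts < (day + 1) * 1440.0)
    counts = epochs.loc[m, "counts"].to_numpy(dtype=float)
    steps = int(epochs.loc[m, "steps"].sum()) if "steps" in epochs else 0
    worn = detect_nonwear(counts)
    wear_h = float(worn.sum()) / 60.0

    awake = np.ones(len(counts), dtype=bool)
    if sleep is not None and sleep.valid and sleep.sleep_mask is not None:
        clock = ts[m] % 1440.0
        in_bed = _bed_window_mask(clock, sleep.bed_start_min, sleep.bed_end_min)
        asleep_window = score_epochs(counts)  # same classifier, day-local
        awake &= ~(in_bed & asleep_window)
    sed = worn & awake & (counts < sedentary_counts)
    act = worn & awake & (counts >= sedentary_counts)
    return DailyActivity(
        steps=steps,
        wear_h=wear_h,
        sedentary_h=float(sed.sum()) / 60.0,
        active_h=float(act.sum()) / 60.0,
    )
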