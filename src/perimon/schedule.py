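"""Duty-cycle schedule and the battery-life / sampling-interval trade-off.

A wrist device cannot stream PPG continuously for months: sensing is
duty-cycled into short sessions.  The default plan records 12 minutes
every second hour — 2 minutes of sensor calibration (discarded as
unreliable) followed by two consecutive 5-minute analysis windows, of
which the cleaner one is kept for short-term HRV.

Battery life as a function of the session interval is modelled as

    lifetime = capacity / (idle_power + ppg_power_extra * duty)

with duty = session_min / interval_min.  The model is scale-invariant
in (capacity, idle_power, ppg_power_extra), so capacity is fixed at 1
(normalized energy units) and the two power parameters are fitted by
least squares on inverse lifetime, which is linear in duty.  With two
distinct observations the fit is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hrv import HrvSummary
from .quality import PpgStream, QualityLabel

__all__ = [
    "SchedulePlan",
    "EnergyModel",
    "segment_session",
    "select_window",
    "daily_schedule",
    "fit_energy_model",
    "predict_lifetime",
]

WINDOW_VALIDITY_THRESHOLD = 0.5  # minimum fraction of reliable quality labels


@dataclass(frozen=True)
class SchedulePlan:
    """Session structure of the duty-cycled collection schedule."""

    interval_min: float = 120.0
    session_min: float = 12.0
    calibration_min: float = 2.0
    window_min: float = 5.0
    windows_per_session: int = 2

    def __post_init__(self) -> None:
        expected = self.calibration_min + self.windows_per_session * self.window_min
        if abs(expected - self.session_min) > 1e-9:
            raise ValueError(
                f"calibration ({self.calibration_min}) + {self.windows_per_session} x "
                f"window ({self.window_min}) must equal session_min ({self.session_min})"
            )
        if self.interval_min < self.session_min:
            raise ValueError("interval_min must be >= session_min")


@dataclass(frozen=True)
class EnergyModel:
    """Normalized battery model; all parameters strictly positive."""

    capacity: float
    idle_power: float
    ppg_power_extra: float
    session_min: float = 12.0

    def __post_init__(self) -> None:
        if self.capacity <= 0 or self.idle_power <= 0 or self.ppg_power_extra <= 0:
            raise ValueError("capacity and power parameters must be strictly positive")

    def lifetime_h(self, interval_min: float) -> float:
        duty = self.session_min / interval_min
        return self.capacity / (self.idle_power + self.ppg_power_extra * duty)


def segment_session(
    stream: PpgStream, plan: SchedulePlan = SchedulePlan()
) -> tuple[tuple[float, float], list[tuple[float, float]]]:
    """Split one session stream into the calibration segment and analysis windows.

    Returns ``(calibration, windows)`` as [start_ms, end_ms) pairs
    relative to the stream's own timeline.  The first
    ``calibration_min`` are discarded as unreliable; the remainder is
    cut into up to ``windows_per_session`` consecutive windows of
    ``window_min``.  A short stream yields fewer windows with a
    warning; a stream too short for a single window is an error.
    """
    t0 = float(stream.timestamps_ms[0])
    end = float(stream.timestamps_ms[-1])
    cal_end = t0 + plan.calibration_min * 60000.0
    win_ms = plan.window_min * 60000.0
    # a stream sampled over [0, T) ends one period short of T; tolerate that
    tol_ms = 1500.0 / stream.nominal_rate
    windows: list[tuple[float, float]] = []
    lo = cal_end
    for _ in range(plan.windows_per_session):
        hi = lo + win_ms
        if hi > end + tol_ms:
            break
        windows.append((lo, hi))
        lo = hi
    if not windows:
        raise ValueError(
            f"stream of {stream.duration_s / 60:.1f} min is too short for one "
            f"{plan.window_min:.0f}-min window after calibration discard"
        )
    if len(windows) < plan.windows_per_session:
        warnings.warn(
            f"session truncated: {len(windows)} of {plan.windows_per_session} windows fit",
            stacklevel=2,
        )
    return (t0, cal_end), windows


def _reliable_fraction(window: tuple[float, float], labels: list[QualityLabel]) -> float:
    lo, hi = window
    tot = rel = 0.0
    for lab in labels:
        ov = min(hi, lab.end_ms) - max(lo, lab.start_ms)
        if ov > 0:
            tot += ov
            if lab.reliable:
                rel += ov
    return rel / tot if tot > 0 else 0.0


def select_window(
    summaries: list[HrvSummary],
    labels: list[QualityLabel],
    threshold: float = WINDOW_VALIDITY_THRESHOLD,
) -> HrvSummary | None:
    """Keep the cleaner of a session's analysis windows.

    Picks the window whose quality labels have the highest reliable
    fraction; ties break toward the earlier window.  Returns ``None``
    when every window falls below ``threshold`` — the session then
    yields no HRV point.
    """
    best: HrvSummary | None = None
    best_frac = -1.0
    for s in summaries:
        frac = _reliable_fraction((s.start_ms, s.end_ms), labels)
        if frac >= threshold and frac > best_frac + 1e-12:
            best, best_frac = s, frac
    return best


def daily_schedule(
    plan: SchedulePlan = SchedulePlan(), anchor_min: float = 0.0
) -> tuple[list[float], float]:
    """Session start times (minutes after local midnight) and usable minutes.

    Sessions start at ``anchor_min + k * interval_min`` for every k that
    fits a full session within the day; usable minutes count the
    analysis windows only (calibration is overhead).
    """
    starts: list[float] = []
    t = anchor_min
    while t + plan.session_min <= 1440.0 + 1e-9:
        starts.append(t)
        t += plan.interval_min
    usable = len(starts) * plan.windows_per_session * plan.window_min
    return starts, usable


def fit_energy_model(
    observations: list[tuple[float, float]], session_min: float = 12.0
) -> EnergyModel:
    """Fit the battery model to (interval_min, lifetime_h) observations.

    Inverse lifetime is linear in the duty fraction, so the fit is an
    ordinary least-squares line through (duty, 1/lifetime); with
    exactly two distinct observations it reproduces both exactly.
    """
    if len(observations) < 2:
        raise ValueError("need at least two observations")
    intervals = np.array([o[0] for o in observations], dtype=float)
    lifetimes = np.array([o[1] for o in observations], dtype=float)
    if len(np.unique(intervals)) < 2:
        raise ValueError("observations must cover at least two distinct intervals")
    if np.any(intervals <= 0) or np.any(lifetimes <= 0):
        raise ValueError("intervals and lifetimes must be positive")
    duty = session_min / intervals
    A = np.column_stack([np.ones_like(duty), duty])
    coef, *_ = np.linalg.lstsq(A, 1.0 / lifetimes, rcond=None)
    idle, extra = float(coef[0]), float(coef[1])
    if idle <= 0 or extra <= 0:
        raise ValueError(
            "observations are inconsistent with a monotone battery model "
            "(fitted power terms must be positive)"
        )
    return EnergyModel(capacity=1.0, idle_power=idle, ppg_power_extra=extra, session_min=session_min)


def predict_lifetime(model: EnergyModel, plan: SchedulePlan) -> float:
    """Predicted battery lifetime (hours) under a schedule plan."""
    m = model if model.session_min == plan.session_min else EnergyModel(
        model.capacity, model.idle_power, model.ppg_power_extra, plan.session_min
    )
    return m.lifetime_h(plan.interval_min)
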