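"""Synthetic signal and cohort generators.

Every generator emulates one class of input the analytics consume — raw
PPG sample streams from a duty-cycled wrist sensor, 1-min actigraphy
epochs with step counts, and per-participant adherence timelines across
pregnancy and postpartum — and returns the ground truth alongside the
signal so downstream recovery can be measured, not assumed.

Beat-to-beat intervals are modulated in the two spectral bands that
short-term heart-rate-variability analysis integrates: a low-frequency
band (0.04–0.15 Hz) and a high-frequency, respiration-coupled band
(0.15–0.4 Hz).  The waveform model renders one symmetric pulse per beat
(no dicrotic notch) — sufficient for peak-counting analytics at the
20 Hz sampling rate of the target device.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "Modulation",
    "Artifact",
    "PpgSimConfig",
    "ActigraphySimConfig",
    "CohortSimConfig",
    "BeatTruth",
    "simulate_beat_times",
    "render_ppg",
    "simulate_session",
    "simulate_actigraphy",
    "simulate_cohort",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


class ConfigError(ValueError):
    """Raised when a simulation config is non-physiological or inconsistent."""


@dataclass(frozen=True)
class Modulation:
    """A single sinusoidal IBI modulation component."""

    freq_hz: float
    amp_ms: float

    def __post_init__(self) -> None:
        if self.amp_ms < 0:
            raise ConfigError(f"modulation amplitude must be >= 0, got {self.amp_ms}")
        if self.freq_hz < 0:
            raise ConfigError(f"modulation frequency must be >= 0, got {self.freq_hz}")


ArtifactKind = Literal["motion", "flatline", "saturation"]


@dataclass(frozen=True)
class Artifact:
    """A corrupted interval of the rendered PPG stream."""

    start_s: float
    duration_s: float
    kind: ArtifactKind

    def __post_init__(self) -> None:
        if self.start_s < 0 or self.duration_s <= 0:
            raise ConfigError("artifact must have start >= 0 and duration > 0")
        if self.kind not in ("motion", "flatline", "saturation"):
            raise ConfigError(f"unknown artifact kind {self.kind!r}")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class PpgSimConfig:
    """Parameters of the synthetic PPG generator.

    ``lf_mod``/``hf_mod`` modulate the inter-beat interval sinusoidally in
    the LF (0.04–0.15 Hz) and HF (0.15–0.4 Hz) bands; ``ibi_jitter_ms``
    adds white Gaussian beat-to-beat jitter; ``noise_sd`` is additive
    sample noise on the rendered waveform (device amplitude units, pulse
    amplitude is 1).  The first ``calibration_s`` seconds are rendered as
    a low-amplitude, exponentially settling startup transient emulating
    sensor calibration.
    """

    sampling_rate: float = 20.0
    mean_hr: float = 70.0
    lf_mod: Modulation = Modulation(0.1, 30.0)
    hf_mod: Modulation = Modulation(0.25, 20.0)
    ibi_jitter_ms: float = 5.0
    noise_sd: float = 0.05
    artifacts: tuple[Artifact, ...] = ()
    calibration_s: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be > 0")
        if self.mean_hr <= 0:
            raise ConfigError("mean_hr must be > 0")
        base_ibi = 60000.0 / self.mean_hr
        if base_ibi - self.lf_mod.amp_ms - self.hf_mod.amp_ms <= 0:
            raise ConfigError("modulation amplitudes imply non-positive IBI")
        if self.lf_mod.amp_ms > 0 and not (LF_BAND[0] <= self.lf_mod.freq_hz <= LF_BAND[1]):
            raise ConfigError("lf_mod frequency outside the 0.04-0.15 Hz band")
        if self.hf_mod.amp_ms > 0 and not (HF_BAND[0] <= self.hf_mod.freq_hz <= HF_BAND[1]):
            raise ConfigError("hf_mod frequency outside the 0.15-0.4 Hz band")
        if self.ibi_jitter_ms < 0 or self.noise_sd < 0:
            raise ConfigError("noise parameters must be >= 0")
        if self.calibration_s < 0:
            raise ConfigError("calibration_s must be >= 0")


@dataclass
class BeatTruth:
    """Ground-truth beat sequence emitted by :func:`simulate_beat_times`."""

    beat_times_s: np.ndarray
    ibis_ms: np.ndarray

    @property
    def mean_hr(self) -> float:
        return 60000.0 / float(np.mean(self.ibis_ms))

    @property
    def sdnn_ms(self) -> float:
        return float(np.std(self.ibis_ms, ddof=1))

    @property
    def rmssd_ms(self) -> float:
        d = np.diff(self.ibis_ms)
        return float(np.sqrt(np.mean(d * d)))


def simulate_beat_times(cfg: PpgSimConfig, duration_s: float) -> BeatTruth:
    """Generate beat timestamps with LF/HF-modulated inter-beat intervals.

    The n-th interval is ``60000/mean_hr + lf·sin(2π f_lf t_n) +
    hf·sin(2π f_hf t_n) + N(0, jitter)`` evaluated at the time of the
    beat that opens the interval.  Jittered intervals are floored at
    200 ms to keep the sequence physiological.
    """
    if duration_s <= 0:
        raise ConfigError("duration must be > 0")
    rng = np.random.default_rng(cfg.seed)
    base = 60000.0 / cfg.mean_hr
    # generous upper bound on beat count
    n_max = int(duration_s / (base - cfg.lf_mod.amp_ms - cfg.hf_mod.amp_ms) * 1000) + 8
    times = np.empty(n_max)
    ibis = np.empty(n_max)
    t = 0.0
    n = 0
    while t < duration_s and n < n_max:
        times[n] = t
        ibi = (
            base
            + cfg.lf_mod.amp_ms * np.sin(2 * np.pi * cfg.lf_mod.freq_hz * t)
            + cfg.hf_mod.amp_ms * np.sin(2 * np.pi * cfg.hf_mod.freq_hz * t)
        )
        if cfg.ibi_jitter_ms > 0:
            ibi += rng.normal(0.0, cfg.ibi_jitter_ms)
        ibi = max(ibi, 200.0)
        ibis[n] = ibi
        t += ibi / 1000.0
        n += 1
    return BeatTruth(beat_times_s=times[:n].copy(), ibis_ms=ibis[: n - 1].copy())


def _gaussian_pulse_train(
    t: np.ndarray, beat_times_s: np.ndarray, width_s: float = 0.11
) -> np.ndarray:
    """Sum of unit-amplitude Gaussian pulses centered on the beats."""
    fs = 1.0 / (t[1] - t[0]) if len(t) > 1 else 1.0
    out = np.zeros_like(t)
    half = int(np.ceil(4 * width_s * fs))
    for bt in beat_times_s:
        c = int(round(bt * fs))
        lo, hi = max(c - half, 0), min(c + half + 1, len(t))
        if lo >= hi:
            continue
        out[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - bt) / width_s) ** 2)
    return out


def render_ppg(
    beat_times_s: np.ndarray,
    cfg: PpgSimConfig,
    duration_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a PPG sample stream from beat times.

    Returns ``(timestamps_ms, samples)`` sampled at ``cfg.sampling_rate``.
    The calibration prefix is replaced by a drifting low-amplitude
    transient; artifact intervals are corrupted according to their kind
    (motion: additive band-overlapping oscillation, flatline: constant,
    saturation: amplitude clipping).
    """
    beat_times_s = np.asarray(beat_times_s, dtype=float)
    if len(beat_times_s) > 1 and np.any(np.diff(beat_times_s) <= 0):
        raise ConfigError("beat times must be strictly increasing")
    if duration_s is None:
        duration_s = float(beat_times_s[-1]) + 1.0 if len(beat_times_s) else 1.0
    for a in cfg.artifacts:
        if a.end_s > duration_s + 1e-9:
            raise ConfigError(f"artifact [{a.start_s}, {a.end_s}) s exceeds signal duration")

    fs = cfg.sampling_rate
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(cfg.seed + 1)  # separate stream from beat jitter

    x = _gaussian_pulse_train(t, beat_times_s)
    if cfg.calibration_s > 0:
        cal = t < cfg.calibration_s
        # low-amplitude pulses under an exponentially settling baseline drift
        tau = max(cfg.calibration_s / 4.0, 1e-6)
        x[cal] = 0.2 * x[cal] + 2.5 * np.exp(-t[cal] / tau)
    if cfg.noise_sd > 0:
        x = x + rng.normal(0.0, cfg.noise_sd, size=n)

    for a in cfg.artifacts:
        lo, hi = int(round(a.start_s * fs)), int(round(a.end_s * fs))
        lo, hi = max(lo, 0), min(hi, n)
        if hi <= lo:
            continue
        if a.kind == "motion":
            w = rng.normal(0.0, 1.0, size=hi - lo)
            if hi - lo > 30:  # band-overlapping oscillation: low-passed heavy noise
                sos = sps.butter(2, min(4.0, 0.45 * fs), btype="low", fs=fs, output="sos")
                w = sps.sosfilt(sos, w)
            x[lo:hi] += 3.0 * w / max(np.std(w), 1e-12)
        elif a.kind == "flatline":
            x[lo:hi] = x[lo] if lo < n else 0.0
        elif a.kind == "saturation":
            rail = np.percentile(x[lo:hi], 60.0)
            x[lo:hi] = np.minimum(x[lo:hi], rail)
    return t * 1000.0, x


def simulate_session(
    cfg: PpgSimConfig, duration_s: float = 720.0
) -> tuple[np.ndarray, np.ndarray, BeatTruth]:
    """One duty-cycle recording: beat simulation plus waveform rendering.

    Default duration is a full 12-min session (2 min calibration + two
    5-min analysis windows).
    """
    truth = simulate_beat_times(cfg, duration_s)
    ts_ms, x = render_ppg(truth.beat_times_s, cfg, duration_s)
    return ts_ms, x, truth


# ---------------------------------------------------------------------------
# actigraphy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WasoEpisode:
    onset_min: float  # minutes after sleep onset
    duration_min: float


@dataclass(frozen=True)
class NonwearBlock:
    start_min: float  # minutes after local midnight
    duration_min: float

    @property
    def end_min(self) -> float:
        return self.start_min + self.duration_min


@dataclass(frozen=True)
class ActigraphySimConfig:
    """Parameters of the 1-min-epoch actigraphy generator.

    Clock times are minutes after local midnight; a bed window crossing
    midnight is expressed with ``bed_start_min > bed_end_min``.  Sleep
    epochs carry near-zero counts with a small deterministic position
    shift every ~45 min (so sustained zeros remain specific to
    non-wear); wake-after-sleep-onset episodes and daytime activity are
    Poisson bursts at the configured levels.
    """

    bed_start_min: float = 23 * 60.0
    bed_end_min: float = 7 * 60.0
    true_tst_min: float = 430.0
    sleep_latency_min: float = 10.0
    waso_episodes: tuple[WasoEpisode, ...] = (WasoEpisode(180.0, 20.0),)
    daytime_activity_level: float = 30.0
    sedentary_level: float = 2.0
    sedentary_hours_per_day: float = 6.0
    nonwear_blocks: tuple[NonwearBlock, ...] = ()
    steps_per_active_hour: float = 600.0
    waso_activity_level: float = 40.0
    latency_activity_level: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        tib = self.time_in_bed_min
        waso = sum(w.duration_min for w in self.waso_episodes)
        if self.true_tst_min + waso + self.sleep_latency_min > tib + 1e-9:
            raise ConfigError("TST + WASO + latency exceed the bed window")
        blocks = sorted(self.nonwear_blocks, key=lambda b: b.start_min)
        for a, b in zip(blocks, blocks[1:]):
            if a.end_min > b.start_min:
                raise ConfigError("nonwear blocks overlap")
        for b in blocks:
            if b.start_min < 0 or b.end_min > 1440:
                raise ConfigError("nonwear block outside the day")

    @property
    def time_in_bed_min(self) -> float:
        if self.bed_end_min >= self.bed_start_min:
            return self.bed_end_min - self.bed_start_min
        return 1440.0 - self.bed_start_min + self.bed_end_min


@dataclass
class ActigraphyTruth:
    """Per-day ground truth of the actigraphy generator."""

    tst_min: float
    waso_min: float
    sleep_latency_min: float
    wear_h: np.ndarray  # per day
    sedentary_h: float  # awake, worn, low-activity hours per day
    bed_start_min: float
    bed_end_min: float


def simulate_actigraphy(
    cfg: ActigraphySimConfig, n_days: int
) -> tuple[pd.DataFrame, ActigraphyTruth]:
    """Generate 1-min activity/step epochs over ``n_days`` calendar days.

    Returns a frame with columns ``timestamp_min`` (minutes from the
    start of day 0), ``counts``, ``steps``, ``worn`` plus the ground
    truth.  The sleep architecture is identical across days; non-wear
    blocks repeat daily at the configured clock times.
    """
    if n_days < 1:
        raise ConfigError("n_days must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    n = n_days * 1440
    minutes = np.arange(n)
    mod = minutes % 1440  # clock minute

    if cfg.bed_end_min >= cfg.bed_start_min:
        in_bed = (mod >= cfg.bed_start_min) & (mod < cfg.bed_end_min)
    else:
        in_bed = (mod >= cfg.bed_start_min) | (mod < cfg.bed_end_min)

    # minutes since bed start (valid where in_bed)
    since_bed = np.where(
        mod >= cfg.bed_start_min, mod - cfg.bed_start_min, mod + 1440 - cfg.bed_start_min
    )
    onset = cfg.sleep_latency_min
    # sleep/wake template within the bed window
    asleep = in_bed & (since_bed >= onset)
    final_wake = onset + cfg.true_tst_min + sum(w.duration_min for w in cfg.waso_episodes)
    asleep &= since_bed < final_wake
    in_waso = np.zeros(n, dtype=bool)
    for w in cfg.waso_episodes:
        lo = onset + w.onset_min
        in_waso |= in_bed & (since_bed >= lo) & (since_bed < lo + w.duration_min)
    asleep &= ~in_waso
    latency = in_bed & (since_bed < onset)

    counts = rng.poisson(cfg.daytime_activity_level, size=n).astype(float)
    counts = np.maximum(counts, 1.0)  # awake worn epochs never all-zero
    # sedentary stretch: first configured awake hours after the bed window
    sed_len = int(round(cfg.sedentary_hours_per_day * 60))
    sed_start = cfg.bed_end_min
    since_wakeup = (mod - sed_start) % 1440
    sedentary = (~in_bed) & (since_wakeup < sed_len)
    counts[sedentary] = np.maximum(rng.poisson(cfg.sedentary_level, size=int(sedentary.sum())), 1.0)

    counts[latency] = np.maximum(rng.poisson(cfg.latency_activity_level, size=int(latency.sum())), 1.0)
    counts[in_waso] = np.maximum(rng.poisson(cfg.waso_activity_level, size=int(in_waso.sum())), 1.0)
    counts[asleep] = 0.0
    # deterministic position shifts every 45 min of sleep keep zero runs < 60 min
    shift = asleep & (since_bed % 45 == 44)
    counts[shift] = 2.0

    worn = np.ones(n, dtype=bool)
    for b in cfg.nonwear_blocks:
        nw = (mod >= b.start_min) & (mod < b.end_min)
        worn &= ~nw
    counts[~worn] = 0.0

    active = worn & ~in_bed & ~sedentary
    steps = np.zeros(n)
    steps[active] = rng.poisson(cfg.steps_per_active_hour / 60.0, size=int(active.sum()))
    steps[~worn] = 0.0

    frame = pd.DataFrame(
        {"timestamp_min": minutes, "counts": counts, "steps": steps, "worn": worn}
    )
    nonwear_min = sum(b.duration_min for b in cfg.nonwear_blocks)
    sed_awake_h = float((sedentary & worn).sum()) / 60.0 / n_days
    truth = ActigraphyTruth(
        tst_min=cfg.true_tst_min,
        waso_min=sum(w.duration_min for w in cfg.waso_episodes),
        sleep_latency_min=cfg.sleep_latency_min,
        wear_h=np.full(n_days, 24.0 - nonwear_min / 60.0),
        sedentary_h=sed_awake_h,
        bed_start_min=cfg.bed_start_min,
        bed_end_min=cfg.bed_end_min,
    )
    return frame, truth


# ---------------------------------------------------------------------------
# cohort adherence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSimConfig:
    """Parameters of the cohort adherence generator.

    Defaults emulate the feasibility profile of a ~28-participant
    high-risk pregnancy cohort enrolled around gestational week 13 and
    followed three months postpartum: wear time near 17 h/day declining
    slowly through pregnancy and dropping after delivery, daily
    questionnaire answer probability 0.675 in pregnancy and 0.57
    postpartum, and blood-pressure self-measurements at 0.74/week in
    pregnancy and 0.29/week postpartum.
    """

    n_participants: int = 28
    enrollment_gw_mean: float = 13.4
    enrollment_gw_sd: float = 4.0
    delivery_gw_mean: float = 39.0
    delivery_gw_sd: float = 1.5
    postpartum_weeks: float = 12.0
    wear_pregnancy_mean: float = 17.01
    wear_pregnancy_slope: float = 0.0  # h/day per gestational week
    wear_postpartum_mean: float = 13.72
    wear_participant_sd: float = 3.5  # between-participant offset
    wear_day_sd: float = 2.0  # within-participant daily noise
    answer_prob_pregnancy: float = 0.675
    answer_prob_postpartum: float = 0.57
    bp_rate_pregnancy: float = 0.74  # measurements / week
    bp_rate_postpartum: float = 0.29
    dropout_hazard_per_day: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        for p in (self.answer_prob_pregnancy, self.answer_prob_postpartum):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("answer probabilities must lie in [0, 1]")
        if self.bp_rate_pregnancy < 0 or self.bp_rate_postpartum < 0:
            raise ConfigError("BP rates must be >= 0")
        if not 0.0 <= self.wear_pregnancy_mean <= 24.0:
            raise ConfigError("wear hours must lie in [0, 24]")
        if not 0.0 <= self.wear_postpartum_mean <= 24.0:
            raise ConfigError("wear hours must lie in [0, 24]")
        if self.enrollment_gw_mean >= self.delivery_gw_mean:
            raise ConfigError("enrollment must precede delivery on average")
        if not 0.0 <= self.dropout_hazard_per_day <= 1.0:
            raise ConfigError("dropout hazard must lie in [0, 1]")


def simulate_cohort(
    cfg: CohortSimConfig, start_date: str = "2020-01-06"
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate per-participant daily adherence records.

    Returns ``(records, meta, truth)`` where ``records`` has columns
    ``participant_id, date, wear_h, answered, bp_count`` and ``meta``
    has ``participant_id, enrollment_gw, delivery_date`` (delivery_date
    empty for participants censored before delivery).  All participants
    enroll on ``start_date``; gestational age at enrollment varies.
    """
    rng = np.random.default_rng(cfg.seed)
    t0 = pd.Timestamp(start_date)
    rec_rows: list[dict] = []
    meta_rows: list[dict] = []
    for i in range(cfg.n_participants):
        pid = f"P{i:03d}"
        enroll_gw = float(np.clip(rng.normal(cfg.enrollment_gw_mean, cfg.enrollment_gw_sd), 5.0, 35.0))
        delivery_gw = float(max(rng.normal(cfg.delivery_gw_mean, cfg.delivery_gw_sd), enroll_gw + 1.0))
        days_to_delivery = int(round((delivery_gw - enroll_gw) * 7))
        n_days = days_to_delivery + int(round(cfg.postpartum_weeks * 7))
        if cfg.dropout_hazard_per_day > 0:
            drop = rng.geometric(cfg.dropout_hazard_per_day)
            n_days = min(n_days, int(drop))
        offset = rng.normal(0.0, cfg.wear_participant_sd)
        delivered = n_days > days_to_delivery
        delivery_date = t0 + pd.Timedelta(days=days_to_delivery)
        for d in range(n_days):
            date = t0 + pd.Timedelta(days=d)
            postpartum = d >= days_to_delivery
            if postpartum:
                base = cfg.wear_postpartum_mean
                p_ans, bp_rate = cfg.answer_prob_postpartum, cfg.bp_rate_postpartum
            else:
                gw = enroll_gw + d / 7.0
                base = cfg.wear_pregnancy_mean + cfg.wear_pregnancy_slope * (gw - enroll_gw)
                p_ans, bp_rate = cfg.answer_prob_pregnancy, cfg.bp_rate_pregnancy
            wear = base + offset
            if cfg.wear_day_sd > 0:
                wear += rng.normal(0.0, cfg.wear_day_sd)
            rec_rows.append(
                {
                    "participant_id": pid,
                    "date": date.date().isoformat(),
                    "wear_h": float(np.clip(wear, 0.0, 24.0)),
                    "answered": int(rng.random() < p_ans),
                    "bp_count": int(rng.poisson(bp_rate / 7.0)),
                }
            )
        meta_rows.append(
            {
                "participant_id": pid,
                "enrollment_gw": round(enroll_gw, 2),
                "delivery_date": delivery_date.date().isoformat() if delivered else "",
            }
        )
    records = pd.DataFrame(rec_rows)
    meta = pd.DataFrame(meta_rows)
    truth = {
        "wear_pregnancy_mean": cfg.wear_pregnancy_mean,
        "wear_postpartum_mean": cfg.wear_postpartum_mean,
        "answer_prob_pregnancy": cfg.answer_prob_pregnancy,
        "answer_prob_postpartum": cfg.answer_prob_postpartum,
        "bp_rate_pregnancy": cfg.bp_rate_pregnancy,
        "bp_rate_postpartum": cfg.bp_rate_postpartum,
        "wear_pregnancy_slope": cfg.wear_pregnancy_slope,
    }
    return records, meta, truth
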