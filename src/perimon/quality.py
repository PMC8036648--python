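"""PPG quality gating: raw sample stream → artifact-filtered NN intervals.

The stage chain is band-pass to the cardiac frequency range (0.5–3 Hz),
adaptive peak detection with sub-sample refinement, rule-based
per-window quality labelling, and interval filtering to a "normal"
(NN) inter-beat series.  The quality classifier is a transparent
feature-based stand-in exposing the same per-window binary label a
learned model would, so one can be swapped in behind the same
interface.

At a 20 Hz sampling rate the inter-sample spacing is 50 ms — larger
than the beat-to-beat differences HRV statistics measure — so peak
times are refined to sub-sample precision by parabolic interpolation
of the three samples around each detected maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "PpgStream",
    "QualityLabel",
    "NnSeries",
    "bandpass_cardiac",
    "detect_peaks",
    "assess_quality",
    "to_nn",
    "stream_to_nn",
]

CARDIAC_BAND_HZ = (0.5, 3.0)
NN_BOUNDS_MS = (300.0, 2000.0)
REFRACTORY_MS = 300.0
ECTOPIC_REL_TOL = 0.20  # vs median of previous 5 retained intervals
MIN_FILTER_DURATION_S = 10.0


@dataclass
class PpgStream:
    """A raw or filtered PPG sample stream.

    ``timestamps_ms`` must be strictly increasing and the effective
    sampling rate must be within 20% of ``nominal_rate``.
    """

    timestamps_ms: np.ndarray
    samples: np.ndarray
    nominal_rate: float = 20.0

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.timestamps_ms.shape != self.samples.shape:
            raise ValueError("timestamps and samples must have equal length")
        if len(self.timestamps_ms) > 1:
            dt = np.diff(self.timestamps_ms)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            eff = 1000.0 * (len(self.timestamps_ms) - 1) / (
                self.timestamps_ms[-1] - self.timestamps_ms[0]
            )
            if abs(eff - self.nominal_rate) > 0.2 * self.nominal_rate:
                raise ValueError(
                    f"effective rate {eff:.2f} Hz deviates more than 20% "
                    f"from nominal {self.nominal_rate} Hz"
                )

    @property
    def duration_s(self) -> float:
        if len(self.timestamps_ms) < 2:
            return 0.0
        return (self.timestamps_ms[-1] - self.timestamps_ms[0]) / 1000.0


@dataclass(frozen=True)
class QualityLabel:
    """Reliability verdict for one window of the stream."""

    start_ms: float
    end_ms: float
    reliable: bool
    reasons: tuple[str, ...] = ()


@dataclass
class NnSeries:
    """Artifact-filtered inter-beat intervals with their beat timestamps.

    ``beat_times_ms`` are all detected beats (pre-filtering); each
    retained interval ``nn_ms[i]`` ends at ``nn_times_ms[i]``.
    """

    beat_times_ms: np.ndarray
    nn_times_ms: np.ndarray
    nn_ms: np.ndarray
    removed_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.beat_times_ms = np.asarray(self.beat_times_ms, dtype=float)
        self.nn_times_ms = np.asarray(self.nn_times_ms, dtype=float)
        self.nn_ms = np.asarray(self.nn_ms, dtype=float)
        if len(self.nn_times_ms) != len(self.nn_ms):
            raise ValueError("nn_times_ms and nn_ms must have equal length")

    def __len__(self) -> int:
        return len(self.nn_ms)


def bandpass_cardiac(stream: PpgStream) -> PpgStream:
    """Zero-phase band-pass of the stream to the cardiac band (0.5–3 Hz)."""
    if stream.duration_s < MIN_FILTER_DURATION_S:
        raise ValueError(
            f"stream of {stream.duration_s:.1f} s is shorter than the "
            f"{MIN_FILTER_DURATION_S:.0f} s filter warm-up minimum"
        )
    fs = stream.nominal_rate
    hi = min(CARDIAC_BAND_HZ[1], 0.45 * fs)
    sos = sps.butter(3, [CARDIAC_BAND_HZ[0], hi], btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, stream.samples)
    return PpgStream(stream.timestamps_ms.copy(), filtered, stream.nominal_rate)


def _parabolic_refine(x: np.ndarray, i: int) -> float:
    """Sub-sample offset of a local maximum at index i, in samples."""
    if i <= 0 or i >= len(x) - 1:
        return 0.0
    denom = x[i - 1] - 2.0 * x[i] + x[i + 1]
    if denom >= 0 or abs(denom) < 1e-18:
        return 0.0
    delta = 0.5 * (x[i - 1] - x[i + 1]) / denom
    return float(np.clip(delta, -0.5, 0.5))


def detect_peaks(stream: PpgStream) -> np.ndarray:
    """Beat timestamps (ms) from a band-passed stream.

    Local maxima above an adaptive amplitude threshold (scale-invariant,
    derived from the robust signal amplitude) separated by a 300 ms
    refractory period, refined to sub-sample precision by parabolic
    interpolation.  Returns an empty array when no peaks are found.
    """
    x = stream.samples
    fs = stream.nominal_rate
    if len(x) < 3:
        return np.array([])
    scale = np.percentile(np.abs(x), 95)
    if scale <= 0:
        return np.array([])
    height = 0.35 * scale
    distance = max(int(round(REFRACTORY_MS / 1000.0 * fs)), 1)
    idx, _ = sps.find_peaks(x, height=height, distance=distance, prominence=0.25 * scale)
    if len(idx) == 0:
        return np.array([])
    t0 = stream.timestamps_ms[0]
    dt_ms = 1000.0 / fs
    times = np.array([t0 + (i + _parabolic_refine(x, i)) * dt_ms for i in idx])
    return times


def assess_quality(stream: PpgStream, window_s: float = 10.0) -> list[QualityLabel]:
    """Rule-based per-window quality labels tiling the stream.

    A window is unreliable when any rule fires: *flatline* (sample
    variance below floor), *clipping* (≥ 5% of samples at an amplitude
    rail), *rate_gap* (inter-sample gap exceeding twice the nominal
    period), or *low_periodicity* (no dominant autocorrelation peak at
    cardiac lags after cardiac band-passing).
    """
    if stream.duration_s < window_s:
        raise ValueError("stream must cover at least one quality window")
    fs = stream.nominal_rate
    t0 = stream.timestamps_ms[0]
    total_ms = stream.timestamps_ms[-1] - t0
    n_win = max(int(total_ms // (window_s * 1000.0)), 1)
    try:
        bp = bandpass_cardiac(stream).samples
    except ValueError:
        bp = stream.samples
    global_sd = float(np.std(stream.samples))

    labels: list[QualityLabel] = []
    for w in range(n_win):
        lo_ms = t0 + w * window_s * 1000.0
        hi_ms = lo_ms + window_s * 1000.0
        if w == n_win - 1:
            hi_ms = t0 + total_ms + 1e-6  # last window absorbs the remainder
        m = (stream.timestamps_ms >= lo_ms) & (stream.timestamps_ms < hi_ms)
        xs = stream.samples[m]
        reasons: list[str] = []
        if len(xs) == 0:
            labels.append(QualityLabel(lo_ms, hi_ms, False, ("rate_gap",)))
            continue
        if np.std(xs) < max(1e-6 * global_sd, 1e-12):
            reasons.append("flatline")
        else:
            rng_eps = 1e-9 * max(np.ptp(xs), 1.0)
            at_top = np.sum(np.abs(xs - xs.max()) <= rng_eps)
            at_bot = np.sum(np.abs(xs - xs.min()) <= rng_eps)
            if max(at_top, at_bot) >= 0.05 * len(xs):
                reasons.append("clipping")
        ts = stream.timestamps_ms[m]
        if len(ts) > 1 and np.max(np.diff(ts)) > 2000.0 / fs:
            reasons.append("rate_gap")
        if "flatline" not in reasons:
            xb = bp[m]
            if _cardiac_periodicity(xb, fs) < 0.45:
                reasons.append("low_periodicity")
        labels.append(QualityLabel(lo_ms, hi_ms, not reasons, tuple(reasons)))
    return labels


def _cardiac_periodicity(x: np.ndarray, fs: float) -> float:
    """Peak normalized autocorrelation at lags of 300–1500 ms."""
    x = x - np.mean(x)
    denom = float(np.dot(x, x))
    if denom <= 0 or len(x) < int(1.5 * fs) + 2:
        return 0.0
    lo = max(int(round(0.3 * fs)), 1)
    hi = min(int(round(1.5 * fs)), len(x) - 2)
    if hi <= lo:
        return 0.0
    ac = np.array([np.dot(x[: len(x) - k], x[k:]) / denom for k in range(lo, hi + 1)])
    return float(np.max(ac))


def to_nn(beat_times_ms: np.ndarray, labels: list[QualityLabel] | None = None) -> NnSeries:
    """Filter successive inter-beat intervals down to a normal (NN) series.

    An interval is dropped when it falls outside 300–2000 ms, deviates
    more than 20% from the median of the previous five retained
    intervals, or overlaps a window labelled unreliable.
    """
    beat_times_ms = np.asarray(beat_times_ms, dtype=float)
    if len(beat_times_ms) < 2:
        return NnSeries(beat_times_ms, np.array([]), np.array([]), 0.0)
    bad_segments = (
        [(l.start_ms, l.end_ms) for l in labels if not l.reliable] if labels else []
    )
    ibis = np.diff(beat_times_ms)
    kept_t: list[float] = []
    kept_nn: list[float] = []
    removed = 0
    for i, nn in enumerate(ibis):
        t_start, t_end = beat_times_ms[i], beat_times_ms[i + 1]
        ok = NN_BOUNDS_MS[0] <= nn <= NN_BOUNDS_MS[1]
        if ok and kept_nn:
            ref = float(np.median(kept_nn[-5:]))
            if abs(nn - ref) > ECTOPIC_REL_TOL * ref:
                ok = False
        if ok:
            for lo, hi in bad_segments:
                if t_start < hi and t_end > lo:
                    ok = False
                    break
        if ok:
            kept_t.append(t_end)
            kept_nn.append(float(nn))
        else:
            removed += 1
    return NnSeries(
        beat_times_ms=beat_times_ms,
        nn_times_ms=np.array(kept_t),
        nn_ms=np.array(kept_nn),
        removed_fraction=removed / len(ibis),
    )


def stream_to_nn(stream: PpgStream, window_s: float = 10.0) -> tuple[NnSeries, list[QualityLabel]]:
    """Full quality chain: band-pass, peak detection, labelling, NN filtering."""
    labels = assess_quality(stream, window_s=window_s)
    beats = detect_peaks(bandpass_cardiac(stream))
    return to_nn(beats, labels), labels
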