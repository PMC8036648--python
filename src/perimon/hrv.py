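"""Short-term heart-rate-variability statistics from NN-interval series.

Time-domain statistics follow the standard short-term definitions:
AVNN is the mean NN interval, SDNN the sample standard deviation
(n−1 denominator), RMSSD the root mean square of successive NN
differences, and HR the beat count normalized to beats per minute.

Spectral power is estimated with a Lomb–Scargle periodogram evaluated
directly on the unevenly spaced beat times — no resampling or
interpolation, which would bias the spectrum when many intervals have
been removed.  The periodogram is normalized so the power integrated
over the evaluated frequency range equals the NN variance (ms²), and
band powers are integrals over the low-frequency band [0.04, 0.15) Hz
and the high-frequency band [0.15, 0.4] Hz.  Elevated LF/HF is the
conventional sympathetic-dominance (stress) direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle

from .quality import NnSeries

__all__ = ["HrvSummary", "time_domain", "freq_domain", "session_hrv"]

LF_BAND_HZ = (0.04, 0.15)
HF_BAND_HZ = (0.15, 0.40)
MIN_NN_PER_WINDOW = 30
MIN_COVERAGE = 0.5


@dataclass
class HrvSummary:
    """Per-window HRV metrics; metrics are ``None`` when data are insufficient."""

    start_ms: float
    end_ms: float
    n_nn: int
    coverage: float
    valid: bool
    reason: str | None = None
    hr: float | None = None
    avnn: float | None = None
    sdnn: float | None = None
    rmssd: float | None = None
    lf: float | None = None
    hf: float | None = None
    lf_hf: float | None = None

    def as_dict(self) -> dict:
        return {
            "window_start_ms": self.start_ms,
            "window_end_ms": self.end_ms,
            "n_nn": self.n_nn,
            "coverage": round(self.coverage, 4),
            "valid": self.valid,
            "reason": self.reason,
            "hr": self.hr,
            "avnn": self.avnn,
            "sdnn": self.sdnn,
            "rmssd": self.rmssd,
            "lf": self.lf,
            "hf": self.hf,
            "lf_hf": self.lf_hf,
        }


def _window_slice(nn: NnSeries, window: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = window
    m = (nn.nn_times_ms >= lo) & (nn.nn_times_ms < hi)
    return nn.nn_times_ms[m], nn.nn_ms[m]


def _insufficient(window: tuple[float, float], n: int, cov: float, why: str) -> HrvSummary:
    return HrvSummary(window[0], window[1], n, cov, valid=False, reason=why)


def time_domain(
    nn: NnSeries,
    window: tuple[float, float],
    *,
    min_nn: int = MIN_NN_PER_WINDOW,
    min_coverage: float = MIN_COVERAGE,
) -> HrvSummary:
    """AVNN/SDNN/RMSSD/HR over one window.

    The window must contain at least ``min_nn`` retained intervals
    spanning at least ``min_coverage`` of its length, otherwise the
    summary is flagged insufficient with metrics absent.  HR counts the
    detected beats inside the window per minute.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("window end must exceed window start")
    t, x = _window_slice(nn, window)
    cov = float(np.sum(x)) / (hi - lo)
    if len(x) < min_nn or cov < min_coverage:
        return _insufficient(window, len(x), cov, "insufficient_nn")
    beats_in = np.sum((nn.beat_times_ms >= lo) & (nn.beat_times_ms < hi))
    minutes = (hi - lo) / 60000.0
    d = np.diff(x)
    return HrvSummary(
        start_ms=lo,
        end_ms=hi,
        n_nn=len(x),
        coverage=cov,
        valid=True,
        hr=float(beats_in) / minutes,
        avnn=float(np.mean(x)),
        sdnn=float(np.std(x, ddof=1)),
        rmssd=float(np.sqrt(np.mean(d * d))) if len(d) else 0.0,
    )


def freq_domain(
    nn: NnSeries,
    window: tuple[float, float],
    *,
    min_nn: int = MIN_NN_PER_WINDOW,
    min_coverage: float = MIN_COVERAGE,
    f_grid_hz: tuple[float, float, int] = (0.005, 0.5, 2000),
) -> tuple[float | None, float | None, float | None]:
    """Band-integrated LF and HF power (ms²) and their ratio.

    Returns ``(lf, hf, lf_hf)``; all ``None`` when the window fails the
    validity preconditions, and ``lf_hf`` alone ``None`` when HF power
    is degenerate (zero).
    """
    t_ms, x = _window_slice(nn, window)
    cov = float(np.sum(x)) / (window[1] - window[0])
    if len(x) < min_nn or cov < min_coverage:
        return None, None, None
    t = (t_ms - t_ms[0]) / 1000.0
    y = x - np.mean(x)
    var = float(np.var(y))
    if var <= 0:
        return 0.0, 0.0, None
    f_lo, f_hi, n_f = f_grid_hz
    freqs = np.linspace(f_lo, f_hi, n_f)
    pgram = lombscargle(t, y, 2 * np.pi * freqs)
    total = np.trapezoid(pgram, freqs)
    if total <= 0:
        return 0.0, 0.0, None
    psd = pgram * (var / total)  # ms²/Hz; total power over the grid = NN variance
    lf_m = (freqs >= LF_BAND_HZ[0]) & (freqs < LF_BAND_HZ[1])
    hf_m = (freqs >= HF_BAND_HZ[0]) & (freqs <= HF_BAND_HZ[1])
    lf = float(np.trapezoid(psd[lf_m], freqs[lf_m]))
    hf = float(np.trapezoid(psd[hf_m], freqs[hf_m]))
    lf_hf = lf / hf if hf > 0 else None
    return lf, hf, lf_hf


def session_hrv(
    nn: NnSeries,
    windows: list[tuple[float, float]],
    *,
    min_nn: int = MIN_NN_PER_WINDOW,
    min_coverage: float = MIN_COVERAGE,
) -> list[HrvSummary]:
    """One HrvSummary per analysis window of a session.

    Each window gets the time-domain metrics plus Lomb–Scargle band
    powers; windows failing the preconditions come back flagged
    insufficient rather than silently zeroed.
    """
    out: list[HrvSummary] = []
    for w in windows:
        s = time_domain(nn, w, min_nn=min_nn, min_coverage=min_coverage)
        if s.valid:
            s.lf, s.hf, s.lf_hf = freq_domain(nn, w, min_nn=min_nn, min_coverage=min_coverage)
        out.append(s)
    return out
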