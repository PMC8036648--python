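# Methods

This note documents the models, parameter choices and numerical
decisions behind `perimon`, and what the synthetic-data experiments do
and do not demonstrate.

## Signal model and synthetic data

Beat times are generated by integrating an inter-beat-interval (IBI)
process

    IBI(t) = 60000/HR + a_LF sin(2π f_LF t) + a_HF sin(2π f_HF t) + ε,
    ε ~ N(0, σ_jitter²),

with `f_LF ∈ [0.04, 0.15] Hz` and `f_HF ∈ [0.15, 0.4] Hz` — the two
bands short-term HRV analysis integrates. Defaults are HR 70 bpm,
`a_LF` 30 ms at 0.1 Hz, `a_HF` 20 ms at 0.25 Hz and 5 ms white
jitter; these give SDNN/RMSSD in the 20–30 ms range typical of
daytime wrist recordings. Jitter is white; autocorrelated
physiological noise (e.g. 1/f HRV background) is deliberately out of
scope, so spectral estimates on synthetic data are cleaner than on
real recordings.

The waveform renders one symmetric Gaussian pulse (σ = 110 ms) per
beat at the device's 20 Hz rate plus white sample noise. There is no
dicrotic notch — a stated simplification that is irrelevant to
peak-counting analytics at 20 Hz. The first 2 min of a session are
rendered as a low-amplitude pulse train under an exponentially
settling baseline (τ = 30 s), emulating the sensor-calibration
transient; the schedule layer discards this segment unconditionally.
Artifacts corrupt configured intervals: *motion* adds a large
low-passed oscillation overlapping the cardiac band, *flatline* holds
the signal constant, *saturation* clips it at an amplitude rail.
Artifact kind frequencies are free parameters of the generator, not
estimates of any study's observed artifact mix.

Actigraphy is generated per 1-min epoch: Poisson counts at a daytime
level (default 30 counts/min, with a configurable low-count sedentary
stretch), a bed window (default 23:00–07:00) containing a sleep-onset
latency (10 min, restless counts), true sleep (zero counts with a
small deterministic position shift every 45 min so that hour-long
exact-zero runs remain specific to non-wear), and configured
wake-after-sleep-onset (WASO) bursts. Cohort timelines draw daily
wear hours (participant offset + daily noise, clipped to [0, 24]),
Bernoulli questionnaire answers and Poisson blood-pressure counts,
with separate pregnancy/postpartum regimes switching at each
participant's delivery date. Cohort defaults emulate a 28-participant
high-risk pregnancy cohort: wear 17.01 h/day in pregnancy and
13.72 postpartum, answer probabilities 0.675/0.57, BP rates
0.74/0.29 per week, enrollment around gestational week 13.

All generators are deterministic given seed + config, and always
return their ground truth; every recovery test measures against it.

## Quality gating

The band-pass is a 3rd-order Butterworth (0.5–3 Hz) applied forward
and backward (zero phase). Peaks are local maxima above an adaptive
threshold (0.35 × the 95th percentile of |x|, with a proportional
prominence requirement — both scale with the signal, so detection is
amplitude-scale invariant) separated by a 300 ms refractory period.
At 20 Hz the sample spacing is 50 ms, larger than the beat-to-beat
differences RMSSD measures, so each peak is refined by fitting a
parabola through its three surrounding samples; this brings the NN
error to ~12 ms mean absolute on clean synthetic data.

Quality labels tile the stream in non-overlapping 10-s windows (a
balance between temporal resolution and the stability of the
autocorrelation estimate). Rules: *flatline* (window SD below
10⁻⁶ of the stream SD), *clipping* (≥ 5% of samples at the window's
amplitude rail), *rate_gap* (an inter-sample gap above twice the
nominal period), *low_periodicity* (maximum normalized
autocorrelation over cardiac lags 300–1500 ms below 0.45). This is a
transparent, feature-based stand-in for a learned quality classifier;
the interface — a binary per-window label — is what the rest of the
pipeline depends on, so a trained model can be swapped in.

NN filtering drops intervals outside 300–2000 ms, intervals deviating
more than 20% from the median of the previous five retained intervals
(the standard ectopic-beat heuristic), and intervals overlapping an
unreliable window. Filtering can only remove intervals, and the
removed fraction is always recorded.

## HRV

SDNN uses the n−1 denominator. HR is the count of detected beats in
the window normalized to beats/min. A window is valid with ≥ 30
retained NN intervals covering ≥ 50% of its length; failing windows
are flagged insufficient with metrics absent, never silently zero.
These thresholds bound estimator variance for 5-min windows; they are
design choices.

Spectral power uses the Lomb–Scargle periodogram evaluated directly on
the unevenly spaced beat times — interpolation + FFT was the
considered alternative and was rejected because interpolation biases
the spectrum when the removed fraction is high. The periodogram is
evaluated on 2000 frequencies over 0.005–0.5 Hz and normalized so its
integral equals the NN variance (ms²); LF and HF are then band
integrals over [0.04, 0.15) and [0.15, 0.4] Hz (half-open at 0.15 Hz
to avoid double counting). With broadband jitter this attributes all
in-grid variance to the grid, which slightly inflates absolute band
powers but leaves band fractions and LF/HF nearly unbiased — the
quantities the analytics consume.

## Schedule and energy

The session plan enforces `calibration + windows × window = session`
at construction (2 + 2×5 = 12 min by default) and sessions start
every `interval` minutes anchored at local midnight (the anchoring is
a convention). Window selection keeps the window with the larger
fraction of reliable labels, ties toward the earlier window, and
yields nothing when both windows fall below 50% reliable — one
HRV point per session at most. Merging two clean windows was the
considered alternative; keep-best-one is implemented.

Battery life is modelled as `capacity / (idle + extra·duty)` with
`duty = session/interval`. The model is scale-invariant in its three
parameters, so capacity is normalized to 1 and the two power terms are
fitted by ordinary least squares on inverse lifetime (linear in duty).
With the two measured points (15 min → 25 h, 240 min → 157 h) the fit
is exact and predicts 116.1 h at the 2-h interval and an idle-only
asymptote of 242.3 h. The calibration points come from flight-mode
bench measurements; radio, display and app overhead are explicitly
outside the model, so real-use lifetimes are shorter.

## Sleep and activity

Non-wear is a run of ≥ 60 consecutive exact-zero 1-min epochs — the
standard actigraphy heuristic. Sleep/wake is a center-weighted moving
average over epochs t−4…t+2 with weights
(0.01, 0.01, 0.02, 0.04, 0.20, 0.04, 0.02) against threshold 1 — a
stand-in in the Cole–Kripke family with weights rescaled to
tens-of-counts wrist data and chosen so that a high-count wake burst
spills at most ~2 epochs into its neighbours (keeping WASO bias under
5 min). Sleep onset is the first run of ≥ 10 sleep epochs inside the
externally supplied bed window; TST counts sleep epochs from onset,
WASO counts wake epochs between onset and the final awakening,
SE = 100·TST/time-in-bed. Bed windows must be supplied (config or
per-day file); automatic bed-window inference is out of scope.
Sedentary time is worn, awake epochs below 10 counts/min.

## Adherence

Days align on gestational week during pregnancy (enrollment
gestational age + elapsed weeks, floored) and on weeks since delivery
postpartum, with the delivery day opening postpartum week 1. Phase
wear means weight participants equally (per-participant daily means,
then cohort mean ± SD across participants); the reported SD is
therefore a between-participant SD — a day-weighted alternative is
available by flag. Answer rate is answered days over observed days;
BP rate is total measurements over observed weeks. Censored
participants contribute through their last observed day. Weekly
curves record n_contributing and support an exclusion list so a
single outlying participant can be removed before averaging without
touching anyone else's contribution.

## Imputation, baselines, anomalies

Metric series are slot-indexed: one slot per scheduled session for
HRV metrics, one per day for sleep/activity. Imputation fits a linear
model on day index and time-of-day harmonics to the observed slots and
corrects each prediction by the inverse-distance-weighted mean
residual of the 5 nearest observed slots; missing runs spanning more
than 3 days stay missing and are flagged unimputable, and series with
under 20% observed slots are rejected with advice to exclude.

The personal baseline for a slot is purely trailing: the median of
same-time-of-day values over the preceding 14 days, with dispersion
estimated as a pooled scaled MAD — every point in the trailing window
contributes its absolute deviation from its own time-of-day bin's
median, and 1.4826 × the median of those deviations estimates the
noise scale. Time-of-day bins are 6 h wide (four per day): at 12
sessions/day this yields ~40 points per bin median and ~160 per
dispersion estimate, which keeps the false-flag rate of a clean
Gaussian series near the nominal two-sided 3σ tail (measured ≈ 0.4–0.8%,
within the 1% budget) where a per-bin MAD over ~40 points would not.
A slot is scored as `(value − expected)/max(dispersion, floor)` with
the floor at 1% of |expected|; |score| > 3 flags it, and flagged HRV
metrics carry a direction annotation (e.g. elevated LF/HF — the
stress direction). Imputed values stabilize baselines but are never
themselves scored, and baselines see imputed-then-observed history
(imputation feeds baseline modelling; feeding raw series instead was
the considered alternative).

## Problem sizes

The test suite and acceptance script run 100 five-minute sessions for
HRV recovery, 50 seeds × 4 sampling rates for the rate contract,
50 actigraphy nights, a 100-participant simulated cohort, and a
28-day single-participant pipeline run with a one-week injected
anomaly — sizes at which the binomial/Poisson sampling error of the
recovered quantities is a few percent, matching the stated tolerances.

## Known limitations

- The PPG waveform and artifact models are morphology-light; passing
  recovery tests shows the analytics are correct under the stated
  signal model, not that they match any specific device's artifact
  mix.
- Sleep scoring is not validated against polysomnography; only
  internal consistency and synthetic recovery are claimed.
- The energy model omits radio/app overhead and adaptive duty cycling.
- Long-term (24-h) HRV is out of scope by design: the duty-cycled
  schedule yields short-term windows only.
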