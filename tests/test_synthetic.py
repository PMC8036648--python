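"""Generator properties: determinism, ground-truth consistency, artifact shape."""

import numpy as np
import pytest

import perimon as pm
from perimon.synthetic import ConfigError


def _cfg(**kw):
    base = dict(
        mean_hr=60.0,
        lf_mod=pm.Modulation(0.1, 0.0),
        hf_mod=pm.Modulation(0.25, 0.0),
        ibi_jitter_ms=0.0,
        calibration_s=0.0,
        seed=0,
    )
    base.update(kw)
    return pm.PpgSimConfig(**base)


class TestBeatTimes:
    def test_constant_rate(self):
        truth = pm.simulate_beat_times(_cfg(), 60.0)
        assert len(truth.beat_times_s) == 60
        assert np.allclose(truth.ibis_ms, 1000.0)

    def test_lf_sinusoid_sd_matches_rms(self):
        # sample SD of a sinusoidal IBI series is amp/sqrt(2)
        truth = pm.simulate_beat_times(
            _cfg(mean_hr=75.0, lf_mod=pm.Modulation(0.1, 40.0)), 300.0
        )
        assert np.std(truth.ibis_ms, ddof=1) == pytest.approx(40.0 / np.sqrt(2), rel=0.10)

    def test_determinism(self):
        cfg = _cfg(ibi_jitter_ms=8.0, seed=5)
        a = pm.simulate_beat_times(cfg, 120.0)
        b = pm.simulate_beat_times(cfg, 120.0)
        assert np.array_equal(a.beat_times_s, b.beat_times_s)
        assert np.array_equal(a.ibis_ms, b.ibis_ms)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(mean_hr=-10.0),
            dict(mean_hr=40.0, lf_mod=pm.Modulation(0.1, 900.0), hf_mod=pm.Modulation(0.25, 700.0)),
            dict(sampling_rate=0.0),
        ],
    )
    def test_nonphysiological_config_rejected(self, bad):
        with pytest.raises(ConfigError):
            _cfg(**bad)


class TestRenderPpg:
    def test_round_trip_peak_count(self):
        cfg = _cfg(mean_hr=60.0, noise_sd=0.02, seed=1)
        truth = pm.simulate_beat_times(cfg, 11.0)
        assert len(truth.beat_times_s) == 11
        ts, x = pm.render_ppg(truth.beat_times_s, cfg, 11.0)
        beats = pm.detect_peaks(pm.bandpass_cardiac(pm.PpgStream(ts, x, 20.0)))
        assert abs(len(beats) - 11) <= 1

    def test_flatline_segment_has_zero_variance(self):
        cfg = _cfg(artifacts=(pm.Artifact(30.0, 30.0, "flatline"),), seed=2)
        truth = pm.simulate_beat_times(cfg, 90.0)
        ts, x = pm.render_ppg(truth.beat_times_s, cfg, 90.0)
        seg = x[(ts >= 30000.0) & (ts < 60000.0)]
        assert np.all(seg == seg[0])

    def test_clean_hr_recovery_within_1_bpm(self):
        # count beats over an interior 60-s window so filter edges don't bias
        cfg = _cfg(mean_hr=70.0, noise_sd=0.05, ibi_jitter_ms=5.0, seed=3)
        ts, x, truth = pm.simulate_session(cfg, 80.0)
        nn, _ = pm.stream_to_nn(pm.PpgStream(ts, x, 20.0))
        w = (10000.0, 70000.0)
        hr = np.sum((nn.beat_times_ms >= w[0]) & (nn.beat_times_ms < w[1]))
        true_hr = np.sum((truth.beat_times_s >= 10.0) & (truth.beat_times_s < 70.0))
        assert abs(hr - true_hr) <= 1.0

    def test_spectral_peak_at_cardiac_frequency(self):
        from scipy.signal import periodogram

        cfg = _cfg(mean_hr=72.0, noise_sd=0.0, seed=4)
        ts, x, _ = pm.simulate_session(cfg, 300.0)
        f, p = periodogram(x - x.mean(), fs=20.0)
        band = (f > 0.5) & (f < 3.0)
        assert f[band][np.argmax(p[band])] == pytest.approx(72.0 / 60.0, abs=0.05)

    def test_artifact_beyond_duration_rejected(self):
        with pytest.raises(ConfigError):
            cfg = _cfg(artifacts=(pm.Artifact(50.0, 30.0, "motion"),))
            pm.render_ppg(np.arange(0, 60.0), cfg, 60.0)


class TestActigraphy:
    def test_ground_truth_bookkeeping(self):
        cfg = pm.ActigraphySimConfig(
            true_tst_min=480.0,
            sleep_latency_min=0.0,
            waso_episodes=(),
            bed_start_min=23 * 60.0,
            bed_end_min=7 * 60.0,
            seed=0,
        )
        _, truth = pm.simulate_actigraphy(cfg, 1)
        assert truth.tst_min == 480.0
        assert truth.waso_min == 0.0

    def test_waso_episode_truth(self):
        cfg = pm.ActigraphySimConfig(waso_episodes=(pm.WasoEpisode(120.0, 20.0),), seed=0)
        _, truth = pm.simulate_actigraphy(cfg, 1)
        assert truth.waso_min == 20.0

    def test_nonwear_truth(self):
        cfg = pm.ActigraphySimConfig(nonwear_blocks=(pm.NonwearBlock(13 * 60.0, 120.0),), seed=0)
        frame, truth = pm.simulate_actigraphy(cfg, 1)
        assert truth.wear_h[0] == 22.0
        nw = frame[(frame.timestamp_min >= 13 * 60) & (frame.timestamp_min < 15 * 60)]
        assert (nw.counts == 0).all() and (~nw.worn).all()

    def test_overlapping_nonwear_rejected(self):
        with pytest.raises(ConfigError):
            pm.ActigraphySimConfig(
                nonwear_blocks=(pm.NonwearBlock(60.0, 120.0), pm.NonwearBlock(100.0, 60.0))
            )

    def test_oversubscribed_bed_window_rejected(self):
        with pytest.raises(ConfigError):
            pm.ActigraphySimConfig(true_tst_min=470.0, waso_episodes=(pm.WasoEpisode(60.0, 60.0),))


class TestCohort:
    def test_answer_fraction_recovery(self):
        cfg = pm.CohortSimConfig(n_participants=100, answer_prob_pregnancy=0.675, seed=1)
        rec, meta, _ = pm.simulate_cohort(cfg)
        from perimon.adherence import CohortTimeline, align_weeks

        df = align_weeks(CohortTimeline(rec, meta))
        frac = df.loc[df.phase == "pregnancy", "answered"].mean()
        assert frac == pytest.approx(0.675, abs=0.03)

    def test_zero_noise_wear_constant(self):
        cfg = pm.CohortSimConfig(
            n_participants=3, wear_participant_sd=0.0, wear_day_sd=0.0, seed=2
        )
        rec, meta, _ = pm.simulate_cohort(cfg)
        from perimon.adherence import CohortTimeline, align_weeks

        df = align_weeks(CohortTimeline(rec, meta))
        preg = df[df.phase == "pregnancy"]
        assert np.allclose(preg["wear_h"], cfg.wear_pregnancy_mean)

    def test_bp_rate_recovery(self):
        cfg = pm.CohortSimConfig(n_participants=100, bp_rate_pregnancy=0.74, seed=3)
        rec, meta, _ = pm.simulate_cohort(cfg)
        from perimon.adherence import CohortTimeline, phase_summary

        s = phase_summary(CohortTimeline(rec, meta))["pregnancy"]
        assert s.bp_per_week == pytest.approx(0.74, rel=0.10)

    def test_determinism(self):
        cfg = pm.CohortSimConfig(n_participants=5, seed=9)
        a, am, _ = pm.simulate_cohort(cfg)
        b, bm, _ = pm.simulate_cohort(cfg)
        assert a.equals(b) and am.equals(bm)
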