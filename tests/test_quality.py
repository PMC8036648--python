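"""Quality chain: cardiac band-pass, peak detection, labelling, NN filtering."""

import numpy as np
import pytest

import perimon as pm
from perimon.quality import to_nn


def _tone(freq_hz, duration_s=300.0, fs=20.0):
    t = np.arange(int(duration_s * fs)) / fs
    return pm.PpgStream(t * 1000.0, np.sin(2 * np.pi * freq_hz * t), fs)


class TestBandpass:
    def test_baseline_wander_attenuated_20db(self):
        out = pm.bandpass_cardiac(_tone(0.1))
        # compare RMS in the steady-state middle to avoid filter edges
        sl = slice(1000, -1000)
        ratio = np.std(out.samples[sl]) / np.std(_tone(0.1).samples[sl])
        assert 20 * np.log10(ratio) <= -20.0

    def test_cardiac_tone_passes(self):
        out = pm.bandpass_cardiac(_tone(1.2))
        sl = slice(1000, -1000)
        ratio = np.std(out.samples[sl]) / np.std(_tone(1.2).samples[sl])
        assert 20 * np.log10(ratio) >= -1.0

    def test_constant_input_zeroed(self):
        t = np.arange(600) * 50.0
        out = pm.bandpass_cardiac(pm.PpgStream(t, np.full(600, 3.3), 20.0))
        assert np.allclose(out.samples, 0.0, atol=1e-9)

    def test_short_stream_rejected_with_minimum_named(self):
        t = np.arange(100) * 50.0
        with pytest.raises(ValueError, match="10"):
            pm.bandpass_cardiac(pm.PpgStream(t, np.random.default_rng(0).normal(size=100), 20.0))


class TestDetectPeaks:
    def test_clean_70bpm_count(self, clean_window):
        stream, truth, _ = clean_window
        beats = pm.detect_peaks(pm.bandpass_cardiac(stream))
        assert abs(len(beats) - len(truth.beat_times_s)) <= 1

    def test_flatline_yields_no_peaks(self):
        t = np.arange(1200) * 50.0
        assert len(pm.detect_peaks(pm.PpgStream(t, np.zeros(1200), 20.0))) == 0

    def test_amplitude_scale_invariance(self, clean_window):
        stream, _, _ = clean_window
        bp = pm.bandpass_cardiac(stream)
        a = pm.detect_peaks(bp)
        b = pm.detect_peaks(pm.PpgStream(bp.timestamps_ms, bp.samples * 10.0, bp.nominal_rate))
        assert np.array_equal(a, b)

    def test_subsample_refinement_beats_quantization(self, clean_nn):
        # mean absolute NN error must be below the 50 ms sample period
        nn, _, truth = clean_nn
        true_t = truth.beat_times_s * 1000.0
        idx = np.clip(np.searchsorted(true_t[1:], nn.nn_times_ms), 0, len(truth.ibis_ms) - 1)
        mae = np.mean(np.abs(nn.nn_ms - truth.ibis_ms[idx]))
        assert mae < 15.0


class TestAssessQuality:
    def test_clean_windows_reliable(self, clean_window):
        stream, _, _ = clean_window
        labels = pm.assess_quality(stream)
        assert all(l.reliable for l in labels)

    def test_labels_tile_stream(self, clean_window):
        stream, _, _ = clean_window
        labels = pm.assess_quality(stream)
        for a, b in zip(labels, labels[1:]):
            assert a.end_ms == b.start_ms
        assert labels[0].start_ms == stream.timestamps_ms[0]
        assert labels[-1].end_ms >= stream.timestamps_ms[-1]

    @pytest.mark.parametrize(
        "kind,reason",
        [("flatline", "flatline"), ("saturation", "clipping"), ("motion", "low_periodicity")],
    )
    def test_artifact_reason(self, kind, reason):
        cfg = pm.PpgSimConfig(
            mean_hr=70.0, calibration_s=0.0, artifacts=(pm.Artifact(40.0, 30.0, kind),), seed=8
        )
        ts, x, _ = pm.simulate_session(cfg, 120.0)
        labels = pm.assess_quality(pm.PpgStream(ts, x, 20.0))
        mid = [l for l in labels if l.start_ms >= 40000.0 and l.end_ms <= 70000.0]
        assert mid and all(not l.reliable and reason in l.reasons for l in mid)

    def test_motion_sensitivity(self):
        # >= 90% of fully motion-corrupted 10-s windows must be flagged
        hits = total = 0
        for seed in range(50):
            cfg = pm.PpgSimConfig(
                mean_hr=70.0,
                calibration_s=0.0,
                artifacts=(pm.Artifact(40.0, 40.0, "motion"),),
                seed=seed,
            )
            ts, x, _ = pm.simulate_session(cfg, 120.0)
            for l in pm.assess_quality(pm.PpgStream(ts, x, 20.0)):
                if l.start_ms >= 40000.0 and l.end_ms <= 80000.0:
                    total += 1
                    hits += not l.reliable
        assert total == 200
        assert hits / total >= 0.90

    def test_rate_gap_detected(self):
        t = np.arange(600) * 50.0
        t[300:] += 300.0  # a 350 ms hole in an otherwise regular stream
        x = np.sin(2 * np.pi * 1.2 * t / 1000.0)
        labels = pm.assess_quality(pm.PpgStream(t, x, 20.0))
        assert any("rate_gap" in l.reasons for l in labels)


class TestToNn:
    def test_regular_beats(self):
        nn = to_nn(np.array([0.0, 800.0, 1600.0, 2400.0]))
        assert np.allclose(nn.nn_ms, [800.0, 800.0, 800.0])
        assert nn.removed_fraction == 0.0

    def test_double_detection_removed(self):
        nn = to_nn(np.array([0.0, 800.0, 950.0, 1750.0, 2550.0]))
        assert 150.0 not in nn.nn_ms
        assert nn.removed_fraction == pytest.approx(0.25)

    def test_ectopic_20pct_rule(self):
        beats = np.concatenate([np.arange(0, 8000.0, 800.0), [8400.0, 9200.0]])
        nn = to_nn(beats)  # the 1200 ms interval deviates 50% from the running median
        assert 1200.0 not in nn.nn_ms

    def test_unreliable_window_overlap_removed(self):
        labels = [
            pm.QualityLabel(0.0, 1000.0, True),
            pm.QualityLabel(1000.0, 2000.0, False, ("flatline",)),
            pm.QualityLabel(2000.0, 3200.0, True),
        ]
        nn = to_nn(np.array([0.0, 800.0, 1600.0, 2400.0, 3200.0]), labels)
        # intervals [800,1600] and [1600,2400] overlap the bad window
        assert np.allclose(nn.nn_ms, [800.0])

    def test_clean_session_low_removal(self, clean_nn):
        nn, _, _ = clean_nn
        assert nn.removed_fraction < 0.05

    def test_filtering_never_increases_count(self, clean_nn):
        nn, _, _ = clean_nn
        assert len(nn.nn_ms) <= len(nn.beat_times_ms) - 1
        assert np.all((nn.nn_ms >= 300.0) & (nn.nn_ms <= 2000.0))

    def test_fewer_than_two_beats_empty(self):
        nn = to_nn(np.array([500.0]))
        assert len(nn) == 0


class TestPpgStream:
    def test_rate_contract_enforced(self):
        t = np.arange(600) * 80.0  # 12.5 Hz effective vs 20 nominal
        with pytest.raises(ValueError, match="20%"):
            pm.PpgStream(t, np.zeros(600), 20.0)

    def test_nonmonotone_rejected(self):
        t = np.array([0.0, 50.0, 40.0, 100.0])
        with pytest.raises(ValueError):
            pm.PpgStream(t, np.zeros(4), 20.0)
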