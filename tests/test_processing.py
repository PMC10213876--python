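"""Measurement chain: R-peak detection, templates, tangent T-end."""

import numpy as np
import pytest

from qtiholter import (BeatTemplate, ECGRecording, build_templates,
                       detect_r_peaks, generate_recording, locate_qrs_onset,
                       locate_t_end_tangent, measure_recording,
                       synthesize_beat)
from qtiholter.simulate import _PRE_ONSET_MS, R_OFFSET_MS

from conftest import CLEAN, make_profile


def truth_r_samples(rec, truth):
    return (truth.beats.r_peak_s * rec.fs_hz).round().astype(int).to_numpy()


def beat_template(waveform, fs, mean_rr_ms=900.0):
    onset = int(round(_PRE_ONSET_MS * fs / 1000.0))
    r = onset + int(round(R_OFFSET_MS * fs / 1000.0))
    return BeatTemplate(waveform=waveform, window_index=0, window_start_s=0.0,
                        n_beats_averaged=20, mean_rr_ms=mean_rr_ms,
                        channel_used=0, fs_hz=fs, r_sample=r)


class TestDetectRPeaks:
    def test_every_truth_peak_matched_within_one_sample(self, clean_recording):
        _, rec, truth = clean_recording
        peaks = detect_r_peaks(rec, 0)
        tr = truth_r_samples(rec, truth)
        assert len(peaks) == len(tr)
        assert np.max(np.abs(peaks - tr)) <= 1

    def test_recall_precision_under_noise(self):
        p = make_profile()  # default noise, wander, ectopy
        rec, truth = generate_recording(p, 600.0,
                                        rng=np.random.default_rng(8))
        peaks = detect_r_peaks(rec, 0)
        tr = truth_r_samples(rec, truth)
        tol = int(0.05 * rec.fs_hz)
        d_truth = np.abs(tr[:, None] - peaks[None, :]).min(axis=1)
        d_det = np.abs(peaks[:, None] - tr[None, :]).min(axis=1)
        assert (d_truth <= tol).mean() >= 0.999  # recall
        assert (d_det <= tol).mean() >= 0.999  # precision

    def test_zero_signal_warns_and_returns_empty(self):
        rec = ECGRecording(np.zeros((1, 5000)), fs_hz=200.0)
        with pytest.warns(UserWarning):
            peaks = detect_r_peaks(rec, 0)
        assert peaks.size == 0

    def test_beat_count_bookkeeping(self, clean_recording):
        _, rec, truth = clean_recording
        peaks = detect_r_peaks(rec, 0)
        # sum-of-intervals oracle: duration over realized mean RR
        expected = rec.duration_s * 1000.0 / truth.beats.rr_ms.mean()
        assert abs(len(peaks) - expected) / expected < 0.01


class TestBuildTemplates:
    def test_sixty_second_recording_gives_two_templates(self):
        p = make_profile(**CLEAN)
        rec, _ = generate_recording(p, 60.0, rng=np.random.default_rng(0))
        peaks = detect_r_peaks(rec, 0)
        templates, _ = build_templates(rec, peaks)
        assert len(templates) == 2

    def test_window_count_never_exceeds_ceiling(self, clean_recording):
        _, rec, _ = clean_recording
        peaks = detect_r_peaks(rec, 0)
        templates, _ = build_templates(rec, peaks)
        assert len(templates) <= int(np.ceil(rec.duration_s / 30.0))

    def test_identical_beats_average_to_a_single_beat(self):
        p = make_profile(**CLEAN, rr_circadian_amp=0.0, rr_short_term_sd=0.0)
        rec, _ = generate_recording(p, 90.0, rng=np.random.default_rng(0))
        peaks = detect_r_peaks(rec, 0)
        templates, _ = build_templates(rec, peaks)
        fs = rec.fs_hz
        single = synthesize_beat(p.alpha_true * p.rr_mean + p.beta_true,
                                 p.rr_mean, p, fs)
        # overlap region: template starts 300 ms before R, beat 200 ms
        tmpl = templates[0]
        off = int(0.1 * fs)  # template leads the beat render by 100 ms
        n = len(single)
        assert np.max(np.abs(tmpl.waveform[off:off + n] - single)) < 5e-3

    def test_averaging_reduces_white_noise_as_sqrt_n(self):
        p = make_profile(**CLEAN, rr_circadian_amp=0.0, rr_short_term_sd=0.0)
        rec, _ = generate_recording(p, 90.0, rng=np.random.default_rng(1))
        clean = rec.signal.copy()
        sigma = 0.05
        rec.signal = clean + np.random.default_rng(2).normal(
            0.0, sigma, clean.shape).astype(np.float32)
        peaks = detect_r_peaks(rec, 0)
        templates, _ = build_templates(rec, peaks)
        rec_clean = ECGRecording(clean, fs_hz=rec.fs_hz)
        templates_clean, _ = build_templates(rec_clean, peaks)
        resid = templates[0].waveform - templates_clean[0].waveform
        n = templates[0].n_beats_averaged
        expected = sigma / np.sqrt(n)
        assert 0.5 * expected < resid.std() < 1.6 * expected

    def test_mean_rr_matches_truth_window_nn(self, clean_recording):
        _, rec, truth = clean_recording
        peaks = detect_r_peaks(rec, 0)
        templates, _ = build_templates(rec, peaks)
        tr = truth_r_samples(rec, truth)
        for tmpl in templates:
            w0 = tmpl.window_start_s * rec.fs_hz
            w1 = w0 + 30.0 * rec.fs_hz
            rs = tr[(tr >= w0) & (tr < w1)]
            nn = np.diff(rs) / rec.fs_hz * 1000.0
            assert tmpl.mean_rr_ms == pytest.approx(nn.mean(), abs=2.0)

    def test_ectopic_beats_are_rejected_from_average(self):
        p = make_profile(qt_noise_sd=0.0, noise_sd=0.0, wander_amp=0.0,
                         ectopy_rate=0.15, rr_circadian_amp=0.0,
                         rr_short_term_sd=0.0)
        rec, truth = generate_recording(p, 60.0,
                                        rng=np.random.default_rng(9))
        n_ectopic = int(truth.beats.ectopic.sum())
        assert n_ectopic > 0
        peaks = detect_r_peaks(rec, 0)
        templates, _ = build_templates(rec, peaks)
        total_averaged = sum(t.n_beats_averaged for t in templates)
        assert total_averaged <= len(truth.beats) - n_ectopic + 2


class TestQRSOnset:
    def test_onset_within_one_sample_of_truth(self, clean_recording):
        p, rec, truth = clean_recording
        peaks = detect_r_peaks(rec, 0)
        templates, _ = build_templates(rec, peaks)
        fs = rec.fs_hz
        true_offset = int(round(R_OFFSET_MS * fs / 1000.0))
        for tmpl in templates:
            onset = locate_qrs_onset(tmpl)
            assert onset is not None
            assert abs((tmpl.r_sample - onset) - true_offset) <= 1

    def test_flat_template_fails(self):
        tmpl = beat_template(np.zeros(220), fs=200.0)
        assert locate_qrs_onset(tmpl) is None


class TestTangentTEnd:
    def test_triangular_t_wave_closed_form(self):
        """A straight descending limb is its own tangent: the detected
        T end must equal the limb's baseline crossing exactly."""
        fs = 200.0
        w = np.zeros(260)
        r = 68
        w[r] = 1.0  # minimal QRS spike so the template has an R
        apex, h, end = 130, 0.4, 170
        up = np.arange(100, apex)
        w[up] = h * (up - 100) / (apex - 100)
        down = np.arange(apex, end)
        w[down] = h * (end - down) / (end - apex)
        tmpl = BeatTemplate(waveform=w, window_index=0, window_start_s=0.0,
                            n_beats_averaged=20, mean_rr_ms=950.0,
                            channel_used=0, fs_hz=fs, r_sample=r)
        t_end, quality = locate_t_end_tangent(tmpl, qrs_onset=60)
        assert quality == "ok"
        assert t_end == pytest.approx(end, abs=1e-6)

    @pytest.mark.parametrize("qt,rr", [(340.0, 700.0), (400.0, 900.0),
                                       (480.0, 1100.0), (560.0, 1200.0)])
    def test_programmed_qt_recovered_within_one_sample(self, qt, rr):
        p = make_profile(**CLEAN)
        fs = 200.0
        w = synthesize_beat(qt, rr, p, fs)
        tmpl = beat_template(w, fs, mean_rr_ms=rr)
        onset = locate_qrs_onset(tmpl)
        t_end, quality = locate_t_end_tangent(tmpl, onset)
        assert quality == "ok"
        measured = (t_end - onset) / fs * 1000.0
        assert abs(measured - qt) <= 1000.0 / fs  # one sample

    def test_zero_amplitude_t_gives_no_t_wave(self):
        p = make_profile(t_amplitude=0.0, noise_sd=0.0, wander_amp=0.0)
        w = synthesize_beat(400.0, 900.0, p, 200.0)
        tmpl = beat_template(w, 200.0)
        onset = locate_qrs_onset(tmpl)
        _, quality = locate_t_end_tangent(tmpl, onset)
        assert quality == "no_t_wave"

    def test_inverted_t_wave_measured(self):
        p = make_profile(t_amplitude=-0.35, noise_sd=0.0, wander_amp=0.0)
        w = synthesize_beat(400.0, 900.0, p, 200.0)
        tmpl = beat_template(w, 200.0)
        onset = locate_qrs_onset(tmpl)
        t_end, quality = locate_t_end_tangent(tmpl, onset)
        assert quality == "ok"
        assert (t_end - onset) / 200.0 * 1000.0 == pytest.approx(400.0, abs=5.0)


class TestMeasureRecording:
    def test_clean_recording_every_window_ok(self, clean_recording):
        _, rec, _ = clean_recording
        meas, report = measure_recording(rec, min_useful_h=0.1)
        assert report.status == "ok"
        n_windows = int(np.ceil(rec.duration_s / 30.0))
        assert report.quality_counts.get("ok", 0) == n_windows
        assert all(m.quality == "ok" for m in meas)

    def test_three_hour_recording_marked_invalid(self):
        p = make_profile(**CLEAN)
        rec, _ = generate_recording(p, 3 * 3600.0,
                                    rng=np.random.default_rng(2))
        _, report = measure_recording(rec)
        assert report.status == "invalid"
        assert "4" in report.reason and "useful" in report.reason

    def test_qt_over_700_everywhere_gives_zero_ok_and_invalid(self):
        p = make_profile(alpha_true=0.0, beta_true=720.0, rr_mean=1000.0,
                         rr_circadian_amp=40.0, **CLEAN)
        rec, _ = generate_recording(p, 1800.0,
                                    rng=np.random.default_rng(3))
        meas, report = measure_recording(rec, min_useful_h=0.2)
        assert report.status == "invalid"
        assert report.quality_counts.get("ok", 0) == 0
        assert report.quality_counts.get("qt_gt_700", 0) > 0

    def test_no_ok_measurement_exceeds_700(self, clean_recording):
        _, rec, _ = clean_recording
        meas, _ = measure_recording(rec, min_useful_h=0.1)
        for m in meas:
            if m.quality == "ok":
                assert 100.0 < m.qt_ms <= 700.0

    def test_measured_qt_matches_truth_windows(self, clean_recording):
        """End-to-end fidelity: noise-free measured QT within one sample
        of the ground-truth window mean for >= 99% of templates."""
        _, rec, truth = clean_recording
        meas, _ = measure_recording(rec, min_useful_h=0.1)
        tb = truth.beats.copy()
        tb["w"] = (tb.r_peak_s // 30).astype(int)
        gt = tb.groupby("w").qt_ms.mean()
        errs = np.array([abs(m.qt_ms - gt[m.window_index])
                         for m in meas if m.quality == "ok"])
        one_sample_ms = 1000.0 / rec.fs_hz
        assert (errs <= one_sample_ms).mean() >= 0.99
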