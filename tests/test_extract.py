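import dataclasses
import math

import numpy as np
import pytest

from conftest import contralateral_template, vertex_template
from noxep.eeg_sim import (
    SFREQ,
    Component,
    EPGroundTruth,
    StimulusTrain,
    powerlaw_noise,
    synthesize_session,
)
from noxep.extract import (
    ComponentResult,
    ROIWindows,
    detect_n1,
    detect_vertex_components,
    extract_session,
    n2_onset_ms,
    presence_threshold_uv,
    session_snr,
)
from noxep.preprocess import EpochSet

CHANNELS = ("Cz", "C3", "C4", "Fz", "A1", "A2")


def brute_force_extrema(trace, times_ms, window, sign):
    """Independent oracle: explicit scan over every sample in the window."""
    best_val, best_t = None, None
    for t, v in zip(times_ms, trace):
        if window[0] <= t < window[1]:
            if best_val is None or sign * v > sign * best_val:
                best_val, best_t = v, t
    return best_t, best_val


class TestSessionSNR:
    def _trace(self, pre_amp, post_amp, times_ms, roi):
        trace = np.zeros_like(times_ms)
        trace[times_ms < 0] = pre_amp
        post = (times_ms >= roi.snr_roi[0]) & (times_ms < roi.snr_roi[1])
        trace[post] = post_amp
        return trace

    def test_rms_ratio_2_gives_6db(self, times_ms):
        roi = ROIWindows.for_modality("lep")
        trace = self._trace(1.0, 2.0, times_ms, roi)
        assert session_snr(trace, times_ms, roi) == pytest.approx(20 * math.log10(2), abs=1e-9)

    def test_rms_ratio_1_gives_0db(self, times_ms):
        roi = ROIWindows.for_modality("chep")
        trace = self._trace(1.0, 1.0, times_ms, roi)
        assert session_snr(trace, times_ms, roi) == pytest.approx(0.0, abs=1e-9)

    def test_sqrt2_ratio_sits_at_3db_boundary(self, times_ms):
        roi = ROIWindows.for_modality("lep")
        trace = self._trace(1.0, math.sqrt(2), times_ms, roi)
        assert session_snr(trace, times_ms, roi) == pytest.approx(10 * math.log10(2), abs=1e-9)

    def test_zero_pre_trigger_rms_is_degenerate(self, times_ms):
        roi = ROIWindows.for_modality("lep")
        trace = self._trace(0.0, 1.0, times_ms, roi)
        with pytest.raises(ValueError, match="degenerate"):
            session_snr(trace, times_ms, roi)


class TestROIWindows:
    def test_modality_windows(self):
        assert ROIWindows.for_modality("lep").snr_roi == (150.0, 550.0)
        assert ROIWindows.for_modality("chep").snr_roi == (300.0, 650.0)

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            ROIWindows("lep", (150, 550), (300, 150), (250, 450))
        with pytest.raises(ValueError):
            ROIWindows("lep", (150, 550), (300, 400), (200, 450))


class TestVertexDetection:
    def test_matches_brute_force_scan_on_random_traces(self, times_ms):
        """Vectorized N2/P2 detection equals an explicit per-sample scan,
        including the P2-after-N2 constraint."""
        roi = ROIWindows.for_modality("lep")
        rng = np.random.default_rng(123)
        for _ in range(20):
            trace = powerlaw_noise((times_ms.size,), rng, rms=5.0)
            n2, p2 = detect_vertex_components(trace, times_ms, roi, presence_multiplier=0.0)
            t_n2, v_n2 = brute_force_extrema(trace, times_ms, roi.search_n2, sign=-1)
            assert n2.latency_ms == t_n2 and n2.amplitude_uv == v_n2
            t_p2, v_p2 = brute_force_extrema(
                trace, times_ms, (max(roi.search_p2[0], np.nextafter(t_n2, np.inf)), roi.search_p2[1]), sign=+1
            )
            assert p2.latency_ms == t_p2 and p2.amplitude_uv == v_p2

    def test_noiseless_chep_recovery(self, noiseless_chep, times_ms):
        """Noiseless calibrated CHEP trace: detected N2/P2 equal the composite
        template's extrema exactly and the bump centres closely."""
        trace = vertex_template(noiseless_chep, times_ms)
        roi = ROIWindows.for_modality("chep")
        n2, p2 = detect_vertex_components(trace, times_ms, roi)
        t_n2, v_n2 = brute_force_extrema(trace, times_ms, roi.search_n2, -1)
        assert n2.present and p2.present
        assert abs(n2.latency_ms - t_n2) <= 1000 / SFREQ
        assert n2.amplitude_uv == pytest.approx(v_n2, abs=1e-9)
        assert n2.latency_ms == pytest.approx(392.0, abs=3.0)
        assert p2.latency_ms == pytest.approx(494.0, abs=3.0)
        assert n2.amplitude_uv == pytest.approx(-10.6, rel=0.05)
        assert p2.amplitude_uv == pytest.approx(13.0, rel=0.05)

    def test_flat_post_stimulus_trace_reports_absences(self, times_ms):
        rng = np.random.default_rng(5)
        trace = np.zeros_like(times_ms)
        pre = times_ms < 0
        trace[pre] = rng.normal(0, 2.0, pre.sum())
        n2, p2 = detect_vertex_components(trace, times_ms, ROIWindows.for_modality("lep"))
        assert not n2.present and not p2.present
        assert n2.amplitude_uv == 0.0 and p2.amplitude_uv == 0.0
        assert math.isnan(n2.latency_ms) and math.isnan(p2.latency_ms)

    def test_presence_threshold_is_sqrt2_times_pre_rms(self, times_ms):
        trace = np.zeros_like(times_ms)
        trace[(times_ms >= -500) & (times_ms < 0)] = 2.0
        assert presence_threshold_uv(trace, times_ms) == pytest.approx(2 * math.sqrt(2))


class TestN1Detection:
    def test_noiseless_lep_n1_recovered_before_n2(self, noiseless_lep, times_ms):
        vertex = vertex_template(noiseless_lep, times_ms)
        contra = contralateral_template(noiseless_lep, times_ms)
        roi = ROIWindows.for_modality("lep")
        n2, _ = detect_vertex_components(vertex, times_ms, roi)
        onset = n2_onset_ms(vertex, times_ms, n2)
        n1 = detect_n1(contra, times_ms, roi, n2, onset)
        assert n1.present
        assert n1.latency_ms == pytest.approx(175.0, abs=3.0)
        assert n1.latency_ms < n2.latency_ms
        assert n1.amplitude_uv == pytest.approx(-7.1, rel=0.05)

    def test_n1_absent_when_n2_absent(self, times_ms):
        contra = np.zeros_like(times_ms)
        n1 = detect_n1(
            contra, times_ms, ROIWindows.for_modality("lep"), ComponentResult.absent()
        )
        assert not n1.present and n1.amplitude_uv == 0.0

    def test_n1_after_n2_onset_reported_absent(self, noiseless_lep, times_ms):
        """Moving the contralateral bump past the N2 onset violates the
        precedence rule, so N1 must be reported absent."""
        vertex = vertex_template(noiseless_lep, times_ms)
        late = dataclasses.replace(
            noiseless_lep, n1=Component(205.0, -7.1, 15.0)
        )
        contra = contralateral_template(late, times_ms)
        roi = ROIWindows.for_modality("lep")
        n2, _ = detect_vertex_components(vertex, times_ms, roi)
        onset = n2_onset_ms(vertex, times_ms, n2)
        assert onset < 205.0
        n1 = detect_n1(contra, times_ms, roi, n2, onset)
        assert not n1.present

    def test_onset_lies_between_half_amplitude_and_peak(self, noiseless_chep, times_ms):
        vertex = vertex_template(noiseless_chep, times_ms)
        roi = ROIWindows.for_modality("chep")
        n2, _ = detect_vertex_components(vertex, times_ms, roi)
        onset = n2_onset_ms(vertex, times_ms, n2)
        width = noiseless_chep.n2.width_ms
        expected = noiseless_chep.n2.latency_ms - width * math.sqrt(2 * math.log(2))
        assert onset == pytest.approx(expected, abs=2.0)


class TestExtractSession:
    def _session(self, truth, modality, seed=0, n=20):
        train = StimulusTrain(
            modality="laser" if modality == "lep" else "contact_heat", n_stimuli=n
        )
        return synthesize_session(truth, train, seed=seed)

    def test_noiseless_session_recovers_all_components(self, noiseless_chep):
        result = extract_session(self._session(noiseless_chep, "chep"), "chep")
        assert not result.session_excluded
        assert result.n1.present and result.n2.present and result.p2.present
        assert result.n2.latency_ms == pytest.approx(392.0, abs=3.0)
        assert result.p2.latency_ms == pytest.approx(494.0, abs=3.0)
        assert result.n2p2_amplitude_uv == pytest.approx(23.6, rel=0.05)

    def test_template_recoverability_epoch_pipeline(self, separated_truth):
        """Noiseless well-separated components pass through the epoch-mode
        pipeline with latency error <= 1 sample and amplitude error < 1%."""
        roi = ROIWindows("any", (100.0, 1500.0), (400.0, 800.0), (1000.0, 1400.0))
        result = extract_session(self._session(separated_truth, "lep"), "lep", roi=roi)
        dt = 1000 / SFREQ
        assert result.n2.latency_ms == pytest.approx(600.0, abs=dt)
        assert result.p2.latency_ms == pytest.approx(1200.0, abs=dt)
        assert result.n2.amplitude_uv == pytest.approx(-12.0, rel=0.01)
        assert result.p2.amplitude_uv == pytest.approx(9.0, rel=0.01)
        assert result.n1.latency_ms == pytest.approx(200.0, abs=dt)
        assert result.n1.amplitude_uv == pytest.approx(-8.0, rel=0.01)

    def test_single_noiseless_epoch_equals_full_average(self, noiseless_lep):
        r1 = extract_session(self._session(noiseless_lep, "lep", n=1), "lep")
        r20 = extract_session(self._session(noiseless_lep, "lep", n=20), "lep")
        assert r1.n2.latency_ms == r20.n2.latency_ms
        assert r1.n2.amplitude_uv == pytest.approx(r20.n2.amplitude_uv, abs=1e-9)
        assert r1.p2.latency_ms == r20.p2.latency_ms

    def test_high_noise_session_excluded_without_components(self, noiseless_lep):
        noisy = dataclasses.replace(noiseless_lep, noise_rms=80.0, latency_jitter_sd=10.0)
        result = extract_session(self._session(noisy, "lep", seed=3), "lep")
        assert result.session_snr_db < 3.0
        assert result.session_excluded
        assert not (result.n1.present or result.n2.present or result.p2.present)
        assert result.n2p2_amplitude_uv == 0.0

    def test_exclusion_consistency_and_latency_order(self):
        """Across random sessions: excluded sessions never report components,
        and whenever all three are present N1 < N2 < P2 in latency."""
        rng = np.random.default_rng(77)
        from noxep.eeg_sim import sample_ground_truth

        for i in range(10):
            modality = "lep" if i % 2 else "chep"
            truth = sample_ground_truth(modality, rng)
            result = extract_session(
                self._session(truth, modality, seed=int(rng.integers(2**31))), modality
            )
            if result.session_excluded:
                assert not (result.n1.present or result.n2.present or result.p2.present)
            if result.n1.present and result.n2.present and result.p2.present:
                assert result.n1.latency_ms < result.n2.latency_ms < result.p2.latency_ms

    def test_no_usable_epochs_is_an_error(self, noiseless_lep):
        eps = self._session(noiseless_lep, "lep", n=2)
        eps.rejected = [0, 1]
        with pytest.raises(ValueError, match="usable"):
            extract_session(eps, "lep")

    def test_row_export_schema(self, noiseless_lep):
        row = extract_session(self._session(noiseless_lep, "lep"), "lep").to_row()
        for key in ("snr_db", "excluded", "n2_latency_ms", "n2p2_uv", "n_epochs"):
            assert key in row
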