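"""Detector behavior: hand-built probes, recovery, and invariants."""

import numpy as np
import pytest

from somnocog import (
    SOParams,
    SpindleParams,
    detect_slow_oscillations,
    detect_spindles,
    summarize_event_shapes,
)
from somnocog.detect import _so_band
from somnocog.synthetic import _pink_noise, _so_template, _spindle_template

from conftest import FS, mask_for, match_counts, quiet_night_signal


def put(x, t_s, tmpl):
    i = int(t_s * FS)
    x[i : i + len(tmpl)] += tmpl
    return x


class TestSlowOscillations:
    def test_silent_signal_yields_no_events(self):
        hyp, x = quiet_night_signal(noise_sd=0.0)
        assert detect_slow_oscillations(x, FS, mask_for(x, hyp)) == []

    def test_textbook_waveform_detected_once(self):
        """40 μV/400 ms negative + 30 μV/300 ms positive half-sine → 1 event
        with trough-to-peak close to 70 μV on the detection trace."""
        hyp, x = quiet_night_signal()
        put(x, 60.0, _so_template(FS, 40.0, 30.0, 0.4, 0.3))
        events = detect_slow_oscillations(x, FS, mask_for(x, hyp))
        assert len(events) == 1
        assert abs(events[0].onset_s - 60.0) < 0.2
        assert abs(events[0].p2p_uV - 70.0) < 8.0  # narrowband filter droop

    def test_subthreshold_p2p_rejected(self):
        """Same shape scaled to 50 μV trough-to-peak fails the 61 μV rule."""
        hyp, x = quiet_night_signal()
        put(x, 60.0, _so_template(FS, 40.0 * 50 / 70, 30.0 * 50 / 70, 0.4, 0.3))
        assert detect_slow_oscillations(x, FS, mask_for(x, hyp)) == []

    def test_weak_negative_peak_rejected(self):
        """Trough of 25 μV fails the 33 μV negative-amplitude rule even
        though trough-to-peak exceeds 61 μV."""
        hyp, x = quiet_night_signal()
        put(x, 60.0, _so_template(FS, 25.0, 45.0, 0.4, 0.5))
        assert detect_slow_oscillations(x, FS, mask_for(x, hyp)) == []

    def test_overlong_positive_halfwave_rejected(self):
        hyp, x = quiet_night_signal(n_epochs=10)
        put(x, 60.0, _so_template(FS, 45.0, 30.0, 0.4, 1.4))
        assert detect_slow_oscillations(x, FS, mask_for(x, hyp)) == []

    def test_event_in_unusable_epoch_dropped(self):
        hyp, x = quiet_night_signal()
        hyp.stages[2] = "REM"  # epoch holding the event
        put(x, 61.0, _so_template(FS, 40.0, 30.0, 0.4, 0.3))
        assert detect_slow_oscillations(x, FS, mask_for(x, hyp)) == []

    def test_detection_invariant_to_dc_offset(self, synthetic_night):
        _, _, _, filt, mask = synthetic_night
        a = detect_slow_oscillations(filt, FS, mask)
        b = detect_slow_oscillations(filt + 40.0, FS, mask)
        assert [e.onset_s for e in a] == pytest.approx([e.onset_s for e in b], abs=1e-6)


class TestSpindles:
    def test_event_free_pink_noise_near_silent(self):
        """False-alarm rate on pure 1/f background is far below the real
        spindle density scale (~1.5/min): without the absolute-sigma-power
        criterion a three-feature threshold detector retains a small residual
        rate on featureless noise, but it must stay under 0.1/min pooled
        over 10 seeds of 10-minute records."""
        hyp, _ = quiet_night_signal(n_epochs=20)
        total = 0
        for seed in range(10):
            x = _pink_noise(int(20 * 30 * FS), FS, 15.0, 1.0, np.random.default_rng(seed))
            total += len(detect_spindles(x, FS, mask_for(x, hyp)))
        assert total / (10 * 10.0) < 0.1

    def test_injected_burst_recovered_once(self):
        """One 13 Hz, 1.0 s, 20 μV Hann burst in 15 μV pink noise → exactly
        one detection of plausible duration."""
        hyp, _ = quiet_night_signal(n_epochs=20)
        x = _pink_noise(int(20 * 30 * FS), FS, 15.0, 1.0, np.random.default_rng(3))
        put(x, 150.0, _spindle_template(FS, 20.0, 13.0, 1.0, 0.0))
        events = detect_spindles(x, FS, mask_for(x, hyp))
        assert len(events) == 1
        assert abs(events[0].onset_s - 150.0) < 0.5
        assert 0.6 <= events[0].duration_s <= 1.6

    def test_too_short_burst_rejected(self):
        """A 0.3 s burst falls below the 0.5 s minimum and is not reported
        at the injection site."""
        hyp, _ = quiet_night_signal(n_epochs=20)
        x = _pink_noise(int(20 * 30 * FS), FS, 15.0, 1.0, np.random.default_rng(4))
        put(x, 150.0, _spindle_template(FS, 20.0, 13.0, 0.3, 0.0))
        events = detect_spindles(x, FS, mask_for(x, hyp))
        assert not any(abs(e.onset_s - 150.0) < 1.0 for e in events)

    def test_window_longer_than_signal_errors(self):
        hyp, x = quiet_night_signal(n_epochs=1)
        with pytest.raises(ValueError, match="window"):
            detect_spindles(x[:50], FS, mask_for(x, hyp))


class TestRecoveryAndInvariants:
    def test_detectors_recover_injected_truth(self, synthetic_night):
        """Sensitivity and precision ≥ 0.9 on one default-SNR night."""
        _, _, truth, filt, mask = synthetic_night
        so = detect_slow_oscillations(filt, FS, mask)
        sp = detect_spindles(filt, FS, mask)
        for kind, det in (("SO", so), ("spindle", sp)):
            t = [e for e in truth if e.type == kind]
            nt, nd, mt, md = match_counts(t, det)
            assert mt / nt >= 0.9, f"{kind} sensitivity {mt / nt:.2f}"
            assert md / nd >= 0.9, f"{kind} precision {md / nd:.2f}"

    def test_every_detection_repasses_criteria_independently(self, synthetic_night):
        """Criterion-oracle equivalence: each returned SO re-passes all four
        amplitude/duration rules when re-measured from the trace; every
        spindle duration lies in [0.5, 2.5] s; all events in usable epochs."""
        _, _, _, filt, mask = synthetic_night
        p = SOParams()
        so = detect_slow_oscillations(filt, FS, mask, p)
        xf = _so_band(filt, FS, p)
        assert so, "expected detections on the synthetic night"
        for e in so:
            i0 = int(np.ceil(e.onset_s * FS))
            i1 = int((e.onset_s + e.duration_s) * FS)
            seg = xf[i0:i1]
            trough = seg.min()
            zero_up = i0 + np.where(np.diff(np.signbit(seg).astype(int)) == -1)[0]
            assert len(zero_up) >= 1
            t1 = zero_up[0] / FS
            neg_ms = (t1 - e.onset_s) * 1000.0
            pos_ms = (e.onset_s + e.duration_s - t1) * 1000.0
            peak = xf[int(t1 * FS) : i1].max()
            assert -trough >= p.neg_amp_uV - 1e-6
            assert peak - trough >= p.p2p_amp_uV - 1e-6
            assert p.neg_dur_min_ms - 8 <= neg_ms <= p.neg_dur_max_ms + 8
            assert pos_ms <= p.pos_dur_max_ms + 8
            assert mask.contains_interval(e.onset_s, e.duration_s)
        sp = detect_spindles(filt, FS, mask)
        for e in sp:
            assert 0.5 <= e.duration_s <= 2.5
            assert mask.contains_interval(e.onset_s, e.duration_s)


class TestEventShapeSummaries:
    def test_single_event_average_equals_its_trace(self):
        hyp, x = quiet_night_signal()
        tmpl = _so_template(FS, 45.0, 35.0, 0.5, 0.4)
        put(x, 60.0, tmpl)
        events = detect_slow_oscillations(x, FS, mask_for(x, hyp))
        shapes = summarize_event_shapes(events, x, FS)
        xf = _so_band(x, FS, SOParams())
        anchor = np.argmin(xf)
        hw = int(2.0 * FS)
        assert np.allclose(shapes["SO"]["mean"], xf[anchor - hw : anchor + hw + 1])
        assert np.allclose(shapes["SO"]["sem"], 0.0)

    def test_average_recovers_template_and_ignores_order(self):
        """Identical injected waveforms average back to the template shape,
        regardless of the order events are supplied in."""
        hyp, x = quiet_night_signal(n_epochs=30, noise_sd=2.0, seed=5)
        tmpl = _so_template(FS, 45.0, 35.0, 0.5, 0.4)
        for t0 in (40.0, 150.0, 300.0, 420.0, 610.0, 755.0):
            put(x, t0, tmpl)
        events = detect_slow_oscillations(x, FS, mask_for(x, hyp))
        assert len(events) == 6
        fwd = summarize_event_shapes(events, x, FS)
        rev = summarize_event_shapes(events[::-1], x, FS)
        assert np.allclose(fwd["SO"]["mean"], rev["SO"]["mean"])
        # trough depth of the average ≈ filtered template trough
        xf_t = _so_band(np.pad(tmpl, int(5 * FS)), FS, SOParams())
        assert abs(fwd["SO"]["mean"].min() - xf_t.min()) < 3.0

    def test_empty_event_list_raises(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_event_shapes([], np.zeros(1000), FS)
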