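"""SWR detector: candidate placement, wavelet boundaries, measurement,
the two published rejection rules, and ground-truth recovery properties."""

import numpy as np
import pytest

from ripplestats import (
    LfpRecording,
    SwrDetectionParams,
    SwrEvent,
    SynthLfpConfig,
    TimeFrequencyPower,
    apply_rejection,
    band_pass,
    detect_candidates,
    detect_swrs,
    evaluate_detection,
    event_boundaries,
    generate_lfp,
    measure_event,
    morlet_cwt,
    sliding_rms,
)
from ripplestats.swr import REJECT_SHORT, REJECT_WEAK, background_stats, summarize

FS = 10_000.0


def benchmark_recording(seed, n=20, dur_ms=30.0, amp_scale=8.0, duration_s=60.0):
    """Noise + exactly n implanted 200 Hz ripples at amp_scale x band RMS."""
    noise, _ = generate_lfp(SynthLfpConfig(duration_s=duration_s, swr_rate_hz=0.0, seed=seed))
    band_rms = float(np.sqrt(np.mean(band_pass(noise, 150, 250).samples ** 2)))
    cfg = SynthLfpConfig(
        duration_s=duration_s,
        swr_count=n,
        swr_freq_range_hz=(200.0, 200.0),
        swr_duration_ms=(dur_ms, 0.0),
        swr_amplitude_uv=(2 * amp_scale * band_rms, 0.0),  # peak-to-trough = 2A
        seed=seed,
    )
    rec, truth = generate_lfp(cfg)
    return rec, [e for e in truth if e.kind == "swr"], band_rms


class TestDetectCandidates:
    def test_zero_rms_gives_no_candidates(self):
        rms = LfpRecording(np.zeros(10_000), FS)
        assert detect_candidates(rms) == []

    def test_single_bump_one_candidate_at_apex(self):
        rng = np.random.default_rng(2)
        x = 1.0 + rng.normal(0, 0.05, 50_000)
        t = np.arange(x.size) / FS
        apex = 2.5
        x += 0.8 * np.exp(-0.5 * ((t - apex) / 0.01) ** 2)  # ~>6 SD bump
        cands = detect_candidates(LfpRecording(x, FS))
        assert len(cands) == 1
        assert cands[0] == pytest.approx(apex, abs=0.001)

    def test_two_bumps_30ms_apart_merged(self):
        rng = np.random.default_rng(3)
        x = 1.0 + rng.normal(0, 0.05, 50_000)
        t = np.arange(x.size) / FS
        for apex, h in ((2.5, 0.8), (2.53, 0.6)):
            x += h * np.exp(-0.5 * ((t - apex) / 0.004) ** 2)
        cands = detect_candidates(LfpRecording(x, FS))
        assert len(cands) == 1
        assert cands[0] == pytest.approx(2.5, abs=0.002)


class TestEventBoundaries:
    def synthetic_tf(self, elevated=True, span_ms=30.0):
        rng = np.random.default_rng(7)
        grid = np.arange(100.0, 301.0, 2.0)
        times = np.arange(2001) / FS
        power = rng.exponential(1.0, (grid.size, times.size))
        if elevated:
            band = (grid >= 150) & (grid <= 250)
            mid = times.size // 2
            half = int(span_ms / 2 / 1000 * FS)
            power[np.ix_(band, np.arange(mid - half, mid + half))] += 50.0
        return TimeFrequencyPower(grid, times, power)

    def test_no_crossing_rejects(self):
        assert event_boundaries(self.synthetic_tf(elevated=False)) is None

    def test_elevated_span_recovered(self):
        b = event_boundaries(self.synthetic_tf(span_ms=30.0))
        assert b is not None
        onset, offset = b
        assert (offset - onset) * 1000 == pytest.approx(30.0, abs=10.0)

    def test_implanted_ripple_boundaries_near_truth(self):
        rec, truth, _ = benchmark_recording(seed=11, n=5, duration_s=20.0)
        params = SwrDetectionParams()
        ev = truth[2]
        i_c = int(round(ev.center_s * FS))
        window = rec.slice(i_c - 1000, i_c + 1001)
        tf = morlet_cwt(window, params.freq_grid())
        b = event_boundaries(tf, params)
        assert b is not None
        onset, offset = b
        assert onset == pytest.approx(ev.onset_s, abs=0.015)
        assert offset == pytest.approx(ev.offset_s, abs=0.015)


class TestMeasureEvent:
    def test_clean_ripple_peak_frequency_exact(self):
        # noiseless implanted ripple: peak within two grid steps of truth
        params = SwrDetectionParams()
        t = np.arange(2001) / FS
        env = np.zeros_like(t)
        i0, i1 = 850, 1150  # 30 ms support around the window centre
        env[i0:i1] = np.hanning(i1 - i0)
        for f0 in (180.0, 200.0, 220.0):
            x = 10.0 * env * np.cos(2 * np.pi * f0 * (t - 0.1))
            window = LfpRecording(x, FS)
            tf = morlet_cwt(window, params.freq_grid())
            measured = measure_event(
                band_pass(window, 150, 250),
                sliding_rms(window, 5.0),
                tf,
                (t[i0], t[i1 - 1]),
                (0.0, 1.0),
                params,
            )
            assert measured.peak_freq_hz == pytest.approx(f0, abs=4.0)

    def test_noisy_pipeline_mean_peak_frequency(self):
        # with 1/f background the per-event argmax wanders over the broad
        # wavelet peak (sigma_f = f/omega0 ~ 33 Hz) but the mean stays tight
        rec, truth, _ = benchmark_recording(seed=12, n=10, duration_s=30.0)
        events, _ = detect_swrs(rec)
        acc = [e for e in events if e.accepted]
        res = evaluate_detection([e.center_s for e in acc], [e.center_s for e in truth])
        assert res["n_matched"] >= 9
        errs = [abs(acc[i].peak_freq_hz - 200.0) for i, _ in res["matches"]]
        assert np.mean(errs) <= 5.0

    def test_sinusoid_amplitude_is_peak_to_trough(self):
        params = SwrDetectionParams()
        t = np.arange(2001) / FS
        a = 12.5
        x = a * np.sin(2 * np.pi * 200 * t)
        window = LfpRecording(x, FS)
        tf = morlet_cwt(window, params.freq_grid())
        ev = measure_event(window, sliding_rms(window, 5.0), tf, (0.05, 0.15), (0.0, 1.0), params)
        assert ev.amplitude_uv == pytest.approx(2 * a, rel=0.05)

    def test_noise_only_window_weak_rms(self, noise_recording):
        params = SwrDetectionParams()
        bp = band_pass(noise_recording, 150, 250)
        rms = sliding_rms(bp, 5.0)
        bg = background_stats(rms)
        window = noise_recording.slice(100_000, 102_001)
        tf = morlet_cwt(window, params.freq_grid())
        ev = measure_event(
            bp.slice(100_000, 102_001),
            rms.slice(100_000, 102_001),
            tf,
            (window.times_s[900], window.times_s[1100]),
            bg,
            params,
        )
        assert ev.mean_rms_sd < 1.5


class TestApplyRejection:
    @pytest.mark.parametrize(
        "duration_ms, mean_rms_sd, kept, reason",
        [
            (9.9, 5.0, False, REJECT_SHORT),
            (25.0, 1.4, False, REJECT_WEAK),
            (25.0, 2.0, True, ""),
        ],
    )
    def test_rules(self, duration_ms, mean_rms_sd, kept, reason):
        ev = SwrEvent(1.0, 0.99, 0.99 + duration_ms / 1000, duration_ms, 200.0, 20.0, mean_rms_sd)
        accepted = apply_rejection([ev])
        assert (ev in accepted) is kept
        assert ev.reject_reason == reason

    def test_accepted_events_satisfy_both_rules(self):
        rec, _, _ = benchmark_recording(seed=13, n=10, duration_s=30.0)
        events, _ = detect_swrs(rec)
        for e in events:
            if e.accepted:
                assert e.duration_ms >= 10.0
                assert e.mean_rms_sd >= 1.5


class TestDetectSwrs:
    def test_flat_recording_no_events(self):
        events, summary = detect_swrs(LfpRecording(np.zeros(20_000), FS))
        assert events == []
        assert summary.n_events == 0
        assert summary.incidence_hz == 0.0
        assert summary.mean_peak_freq_hz is None

    def test_incidence_is_count_over_duration(self):
        events = [
            SwrEvent(i, i - 0.01, i + 0.01, 20.0, 200.0, 20.0, 3.0) for i in range(1, 11)
        ]
        summary = summarize(events, 20.0)
        assert summary.incidence_hz == pytest.approx(0.5)

    def test_high_snr_recovery(self):
        rec, truth, _ = benchmark_recording(seed=14, n=20, duration_s=60.0)
        events, _ = detect_swrs(rec)
        acc = [e for e in events if e.accepted]
        res = evaluate_detection([e.center_s for e in acc], [e.center_s for e in truth])
        assert res["sensitivity"] >= 0.95
        assert res["fdr"] <= 0.05

    def test_amplitude_scaling_equivariance(self):
        rec, _, _ = benchmark_recording(seed=15, n=8, duration_s=30.0)
        events, _ = detect_swrs(rec)
        scaled = LfpRecording(rec.samples * 5.0, FS)
        events2, _ = detect_swrs(scaled)
        assert len(events2) == len(events)
        for a, b in zip(events, events2):
            assert b.center_s == pytest.approx(a.center_s, abs=1e-9)
            assert b.duration_ms == pytest.approx(a.duration_ms, abs=1e-6)
            assert b.peak_freq_hz == a.peak_freq_hz
            assert b.amplitude_uv == pytest.approx(5.0 * a.amplitude_uv, rel=1e-9)
            assert b.accepted == a.accepted

    def test_threshold_monotonicity(self):
        rec, _, _ = benchmark_recording(seed=16, n=10, duration_s=30.0)
        counts = []
        for thr in (3.0, 4.0, 5.0, 6.0):
            events, _ = detect_swrs(rec, SwrDetectionParams(detect_threshold_sd=thr))
            counts.append(sum(e.accepted for e in events))
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            detect_swrs(LfpRecording(np.zeros(5000), FS))


class TestIncidenceLinearity:
    def test_doubling_rate_doubles_incidence(self):
        # implant rates well below refractory saturation
        inc = {}
        for rate in (0.25, 0.5):
            vals = []
            for seed in (1, 2, 3, 4, 5):
                rec, _ = generate_lfp(
                    SynthLfpConfig(duration_s=100.0, swr_rate_hz=rate, seed=seed)
                )
                _, summary = detect_swrs(rec)
                vals.append(summary.incidence_hz)
            inc[rate] = np.mean(vals)
        assert inc[0.5] / inc[0.25] == pytest.approx(2.0, rel=0.15)


class TestMatching:
    def test_greedy_one_to_one(self):
        res = evaluate_detection([1.0, 1.005, 2.0], [1.001, 5.0])
        assert res["n_matched"] == 1
        assert res["matches"] == [(0, 0)]
        assert res["sensitivity"] == 0.5
        assert res["fdr"] == pytest.approx(2 / 3)
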