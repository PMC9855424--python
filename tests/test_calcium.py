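"""Transient kinetics: detection, segmentation, decay fitting, summaries."""

import math

import numpy as np
import pytest

from cardiopheno.calcium import (
    Trace,
    compute_dff,
    compute_ratio,
    detect_beats,
    extract_beats,
    fit_decay_tau,
    segment_transients,
    summarize_trace,
)
from cardiopheno.synthetic import make_calcium_trace, make_fura2_pair

# time at which the half-cosine ramp crosses 10% of its amplitude,
# as a fraction of the full rise time: solve (1-cos(pi s))/2 = 0.1
TEN_PCT_CROSSING = math.acos(1.0 - 2 * 0.1) / math.pi


def make_trace(values, fs=50.0, kind="raw", name=""):
    return Trace(np.arange(len(values)) / fs, np.asarray(values, float), kind, name)


class TestTraceInvariants:
    def test_non_uniform_grid_rejected(self):
        t = np.arange(150) / 50.0
        t[70] += 0.01
        with pytest.raises(ValueError, match="non-uniform"):
            Trace(t, np.zeros(150))

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            Trace(np.arange(50) / 50.0, np.ones(50))

    def test_non_finite_values_rejected(self):
        v = np.ones(150)
        v[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            make_trace(v)


class TestDff:
    def test_constant_trace_maps_to_zero(self):
        out = compute_dff(make_trace(np.full(150, 5.0)))
        assert np.allclose(out.values, 0.0)
        assert out.signal_kind == "dff"

    def test_gain_invariance(self):
        tr, _ = make_calcium_trace(duration_s=20.0, amplitude=300.0, diastolic=400.0)
        scaled = Trace(tr.time_s, 7.0 * tr.values, "raw")
        assert np.allclose(compute_dff(tr).values, compute_dff(scaled).values, atol=1e-12)

    def test_recovers_amplitude_over_diastolic(self):
        # long diastole so the previous decay has fully returned to baseline
        amp, dias = 300.0, 400.0
        tr, _ = make_calcium_trace(
            duration_s=60.0, interval_s=2.5, tau_s=0.3, amplitude=amp, diastolic=dias
        )
        dff = compute_dff(tr)
        summ = summarize_trace(dff, extract_beats(dff))
        assert summ.mean_amplitude == pytest.approx(amp / dias, rel=0.02)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="background"):
            compute_dff(make_trace(np.linspace(-1.0, 1.0, 150)))


class TestRatio:
    def test_proportional_channels_give_constant_ratio(self):
        f380 = make_trace(np.linspace(100, 200, 150))
        f340 = make_trace(2.0 * f380.values)
        assert np.allclose(compute_ratio(f340, f380).values, 2.0)

    def test_nonpositive_denominator_reports_first_index(self):
        f380 = make_trace(np.linspace(50, -50, 150))
        f340 = make_trace(np.ones(150))
        with pytest.raises(ValueError, match="sample 75"):
            compute_ratio(f340, f380)

    def test_grid_mismatch_rejected(self):
        a = make_trace(np.ones(150), fs=50.0)
        b = make_trace(np.ones(150), fs=25.0)
        with pytest.raises(ValueError, match="time grid"):
            compute_ratio(a, b)

    def test_ratio_and_dff_pipelines_agree_on_beat_timing(self):
        ratio, _ = make_calcium_trace(
            duration_s=60.0, amplitude=0.6, diastolic=0.9, signal_kind="ratio"
        )
        f340, f380, _ = make_fura2_pair(ratio, f380_baseline=800.0)
        peaks_ratio = detect_beats(compute_ratio(f340, f380))
        peaks_dff = detect_beats(compute_dff(f340))
        assert np.array_equal(peaks_ratio, peaks_dff)


class TestDetectBeats:
    def test_counts_and_positions_match_truth(self, paced_trace):
        trace, spec = paced_trace
        peaks = detect_beats(trace)
        truth = np.array(spec.truth["peak_times_s"])
        assert len(peaks) == len(truth) == 30
        assert np.max(np.abs(peaks - truth)) <= 1.0 / trace.fs_hz

    def test_monotone_ramp_has_no_peaks(self):
        assert detect_beats(make_trace(np.linspace(0, 1, 200))).size == 0

    def test_flat_trace_has_no_peaks(self):
        assert detect_beats(make_trace(np.full(200, 2.0))).size == 0

    def test_peak_count_stable_across_noise_seeds_at_snr_5(self):
        counts = {
            len(
                detect_beats(
                    make_calcium_trace(duration_s=60.0, noise_sigma=0.2, seed=s)[0]
                )
            )
            for s in range(50)
        }
        assert counts == {30}


class TestSegmentTransients:
    def test_onset_matches_half_cosine_crossing(self, paced_trace):
        trace, spec = paced_trace
        beats = segment_transients(trace, detect_beats(trace))
        ttp = spec.truth["ttp_s"]
        expected_onset = np.array(spec.truth["onset_times_s"][1:]) + ttp * TEN_PCT_CROSSING
        got = np.array([b.onset_s for b in beats[1:]])
        assert np.max(np.abs(got - expected_onset[: len(got)])) <= 1.0 / trace.fs_hz

    def test_peak_at_trace_start_is_dropped(self):
        # a decay-only first "beat": peak at sample 0 has no onset
        tr, _ = make_calcium_trace(duration_s=60.0)
        v = np.concatenate([[2.5], tr.values[1:]])
        tr2 = Trace(tr.time_s, v, "raw")
        peaks = np.concatenate([[0.0], detect_beats(tr)[1:]])
        beats = segment_transients(tr2, peaks)
        assert len(beats) == len(peaks) - 1

    def test_windows_are_disjoint_and_ordered(self, paced_trace):
        trace, _ = paced_trace
        beats = segment_transients(trace, detect_beats(trace))
        for a, b in zip(beats, beats[1:]):
            assert a.onset_s < a.peak_s < a.window_end_s <= b.onset_s

    def test_truncated_final_decay_marked_incomplete(self):
        tr, spec = make_calcium_trace(duration_s=60.0, interval_s=2.0, tau_s=0.4)
        cut = int(round((spec.truth["peak_times_s"][-1] + 0.3) * tr.fs_hz))
        # cut the last decay well before 1/e relaxation; detect without
        # smoothing so the boundary peak keeps enough prominence
        tr2 = Trace(tr.time_s[:cut], tr.values[:cut], "raw")
        beats = segment_transients(tr2, detect_beats(tr2, smooth_s=0.0))
        assert beats[-1].peak_s == pytest.approx(spec.truth["peak_times_s"][-1])
        assert beats[-1].complete is False
        assert all(b.complete for b in beats[:-1])


class TestDecayFit:
    def test_noiseless_tau_recovered_to_one_percent(self, paced_trace):
        trace, spec = paced_trace
        beats = segment_transients(trace, detect_beats(trace))
        tau, r2, reason = fit_decay_tau(trace, beats[2])
        assert reason is None
        assert tau == pytest.approx(spec.truth["tau_s"], abs=0.004)
        assert r2 > 0.999

    def test_offset_invariance(self, paced_trace):
        trace, _ = paced_trace
        shifted = Trace(trace.time_s, trace.values + 10.0, "raw")
        b1 = segment_transients(trace, detect_beats(trace))[2]
        b2 = segment_transients(shifted, detect_beats(shifted))[2]
        tau1, _, _ = fit_decay_tau(trace, b1)
        tau2, _, _ = fit_decay_tau(shifted, b2)
        assert tau1 == pytest.approx(tau2, rel=1e-6)

    def test_median_error_under_five_percent_at_five_percent_noise(self):
        errs = []
        for seed in range(50):
            tr, _ = make_calcium_trace(duration_s=30.0, noise_sigma=0.05, seed=seed)
            summ = summarize_trace(tr, extract_beats(tr))
            errs.append(abs(summ.mean_tau_s - 0.4) / 0.4)
        assert np.median(errs) < 0.05

    def test_short_decay_reports_reason(self):
        tr, _ = make_calcium_trace(duration_s=60.0)
        beats = segment_transients(tr, detect_beats(tr))
        b = beats[0]
        b.end_idx = b.peak_idx + 3
        tau, r2, reason = fit_decay_tau(tr, b)
        assert tau is None and reason == "too_few_decay_samples"

    def test_drift_changes_tau_by_less_than_three_percent(self):
        tr0, _ = make_calcium_trace(duration_s=60.0)
        trd, _ = make_calcium_trace(duration_s=60.0, drift_per_s=0.01)
        tau0 = summarize_trace(tr0, extract_beats(tr0)).mean_tau_s
        taud = summarize_trace(trd, extract_beats(trd)).mean_tau_s
        assert abs(taud - tau0) / tau0 < 0.03


class TestSummarize:
    def test_paced_protocol_rate_exact_and_sd_zero(self, paced_trace):
        trace, _ = paced_trace
        summ = summarize_trace(trace, extract_beats(trace))
        assert summ.beat_rate_hz == pytest.approx(0.5, abs=1e-9)
        assert summ.beat_rate_bpm == pytest.approx(30.0, abs=1e-7)
        assert summ.interval_sd_s == 0.0

    def test_interval_sd_recovers_known_jitter(self):
        sds = [
            summarize_trace(
                tr := make_calcium_trace(
                    duration_s=220.0, interval_jitter_sd_s=0.1, seed=s
                )[0],
                extract_beats(tr),
            ).interval_sd_s
            for s in range(50)
        ]
        assert np.mean(sds) == pytest.approx(0.1, abs=0.02)

    def test_interval_sd_grows_with_jitter(self):
        means = []
        for jitter in (0.02, 0.05, 0.1):
            sds = [
                summarize_trace(
                    tr := make_calcium_trace(
                        duration_s=120.0, interval_jitter_sd_s=jitter, seed=s
                    )[0],
                    extract_beats(tr),
                ).interval_sd_s
                for s in range(50)
            ]
            means.append(np.mean(sds))
        assert means[0] < means[1] < means[2]

    def test_one_doubled_interval_among_twenty_beats(self):
        # 20 peaks -> 19 intervals, one gap doubled -> 1 irregular interval
        peaks = list(np.arange(20) * 2.0)
        peaks = peaks[:10] + [p + 2.0 for p in peaks[10:]]  # double one interval
        t = np.arange(int(50 * (peaks[-1] + 2)) ) / 50.0
        v = np.zeros_like(t)
        for p in peaks:
            v[int(p * 50)] = 1.0  # synthetic delta peaks, segmentation not needed
        from cardiopheno.calcium import Beat

        beats = [
            Beat(p - 0.1, p, 1.0, 0.0, True, int(p * 50), int(p * 50) + 1, p + 0.5)
            for p in peaks
        ]
        tr = Trace(t, v + 1.0, "raw")
        summ = summarize_trace(tr, beats)
        assert summ.n_beats == 20
        assert summ.irregular_event_fraction == pytest.approx(1 / 19)

    def test_fewer_than_two_beats_flagged(self, paced_trace):
        trace, _ = paced_trace
        summ = summarize_trace(trace, [])
        assert summ.n_beats == 0
        assert math.isnan(summ.beat_rate_hz)
        assert "fewer_than_2_beats" in summ.flags


class TestEndToEndRecovery:
    def test_noiseless_parameters_recovered(self, paced_trace):
        """TTP/tau/amplitude/diastolic/rate all within 1% or 1 sample."""
        trace, spec = paced_trace
        summ = summarize_trace(trace, extract_beats(trace))
        dt = 1.0 / trace.fs_hz
        expected_ttp = spec.truth["ttp_s"] * (1.0 - TEN_PCT_CROSSING)
        assert abs(summ.mean_ttp_s - expected_ttp) <= dt
        assert summ.mean_tau_s == pytest.approx(spec.truth["tau_s"], rel=0.01)
        assert summ.mean_amplitude == pytest.approx(spec.truth["amplitude"], rel=0.01)
        assert summ.mean_diastolic == pytest.approx(spec.truth["diastolic"], rel=0.01)
        assert summ.beat_rate_hz == pytest.approx(spec.truth["rate_hz"], rel=0.01)
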