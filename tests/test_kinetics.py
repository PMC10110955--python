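"""Event-measurement tests: evoked kinetics, epoch averaging, block, spontaneous."""

import numpy as np
import pytest

from gpcal.background import correct
from gpcal.core import Trace
from gpcal.kinetics import (
    ResponseKinetics,
    average_epoch,
    detect_spontaneous,
    measure_epoch,
    measure_response,
    percent_remaining,
)
from gpcal.synthetic import (
    BleachModel,
    SpontaneousModel,
    TransientKernel,
    kernel_from_kinetics,
    simulate_trace,
)


def triangle_trace(peak=0.08, half_base=1.0, apex_t=15.0, fr=10.0, n=300):
    """Symmetric triangular event on a flat baseline (analytic geometry)."""
    t = np.arange(n) / fr
    y = peak * np.clip(1.0 - np.abs(t - apex_t) / half_base, 0.0, None)
    return Trace(roi_id=0, values=y, frame_rate=fr)


class TestMeasureResponse:
    def test_flat_trace_reports_missing(self):
        tr = Trace(roi_id=0, values=np.zeros(200), frame_rate=10.0)
        r = measure_response(tr, 10.0)
        assert r.amplitude == 0.0
        assert np.isnan(r.duration_half_max)
        assert np.isnan(r.rise_10_90)
        assert np.isnan(r.decay_90_10)

    def test_triangular_event_analytic_geometry(self):
        """Peak 0.08, base width 2 s: FWHM = 1.0 s, rise = decay = 0.8 s."""
        r = measure_response(triangle_trace(), 14.0, window=3.0, deconvolve_exposure=False)
        # the 5-point parabola peak refinement slightly rounds the apex kink
        assert r.amplitude == pytest.approx(0.08, rel=0.05)
        assert r.duration_half_max == pytest.approx(1.0, rel=0.05)
        assert r.rise_10_90 == pytest.approx(0.8, rel=0.05)
        assert r.decay_90_10 == pytest.approx(0.8, rel=0.05)
        assert r.peak_time == pytest.approx(15.0, abs=0.05)

    def test_generator_event_recovery_against_dense_truth(self, rng):
        """Well-resolved synthetic events recover within 10-15% of the
        dense-grid ground truth (small-scale parameter-recovery check)."""
        errs = {"amplitude": [], "fwhm": [], "rise": [], "decay": []}
        for _ in range(30):
            amp = float(np.exp(rng.uniform(np.log(0.02), np.log(0.15))))
            fwhm = float(np.exp(rng.uniform(np.log(0.5), np.log(2.5))))
            k = kernel_from_kinetics(amp, fwhm=fwhm, rise_10_90=0.23 * fwhm, onset_time=10.0)
            tr, truth = simulate_trace(
                BleachModel(), [k], noise_sd=amp * 100 / 20, duration=30.0, seed=rng
            )
            r = measure_response(correct(tr).corrected, 10.0)
            t = truth.iloc[0]
            errs["amplitude"].append(abs(r.amplitude - t.amplitude) / t.amplitude)
            errs["fwhm"].append(abs(r.duration_half_max - t.fwhm) / t.fwhm)
            errs["rise"].append(abs(r.rise_10_90 - t.rise_10_90) / t.rise_10_90)
            errs["decay"].append(abs(r.decay_90_10 - t.decay_90_10) / t.decay_90_10)
        assert np.median(errs["amplitude"]) < 0.10
        assert np.median(errs["fwhm"]) < 0.15
        assert np.median(errs["rise"]) < 0.15
        assert np.median(errs["decay"]) < 0.15

    def test_scale_equivariance(self, noisy_event_trace):
        tr, _ = noisy_event_trace
        corrected = correct(tr).corrected
        r1 = measure_response(corrected, 10.0)
        scaled = Trace(roi_id=0, values=3.0 * corrected.values, frame_rate=10.0)
        r2 = measure_response(scaled, 10.0)
        assert r2.amplitude == pytest.approx(3.0 * r1.amplitude, rel=1e-9)
        assert r2.duration_half_max == pytest.approx(r1.duration_half_max, rel=1e-9)
        assert r2.rise_10_90 == pytest.approx(r1.rise_10_90, rel=1e-9)
        assert r2.decay_90_10 == pytest.approx(r1.decay_90_10, rel=1e-9)

    def test_time_shift_equivariance(self, noisy_event_trace):
        tr, _ = noisy_event_trace
        corrected = correct(tr).corrected
        r1 = measure_response(corrected, 10.0)
        shift_frames = 40  # shift stimulus and trace together by 4 s
        shifted = Trace(
            roi_id=0,
            values=np.concatenate([np.zeros(shift_frames), corrected.values]),
            frame_rate=10.0,
        )
        r2 = measure_response(shifted, 14.0)
        assert r2.amplitude == pytest.approx(r1.amplitude, rel=1e-6)
        assert r2.duration_half_max == pytest.approx(r1.duration_half_max, rel=1e-6)
        assert r2.peak_time - 4.0 == pytest.approx(r1.peak_time, abs=1e-6)

    def test_subframe_consistency_at_high_snr(self):
        """x100 upsampled 10 Hz measurements approach dense-grid values for a
        well-resolved event at SNR 50."""
        k = kernel_from_kinetics(0.10, fwhm=1.2, rise_10_90=0.3, onset_time=10.0)
        tr, truth = simulate_trace(BleachModel(), [k], noise_sd=0.10 * 100 / 50, duration=30.0, seed=0)
        r = measure_response(correct(tr).corrected, 10.0)
        t = truth.iloc[0]
        assert r.amplitude == pytest.approx(t.amplitude, rel=0.05)
        assert r.duration_half_max == pytest.approx(t.fwhm, rel=0.08)
        assert r.rise_10_90 == pytest.approx(t.rise_10_90, rel=0.15)
        assert r.decay_90_10 == pytest.approx(t.decay_90_10, rel=0.15)

    def test_window_must_cover_three_frames(self):
        tr = Trace(roi_id=0, values=np.zeros(100), frame_rate=10.0)
        with pytest.raises(ValueError, match="3 frames"):
            measure_response(tr, 9.8, window=0.1)


class TestAverageEpoch:
    def _resp(self, amplitude, fwhm=np.nan, **kw):
        defaults = dict(
            roi_id=1, stimulus_index=0, epoch="baseline", amplitude=amplitude,
            duration_half_max=fwhm, rise_10_90=np.nan, decay_90_10=np.nan,
            peak_time=1.0, n_duration=int(np.isfinite(fwhm)),
        )
        defaults.update(kw)
        return ResponseKinetics(**defaults)

    def test_three_identical_responses(self):
        r = self._resp(0.05, 0.8)
        out = average_epoch([r, r, r])
        assert out.amplitude == pytest.approx(0.05)
        assert out.duration_half_max == pytest.approx(0.8)
        assert out.n_responses == 3

    def test_mean_of_amplitudes(self):
        out = average_epoch([self._resp(a) for a in (0.03, 0.05, 0.07)])
        assert out.amplitude == pytest.approx(0.05)

    def test_missing_duration_averaged_over_defined(self):
        rs = [self._resp(0.05, 0.6), self._resp(0.04, 0.8), self._resp(0.0, np.nan)]
        out = average_epoch(rs)
        assert out.duration_half_max == pytest.approx(0.7)
        assert out.n_duration == 2
        assert out.amplitude == pytest.approx(0.03)

    def test_no_measurable_response(self):
        out = average_epoch([self._resp(0.0, np.nan)] * 3)
        assert out.amplitude == 0.0
        assert np.isnan(out.duration_half_max)

    def test_waveform_averaging_reduces_noise(self):
        """Epoch measurement on the waveform average tracks a weak response
        that is noisy trial-by-trial."""
        k = [
            kernel_from_kinetics(0.03, fwhm=0.5, rise_10_90=0.12, onset_time=float(t))
            for t in (5.0, 15.0, 25.0)
        ]
        tr, _ = simulate_trace(BleachModel(), k, noise_sd=0.25, duration=35.0, seed=4)
        corrected = correct(tr).corrected
        r = measure_epoch(corrected, [5.0, 15.0, 25.0], window=5.0)
        assert r.amplitude == pytest.approx(0.03, rel=0.25)
        assert r.n_responses == 3


class TestPercentRemaining:
    def _resp(self, amplitude, fwhm):
        return ResponseKinetics(
            roi_id=1, stimulus_index=-1, epoch="x", amplitude=amplitude,
            duration_half_max=fwhm, rise_10_90=np.nan, decay_90_10=np.nan, peak_time=0.0,
        )

    def test_quarter_remaining(self):
        out = percent_remaining(self._resp(0.05, 0.8), self._resp(0.0125, 0.4))
        assert out.pct_amplitude_remaining == pytest.approx(25.0)
        assert out.pct_duration_remaining == pytest.approx(50.0)

    def test_inclusion_filter_threshold(self):
        # 0.009 dF/F0 during the antagonist: excluded from duration analysis
        out = percent_remaining(self._resp(0.05, 0.8), self._resp(0.009, 0.3))
        assert not out.included_in_duration
        out2 = percent_remaining(self._resp(0.05, 0.8), self._resp(0.0101, 0.3))
        assert out2.included_in_duration

    def test_identity_is_hundred_percent(self):
        before = self._resp(0.04, 0.7)
        out = percent_remaining(before, before)
        assert out.pct_amplitude_remaining == pytest.approx(100.0)
        assert out.pct_duration_remaining == pytest.approx(100.0)
        assert out.included_in_duration

    def test_nonresponder_rejected(self):
        with pytest.raises(ValueError, match="never responded"):
            percent_remaining(self._resp(0.0, np.nan), self._resp(0.01, 0.1))


class TestDetectSpontaneous:
    def test_flat_noise_below_threshold(self, rng):
        values = rng.standard_normal(600) * 1e-3
        values -= values.mean()
        tr = Trace(roi_id=0, values=values, frame_rate=10.0)
        s = detect_spontaneous(tr, threshold_k=10.0)
        assert s.n_events == 0
        assert s.frequency_hz == 0.0

    def test_twelve_events_in_sixty_seconds(self):
        kernels = [
            TransientKernel(0.08, 0.05, 0.3, onset_time=2.0 + 4.8 * i) for i in range(12)
        ]
        tr, _ = simulate_trace(BleachModel(), kernels, noise_sd=0.2, duration=60.0, seed=1)
        s = detect_spontaneous(correct(tr).corrected)
        assert s.n_events == 12
        assert s.frequency_hz == pytest.approx(0.2)
        assert s.frequency_per_min == pytest.approx(12.0)

    def test_poisson_rate_recovery_at_study_rates(self):
        """At the observed median glial rate (~0.3 Hz) the 10 Hz recordings
        recover the injected Poisson rate within 15%."""
        errs = []
        for seed in range(4):
            spont = SpontaneousModel(rate=0.3, amp_median=0.05, amp_sigma=0.3)
            tr, truth = simulate_trace(
                BleachModel(), [], spont=spont, noise_sd=0.3, duration=100.0, seed=seed
            )
            s = detect_spontaneous(correct(tr).corrected)
            true_rate = (truth["kind"] == "spontaneous").sum() / 100.0
            errs.append(s.frequency_hz / true_rate - 1.0)
        assert abs(np.median(errs)) < 0.15

    def test_poisson_rate_recovery_at_max_rate_dense_sampling(self):
        """At the top of the observed range (1.6 Hz) individual events pile up
        within single 10 Hz frames; with adequate sampling (40 Hz) the
        detector recovers the rate within 15% (overlap merging permitted)."""
        errs = []
        for seed in range(4):
            spont = SpontaneousModel(rate=1.6, amp_median=0.05, amp_sigma=0.3)
            tr, truth = simulate_trace(
                BleachModel(), [], spont=spont, noise_sd=0.3,
                duration=100.0, seed=seed, frame_rate=40.0,
            )
            s = detect_spontaneous(correct(tr, window_frames=800).corrected)
            true_rate = (truth["kind"] == "spontaneous").sum() / 100.0
            errs.append(s.frequency_hz / true_rate - 1.0)
        assert abs(np.median(errs)) < 0.15

    def test_excluded_windows_remove_evoked_events(self):
        k = kernel_from_kinetics(0.1, fwhm=0.5, rise_10_90=0.12, onset_time=20.0)
        tr, _ = simulate_trace(BleachModel(), [k], noise_sd=0.2, duration=60.0, seed=2)
        corrected = correct(tr).corrected
        with_event = detect_spontaneous(corrected)
        without = detect_spontaneous(corrected, exclude_windows=[(20.0, 30.0)])
        assert with_event.n_events >= 1
        assert without.n_events == 0
        assert without.duration_s == pytest.approx(50.0)

    def test_short_recording_rejected(self):
        tr = Trace(roi_id=0, values=np.zeros(50), frame_rate=10.0)
        with pytest.raises(ValueError, match="10 s"):
            detect_spontaneous(tr)
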