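"""Generator tests: bleach models, transient kernels, traces, movies, cohorts."""

import numpy as np
import pandas as pd
import pytest

from gpcal.core import Trace
from gpcal.preprocess import extract_traces
from gpcal.synthetic import (
    SHR,
    WKY,
    BleachModel,
    CohortConfig,
    GroupKinetics,
    SpontaneousModel,
    TransientKernel,
    _shape_table,
    achievable_rise_fwhm_ratio,
    disk_rois,
    draw_cell_parameters,
    kernel_from_kinetics,
    kernel_metrics,
    lognormal_sigma_from_median_ci,
    simulate_cohort,
    simulate_movie,
    simulate_trace,
)

from conftest import dense_kernel_metrics


class TestBleachModel:
    def test_no_bleach_is_constant(self):
        bl = BleachModel(kind="none", amplitudes=(), time_constants=(), initial_F=100.0)
        t = np.linspace(0, 600, 1000)
        assert np.all(bl(t) == 100.0)

    def test_exponential_matches_closed_form(self):
        bl = BleachModel(kind="exponential", amplitudes=(0.3,), time_constants=(120.0,))
        t = np.linspace(0, 300, 500)
        expected = 100.0 * (0.7 + 0.3 * np.exp(-t / 120.0))
        np.testing.assert_allclose(bl(t), expected, rtol=1e-12)

    def test_biexponential_is_monotone_nonincreasing(self):
        bl = BleachModel(
            kind="bi-exponential", amplitudes=(0.15, 0.2), time_constants=(40.0, 300.0)
        )
        values = bl(np.linspace(0, 720, 2000))
        assert np.all(np.diff(values) <= 0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(kind="exponential", amplitudes=(0.3,), time_constants=(-5.0,)),
            dict(kind="exponential", amplitudes=(1.2,), time_constants=(100.0,)),
            dict(kind="bi-exponential", amplitudes=(0.6, 0.5), time_constants=(50.0, 200.0)),
            dict(kind="exponential", amplitudes=(0.2, 0.2), time_constants=(50.0, 100.0)),
        ],
    )
    def test_invalid_models_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BleachModel(**kwargs)


class TestKernel:
    @pytest.mark.parametrize(
        "rise_tau,decay_tau",
        [(0.01, 0.05), (0.03, 0.04), (0.1, 1.0), (0.3, 0.5), (0.002, 0.2)],
    )
    def test_metrics_match_dense_scan_oracle(self, rise_tau, decay_tau):
        k = TransientKernel(amplitude=0.08, rise_tau=rise_tau, decay_tau=decay_tau)
        exact = kernel_metrics(k)
        brute = dense_kernel_metrics(k)
        for key in ("fwhm", "rise_10_90", "decay_90_10", "peak_time"):
            assert exact[key] == pytest.approx(brute[key], rel=1e-3, abs=2e-5)
        assert k.evaluate(np.array([exact["peak_time"]]))[0] == pytest.approx(0.08, rel=1e-6)

    def test_peak_value_equals_amplitude(self):
        k = TransientKernel(amplitude=0.05, rise_tau=0.02, decay_tau=0.11)
        t = np.linspace(0, 2, 200001)
        assert k.evaluate(t).max() == pytest.approx(0.05, rel=1e-8)

    @pytest.mark.parametrize("fwhm,rise", [(0.8, 0.16), (1.0, 0.05), (0.086, 0.02)])
    def test_kernel_from_kinetics_roundtrip(self, fwhm, rise):
        k = kernel_from_kinetics(amplitude=0.04, fwhm=fwhm, rise_10_90=rise)
        m = kernel_metrics(k)
        assert m["fwhm"] == pytest.approx(fwhm, rel=1e-3)
        assert m["rise_10_90"] == pytest.approx(rise, rel=1e-3)

    def test_rise_fwhm_ratio_supremum(self):
        """The two-exponential family cannot exceed rise/FWHM ~ 0.233 (the
        gamma-shape limit); requests above it clip to the limiting shape."""
        lo, hi = achievable_rise_fwhm_ratio()
        assert hi == pytest.approx(0.2330, abs=2e-3)

    def test_shape_ratio_is_monotone_in_rho(self):
        tab = _shape_table()
        assert np.all(np.diff(tab["ratio"]) > 0)

    def test_out_of_range_ratio_clips_but_keeps_fwhm(self):
        lo, hi = achievable_rise_fwhm_ratio()
        k = kernel_from_kinetics(amplitude=0.05, fwhm=1.0, rise_10_90=2.0 * hi)
        m = kernel_metrics(k)
        assert m["fwhm"] == pytest.approx(1.0, rel=1e-3)

    def test_invalid_taus_rejected(self):
        with pytest.raises(ValueError):
            TransientKernel(amplitude=0.05, rise_tau=0.2, decay_tau=0.1)
        with pytest.raises(ValueError):
            TransientKernel(amplitude=-0.05, rise_tau=0.01, decay_tau=0.1)


class TestSimulateTrace:
    def test_identity_case(self):
        bl = BleachModel(kind="none", amplitudes=(), time_constants=(), initial_F=100.0)
        trace, truth = simulate_trace(bl, [], noise_sd=0.0, duration=20.0)
        assert np.all(trace.values == 100.0)
        assert truth.empty

    def test_bleach_only_matches_closed_form(self):
        bl = BleachModel(kind="exponential", amplitudes=(0.3,), time_constants=(120.0,))
        trace, _ = simulate_trace(bl, [], noise_sd=0.0, duration=60.0)
        # frame value = mean over the exposure; compare at dense precision
        t = (np.arange(600) + 0.5) * 0.1
        expected = 100.0 * (0.7 + 0.3 * np.exp(-t / 120.0))
        np.testing.assert_allclose(trace.values, expected, rtol=2e-7)

    def test_ground_truth_fwhm_matches_brute_force(self, standard_kernel):
        _, truth = simulate_trace(BleachModel(), [standard_kernel], duration=30.0)
        brute = dense_kernel_metrics(standard_kernel, dt=1e-4)
        assert truth.loc[0, "fwhm"] == pytest.approx(brute["fwhm"], rel=1e-3)

    def test_event_outside_recording_rejected(self):
        k = TransientKernel(amplitude=0.05, rise_tau=0.02, decay_tau=0.1, onset_time=99.0)
        with pytest.raises(ValueError, match="outside the recording"):
            simulate_trace(BleachModel(), [k], duration=30.0)

    def test_deterministic_given_seed(self):
        spont = SpontaneousModel(rate=0.5)
        a, ta = simulate_trace(BleachModel(), [], spont=spont, noise_sd=0.4, duration=40.0, seed=3)
        b, tb = simulate_trace(BleachModel(), [], spont=spont, noise_sd=0.4, duration=40.0, seed=3)
        np.testing.assert_array_equal(a.values, b.values)
        pd.testing.assert_frame_equal(ta, tb)

    def test_ground_truth_closure(self, rng):
        """Every injected event appears exactly once; no spurious rows."""
        kernels = [
            TransientKernel(amplitude=0.05, rise_tau=0.02, decay_tau=0.1, onset_time=float(t))
            for t in (5.0, 15.0, 25.0)
        ]
        spont = SpontaneousModel(rate=0.4)
        _, truth = simulate_trace(
            BleachModel(), kernels, spont=spont, noise_sd=0.3, duration=60.0, seed=11
        )
        evoked = truth[truth["kind"] == "evoked"]
        assert sorted(evoked["onset_time"]) == [5.0, 15.0, 25.0]
        n_spont = (truth["kind"] == "spontaneous").sum()
        assert len(truth) == 3 + n_spont
        assert truth["onset_time"].between(0, 60).all()


class TestSimulateMovie:
    def test_constant_trace_paints_roi(self):
        tr = Trace(roi_id=1, values=np.full(20, 50.0), frame_rate=10.0)
        rois = disk_rois([(16, 16)], 4, (32, 32))
        movie, rois_out, shifts = simulate_movie([tr], rois, jitter=0, background_level=10.0)
        sel = rois_out.label_mask == 1
        for frame in movie.frames:
            assert np.all(frame[sel] == 50.0)
            assert np.all(frame[~sel] == 10.0)
        assert (shifts[["dy", "dx"]].to_numpy() == 0).all()

    def test_true_shift_table_equals_applied(self, rng):
        tr = Trace(roi_id=1, values=np.full(30, 80.0), frame_rate=10.0)
        rois = disk_rois([(20, 20)], 4, (40, 40))
        applied = rng.integers(-3, 4, size=(30, 2))
        _, _, table = simulate_movie([tr], rois, jitter=3, shifts=applied)
        np.testing.assert_array_equal(table[["dy", "dx"]].to_numpy(), applied)

    def test_roi_near_edge_with_jitter_rejected(self):
        tr = Trace(roi_id=1, values=np.full(10, 50.0), frame_rate=10.0)
        rois = disk_rois([(5, 5)], 4, (32, 32))
        with pytest.raises(ValueError, match="jitter"):
            simulate_movie([tr], rois, jitter=3)

    def test_two_rois_round_trip_through_extraction(self):
        t1 = Trace(roi_id=1, values=np.full(15, 40.0), frame_rate=10.0)
        t2 = Trace(roi_id=2, values=np.full(15, 90.0), frame_rate=10.0)
        rois = disk_rois([(16, 16), (16, 40)], 5, (32, 56))
        movie, rois_out, _ = simulate_movie([t1, t2], rois, jitter=0)
        out = extract_traces(movie, rois_out)
        np.testing.assert_allclose(out[0].values, 40.0)
        np.testing.assert_allclose(out[1].values, 90.0)

    def test_overlapping_rois_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            disk_rois([(16, 16), (16, 20)], 5, (32, 32))


class TestCohort:
    def test_sigma_from_median_ci(self):
        # wider CI or smaller n -> larger implied dispersion
        s1 = lognormal_sigma_from_median_ci(0.8, 1.25, 100)
        s2 = lognormal_sigma_from_median_ci(0.5, 2.0, 100)
        s3 = lognormal_sigma_from_median_ci(0.8, 1.25, 25)
        assert s2 > s1
        # same CI width from a smaller sample implies *less* dispersion
        assert s3 == pytest.approx(s1 / 2)

    def test_zero_block_fraction_silences_antagonist_epoch(self):
        groups = {
            "WKY": GroupKinetics(
                amplitude_median=0.033, fwhm_median=0.086, rise_median=0.02,
                amplitude_sigma=0.5, fwhm_sigma=0.3, block_fraction=0.0, block_sigma=0.0,
            )
        }
        cfg = CohortConfig(groups=groups, n_cells={"WKY": 5}, noise_sd=0.0)
        cohort = simulate_cohort(cfg, seed=0)
        ant = cohort.events[cohort.events["epoch"] == "antagonist"]
        assert ant.empty  # zero-amplitude events are not injected
        truth = cohort.epoch_truth
        assert (truth.loc[truth["epoch"] == "antagonist", "true_amplitude"] == 0).all()

    def test_cohort_deterministic(self):
        cfg = CohortConfig(n_cells={"WKY": 4, "SHR": 4}, epochs=("baseline",))
        a = simulate_cohort(cfg, seed=5)
        b = simulate_cohort(cfg, seed=5)
        pd.testing.assert_frame_equal(a.cells, b.cells)
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.values, tb.values)

    def test_parameter_medians_converge(self, rng):
        """Calibration: over 10^4 cells the empirical medians match the
        configured group medians to better than 2%."""
        cfg = CohortConfig(n_cells={"WKY": 40000, "SHR": 40000})
        cells = draw_cell_parameters(cfg, rng)
        for genotype, g in (("WKY", WKY), ("SHR", SHR)):
            sub = cells[cells["genotype"] == genotype]
            assert sub["amplitude"].median() == pytest.approx(g.amplitude_median, rel=0.02)
            assert sub["fwhm"].median() == pytest.approx(g.fwhm_median, rel=0.02)
            assert sub["rise_10_90"].median() == pytest.approx(g.rise_median, rel=0.02)

    def test_emergent_decay_close_to_reported_medians(self, rng):
        """The two-exponential pulse fixed by (FWHM, rise) medians implies a
        90-10% decay median within ~5% of the reported group values."""
        cfg = CohortConfig(n_cells={"WKY": 4000, "SHR": 4000})
        cells = draw_cell_parameters(cfg, rng)
        wky = cells[cells["genotype"] == "WKY"]["decay_90_10"].median()
        shr = cells[cells["genotype"] == "SHR"]["decay_90_10"].median()
        assert wky == pytest.approx(0.1183, rel=0.05)
        assert shr == pytest.approx(0.1967, rel=0.08)

    def test_epoch_truth_is_exact_trial_mean(self):
        cfg = CohortConfig(n_cells={"WKY": 3, "SHR": 3})
        cohort = simulate_cohort(cfg, seed=2)
        ev = cohort.events
        for (cell, epoch), grp in ev.groupby(["cell_id", "epoch"]):
            row = cohort.epoch_truth.query("cell_id == @cell and epoch == @epoch")
            assert row["true_amplitude"].iloc[0] == pytest.approx(grp["amplitude"].mean())
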