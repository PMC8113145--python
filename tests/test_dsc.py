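"""DSC perfusion: dR2* conversion, leakage correction, CBV integration, hotspot rCBV."""

import numpy as np
import pytest

import gliodiff as g
from gliodiff.cohort import gamma_variate_bolus
from gliodiff.dsc import running_integral

ACQ = g.DscAcquisition(te=0.032, tr=1.9, n_frames=50, baseline_window=(0, 8))


def make_series(signal, acq=ACQ):
    return g.DscSeries(times=acq.times, signal=np.asarray(signal, float), acquisition=acq)


def bolus(acq=ACQ, peak=0.01):
    return gamma_variate_bolus(acq.times, t0=10 * acq.tr, alpha=3.0, beta=1.5 * acq.tr,
                               peak=peak)


class TestDeltaR2star:
    def test_constant_signal_gives_zero(self):
        dr2 = g.delta_r2star(make_series(np.full(50, 800.0)))
        assert np.allclose(dr2.values, 0.0)

    def test_inverse_construction(self):
        x = bolus()
        dr2 = g.delta_r2star(make_series(1000.0 * np.exp(-ACQ.te * x)))
        assert np.allclose(dr2.values, x, atol=1e-12)

    def test_known_peak_recovered(self):
        # grid dense enough to contain the analytic peak time t0 + alpha*beta
        acq = g.DscAcquisition(te=0.032, tr=0.19, n_frames=500, baseline_window=(0, 80))
        x = gamma_variate_bolus(acq.times, t0=100 * acq.tr, alpha=3.0,
                                beta=1.5 * acq.tr * 10, peak=0.02)
        dr2 = g.delta_r2star(g.DscSeries(acq.times, 500.0 * np.exp(-acq.te * x), acq))
        assert dr2.values.max() == pytest.approx(0.02, rel=1e-6)

    def test_nonpositive_signal_names_frame(self):
        sig = np.full(50, 100.0)
        sig[13] = 0.0
        with pytest.raises(ValueError, match="13"):
            g.delta_r2star(make_series(sig))

    def test_scale_equivariance(self):
        """Multiplying the signal by a constant leaves dR2*, k1, k2 unchanged."""
        x = bolus()
        big_r = running_integral(g.DeltaR2Series(ACQ.times, x))
        target_vals = 1.4 * x - 0.03 * big_r
        for scale in (1.0, 7.3):
            sig = scale * 1000.0 * np.exp(-ACQ.te * target_vals)
            ref_sig = scale * 1000.0 * np.exp(-ACQ.te * x)
            dt = g.delta_r2star(make_series(sig))
            dr = g.delta_r2star(make_series(ref_sig))
            fit = g.bw_fit(dt, dr)
            assert fit.k1 == pytest.approx(1.4, abs=1e-9)
            assert fit.k2 == pytest.approx(0.03, abs=1e-9)


class TestReferenceCurve:
    def test_single_series_is_itself(self):
        a = g.DeltaR2Series(ACQ.times, bolus())
        out = g.reference_curve([a])
        assert np.array_equal(out.values, a.values)

    def test_two_series_mean(self):
        a = g.DeltaR2Series(ACQ.times, bolus())
        b = g.DeltaR2Series(ACQ.times, 3.0 * bolus())
        out = g.reference_curve([a, b])
        assert np.allclose(out.values, 2.0 * bolus())

    def test_law_of_large_numbers(self, rng):
        clean = bolus()
        sd = 0.002
        noisy = [g.DeltaR2Series(ACQ.times, clean + rng.normal(0, sd, clean.shape))
                 for _ in range(100)]
        out = g.reference_curve(noisy)
        assert np.max(np.abs(out.values - clean)) < sd / 10 * 5  # SD/10 per point, 5-sigma slack

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            g.reference_curve([], mask=None)


class TestBwFit:
    def test_target_equals_reference(self):
        ref = g.DeltaR2Series(ACQ.times, bolus())
        fit = g.bw_fit(ref, ref)
        assert fit.k1 == pytest.approx(1.0, abs=1e-12)
        assert fit.k2 == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.corrected.values, ref.values, atol=1e-12)

    def test_exact_generative_inversion(self):
        ref = g.DeltaR2Series(ACQ.times, bolus())
        big_r = running_integral(ref)
        target = g.DeltaR2Series(ACQ.times, 1.3 * ref.values - 0.04 * big_r)
        fit = g.bw_fit(target, ref)
        assert fit.k1 == pytest.approx(1.3, abs=1e-8)
        assert fit.k2 == pytest.approx(0.04, abs=1e-8)

    def test_correction_direction(self):
        """T1-dominant leakage (k2 > 0) depresses the curve; correction restores area."""
        ref = g.DeltaR2Series(ACQ.times, bolus())
        target = g.DeltaR2Series(ACQ.times, ref.values - 0.05 * running_integral(ref))
        fit = g.bw_fit(target, ref)
        assert g.cbv_integrate(fit.corrected) >= g.cbv_integrate(target)

    def test_brute_force_oracle(self):
        """Closed-form LS equals grid search over (k1, k2) to grid resolution."""
        ref = g.DeltaR2Series(ACQ.times, bolus())
        big_r = running_integral(ref)
        rng = np.random.default_rng(5)
        target_vals = 1.2 * ref.values - 0.03 * big_r + rng.normal(0, 2e-4, 50)
        target = g.DeltaR2Series(ACQ.times, target_vals)
        fit = g.bw_fit(target, ref)
        k1_grid = np.linspace(0.8, 1.6, 161)
        k2_grid = np.linspace(-0.05, 0.10, 151)
        sse = np.array([[np.sum((target_vals - a * ref.values + b * big_r) ** 2)
                         for b in k2_grid] for a in k1_grid])
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert fit.k1 == pytest.approx(k1_grid[i], abs=0.005)
        assert fit.k2 == pytest.approx(k2_grid[j], abs=0.001)

    def test_noisy_k2_recovery_monte_carlo(self):
        """Mean recovered k2 within 10% of truth at 5%-of-peak noise, 200 replicates."""
        truth = g.PatientTruth(cbv_ratio=1.0, k2=0.05)
        tumor_clean, ref = g.gen_dsc_roi_curves(truth, noise_sd=0.0)
        dt = g.delta_r2star(tumor_clean)
        dr = g.delta_r2star(ref)
        sd = 0.05 * np.max(np.abs(dt.values))
        rng = np.random.default_rng(11)
        k2s = []
        for _ in range(200):
            noisy = g.DeltaR2Series(dt.times, dt.values + rng.normal(0, sd, 50))
            k2s.append(g.bw_fit(noisy, dr).k2)
        assert np.mean(k2s) == pytest.approx(0.05, rel=0.10)

    def test_degenerate_reference_rejected(self):
        const = g.DeltaR2Series(ACQ.times, np.full(50, 0.01))
        with pytest.raises(ValueError, match="degenerate|collinear"):
            g.bw_fit(const, const)


class TestCbvIntegrate:
    def test_zero_curve(self):
        assert g.cbv_integrate(g.DeltaR2Series(ACQ.times, np.zeros(50))) == 0.0

    def test_rectangle_area(self):
        times = np.linspace(0.0, 10.0, 2001)
        vals = np.where((times >= 2.0) & (times <= 6.0), 3.0, 0.0)
        area = g.cbv_integrate(g.DeltaR2Series(times, vals))
        assert area == pytest.approx(3.0 * 4.0, rel=0.01)

    def test_bolus_area_against_dense_quadrature(self):
        coarse = bolus()
        area50 = g.cbv_integrate(g.DeltaR2Series(ACQ.times, coarse))
        dense_t = np.linspace(0, ACQ.times[-1], 100_001)
        dense = gamma_variate_bolus(dense_t, t0=10 * ACQ.tr, alpha=3.0, beta=1.5 * ACQ.tr)
        oracle = np.trapezoid(dense, dense_t)
        assert area50 == pytest.approx(oracle, rel=0.005)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            g.cbv_integrate(g.DeltaR2Series(ACQ.times, bolus()), (5, 6))


class TestHotspotRcbv:
    def test_uniform_map_gives_unity(self):
        cbv = np.full(40, 3.0)
        tumor = np.zeros(40, bool); tumor[:15] = True
        contra = np.zeros(40, bool); contra[20:] = True
        assert g.hotspot_rcbv(cbv, tumor, contra, k=10).rcbv_max == pytest.approx(1.0)

    def test_hand_computation(self):
        cbv = np.array([1.0, 1.0, 5.0, 5.0, 2.0, 2.0, 2.0, 2.0])
        tumor = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        contra = ~tumor
        res = g.hotspot_rcbv(cbv, tumor, contra, k=2)
        assert (res.cbv_tumor, res.cbv_reference, res.rcbv_max) == (5.0, 2.0, 2.5)

    def test_generator_round_trip_ratio(self):
        """Voxel map built with true hotspot ratio 2.90 recovers rcbv_max = 2.90."""
        rng = np.random.default_rng(3)
        ref_val = 0.02
        contra_vals = np.full(30, ref_val)
        tumor_vals = np.concatenate([np.full(10, 2.90 * ref_val),
                                     rng.uniform(0.2, 0.8, 20) * 2.90 * ref_val])
        cbv = np.concatenate([tumor_vals, contra_vals])
        tumor = np.zeros(60, bool); tumor[:30] = True
        res = g.hotspot_rcbv(cbv, tumor, ~tumor, k=10)
        assert res.rcbv_max == pytest.approx(2.90, rel=1e-12)

    def test_overlapping_masks_rejected(self):
        cbv = np.ones(20)
        m = np.ones(20, bool)
        with pytest.raises(ValueError, match="overlap"):
            g.hotspot_rcbv(cbv, m, m, k=5)

    def test_nonpositive_reference_rejected(self):
        cbv = np.concatenate([np.ones(10), -np.ones(10)])
        tumor = np.zeros(20, bool); tumor[:10] = True
        with pytest.raises(ValueError, match="reference"):
            g.hotspot_rcbv(cbv, tumor, ~tumor, k=5)
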