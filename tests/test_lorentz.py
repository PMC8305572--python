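import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrdecon.io import Spectrum1D
from nmrdecon.lorentz import (
    DegenerateTripletError,
    LorentzPeak,
    iterate_fit,
    lorentz_eval,
    normalized_mse,
    reconstruct,
    solve_triplet,
)
from nmrdecon.peaks import PeakTriplet, detect_triplets
from .conftest import lorentz


def make_triplet(A, lam, x0, xl, xm, xr):
    return PeakTriplet(
        xl, xm, xr,
        float(lorentz(A, lam, x0, xl)),
        float(lorentz(A, lam, x0, xm)),
        float(lorentz(A, lam, x0, xr)),
    )


class TestSolveTriplet:
    def test_half_height_triplet(self):
        # points at x0 ± λ carry half the maximum height A/λ
        t = PeakTriplet(299, 300, 301, 100.0, 200.0, 100.0)
        pk = solve_triplet(t)
        assert pk.lambda_pts == pytest.approx(1.0)
        assert pk.x0_pts == pytest.approx(300.0)
        assert pk.A == pytest.approx(200.0)  # maximum A/λ = 200 with λ = 1
        assert pk.height == pytest.approx(200.0)

    def test_asymmetric_sampling_recovers_parameters(self):
        t = make_triplet(5.0, 3.0, 50.0, 47, 51, 55)
        pk = solve_triplet(t)
        assert pk.A == pytest.approx(5.0, rel=1e-9)
        assert pk.lambda_pts == pytest.approx(3.0, rel=1e-9)
        assert pk.x0_pts == pytest.approx(50.0, rel=1e-9)

    @given(
        A=st.floats(0.01, 1e4),
        lam=st.floats(0.5, 200.0),
        x0=st.floats(100.0, 10000.0),
        off1=st.integers(-80, -1),
        off2=st.integers(-30, 30),
        off3=st.integers(1, 80),
    )
    @settings(derandomize=True, max_examples=200)
    def test_substitution_residuals_vanish(self, A, lam, x0, off1, off2, off3):
        pts = sorted({int(x0) + off1, int(x0) + off2, int(x0) + off3})
        if len(pts) < 3:
            return
        xl, xm, xr = pts
        t = make_triplet(A, lam, x0, xl, xm, xr)
        pk = solve_triplet(t)
        for x, y in zip(t.indices, t.intensities):
            assert lorentz_eval(pk, np.array([x]))[0] == pytest.approx(y, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateTripletError):
            solve_triplet(PeakTriplet(1, 2, 3, 1.0, -2.0, 1.0))  # negative intensity
        with pytest.raises(DegenerateTripletError):
            solve_triplet(PeakTriplet(1, 2, 3, 2.0, 2.0, 2.0))  # flat: no curvature

    def test_scale_equivariance(self):
        t = make_triplet(5.0, 3.0, 50.0, 47, 51, 55)
        pk = solve_triplet(t)
        c = 17.5
        t2 = PeakTriplet(47, 51, 55, c * t.y_left, c * t.y_middle, c * t.y_right)
        pk2 = solve_triplet(t2)
        assert pk2.A == pytest.approx(c * pk.A, rel=1e-9)
        assert pk2.lambda_pts == pytest.approx(pk.lambda_pts, rel=1e-9)
        assert pk2.x0_pts == pytest.approx(pk.x0_pts, rel=1e-9)

    def test_translation_equivariance(self):
        t = make_triplet(5.0, 3.0, 50.0, 47, 51, 55)
        pk = solve_triplet(t)
        shift = 100000
        t2 = PeakTriplet(
            47 + shift, 51 + shift, 55 + shift, t.y_left, t.y_middle, t.y_right
        )
        pk2 = solve_triplet(t2)
        assert pk2.x0_pts - pk.x0_pts == pytest.approx(shift, rel=1e-12)
        assert pk2.A == pytest.approx(pk.A, rel=1e-9)
        assert pk2.lambda_pts == pytest.approx(pk.lambda_pts, rel=1e-9)


class TestLorentzEval:
    def test_maximum_and_half_height(self):
        pk = LorentzPeak(A=6.0, lambda_pts=3.0, x0_pts=40.0)
        assert lorentz_eval(pk, np.array([40.0]))[0] == pytest.approx(2.0)
        np.testing.assert_allclose(lorentz_eval(pk, np.array([37.0, 43.0])), 1.0)

    def test_symmetry(self):
        pk = LorentzPeak(A=2.0, lambda_pts=5.0, x0_pts=100.0)
        d = np.linspace(0, 50, 11)
        np.testing.assert_allclose(
            lorentz_eval(pk, 100.0 + d), lorentz_eval(pk, 100.0 - d)
        )


class TestReconstruct:
    def test_empty_list_gives_zero_vector(self, flat_axis):
        sp = flat_axis(np.ones(10))
        np.testing.assert_array_equal(reconstruct([], sp), np.zeros(10))

    def test_single_peak_matches_eval(self, flat_axis):
        sp = flat_axis(np.ones(50))
        pk = LorentzPeak(A=2.0, lambda_pts=4.0, x0_pts=25.0)
        np.testing.assert_allclose(
            reconstruct([pk], sp), lorentz_eval(pk, np.arange(50.0))
        )

    def test_linear_in_peak_list(self, flat_axis):
        sp = flat_axis(np.ones(50))
        p1 = LorentzPeak(A=2.0, lambda_pts=4.0, x0_pts=20.0)
        p2 = LorentzPeak(A=1.0, lambda_pts=6.0, x0_pts=35.0)
        np.testing.assert_allclose(
            reconstruct([p1, p2], sp), reconstruct([p1], sp) + reconstruct([p2], sp)
        )

    def test_excluded_points_zeroed(self, flat_axis):
        sp = flat_axis(np.ones(50))
        sp = sp.replace(excluded=np.arange(50) < 10)
        pk = LorentzPeak(A=2.0, lambda_pts=4.0, x0_pts=5.0)
        assert np.all(reconstruct([pk], sp)[:10] == 0)


class TestNormalizedMse:
    def test_identical_inputs_give_zero(self, flat_axis):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert normalized_mse(flat_axis(y), y) == 0.0

    def test_scaling_invariance(self, flat_axis):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert normalized_mse(flat_axis(y), 2.0 * y) == pytest.approx(0.0, abs=1e-30)

    def test_hand_computed_value(self, flat_axis):
        # normalized spectra [1,0,0,0] and [0,1,0,0]; MSE = (1+1)/4
        exp = flat_axis([1.0, 0.0, 0.0, 0.0])
        assert normalized_mse(exp, np.array([0.0, 1.0, 0.0, 0.0])) == pytest.approx(0.5)

    def test_zero_total_is_error(self, flat_axis):
        with pytest.raises(ValueError):
            normalized_mse(flat_axis(np.zeros(4)), np.ones(4))


class TestIterateFit:
    def test_isolated_peak_is_fixed_point(self, single_lorentzian):
        sp, (A, lam, x0) = single_lorentzian
        triplets = detect_triplets(sp)
        res = iterate_fit(sp, triplets, n_iter=10)
        assert res.mse_trace[0] <= 1e-20
        pk = res.peaks[0]
        assert pk.A == pytest.approx(A, rel=1e-6)
        assert pk.lambda_pts == pytest.approx(lam, rel=1e-6)
        assert pk.x0_pts == pytest.approx(x0, rel=1e-6)

    def test_zero_iterations_returns_initial_solves(self, single_lorentzian):
        sp, _ = single_lorentzian
        triplets = detect_triplets(sp)
        res = iterate_fit(sp, triplets, n_iter=0)
        assert len(res.mse_trace) == 1
        direct = solve_triplet(triplets[0])
        assert res.peaks[0].A == pytest.approx(direct.A)
        assert res.peaks[0].lambda_pts == pytest.approx(direct.lambda_pts)

    def test_overlapping_pair_refined_within_five_percent(self, flat_axis):
        x = np.arange(2000, dtype=float)
        lam, A = 20.0, 100.0
        c1, c2 = 980.0, 980.0 + 2 * lam
        y = lorentz(A, lam, c1, x) + lorentz(A, lam, c2, x)
        sp = flat_axis(y)
        triplets = detect_triplets(sp)
        assert len(triplets) == 2
        res = iterate_fit(sp, triplets, n_iter=10)
        best = min(res.mse_trace)
        assert best < res.mse_trace[0]
        for pk, c in zip(res.peaks, (c1, c2)):
            assert pk.A == pytest.approx(A, rel=0.05)
            assert pk.lambda_pts == pytest.approx(lam, rel=0.05)
            assert pk.x0_pts == pytest.approx(c, rel=0.05)

    def test_trace_length_and_best_iteration_contract(self, single_lorentzian):
        sp, _ = single_lorentzian
        res = iterate_fit(sp, detect_triplets(sp), n_iter=7)
        assert len(res.mse_trace) == 8
        assert res.best_iteration == int(np.argmin(res.mse_trace))
        assert res.mse_trace[res.best_iteration] <= res.mse_trace[0]

    def test_spectrum_scaling_scales_amplitudes_only(self, flat_axis):
        x = np.arange(2000, dtype=float)
        y = lorentz(100, 20, 900, x) + lorentz(50, 30, 1200, x)
        c = 7.0
        res1 = iterate_fit(flat_axis(y), detect_triplets(flat_axis(y)), n_iter=5)
        sp2 = flat_axis(c * y)
        res2 = iterate_fit(sp2, detect_triplets(sp2), n_iter=5)
        for p1, p2 in zip(res1.peaks, res2.peaks):
            assert p2.A == pytest.approx(c * p1.A, rel=1e-8)
            assert p2.lambda_pts == pytest.approx(p1.lambda_pts, rel=1e-8)
            assert p2.x0_pts == pytest.approx(p1.x0_pts, rel=1e-8)

    def test_no_triplets_is_error(self, single_lorentzian):
        sp, _ = single_lorentzian
        with pytest.raises(ValueError):
            iterate_fit(sp, [], n_iter=3)

    def test_ppm_reporting_filled_in(self, single_lorentzian):
        sp, (_, lam, x0) = single_lorentzian
        res = iterate_fit(sp, detect_triplets(sp), n_iter=0)
        pk = res.peaks[0]
        assert pk.x0_ppm == pytest.approx(float(sp.index_to_ppm(x0)), abs=1e-6)
        assert pk.lambda_ppm == pytest.approx(lam * sp.ppm_per_point, rel=1e-6)
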