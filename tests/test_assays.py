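import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from enzymof.assays import (
    CalibrationCurve,
    KineticTrace,
    Spectrum,
    TrialResult,
    compute_ee,
    compute_p_loading,
    compute_pi,
    compute_rea,
    compute_release,
    concentration_from_absorbance,
    fit_bca_calibration,
    initial_rate,
    second_derivative_peaks,
)
from enzymof.design_space import Recipe
from enzymof.errors import AssayError

STANDARD_CONCS = [0.125, 0.25, 0.5, 1.0]


class TestCalibration:
    def test_exact_line_recovered(self):
        standards = [(c, 0.8 * c + 0.05) for c in STANDARD_CONCS]
        curve = fit_bca_calibration(standards)
        assert curve.slope == pytest.approx(0.8)
        assert curve.intercept == pytest.approx(0.05)
        assert curve.r_squared == pytest.approx(1.0)

    def test_repeated_concentrations_allowed(self):
        standards = [(0.25, 0.25), (0.25, 0.26), (0.5, 0.45), (1.0, 0.85)]
        curve = fit_bca_calibration(standards)
        assert curve.slope > 0

    def test_noisy_standards_slope_within_5pct(self, rng):
        true_slope, true_intercept = 0.8, 0.05
        concs = np.tile(STANDARD_CONCS, 3)
        absb = true_slope * concs + true_intercept + rng.normal(0, 0.01, size=concs.size)
        curve = fit_bca_calibration(list(zip(concs, absb)))
        assert curve.slope == pytest.approx(true_slope, rel=0.05)

    @pytest.mark.parametrize(
        "standards",
        [[(0.5, 0.4), (1.0, 0.8)], [(0.5, 0.4), (0.5, 0.41), (0.5, 0.39)]],
    )
    def test_underdetermined_standards_rejected(self, standards):
        with pytest.raises(AssayError):
            fit_bca_calibration(standards)

    def test_inverse_mapping(self):
        curve = CalibrationCurve(slope=0.8, intercept=0.05, r_squared=1.0)
        assert concentration_from_absorbance(curve, 0.45) == pytest.approx(0.5)
        assert concentration_from_absorbance(curve, 0.05) == 0.0

    def test_absorbance_below_intercept_clips_with_warning(self):
        curve = CalibrationCurve(slope=0.8, intercept=0.05, r_squared=1.0)
        with pytest.warns(UserWarning, match="clipping"):
            assert concentration_from_absorbance(curve, 0.01) == 0.0

    def test_zero_slope_rejected(self):
        with pytest.raises(AssayError):
            concentration_from_absorbance(CalibrationCurve(0.0, 0.0, 1.0), 0.3)


class TestEncapsulationEfficiency:
    def test_extremes(self):
        assert compute_ee(0.1, 0.0, 0.5) == 100.0
        assert compute_ee(0.1, 0.2, 0.5) == 0.0  # residual equals input mass

    def test_headline_fixture_value(self):
        # 0.1 mg input, 0.0146 mg residual -> 85.4%
        assert compute_ee(0.1, 0.0146 / 0.5, 0.5) == pytest.approx(85.4)

    def test_residual_fraction_complements_ee(self):
        mass, conc, vol = 0.1, 0.03, 0.5
        ee = compute_ee(mass, conc, vol)
        residual_pct = 100.0 * conc * vol / mass
        assert ee + residual_pct == pytest.approx(100.0)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(AssayError):
            compute_ee(0.0, 0.1, 0.5)

    @given(
        mass=st.floats(1e-6, 10.0),
        conc=st.floats(0.0, 10.0),
        vol=st.floats(0.0, 10.0),
    )
    def test_always_in_unit_interval(self, mass, conc, vol):
        assert 0.0 <= compute_ee(mass, conc, vol) <= 100.0


class TestKinetics:
    def test_linear_trace_slope(self):
        t = np.arange(0.0, 125.0, 5.0)
        assert initial_rate(KineticTrace(t, 0.1 + 0.002 * t)) == pytest.approx(0.002)

    def test_saturating_trace_initial_slope_matches_rate_constant(self):
        k = 1e-3
        t = np.arange(0.0, 65.0, 5.0)
        trace = KineticTrace(t, 1.0 - np.exp(-k * t))
        assert initial_rate(trace) == pytest.approx(k, rel=0.05)

    def test_flat_trace_rate_zero(self):
        t = np.arange(0.0, 125.0, 5.0)
        assert initial_rate(KineticTrace(t, np.full_like(t, 0.3))) == 0.0

    @pytest.mark.parametrize(
        "times,absorb",
        [
            (np.array([0, 1, 2, 3]), np.array([0, 1, 2, 3])),  # too short
            (np.array([0, 1, 1, 2, 3]), np.zeros(5)),  # non-increasing times
        ],
    )
    def test_invalid_traces_rejected(self, times, absorb):
        with pytest.raises(AssayError):
            KineticTrace(times, absorb)

    def test_rea_examples(self):
        assert compute_rea(0.002, 0.002) == 100.0
        assert compute_rea(0.0, 0.002) == 0.0
        assert compute_rea(0.201, 1.0) == pytest.approx(20.1)

    def test_rea_not_clipped_above_100(self):
        assert compute_rea(0.003, 0.002) == pytest.approx(150.0)

    def test_rea_requires_positive_free_rate(self):
        with pytest.raises(AssayError):
            compute_rea(0.001, 0.0)


class TestPerformanceIndex:
    def test_headline_product(self):
        assert compute_pi(28.7, 20.1) == pytest.approx(0.0577, abs=5e-5)

    def test_extremes(self):
        assert compute_pi(50.0, 0.0) == 0.0
        assert compute_pi(100.0, 100.0) == 1.0

    @given(ee=st.floats(0, 100), rea=st.floats(0, 100))
    def test_in_unit_interval_for_physical_inputs(self, ee, rea):
        assert 0.0 <= compute_pi(ee, rea) <= 1.0

    def test_p_loading(self):
        assert compute_p_loading(0.042, 1.0) == pytest.approx(4.2)
        with pytest.raises(AssayError):
            compute_p_loading(0.1, 0.0)


class TestRelease:
    def test_no_release(self):
        out = compute_release(0.1, [(1.0, 0.0), (4.0, 0.0), (8.0, 0.0)])
        assert [p for _, p in out] == [0.0, 0.0, 0.0]

    def test_instant_total_release(self):
        out = compute_release(0.1, [(0.1, 0.1), (8.0, 0.1)])
        assert [p for _, p in out] == [100.0, 100.0]

    def test_half_release(self):
        assert compute_release(0.1, [(8.0, 0.05)])[0][1] == pytest.approx(50.0)

    def test_decreasing_series_warns_and_keeps_running_max(self):
        with pytest.warns(UserWarning, match="decreased"):
            out = compute_release(0.1, [(1.0, 0.05), (2.0, 0.03)])
        assert out[1][1] == pytest.approx(50.0)


def _gaussian(x, center, width):
    return np.exp(-0.5 * ((x - center) / width) ** 2)


class TestSecondDerivativePeaks:
    def test_two_component_bands_resolved(self):
        # Band width 8 nm: narrow enough that the second-derivative minima of
        # the overlapped envelope coincide with the true centers within 1 nm
        # (at width 12 the overlap analytically shifts them to ~326.5/355.5).
        wl = np.arange(290.0, 411.0, 1.0)
        spec = Spectrum(wl, _gaussian(wl, 328, 8) + 0.9 * _gaussian(wl, 354, 8))
        peaks = second_derivative_peaks(spec)
        assert len(peaks) == 2
        assert abs(peaks[0] - 328) <= 1.0
        assert abs(peaks[1] - 354) <= 1.0

    def test_single_band(self):
        wl = np.arange(300.0, 401.0, 1.0)
        peaks = second_derivative_peaks(Spectrum(wl, _gaussian(wl, 340, 15)))
        assert len(peaks) == 1
        assert abs(peaks[0] - 340) <= 1.0

    def test_flat_spectrum_has_no_bands(self):
        wl = np.arange(300.0, 401.0, 1.0)
        assert second_derivative_peaks(Spectrum(wl, np.ones_like(wl))) == []

    def test_invariant_to_intensity_scaling(self):
        wl = np.arange(290.0, 411.0, 1.0)
        inten = _gaussian(wl, 328, 8) + 0.9 * _gaussian(wl, 354, 8)
        base = second_derivative_peaks(Spectrum(wl, inten))
        scaled = second_derivative_peaks(Spectrum(wl, 1e4 * inten))
        assert base == scaled

    def test_window_validation(self):
        wl = np.arange(300.0, 316.0, 1.0)
        spec = Spectrum(wl, _gaussian(wl, 308, 3))
        with pytest.raises(AssayError):
            second_derivative_peaks(spec, window=21)
        with pytest.raises(AssayError):
            second_derivative_peaks(spec, window=10)


class TestTrialResult:
    def test_pi_autocomputed_from_ee_and_rea(self):
        t = TrialResult(recipe=Recipe(50, 70, 1.0), ee=28.7, rea=20.1)
        assert t.pi == pytest.approx(0.0577, abs=5e-5)
        assert t.target_value("PI") == t.pi
        assert t.target_value("EE") == 28.7

    def test_out_of_range_ee_rejected(self):
        with pytest.raises(AssayError):
            TrialResult(recipe=Recipe(50, 70, 1.0), ee=101.0)

    def test_failed_trials_skip_validation(self):
        t = TrialResult(recipe=Recipe(50, 70, 1.0), ee=float("nan"), status="failed")
        assert t.status == "failed"
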