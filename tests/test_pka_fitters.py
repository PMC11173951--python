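"""The three pKa estimators, electrode calibration and agreement stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boronpka import (
    AcidSystem,
    ElectrodeCal,
    NoiseSpec,
    SpectroSeries,
    TitrationCurve,
    calibrate_electrode,
    compare_methods,
    equivalence_volume,
    fit_half_neutralization,
    fit_potentiometric_full,
    fit_spectrophotometric_hh,
    generate_potentiometric,
    generate_spectrophotometric,
    locate_equivalence,
    nernst_emf,
    titration_curve,
)
from boronpka.synthetic_data import NOISELESS

from _oracles import grid_search_hh, grid_search_p1, oracle_ph


def make_spectro(pka, noise=NOISELESS, n=25, dilution=None):
    template = SpectroSeries(
        ph_values=np.linspace(5.0, 11.0, n),
        absorbance=np.zeros(n),
        eps_acid=500.0,
        eps_base=1800.0,
        c_total=1e-3,
        dilution_factors=dilution,
    )
    return generate_spectrophotometric(pka, template, noise)


class TestElectrodeCalibration:
    def test_two_point_exact(self):
        cal = calibrate_electrode([4.0, 7.0], [163.36, -14.12])
        assert cal.e0 == pytest.approx(400.0, abs=1e-9)
        assert cal.slope == pytest.approx(59.16, abs=1e-9)

    def test_four_noise_free_buffers_exact(self):
        truth = ElectrodeCal(e0=395.0, slope=58.1)
        buffers = [2.0, 4.0, 7.0, 9.0]
        cal = calibrate_electrode(buffers, nernst_emf(truth, buffers))
        assert cal.e0 == pytest.approx(truth.e0, abs=1e-9)
        assert cal.slope == pytest.approx(truth.slope, abs=1e-9)

    def test_noisy_buffers_recover_within_3_stderr(self):
        truth = ElectrodeCal(e0=400.0, slope=59.16)
        buffers = np.array([2.0, 4.0, 7.0, 9.0])
        rng = np.random.default_rng(5)
        misses = 0
        for _ in range(200):
            emf = nernst_emf(truth, buffers) + rng.normal(0, 0.3, 4)
            cal = calibrate_electrode(buffers, emf)
            # OLS slope sd for 4 points at these abscissae, sigma=0.3 mV
            sx2 = np.sum((buffers - buffers.mean()) ** 2)
            se_slope = 0.3 / np.sqrt(sx2)
            if abs(cal.slope - truth.slope) > 3 * se_slope:
                misses += 1
        assert misses <= 10  # ~0.3% expected outside 3 sigma

    def test_needs_two_distinct_buffers(self):
        with pytest.raises(ValueError):
            calibrate_electrode([7.0, 7.0], [0.0, 0.1])


class TestPotentiometricFull:
    def test_noise_free_recovery_to_1e6(self):
        truth = AcidSystem(pka=8.20, c_acid=1e-3, v0=50.0, c_base=0.05)
        curve = titration_curve(truth, np.linspace(0.0, 2.0, 50))
        result = fit_potentiometric_full(curve, truth.with_(pka=7.5))
        assert result.converged
        assert result.pka == pytest.approx(8.20, abs=1e-6)
        assert result.residual_rms < 1e-8

    def test_noisy_estimate_within_3_stderr(self):
        truth = AcidSystem(pka=7.95, c_acid=1e-3, v0=50.0, c_base=0.05)
        curve = generate_potentiometric(truth, noise=NoiseSpec(seed=1))
        result = fit_potentiometric_full(curve, truth.with_(pka=8.5))
        assert result.converged
        assert result.stderr is not None and result.stderr > 0
        assert abs(result.pka - 7.95) < 3 * result.stderr

    def test_equals_grid_search_oracle(self):
        truth = AcidSystem(pka=7.95, c_acid=1e-3, v0=50.0, c_base=0.05)
        curve = generate_potentiometric(
            truth, np.linspace(0.0, 2.0, 40), noise=NoiseSpec(seed=11)
        )
        result = fit_potentiometric_full(curve, truth.with_(pka=8.5))
        oracle = grid_search_p1(
            curve.volumes, curve.readings,
            truth.c_acid, truth.v0, truth.c_base, truth.pkw,
            center=7.95,
        )
        assert result.pka == pytest.approx(oracle, abs=1e-4)

    def test_emf_curve_with_calibration(self, weak_system):
        cal = ElectrodeCal(e0=400.0, slope=59.16)
        curve = generate_potentiometric(
            weak_system, np.linspace(0.0, 2.0, 40), cal=cal, noise=NOISELESS
        )
        result = fit_potentiometric_full(curve, weak_system.with_(pka=8.0), cal=cal)
        assert result.pka == pytest.approx(weak_system.pka, abs=1e-6)

    def test_co_fit_c_acid_on_noise_free_data(self):
        truth = AcidSystem(pka=8.20, c_acid=1.2e-3, v0=50.0, c_base=0.05)
        curve = titration_curve(truth, np.linspace(0.0, 3.0, 60))
        init = truth.with_(pka=7.8, c_acid=1e-3)
        result = fit_potentiometric_full(curve, init, fit_c_acid=True)
        assert result.pka == pytest.approx(8.20, abs=1e-5)
        assert result.diagnostics["c_acid"] == pytest.approx(1.2e-3, rel=1e-4)

    def test_degenerate_inputs_rejected(self, weak_system):
        flat = TitrationCurve(np.arange(5.0), np.full(5, 7.0))
        with pytest.raises(ValueError):
            fit_potentiometric_full(flat, weak_system)
        short = TitrationCurve(np.arange(3.0), np.array([5.0, 6.0, 7.0]))
        with pytest.raises(ValueError):
            fit_potentiometric_full(short, weak_system)


class TestEquivalenceLocation:
    def test_ideal_curve_within_one_step(self, weak_system, fine_schedule):
        curve = titration_curve(weak_system, fine_schedule)
        veq = locate_equivalence(curve)
        assert abs(veq - equivalence_volume(weak_system)) <= 0.02 + 1e-12

    def test_strong_buffer_curve_on_the_nose(self, strong_buffer_system):
        curve = titration_curve(strong_buffer_system, np.linspace(0.0, 20.0, 101))
        veq = locate_equivalence(curve)
        assert veq == pytest.approx(10.0, abs=0.2)

    def test_spurious_plateaus_single_global_max(self):
        # piecewise curve: two mild bumps, one dominant interior jump at v=6
        v = np.arange(0.0, 10.5, 0.5)
        ph = 4 + 0.1 * v
        ph[v >= 3.0] += 0.3   # mild step
        ph[v >= 6.0] += 3.0   # dominant step
        ph[v >= 8.5] += 0.3   # mild step
        curve = TitrationCurve(v, ph)
        assert locate_equivalence(curve) == pytest.approx(6.0, abs=0.5)

    def test_linear_ramp_has_no_interior_maximum(self):
        curve = TitrationCurve(np.linspace(0, 5, 20), np.linspace(4, 9, 20))
        with pytest.raises(ValueError, match="no interior maximum"):
            locate_equivalence(curve)

    def test_truncated_titration_rejected(self, weak_system):
        curve = titration_curve(weak_system, np.linspace(0.3, 0.9, 31))
        with pytest.raises(ValueError, match="no interior maximum"):
            locate_equivalence(curve)

    def test_tie_resolves_to_run_midpoint(self):
        v = np.arange(0.0, 5.5, 0.5)
        ph = np.array([4.0, 4.1, 4.2, 4.3, 5.3, 6.3, 7.3, 7.4, 7.5, 7.6, 7.7])
        curve = TitrationCurve(v, ph)
        # central differences give an equal-maximum run at v = 2.0 and 2.5
        assert locate_equivalence(curve) == pytest.approx(2.25, abs=1e-12)


class TestHalfNeutralization:
    def test_strong_buffer_recovery(self, strong_buffer_system):
        curve = titration_curve(strong_buffer_system, np.linspace(0.0, 20.0, 101))
        result = fit_half_neutralization(curve)
        assert result.method == "P2"
        assert result.pka == pytest.approx(5.00, abs=0.02)

    def test_weak_acid_negative_bias_decomposition(self, weak_system, fine_schedule):
        """P2's bias splits into the hydroxide offset at the true Veq/2
        (independently computed ≈ -0.01) plus an endpoint-location shift
        bounded by one half volume-step times the buffer slope."""
        curve = titration_curve(weak_system, fine_schedule)
        # oracle offset: pH at the true half-equivalence volume
        oracle_offset = float(oracle_ph(8.76, 1e-3, 50.0, 0.05, 0.5)) - 8.76
        assert oracle_offset == pytest.approx(-0.0099, abs=0.001)
        # read-off component alone (true Veq known): matches the oracle
        read_off = float(np.interp(0.5, curve.volumes, curve.readings))
        assert read_off - 8.76 == pytest.approx(oracle_offset, abs=1e-3)
        # full pipeline: adds the endpoint-location shift, stays negative
        result = fit_half_neutralization(curve)
        slope_at_half = 1.8  # pH/mL for this system near Veq/2
        budget = abs(oracle_offset) + 0.02 * slope_at_half
        assert -budget < result.pka - 8.76 < 0

    def test_bias_tracks_oracle_offset_across_conditions(self):
        """P2's systematic error equals the oracle-computed offset
        pH(Veq/2) - pKa up to the endpoint-location error; the offset is
        negative at the weak end (hydroxide term) and positive for dilute
        stronger acids (free-proton term). Either way it is the built-in
        inaccuracy that makes P2 the quick-but-cruder method."""
        for pka in [4.0, 5.0, 6.5, 8.0, 9.0]:
            for c_acid in [1e-3, 5e-3, 1e-2]:
                system = AcidSystem(pka=pka, c_acid=c_acid, v0=50.0, c_base=0.05)
                veq = equivalence_volume(system)
                curve = titration_curve(system, np.linspace(0, 2 * veq, 101))
                bias = fit_half_neutralization(curve).pka - pka
                offset = float(
                    oracle_ph(pka, c_acid, 50.0, 0.05, veq / 2.0)
                ) - pka
                assert bias == pytest.approx(offset, abs=0.05)

    def test_truncated_curve_errors(self, weak_system):
        curve = titration_curve(weak_system, np.linspace(0.0, 0.9, 46))
        with pytest.raises(ValueError):
            fit_half_neutralization(curve)


class TestSpectrophotometric:
    def test_noise_free_recovery_exact(self):
        series = make_spectro(7.32)
        result = fit_spectrophotometric_hh(series)
        assert result.converged
        assert result.pka == pytest.approx(7.32, abs=1e-6)

    def test_fitted_midpoint_identity(self):
        series = make_spectro(7.32)
        result = fit_spectrophotometric_hh(series)
        a_acid = result.diagnostics["a_acid"]
        a_base = result.diagnostics["a_base"]
        r = 10.0 ** (result.pka - result.pka)
        a_at_pka = (a_acid + a_base * r) / (1 + r)
        assert a_at_pka == pytest.approx(0.5 * (a_acid + a_base), rel=1e-12)

    def test_dilution_correction_restores_pka(self):
        dil = np.linspace(1.0, 1.4, 25)
        series = make_spectro(7.32, dilution=dil)
        result = fit_spectrophotometric_hh(series)
        assert result.pka == pytest.approx(7.32, abs=1e-6)

    def test_noisy_estimate_within_3_stderr_and_equals_grid_oracle(self):
        series = make_spectro(7.32, NoiseSpec(sigma_reading=0.003, seed=7))
        result = fit_spectrophotometric_hh(series)
        assert abs(result.pka - 7.32) < 3 * result.stderr
        a = series.absorbance
        oracle = grid_search_hh(series.ph_values, a, center=7.32)
        assert result.pka == pytest.approx(oracle, abs=1e-4)

    def test_flat_series_rejected(self):
        flat = SpectroSeries(np.linspace(5, 9, 10), np.full(10, 0.5))
        with pytest.raises(ValueError):
            fit_spectrophotometric_hh(flat)


def test_p1_and_s_agree_on_matched_noise_free_system():
    """Same underlying pKa observed potentiometrically and optically must
    fit to the same value to solver precision."""
    truth = AcidSystem(pka=8.10, c_acid=1e-3, v0=50.0, c_base=0.05)
    curve = titration_curve(truth, np.linspace(0.0, 2.0, 50))
    p1 = fit_potentiometric_full(curve, truth.with_(pka=7.5)).pka
    s = fit_spectrophotometric_hh(make_spectro(8.10)).pka
    assert p1 == pytest.approx(s, abs=1e-6)


class TestCompareMethods:
    def test_identical_vectors(self):
        cmp = compare_methods([("a", 7.0, 7.0), ("b", 8.1, 8.1)])
        assert cmp.rms == 0.0 and cmp.max_abs == 0.0 and cmp.n == 2

    def test_missing_pairs_dropped_and_counted(self):
        cmp = compare_methods(
            [("a", 7.0, 7.2), ("b", None, 8.1), ("c", 6.9, float("nan"))]
        )
        assert cmp.n == 1 and cmp.n_missing == 2
        assert cmp.rms == pytest.approx(0.2, abs=1e-12)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            compare_methods([("a", None, 7.0)])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.floats(3, 11), st.floats(3, 11)),
            min_size=1, max_size=20,
        )
    )
    def test_stat_ordering_invariant(self, values):
        pairs = [(str(i), a, b) for i, (a, b) in enumerate(values)]
        cmp = compare_methods(pairs)
        assert cmp.mean_abs <= cmp.rms <= cmp.max_abs + 1e-12
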