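"""ECN scores, calibration fits, QC statistics and unit conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aromaquant.calibration import (CalibrationRangeError, DegenerateDesignError,
                                    EcnCoefficients, RFModel, SamplingGeometry,
                                    compute_ecn, fit_calibration_curve,
                                    fit_rf_vs_ecn, ppb_to_ugm3, predict_rf,
                                    quantify, rf_cv, rf_rse, ugm3_to_ppb)
from aromaquant.registry import MoietyCounts


def ecn_oracle(m: MoietyCounts, k: EcnCoefficients = EcnCoefficients()) -> float:
    """Independent brute force: expand the molecule into an explicit list of
    (coefficient) contributions, one entry per atom/moiety, and sum."""
    contributions = ([k.c_C] * m.n_C + [k.c_H] * m.n_H + [k.c_O] * m.n_O
                     + [k.c_carbonyl] * m.n_carbonyl
                     + [k.c_ether] * m.n_ether + [k.c_methyl] * m.n_methyl)
    return float(sum(contributions))


class TestEcn:
    @pytest.mark.parametrize("counts, expected", [
        ((0, 0, 0, 0, 0, 0), 0.0),
        ((5, 12, 0, 0, 0, 2), 4.88),    # n-pentane
        ((3, 6, 1, 1, 0, 2), 2.14),     # acetone
        ((4, 8, 2, 1, 1, 2), 3.62),     # ethyl acetate
    ])
    def test_hand_computed_examples(self, counts, expected):
        m = MoietyCounts(*counts)
        assert compute_ecn(m) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(c=st.integers(0, 20), o=st.integers(0, 4),
           car=st.integers(0, 4), eth=st.integers(0, 4), me=st.integers(0, 6))
    def test_matches_brute_force_oracle(self, c, o, car, eth, me):
        if car + eth > o:
            o = car + eth
        m = MoietyCounts(c, 3 * me + 2 * c, o, car, eth, me)
        assert compute_ecn(m) == pytest.approx(ecn_oracle(m), abs=1e-12)


class TestCalibrationCurve:
    def test_exact_line_through_origin(self):
        pts = [(x, 100.0 * x) for x in (1.3, 6.52, 13.0, 26.1, 65.2)]
        fit = fit_calibration_curve(pts)
        assert fit.rf == pytest.approx(100.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_single_repeated_loading_is_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            fit_calibration_curve([(5.0, 500.0), (5.0, 501.0)])

    def test_noisy_recovery_of_true_rf(self):
        rng = np.random.default_rng(123)
        true_rf = 250.0
        pts = [(x, true_rf * x * rng.lognormal(sigma=0.02))
               for x in (1.3, 6.52, 13.0, 26.1, 65.2)]
        fit = fit_calibration_curve(pts)
        assert abs(fit.rf - true_rf) / true_rf < 0.03
        assert fit.r2 > 0.99

    def test_mean_ratio_estimator_agrees_on_clean_data(self):
        pts = [(x, 40.0 * x) for x in (1.0, 2.0, 4.0)]
        a = fit_calibration_curve(pts, estimator="zero_intercept")
        b = fit_calibration_curve(pts, estimator="mean_ratio")
        assert a.rf == pytest.approx(b.rf)


class TestSpreadStatistics:
    def test_identical_values_give_zero(self):
        assert rf_cv([10, 10, 10]) == 0.0
        assert rf_rse([10, 10, 10]) == 0.0

    def test_cv_hand_arithmetic(self):
        assert rf_cv([9, 11]) == pytest.approx(100 * math.sqrt(2) / 10)
        assert rf_cv([10, 10, 13]) == pytest.approx(100 * math.sqrt(3) / 11)

    def test_rse_hand_arithmetic_and_n_monotonicity(self):
        assert rf_rse([9, 11]) == pytest.approx(10.0)
        # fixed spread, growing n: RSE shrinks monotonically
        vals = [9, 11]
        prev = rf_rse(vals)
        for _ in range(4):
            vals = vals + [9, 11]
            cur = rf_rse(vals)
            assert cur < prev
            prev = cur

    @pytest.mark.parametrize("stat", [rf_cv, rf_rse])
    def test_scale_invariance(self, stat):
        vals = [8.0, 9.5, 12.0, 10.1]
        assert stat([7.3 * v for v in vals]) == pytest.approx(stat(vals))

    @pytest.mark.parametrize("stat", [rf_cv, rf_rse])
    def test_insufficient_data_rejected(self, stat):
        with pytest.raises(ValueError):
            stat([5.0])


class TestRfEcnModel:
    def test_two_points_interpolate_exactly(self):
        model = fit_rf_vs_ecn([(2.0, 85.0), (5.0, 205.0)])
        assert model.slope == pytest.approx(40.0)
        assert model.intercept == pytest.approx(5.0)
        assert model.r2 == pytest.approx(1.0)

    def test_collinear_points_give_unit_r2(self):
        pts = [(e, 40 * e + 5) for e in np.linspace(1, 9, 19)]
        assert fit_rf_vs_ecn(pts).r2 == pytest.approx(1.0)

    def test_recovery_under_noise_at_study_size(self):
        rng = np.random.default_rng(2024)
        ecns = np.linspace(1.5, 9.0, 19)
        pts = [(e, 40.0 * e + 5.0 + rng.normal(0, 2.0)) for e in ecns]
        model = fit_rf_vs_ecn(pts)
        assert abs(model.slope - 40.0) / 40.0 < 0.10

    def test_degenerate_design_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_rf_vs_ecn([(3.0, 100.0), (3.0, 120.0)])

    def test_predict_rf_and_range_guard(self):
        model = RFModel(slope=40.0, intercept=5.0, r2=1.0, n_standards=19)
        assert predict_rf(model, 2.14) == pytest.approx(90.6)
        assert predict_rf(model, 0.0) == pytest.approx(5.0)
        with pytest.raises(CalibrationRangeError):
            predict_rf(model, -1.0)


class TestQuantify:
    def test_default_geometry_is_50ml(self):
        geom = SamplingGeometry()
        assert geom.sampled_volume_m3 == pytest.approx(5e-5)

    @pytest.mark.parametrize("mass_ng, expected", [(1.0, 20.0), (2.5, 50.0), (0.0, 0.0)])
    def test_mass_to_concentration(self, mass_ng, expected):
        # area = mass * rf with rf = 100
        assert quantify(mass_ng * 100.0, 100.0) == pytest.approx(expected)

    def test_nonpositive_rf_rejected(self):
        with pytest.raises(ValueError):
            quantify(10.0, 0.0)


class TestUnitConversion:
    def test_acetaldehyde_dual_unit_pair(self):
        # 1,618 ppbv of MW 44.05 at Vm 24.5 -> 2,909 ug/m^3
        assert ppb_to_ugm3(1618, 44.05) == pytest.approx(2909, rel=5e-4)

    def test_ethyl_acetate_dual_unit_pair(self):
        assert ppb_to_ugm3(4793, 88.11) == pytest.approx(17240, rel=2e-3)

    def test_zero_maps_to_zero(self):
        assert ppb_to_ugm3(0.0, 88.11) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(ppb=st.floats(1e-6, 1e6), mw=st.floats(10, 300))
    def test_roundtrip_identity(self, ppb, mw):
        assert ugm3_to_ppb(ppb_to_ugm3(ppb, mw), mw) == pytest.approx(ppb, rel=1e-12)

    def test_nonpositive_mw_rejected(self):
        with pytest.raises(ValueError):
            ppb_to_ugm3(1.0, 0.0)
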