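"""Curve fitting: A–Ci (apparent), variable-J recovery, operating-point rules."""

import math

import numpy as np
import pytest

from leafgm.errors import InvalidArgumentError, MissingOperatingPointError, SingularPointError
from leafgm.fitting import (
    FitConfig,
    ResponseCurve,
    cc_from_variable_j,
    fit_aci,
    fit_variable_j,
    gm_at_reference,
    value_at_reference,
)
from leafgm.synth import AciConditions, generate_aci_curve


class TestCcFromVariableJ:
    def test_zero_gross_assimilation_returns_gamma_star(self):
        assert cc_from_variable_j(-1.5, 1.5, 38.6, 180.0) == pytest.approx(38.6)

    def test_pole_raises(self):
        with pytest.raises(SingularPointError):
            cc_from_variable_j(20.0, 1.5, 38.6, 4 * 21.5)

    def test_hand_evaluated_point(self):
        # frozen: 38.6*(180+8*21.5)/(180-4*21.5)
        assert cc_from_variable_j(20.0, 1.5, 38.6, 180.0) == pytest.approx(
            144.54468085106384, rel=1e-12
        )

    def test_array_input_marks_singular_as_nan(self):
        out = cc_from_variable_j(np.array([20.0, 20.0]), 1.5, 38.6, np.array([180.0, 86.0]))
        assert math.isfinite(out[0]) and math.isnan(out[1])


class TestFitAci:
    def test_noiseless_infinite_gm_recovery(self, noiseless_truth):
        noiseless_truth.gm = math.inf
        curve = generate_aci_curve(noiseless_truth, seed=11)
        fit = fit_aci(curve)
        p = fit.params
        assert p.Vcmax25 == pytest.approx(100.0, rel=1e-3)
        assert p.J25 == pytest.approx(180.0, rel=1e-3)
        assert p.Tp25 == pytest.approx(12.0, rel=1e-3)
        assert np.allclose(fit.cc, curve.ci)

    def test_rubisco_only_curve_flags_j_unidentified(self, noiseless_truth):
        noiseless_truth.gm = math.inf
        noiseless_truth.aci = AciConditions(co2_sequence=(300, 250, 200, 150, 100, 75, 50))
        curve = generate_aci_curve(noiseless_truth, seed=3)
        fit = fit_aci(curve)
        assert fit.params.Vcmax25 == pytest.approx(100.0, rel=0.02)
        assert "J25 weakly identified" in fit.flags

    def test_finite_gm_depresses_apparent_vcmax(self, noiseless_truth):
        curve = generate_aci_curve(noiseless_truth, seed=5)  # gm = 0.3
        fit = fit_aci(curve)
        assert fit.params.Vcmax25 < 100.0

    def test_apparent_below_true_over_parameter_grid(self, noiseless_truth):
        # the Ci-basis fit can never beat the generating Vcmax on finite-gm data
        for vcmax, gm, seed in [(80.0, 0.2, 21), (120.0, 0.5, 22), (100.0, 0.15, 23)]:
            noiseless_truth.fvcb.Vcmax25 = vcmax
            noiseless_truth.gm = gm
            curve = generate_aci_curve(noiseless_truth, seed=seed)
            fit = fit_aci(curve)
            assert fit.params.Vcmax25 <= vcmax * (1 + 1e-6)

    def test_too_few_points_rejected(self, noiseless_truth):
        noiseless_truth.aci = AciConditions(co2_sequence=(400, 300, 200))
        curve = generate_aci_curve(noiseless_truth, seed=1)
        with pytest.raises(InvalidArgumentError):
            fit_aci(curve)


class TestFitVariableJ:
    def test_noiseless_round_trip_recovers_all_five(self, noiseless_truth):
        curve = generate_aci_curve(noiseless_truth, seed=1)
        fit = fit_variable_j(curve)
        p = fit.params
        assert p.Vcmax25 == pytest.approx(100.0, rel=0.01)
        assert p.J25 == pytest.approx(180.0, rel=0.01)
        assert p.Rd25 == pytest.approx(1.5, rel=0.01)
        assert p.Tp25 == pytest.approx(12.0, rel=0.01)
        assert p.tau == pytest.approx(0.42, rel=0.01)
        assert gm_at_reference(fit) == pytest.approx(0.3, rel=0.02)

    def test_effectively_infinite_gm_yields_zero_resistance(self, noiseless_truth):
        noiseless_truth.gm = 1e6
        curve = generate_aci_curve(noiseless_truth, seed=7)
        fit = fit_variable_j(curve)
        assert abs(1.0 / gm_at_reference(fit)) < 1e-2

    def test_point_order_invariance_of_objective(self, noiseless_truth):
        curve = generate_aci_curve(noiseless_truth, seed=9)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(curve))
        shuffled = ResponseCurve(
            a=curve.a[perm], ci=curve.ci[perm], ca=curve.ca[perm],
            gsw=curve.gsw[perm], qin=curve.qin[perm], tleaf_c=curve.tleaf_c[perm],
            phipsii=curve.phipsii[perm], co2_r=curve.co2_r[perm], o2=curve.o2,
        )
        f1 = fit_variable_j(curve)
        f2 = fit_variable_j(shuffled)
        assert f1.objective == pytest.approx(f2.objective, abs=1e-8)
        assert f1.params.Vcmax25 == pytest.approx(f2.params.Vcmax25, rel=1e-3)

    def test_multistart_seeds_agree_on_well_conditioned_curve(self, noiseless_truth):
        curve = generate_aci_curve(noiseless_truth, seed=13)
        fits = [fit_variable_j(curve, config=FitConfig(seed=s)) for s in (0, 1)]
        for name in ("Vcmax25", "J25", "Rd25", "Tp25", "tau"):
            a = getattr(fits[0].params, name)
            b = getattr(fits[1].params, name)
            assert a == pytest.approx(b, rel=0.005)

    def test_requires_fluorescence(self, noiseless_truth):
        curve = generate_aci_curve(noiseless_truth, seed=1)
        curve.phipsii = None
        with pytest.raises(InvalidArgumentError):
            fit_variable_j(curve)


class TestOperatingPoint:
    def test_single_point_selection(self):
        assert value_at_reference(np.array([400.0, 300, 200]), np.array([5.0, 6, 7])) == 5.0

    def test_constant_values_return_constant(self, noiseless_truth):
        curve = generate_aci_curve(noiseless_truth, seed=1)
        fit = fit_variable_j(curve)
        assert gm_at_reference(fit) == pytest.approx(0.3, rel=0.02)

    def test_recovery_pair_averaged_when_stable(self):
        co2r = np.array([400.0, 300, 200, 400, 400, 600])
        vals = np.array([1.0, 9, 9, 2.0, 2.1, 9])
        assert value_at_reference(co2r, vals) == pytest.approx(2.05)

    def test_pre_ramp_used_when_recovery_pair_unstable(self):
        co2r = np.array([400.0, 300, 200, 400, 400, 600])
        vals = np.array([1.0, 9, 9, 2.0, 4.0, 9])
        assert value_at_reference(co2r, vals) == 1.0

    def test_missing_operating_point(self):
        with pytest.raises(MissingOperatingPointError):
            value_at_reference(np.array([100.0, 200.0]), np.array([1.0, 2.0]))
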