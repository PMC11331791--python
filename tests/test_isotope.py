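"""13C pipeline: TDL calibration, discrimination, ternary, e*, gm inversion."""

import copy
import math

import numpy as np
import pytest

from leafgm.constants import FractionationParams
from leafgm.errors import (
    CalibrationFailureError,
    InvalidArgumentError,
    MalformedCycleError,
    UndefinedDiscriminationError,
)
from leafgm.isotope import (
    CalibrationModel,
    PairedPoint,
    TankSet,
    TDLCycle,
    calibrate_tdl_cycle,
    delta13c,
    e_star,
    gm_from_discrimination,
    iwue,
    observed_discrimination,
    ternary_correction,
)
from leafgm.synth import NoiseModel, TruthSpec, generate_tdl_session

R_VPDB = 0.0111797


def make_point(delta_in=-8.5, delta_out=-5.0, c_in=420.0, c_out=400.0, **kw):
    def split(total, d):
        r = R_VPDB * (1 + d / 1000)
        return total / (1 + r), total * r / (1 + r)

    c12i, c13i = split(c_in, delta_in)
    c12o, c13o = split(c_out, delta_out)
    defaults = dict(a=20.0, gsw=0.4, e=5e-3, ci=280.0, ca=400.0)
    defaults.update(kw)
    return PairedPoint(c12_in=c12i, c13_in=c13i, c12_out=c12o, c13_out=c13o, **defaults)


class TestDelta13C:
    def test_reference_ratio_is_zero(self):
        assert delta13c(400.0, 400.0 * R_VPDB, R_VPDB) == pytest.approx(0.0, abs=1e-12)

    def test_linear_in_ratio(self):
        assert delta13c(400.0, 400.0 * 0.99 * R_VPDB, R_VPDB) == pytest.approx(-10.0)

    def test_nonpositive_c12_rejected(self):
        with pytest.raises(InvalidArgumentError):
            delta13c(0.0, 1.0, R_VPDB)

    def test_permil_round_trip_has_no_drift(self):
        d = -8.123456789
        for _ in range(50):
            r = R_VPDB * (1 + d / 1000)
            d = (r / R_VPDB - 1) * 1000
        assert d == pytest.approx(-8.123456789, abs=1e-12)


def make_cycle(instrument_gain=(1.0, 1.0), offset=(0.0, 0.0), tanks=None, chamber=None):
    tanks = tanks or TankSet()
    truth = {}
    for name, total in zip(("zero", "span_60", "span_300", "span_1000"), tanks.span_totals):
        truth[name] = tanks.split(total, tanks.delta_cal)
    truth["noaa_delta"] = tanks.split(tanks.noaa_co2, tanks.noaa_delta)
    chamber = chamber or {}
    for name in ("ref_1", "sample_1", "ref_2", "sample_2"):
        truth[name] = chamber.get(name, tanks.split(420.0, -8.0))
    g12, g13 = instrument_gain
    o12, o13 = offset
    return TDLCycle(
        c12_raw={k: (v[0] - o12) / g12 for k, v in truth.items()},
        c13_raw={k: (v[1] - o13) / g13 for k, v in truth.items()},
        timestamps={k: float(i) for i, k in enumerate(truth)},
    ), truth


class TestCalibration:
    def test_identity_instrument_reproduces_tanks(self):
        cycle, truth = make_cycle()
        model, chamber = calibrate_tdl_cycle(cycle, TankSet())
        assert model.gain12 == pytest.approx(1.0, rel=1e-9)
        assert model.residual12 < 1e-9 and model.residual13 < 1e-9
        z12, z13 = model.apply(cycle.c12_raw["zero"], cycle.c13_raw["zero"])
        assert abs(z12) < 1e-9 and abs(z13) < 1e-9

    def test_gain_drift_and_offset_recovered(self):
        cycle, truth = make_cycle(instrument_gain=(1.02, 1.02), offset=(0.5, 0.5 * 0.011))
        _, chamber = calibrate_tdl_cycle(cycle, TankSet())
        for name in ("ref_1", "sample_1", "ref_2", "sample_2"):
            for got, want in zip(chamber[name], truth[name]):
                assert got == pytest.approx(want, rel=1e-3)

    def test_calibration_idempotent_on_calibrated_streams(self):
        cycle, truth = make_cycle()
        model, chamber = calibrate_tdl_cycle(cycle, TankSet())
        ident = CalibrationModel.identity()
        for name, (c12, c13) in chamber.items():
            again = ident.apply(c12, c13)
            assert again[0] == c12 and again[1] == c13

    def test_missing_stream_rejected(self):
        cycle, _ = make_cycle()
        bad = dict(cycle.c12_raw)
        bad.pop("span_300")
        with pytest.raises(MalformedCycleError):
            TDLCycle(c12_raw=bad, c13_raw=cycle.c13_raw, timestamps=cycle.timestamps)

    def test_non_monotone_span_rejected(self):
        cycle, _ = make_cycle()
        cycle.c12_raw["span_300"] = cycle.c12_raw["span_1000"] + 1
        with pytest.raises(CalibrationFailureError):
            calibrate_tdl_cycle(cycle, TankSet())


class TestObservedDiscrimination:
    def test_no_isotopic_difference_gives_zero(self):
        p = make_point(delta_in=-8.5, delta_out=-8.5)
        d, _ = observed_discrimination(p, R_VPDB)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_no_drawdown_is_undefined(self):
        p = make_point(delta_in=-8.5, delta_out=-8.5, c_in=400.0, c_out=400.0)
        with pytest.raises(UndefinedDiscriminationError):
            observed_discrimination(p, R_VPDB)

    def test_imposed_discrimination_recovered_through_mixing(self):
        # forward mixing with Delta = 20 permil at xi = 8, then inversion
        from leafgm.synth import _delta_out_from_discrimination

        big_delta = 20e-3
        c_in, delta_in = 400.0, -8.5 / 1000
        c_out = c_in - c_in / 8.0  # xi = 8 on the total basis, approximately
        d_out = _delta_out_from_discrimination(delta_in, c_in, c_out, big_delta, R_VPDB)
        r_i = R_VPDB * (1 + delta_in)
        r_o = R_VPDB * (1 + d_out)
        p = PairedPoint(
            c12_in=c_in / (1 + r_i), c13_in=c_in * r_i / (1 + r_i),
            c12_out=c_out / (1 + r_o), c13_out=c_out * r_o / (1 + r_o),
            a=20, gsw=0.4, e=5e-3, ci=280, ca=400,
        )
        d, xi = observed_discrimination(p, R_VPDB)
        assert d == pytest.approx(20.0, rel=1e-9)
        assert xi == pytest.approx(8.0, rel=0.01)

    def test_invariant_to_common_concentration_scale(self):
        p1 = make_point()
        p2 = copy.copy(p1)
        for name in ("c12_in", "c13_in", "c12_out", "c13_out"):
            setattr(p2, name, 1.37 * getattr(p1, name))
        d1, _ = observed_discrimination(p1, R_VPDB)
        d2, _ = observed_discrimination(p2, R_VPDB)
        assert d1 == pytest.approx(d2, rel=1e-12)


class TestTernaryAndEStar:
    def test_zero_transpiration(self):
        assert ternary_correction(0.0, 0.3) == 0.0

    def test_monotone_in_transpiration(self):
        ts = [ternary_correction(e, 0.3) for e in (1e-3, 2e-3, 4e-3)]
        assert ts[0] < ts[1] < ts[2]

    def test_hand_evaluated(self):
        # (1 + 0.0044) * 3e-3 / (2 * 0.3)
        assert ternary_correction(3e-3, 0.3) == pytest.approx(5.022e-3, rel=1e-12)

    def test_nonpositive_conductance_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ternary_correction(1e-3, 0.0)

    def test_e_star_zero_when_substrate_matches_measurement(self):
        fr = FractionationParams(e=0.0, delta_substrate=-8.5, delta_measurement_co2=-8.5)
        assert e_star(fr) == pytest.approx(0.0, abs=1e-12)

    def test_e_star_linear_in_signature_offset(self):
        vals = [
            e_star(FractionationParams(e=1.0, delta_substrate=-8.5 + off,
                                       delta_measurement_co2=-8.5))
            for off in (-10.0, 0.0, 10.0)
        ]
        assert vals[1] == pytest.approx(1.0)
        assert vals[2] - vals[1] == pytest.approx(vals[1] - vals[0], rel=1e-12)


class TestGmInversion:
    def test_observed_equal_to_infinite_gm_prediction(self, registry):
        # construct delta_out so that Delta_obs == Delta_i exactly
        from leafgm.synth import _delta_out_from_discrimination, forward_discrimination

        fr = registry.fractionation
        a, ca, ci, gsw, e = 20.0, 400.0, 280.0, 0.4, 5e-3
        rd, gstar = 1.0, 3.9
        di = forward_discrimination(a, ca, ci, ci, e, gsw, rd, gstar, fr)
        c_in = ca + a / 0.833
        d_out = _delta_out_from_discrimination(-8.5e-3, c_in, ca, di, fr.R_std)
        r_i = fr.R_std * (1 - 8.5e-3)
        r_o = fr.R_std * (1 + d_out)
        p = PairedPoint(
            c12_in=c_in / (1 + r_i), c13_in=c_in * r_i / (1 + r_i),
            c12_out=ca / (1 + r_o), c13_out=ca * r_o / (1 + r_o),
            a=a, gsw=gsw, e=e, ci=ci, ca=ca,
        )
        res = gm_from_discrimination(p, fr, gstar, rd)
        assert math.isinf(res["gm"]) or res["gm"] > 1e4
        assert res["cc"] == pytest.approx(ci, abs=0.5)

    def test_lower_observed_discrimination_means_lower_gm(self, registry):
        # xi ~ 21 here, so ~0.05 permil steps in delta_out move Delta_obs by ~1 permil
        fr = registry.fractionation
        gms = []
        for delta_out in (-7.70, -7.75, -7.80):
            p = make_point(delta_out=delta_out)
            res = gm_from_discrimination(p, fr, 3.9, 1.0)
            gms.append(res["gm"])
        # lower delta_out => lower Delta_obs => smaller gm
        assert gms[0] > gms[1] > gms[2] > 0

    def test_nonpositive_assimilation_rejected(self, registry):
        p = make_point(a=-1.0)
        with pytest.raises(InvalidArgumentError):
            gm_from_discrimination(p, registry.fractionation, 3.9, 1.0)


class TestIWUE:
    def test_ratio(self):
        assert iwue(20.0, 0.4) == pytest.approx(50.0)

    def test_zero_assimilation(self):
        assert iwue(0.0, 0.4) == 0.0

    def test_halves_when_gsw_doubles(self):
        assert iwue(20.0, 0.8) == pytest.approx(iwue(20.0, 0.4) / 2)

    def test_nonpositive_gsw_rejected(self):
        with pytest.raises(InvalidArgumentError):
            iwue(20.0, 0.0)


class TestEndToEnd:
    def test_noisy_session_bias_below_two_percent(self, registry):
        """0.1 permil delta-noise: median recovered gm biased < 2% over many points."""
        from leafgm.io import pair_tdl_with_gasexchange, read_tdl_log

        truth = TruthSpec()
        truth.noise = NoiseModel(0.0, 0.0, 0.0, delta_permil=0.1)
        truth.iso.n_cycles = 500
        session = generate_tdl_session(truth, seed=42)
        import io as _io

        buf = _io.StringIO()
        session.tdl.to_csv(buf, index=False)
        buf.seek(0)
        cycles = read_tdl_log(buf)
        pts = pair_tdl_with_gasexchange(cycles, session.gasex, truth.tanks, window_s=1e9)
        tr = session.truth[1]
        gms = []
        for p in pts:
            res = gm_from_discrimination(p, registry.fractionation, tr["gamma_star"], tr["rd"])
            if not res["nonphysical"]:
                gms.append(res["gm"])
        assert len(gms) > 800
        bias = abs(np.median(gms) - tr["gm"]) / tr["gm"]
        assert bias < 0.02
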