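"""Online 13C discrimination coupled with gas exchange.

The measurement system cycles a tunable-diode laser (TDL) through nine gas
streams: a CO2-free zero, three span tanks of one isotopic signature
(nominally 60, 300 and 1000 μmol mol⁻¹), a δ¹³C reference tank, and the
inlet (reference) and outlet (sample) streams of two leaf chambers.  Each
cycle yields its own calibration, which is applied to the chamber streams
of that cycle before computing isotopic quantities.

Model summary (δ and fractionations handled in absolute units internally,
reported in per mil):

* δ¹³C = (R_sample/R_std − 1), R = [¹³CO₂]/[¹²CO₂];
* drawdown ratio ξ = C_in/(C_in − C_out);
* observed discrimination Δobs = ξ(δ_out − δ_in)/(1 + δ_out − ξ(δ_out − δ_in));
* ternary correction t = (1 + ā)·E/(2·g_ac), with g_ac the series
  boundary-layer + stomatal conductance to CO2;
* comprehensive discrimination model (respiration isotopically
  disconnected from the Calvin–Benson cycle):

      Δ = 1/(1−t) · ā (Ca−Ci)/Ca
        + (1+t)/(1−t) · [ a_m (Ci−Cc)/Ca + b Cc/Ca
                          − e*·Rd/(A+Rd) · (Cc−Γ*)/Ca − f Γ*/Ca ]

  so that, with Δi the prediction at Cc = Ci,

      Δi − Δobs = (1+t)/(1−t) · (b − a_m − e*·Rd/(A+Rd)) · (Ci−Cc)/Ca

  and gm = A/(Ci−Cc) follows directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import FractionationParams
from .errors import (
    CalibrationFailureError,
    InvalidArgumentError,
    MalformedCycleError,
    UndefinedDiscriminationError,
)

__all__ = [
    "STREAM_SEQUENCE",
    "TDLCycle",
    "TankSet",
    "CalibrationModel",
    "PairedPoint",
    "calibrate_tdl_cycle",
    "delta13c",
    "observed_discrimination",
    "ternary_correction",
    "e_star",
    "gm_from_discrimination",
    "iwue",
]

#: the nine-valve measurement sequence, in order
STREAM_SEQUENCE = (
    "zero",
    "span_60",
    "span_300",
    "span_1000",
    "noaa_delta",
    "ref_1",
    "sample_1",
    "ref_2",
    "sample_2",
)


@dataclass
class TDLCycle:
    """One nine-stream TDL cycle, pre-averaged to a point per stream.

    ``c12_raw``/``c13_raw`` map stream name → raw isotopologue signal
    (instrument units ≈ μmol mol⁻¹); ``timestamps`` map stream name →
    seconds since session start.
    """

    c12_raw: dict
    c13_raw: dict
    timestamps: dict
    index: int = 0

    def __post_init__(self) -> None:
        for d in (self.c12_raw, self.c13_raw, self.timestamps):
            missing = [s for s in STREAM_SEQUENCE if s not in d]
            if missing or len(d) != len(STREAM_SEQUENCE):
                raise MalformedCycleError(
                    f"cycle {self.index}: expected streams {STREAM_SEQUENCE}, "
                    f"missing {missing}, got {sorted(d)}"
                )


@dataclass
class TankSet:
    """Nominal calibration-tank values.

    Span tanks share one isotopic signature ``delta_cal`` (‰); the δ¹³C
    reference tank carries total CO2 ``noaa_co2`` with signature
    ``noaa_delta``.
    """

    span_totals: tuple = (0.0, 60.0, 300.0, 1000.0)  # total CO2, umol mol^-1
    delta_cal: float = -32.0  # per mil of the span/zero gas
    noaa_co2: float = 400.0
    noaa_delta: float = -8.5
    r_std: float = 0.0111797

    def split(self, total: float, delta_permil: float) -> tuple:
        """Partition a total CO2 mixing ratio into (12C, 13C) components."""
        r = self.r_std * (1.0 + delta_permil / 1000.0)
        c12 = total / (1.0 + r)
        return c12, total - c12


@dataclass
class CalibrationModel:
    """Per-cycle linear calibration: true = gain·raw + offset per isotopologue,
    plus a multiplicative 13C ratio correction anchored to the δ¹³C tank."""

    gain12: float
    offset12: float
    gain13: float
    offset13: float
    ratio_correction: float = 1.0
    residual12: float = 0.0
    residual13: float = 0.0

    def apply(self, c12_raw, c13_raw) -> tuple:
        c12 = self.gain12 * np.asarray(c12_raw, dtype=float) + self.offset12
        c13 = (self.gain13 * np.asarray(c13_raw, dtype=float) + self.offset13) * self.ratio_correction
        return c12, c13

    @classmethod
    def identity(cls) -> "CalibrationModel":
        return cls(1.0, 0.0, 1.0, 0.0)


@dataclass
class PairedPoint:
    """A calibrated chamber in/out pair matched to one gas-exchange log row."""

    c12_in: float
    c13_in: float
    c12_out: float
    c13_out: float
    a: float  # net assimilation, umol m^-2 s^-1
    gsw: float  # mol m^-2 s^-1
    e: float  # transpiration, mol m^-2 s^-1
    ci: float  # umol mol^-1
    ca: float  # umol mol^-1
    tleaf_c: float = 25.0
    o2: float = 20.0  # mmol mol^-1 (2% O2 protocol)
    chamber: int = 1
    time_gap_s: float = 0.0
    gbw: float = math.inf  # boundary-layer conductance to water, mol m^-2 s^-1


def delta13c(c12, c13, r_std: float) -> float | np.ndarray:
    """δ¹³C (‰) of a stream from calibrated isotopologue mixing ratios."""
    c12 = np.asarray(c12, dtype=float)
    if np.any(c12 <= 0):
        raise InvalidArgumentError("12CO2 mixing ratio must be positive")
    out = (np.asarray(c13, dtype=float) / c12 / r_std - 1.0) * 1000.0
    return float(out) if np.ndim(out) == 0 else out


def calibrate_tdl_cycle(cycle: TDLCycle, tanks: TankSet) -> tuple:
    """Fit and apply the per-cycle calibration.

    A straight line (gain, offset) per isotopologue is least-squares fitted
    through the zero and the three span tanks, whose nominal isotopologue
    mixing ratios follow from the tank totals and the shared span
    signature.  A residual multiplicative correction to the 13C channel is
    then anchored on the δ¹³C reference tank.  Returns
    ``(CalibrationModel, {stream: (c12, c13)})`` for the four chamber
    streams.
    """
    span_streams = ("zero", "span_60", "span_300", "span_1000")
    raw12 = np.array([cycle.c12_raw[s] for s in span_streams])
    raw13 = np.array([cycle.c13_raw[s] for s in span_streams])
    if np.any(np.diff(raw12) <= 0) or np.any(np.diff(raw13) <= 0):
        raise CalibrationFailureError("non-monotone span response")
    nom = np.array([tanks.split(c, tanks.delta_cal) for c in tanks.span_totals])
    g12, o12 = np.polyfit(raw12, nom[:, 0], 1)
    g13, o13 = np.polyfit(raw13, nom[:, 1], 1)
    if g12 <= 0 or g13 <= 0:
        raise CalibrationFailureError("non-positive span gain")
    model = CalibrationModel(
        gain12=float(g12), offset12=float(o12),
        gain13=float(g13), offset13=float(o13),
        residual12=float(np.max(np.abs(g12 * raw12 + o12 - nom[:, 0]))),
        residual13=float(np.max(np.abs(g13 * raw13 + o13 - nom[:, 1]))),
    )
    # anchor the 13C/12C ratio on the delta reference tank
    n12 = g12 * cycle.c12_raw["noaa_delta"] + o12
    n13 = g13 * cycle.c13_raw["noaa_delta"] + o13
    if n12 > 0 and n13 > 0:
        r_nom = tanks.r_std * (1.0 + tanks.noaa_delta / 1000.0)
        model.ratio_correction = float(r_nom / (n13 / n12))
    chamber = {}
    for s in ("ref_1", "sample_1", "ref_2", "sample_2"):
        c12, c13 = model.apply(cycle.c12_raw[s], cycle.c13_raw[s])
        chamber[s] = (float(c12), float(c13))
    return model, chamber


def observed_discrimination(
    point: PairedPoint, r_std: float, basis: str = "c12"
) -> tuple:
    """Observed photosynthetic discrimination Δobs (‰) and drawdown ratio ξ.

    ``basis`` selects whether ξ is computed on ¹²CO₂ ("c12", default) or
    total CO2 mixing ratios; δ values enter the discrimination expression
    in absolute units.
    """
    if basis == "c12":
        c_in, c_out = point.c12_in, point.c12_out
    elif basis == "total":
        c_in, c_out = point.c12_in + point.c13_in, point.c12_out + point.c13_out
    else:
        raise InvalidArgumentError("basis must be 'c12' or 'total'")
    if c_in == c_out:
        raise UndefinedDiscriminationError("no CO2 drawdown across the chamber")
    xi = c_in / (c_in - c_out)
    d_in = delta13c(point.c12_in, point.c13_in, r_std) / 1000.0
    d_out = delta13c(point.c12_out, point.c13_out, r_std) / 1000.0
    num = xi * (d_out - d_in)
    delta_obs = num / (1.0 + d_out - num)
    return delta_obs * 1000.0, xi


def ternary_correction(e_trans: float, g_ac: float, a_bar_permil: float = 4.4) -> float:
    """Ternary (CO2/H2O/air) correction factor t = (1 + ā)·E/(2·g_ac)."""
    if g_ac <= 0:
        raise InvalidArgumentError("g_ac must be positive")
    if e_trans < 0:
        raise InvalidArgumentError("transpiration must be >= 0")
    alpha_ac = 1.0 + a_bar_permil / 1000.0
    return alpha_ac * e_trans / (2.0 * g_ac)


def total_co2_conductance(gsw: float, gbw: float = math.inf) -> float:
    """Series boundary-layer + stomatal conductance to CO2 from the water
    values (diffusivity ratios 1.37 and 1.6 respectively)."""
    if gsw <= 0:
        raise InvalidArgumentError("gsw must be positive")
    gsc = gsw / 1.6
    if math.isinf(gbw):
        return gsc
    gbc = gbw / 1.37
    return 1.0 / (1.0 / gsc + 1.0 / gbc)


def e_star(params: FractionationParams) -> float:
    """Apparent (effective) respiratory fractionation e* (‰).

    Combines the intrinsic respiratory fractionation ``e`` with the
    isotopic offset between the respiratory substrate and the CO2 supplied
    during measurement.  Under the disconnected-respiration assumption the
    substrate signature is fixed by growth conditions, so switching the
    measurement O2 level leaves e* unchanged.
    """
    offset = params.delta_substrate - params.delta_measurement_co2
    return params.e + offset / (1.0 + params.delta_measurement_co2 / 1000.0)


def _delta_model(
    a: float, ca: float, ci: float, cc: float, t: float,
    rd: float, gamma_star_: float, fr: FractionationParams,
) -> float:
    """Comprehensive Δ model (absolute units), at arbitrary Cc."""
    ab = fr.a / 1000.0
    am = fr.a_m / 1000.0
    b = fr.b / 1000.0
    f = fr.f / 1000.0
    es = e_star(fr) / 1000.0
    resp = es * rd / (a + rd)
    one = ab * (ca - ci) / ca / (1.0 - t)
    two = (1.0 + t) / (1.0 - t) * (
        am * (ci - cc) / ca
        + b * cc / ca
        - resp * (cc - gamma_star_) / ca
        - f * gamma_star_ / ca
    )
    return one + two


def gm_from_discrimination(
    point: PairedPoint,
    params: FractionationParams,
    gamma_star_: float,
    rd: float,
    basis: str = "c12",
) -> dict:
    """Invert the discrimination model for mesophyll conductance.

    Equates the comprehensive model to Δobs and solves for the mesophyll
    term: with Δi the model prediction at Cc = Ci,

        gm = (1+t)/(1−t) · (b − a_m − e*·Rd/(A+Rd)) · (A/Ca) / (Δi − Δobs)

    Returns a dict with Δobs, ξ, t, Δi, gm, Cc, the drawdown Ci − Cc,
    gm/gsw and iWUE.  A non-positive denominator (observed discrimination
    at or above the infinite-gm prediction) yields gm = NaN with a
    ``nonphysical`` flag; points with A ≤ 0 are rejected.
    """
    if point.a <= 0:
        raise InvalidArgumentError("gm inversion requires A > 0")
    delta_obs_permil, xi = observed_discrimination(point, params.R_std, basis=basis)
    delta_obs = delta_obs_permil / 1000.0
    g_ac = total_co2_conductance(point.gsw, point.gbw)
    t = ternary_correction(point.e, g_ac)
    es = e_star(params) / 1000.0
    resp = es * rd / (point.a + rd)
    delta_i = _delta_model(
        point.a, point.ca, point.ci, point.ci, t, rd, gamma_star_, params
    )
    slope = (1.0 + t) / (1.0 - t) * (params.b / 1000.0 - params.a_m / 1000.0 - resp)
    denom = delta_i - delta_obs
    out = {
        "delta_obs": delta_obs_permil,
        "xi": xi,
        "t": t,
        "delta_i": delta_i * 1000.0,
        "e_star": es * 1000.0,
        "nonphysical": False,
    }
    if denom == 0:
        # observed exactly matches the infinite-gm prediction
        out.update(gm=math.inf, cc=point.ci, drawdown=0.0,
                   gm_over_gsw=math.inf, iwue=iwue(point.a, point.gsw))
        return out
    if denom < 0:
        out.update(gm=math.nan, cc=math.nan, drawdown=math.nan,
                   gm_over_gsw=math.nan, iwue=iwue(point.a, point.gsw),
                   nonphysical=True)
        return out
    gm = slope * (point.a / point.ca) / denom
    cc = point.ci - point.a / gm
    out.update(
        gm=gm,
        cc=cc,
        drawdown=point.ci - cc,
        gm_over_gsw=gm / point.gsw,
        iwue=iwue(point.a, point.gsw),
    )
    return out


def iwue(a: float, gsw: float) -> float:
    """Intrinsic water-use efficiency A/gsw (μmol mol⁻¹)."""
    if gsw <= 0:
        raise InvalidArgumentError("gsw must be positive")
    return a / gsw
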