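"""Synthetic-data generators with known ground truth.

Every analysis stage in the package has exactly one generator here as its
round-trip partner:

* :func:`generate_aci_curve` — 16-step CO2-response curves with
  fluorescence, emulating the descending-then-ascending field protocol
  (reference CO2 sequence 400, 300, 200, 150, 75, 50, 20, 400, 400, 500,
  600, 800, 1000, 1200, 1500, 1800 μmol mol⁻¹ at 1800 μmol m⁻² s⁻¹ light
  and 28 °C leaf temperature);
* :func:`generate_tdl_session` — nine-valve TDL calibration cycles with
  gain drift and noise plus a matching gas-exchange log (greenhouse
  protocol: 25 °C, 2% O2, 400 μmol mol⁻¹ CO2, 180-s logging);
* :func:`generate_cohort` — anatomy and gm tables for a wild type and
  transgenic events with configurable effect-size multipliers (n = 4
  biological replicates by default).

The forward 13C discrimination model used by the TDL generator is written
out here independently of :mod:`leafgm.isotope` (sharing only the constants
registry), so that the forward–inverse round trip is a genuine two-path
check of the algebra.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .anatomy import (
    airspace_conductance,
    compose_gm,
    membrane_conductance,
    wall_conductance_from_porosity,
)
from .constants import ConstantsRegistry
from .errors import InvalidArgumentError
from .fitting import ResponseCurve
from .fvcb import FvCBParams, LeafEnvironment, arrhenius_scale, fvcb_assimilation, gamma_star
from .isotope import STREAM_SEQUENCE, TankSet

__all__ = [
    "AciConditions",
    "IsotopeConditions",
    "InstrumentModel",
    "NoiseModel",
    "CohortDesign",
    "TruthSpec",
    "TDLSession",
    "generate_aci_curve",
    "generate_tdl_session",
    "generate_cohort",
    "forward_discrimination",
]

PAPER_CO2_SEQUENCE = (
    400, 300, 200, 150, 75, 50, 20, 400, 400, 500, 600, 800, 1000, 1200, 1500, 1800
)


@dataclass
class AciConditions:
    """Field CO2-response protocol."""

    co2_sequence: tuple = PAPER_CO2_SEQUENCE
    qin: float = 1800.0  # umol m^-2 s^-1
    tleaf_c: float = 28.0
    o2: float = 210.0  # mmol mol^-1
    gsw_mean: float = 0.4  # mol m^-2 s^-1
    gsw_cv: float = 0.10


@dataclass
class IsotopeConditions:
    """Greenhouse TDL-coupled protocol (low O2 to suppress photorespiration)."""

    ca: float = 400.0  # sample-cell CO2, umol mol^-1
    qin: float = 1800.0
    tleaf_c: float = 25.0
    o2: float = 20.0  # mmol mol^-1 (2%)
    gsw_mean: float = 0.4
    vpd_kpa: float = 1.3
    pressure_kpa: float = 101.325
    flow_per_area: float = 0.833  # mol air m^-2 s^-1 through the chamber
    delta_in: float = -8.5  # per mil, chamber supply air
    n_cycles: int = 10
    cycle_period_s: float = 180.0  # 9 valves x 20 s
    log_interval_s: float = 180.0
    n_chambers: int = 2


@dataclass
class InstrumentModel:
    """TDL gain/offset model; raw = (true − offset)/gain per isotopologue.

    ``gain_drift_frac`` is the total fractional gain drift across the
    session, applied linearly cycle by cycle.
    """

    gain12: float = 1.0
    offset12: float = 0.0
    gain13: float = 1.0
    offset13: float = 0.0
    gain_drift_frac: float = 0.0


@dataclass
class NoiseModel:
    a_frac: float = 0.01  # multiplicative noise on A
    phi_frac: float = 0.01  # multiplicative noise on phiPSII
    gasex_frac: float = 0.0  # multiplicative noise on logged gas-exchange values
    delta_permil: float = 0.0  # sd of delta-13C noise on chamber streams

    def __post_init__(self) -> None:
        if min(self.a_frac, self.phi_frac, self.gasex_frac, self.delta_permil) < 0:
            raise InvalidArgumentError("noise parameters must be >= 0")


@dataclass
class CohortDesign:
    """Two-genotype-class study design mirroring a WT vs transgenic trial."""

    genotypes: tuple = ("WT", "EV-8", "EV-10", "EV-14")
    wt_label: str = "WT"
    n_replicates: int = 4
    n_technical: int = 3
    # WT trait means
    t_cw_nm: float = 160.0
    f_ias: float = 0.30
    t_mes_um: float = 250.0
    s_c: float = 12.0
    p_over_tau: float = 0.05
    w_um: float = 100.0
    curvature_f: float = 1.2
    sc_over_sm: float = 0.8
    cv: float = 0.08
    # transgenic effect multipliers (applied to every non-WT genotype)
    mult: dict = field(
        default_factory=lambda: {
            "t_cw_nm": 0.90,
            "p_over_tau": 1.75,
            "f_ias": 1.12,
            "s_c": 1.05,
            "t_mes_um": 1.05,
        }
    )


@dataclass
class TruthSpec:
    """Complete ground truth for all generators; reproducible by seed."""

    fvcb: FvCBParams = field(
        default_factory=lambda: FvCBParams(
            Vcmax25=100.0, J25=180.0, Rd25=1.5, Tp25=12.0, tau=0.42
        )
    )
    gm: float = 0.3  # mol m^-2 s^-1 (math.inf for an infinite-gm curve)
    aci: AciConditions = field(default_factory=AciConditions)
    iso: IsotopeConditions = field(default_factory=IsotopeConditions)
    instrument: InstrumentModel = field(default_factory=InstrumentModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    cohort: CohortDesign = field(default_factory=CohortDesign)
    tanks: TankSet = field(default_factory=TankSet)
    constants: ConstantsRegistry = field(default_factory=ConstantsRegistry)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["gm"] = float(self.gm) if math.isfinite(self.gm) else "inf"
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TruthSpec":
        d = yaml.safe_load(open(path)) or {}
        out = cls()
        if "fvcb" in d:
            out.fvcb = FvCBParams(**d["fvcb"])
        if "gm" in d:
            out.gm = math.inf if d["gm"] in ("inf", None) else float(d["gm"])
        for name, klass in (
            ("aci", AciConditions), ("iso", IsotopeConditions),
            ("instrument", InstrumentModel), ("noise", NoiseModel),
            ("cohort", CohortDesign), ("tanks", TankSet),
        ):
            if name in d:
                sub = d[name]
                for k, v in list(sub.items()):
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                setattr(out, name, klass(**sub))
        if "constants" in d:
            out.constants = ConstantsRegistry.from_dict(d["constants"])
        return out


def _solve_steady_state(ca, gsw, gm, params, conditions, constants):
    """Solve A = FvCB(Cc) with Cc = Ci − A/gm and Ci = Ca − 1.6 A/gsw.

    The total supply conductance g_tot = 1/(1.6/gsw + 1/gm) makes
    f(Cc) = An(Cc) − g_tot (Ca − Cc) strictly increasing, so the root is
    unique.  Returns (A, Ci, Cc).
    """
    kin = constants.kinetics
    inv_gtot = 1.6 / gsw + (0.0 if math.isinf(gm) else 1.0 / gm)
    gtot = 1.0 / inv_gtot

    def f(cc):
        env = LeafEnvironment(cc=cc, o2=conditions.o2, tleaf_c=conditions.tleaf_c,
                              qin=conditions.qin)
        an = float(fvcb_assimilation(env, params, kin).An[0])
        return an - gtot * (ca - cc)

    lo, hi = 1e-9, max(4.0 * ca, 4000.0)
    if f(lo) >= 0 or f(hi) <= 0:
        raise InvalidArgumentError("no steady-state root: nonphysical truth")
    cc = brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
    a = gtot * (ca - cc)
    ci = cc if math.isinf(gm) else cc + a / gm
    return a, ci, cc


def _j_actual(a, rd, cc, gstar):
    """Electron transport consistent with gross assimilation at Cc."""
    gross = a + rd
    return gross * (4.0 * cc + 8.0 * gstar) / (cc - gstar)


def generate_aci_curve(
    truth: TruthSpec, seed: int, plant_id: str = "plant-1", genotype: str = "WT"
) -> ResponseCurve:
    """Forward-simulate one CO2-response curve with fluorescence.

    Per setpoint the steady state of the coupled supply/demand system is
    solved exactly; φPSII is emitted so that τ·Qin·φPSII equals the
    electron transport actually sustaining carboxylation + oxygenation,
    making the curve exactly invertible by the variable-J fit at zero
    noise.  Noise (if configured) is multiplicative on A and φPSII.
    """
    rng = np.random.default_rng(seed)
    cond = truth.aci
    kin = truth.constants.kinetics
    params = truth.fvcb
    gsw = cond.gsw_mean * max(0.05, 1.0 + cond.gsw_cv * rng.standard_normal())
    rd_t = arrhenius_scale(params.Rd25, kin.Ea_Rd, cond.tleaf_c)
    gstar = gamma_star(cond.o2, cond.tleaf_c, kin)

    rows = {k: [] for k in ("a", "ci", "ca", "gsw", "qin", "tleaf", "phi", "co2r", "time")}
    for i, ca in enumerate(cond.co2_sequence):
        a, ci, cc = _solve_steady_state(ca, gsw, truth.gm, params, cond, truth.constants)
        if abs(cc - gstar) < 1e-9:
            j_act = arrhenius_scale(params.J25, kin.Ea_J, cond.tleaf_c)
        else:
            j_act = _j_actual(a, rd_t, cc, gstar)
        phi = j_act / (params.tau * cond.qin)
        a_obs = a * (1.0 + truth.noise.a_frac * rng.standard_normal())
        phi_obs = phi * (1.0 + truth.noise.phi_frac * rng.standard_normal())
        rows["a"].append(a_obs)
        rows["ci"].append(ci)
        rows["ca"].append(ca)
        rows["gsw"].append(gsw)
        rows["qin"].append(cond.qin)
        rows["tleaf"].append(cond.tleaf_c)
        rows["phi"].append(min(phi_obs, 1.0))
        rows["co2r"].append(float(ca))
        rows["time"].append(240.0 * i)
    return ResponseCurve(
        a=rows["a"], ci=rows["ci"], ca=rows["ca"], gsw=rows["gsw"],
        qin=rows["qin"], tleaf_c=rows["tleaf"], phipsii=rows["phi"],
        co2_r=rows["co2r"], o2=cond.o2, time=rows["time"],
        plant_id=plant_id, genotype=genotype,
    )


# --------------------------------------------------------------------------
# forward 13C discrimination (independent transcription; see module docstring)
# --------------------------------------------------------------------------

def forward_discrimination(
    a, ca, ci, cc, e_trans, gsw, rd, gstar, fr
) -> float:
    """Predicted Δ (absolute units) for a leaf with chloroplast CO2 ``cc``.

    Independent forward transcription of the comprehensive discrimination
    model with isotopically disconnected day respiration:

        Δ = ā(Ca−Ci)/[Ca(1−t)]
          + (1+t)/(1−t)·[a_m(Ci−Cc) + b·Cc − ê(Cc−Γ*) − f·Γ*]/Ca

    with ê = e*·Rd/(A+Rd) and t = (1+ā)E/(2 g_ac), g_ac the stomatal CO2
    conductance (boundary layer lumped in upstream of Ca here).
    """
    a_bar = fr.a / 1000.0
    t = (1.0 + a_bar) * e_trans / (2.0 * (gsw / 1.6))
    e_app = fr.e + (fr.delta_substrate - fr.delta_measurement_co2) / (
        1.0 + fr.delta_measurement_co2 / 1000.0
    )
    e_hat = (e_app / 1000.0) * rd / (a + rd)
    term_air = a_bar * (ca - ci) / (ca * (1.0 - t))
    term_leaf = ((1.0 + t) / (1.0 - t)) * (
        (fr.a_m / 1000.0) * (ci - cc)
        + (fr.b / 1000.0) * cc
        - e_hat * (cc - gstar)
        - (fr.f / 1000.0) * gstar
    ) / ca
    return term_air + term_leaf


def _delta_out_from_discrimination(delta_in_abs, c_in, c_out, big_delta, r_std):
    """Solve Δ = ξ(δo−δi)/(1+δo−ξ(δo−δi)) for δo with ξ on a 12C basis.

    ξ couples to δo through the isotopologue split of C_out, so a short
    fixed-point iteration is used (converges to machine precision in a few
    steps because the split depends only weakly on δ).
    """
    r_in = r_std * (1.0 + delta_in_abs)
    c12_in = c_in / (1.0 + r_in)
    delta_out = delta_in_abs
    for _ in range(60):
        r_out = r_std * (1.0 + delta_out)
        c12_out = c_out / (1.0 + r_out)
        xi = c12_in / (c12_in - c12_out)
        new = (xi * delta_in_abs * (1.0 + big_delta) + big_delta) / (
            xi * (1.0 + big_delta) - big_delta
        )
        if abs(new - delta_out) < 1e-16:
            delta_out = new
            break
        delta_out = new
    return delta_out


@dataclass
class TDLSession:
    """Raw TDL table, matching gas-exchange log, and the underlying truth."""

    tdl: pd.DataFrame  # columns: time, valve, stream, c12_raw, c13_raw
    gasex: pd.DataFrame  # one row per log entry per chamber
    truth: dict  # per-chamber true steady state (a, ci, cc, gm, ...)


def generate_tdl_session(truth: TruthSpec, seed: int, gm_by_chamber=None) -> TDLSession:
    """Forward-simulate a TDL + gas-exchange measurement session.

    Each chamber holds a leaf whose steady state follows from the truth
    FvCB parameters and mesophyll conductance (``gm_by_chamber`` overrides
    ``truth.gm`` per chamber).  Chamber inlet/outlet streams are computed
    from the chamber mass balance and the forward discrimination model,
    then pushed through the instrument gain/offset model together with the
    five calibration streams.  Cycle k of n acquires gains scaled by
    (1 + drift·k/(n−1)).
    """
    rng = np.random.default_rng(seed)
    cond = truth.iso
    kin = truth.constants.kinetics
    fr = truth.constants.fractionation
    tanks = truth.tanks
    gm_list = list(gm_by_chamber or [truth.gm] * cond.n_chambers)
    rd_t = arrhenius_scale(truth.fvcb.Rd25, kin.Ea_Rd, cond.tleaf_c)
    gstar = gamma_star(cond.o2, cond.tleaf_c, kin)
    delta_in_abs = cond.delta_in / 1000.0

    chamber_truth = {}
    streams_true = {}
    for ch, gm in enumerate(gm_list, start=1):
        a, ci, cc = _solve_steady_state(
            cond.ca, cond.gsw_mean, gm, truth.fvcb, cond, truth.constants
        )
        e_trans = cond.gsw_mean * cond.vpd_kpa / cond.pressure_kpa
        big_delta = forward_discrimination(
            a, cond.ca, ci, cc, e_trans, cond.gsw_mean, rd_t, gstar, fr
        )
        c_out = cond.ca
        c_in = c_out + a / cond.flow_per_area
        delta_out_abs = _delta_out_from_discrimination(
            delta_in_abs, c_in, c_out, big_delta, fr.R_std
        )
        r_in = fr.R_std * (1.0 + delta_in_abs)
        r_out = fr.R_std * (1.0 + delta_out_abs)
        streams_true[f"ref_{ch}"] = (c_in / (1.0 + r_in), c_in * r_in / (1.0 + r_in))
        streams_true[f"sample_{ch}"] = (
            c_out / (1.0 + r_out), c_out * r_out / (1.0 + r_out)
        )
        chamber_truth[ch] = {
            "a": a, "ci": ci, "cc": cc, "gm": gm, "gsw": cond.gsw_mean,
            "e": e_trans, "ca": cond.ca, "delta_obs": big_delta * 1000.0,
            "rd": rd_t, "gamma_star": gstar,
        }
    for name, total in zip(("zero", "span_60", "span_300", "span_1000"), tanks.span_totals):
        streams_true[name] = tanks.split(total, tanks.delta_cal)
    streams_true["noaa_delta"] = tanks.split(tanks.noaa_co2, tanks.noaa_delta)

    ins = truth.instrument
    rows = []
    for k in range(cond.n_cycles):
        drift = ins.gain_drift_frac * (k / max(cond.n_cycles - 1, 1))
        g12 = ins.gain12 * (1.0 + drift)
        g13 = ins.gain13 * (1.0 + drift)
        t0 = k * cond.cycle_period_s
        for v, name in enumerate(STREAM_SEQUENCE, start=1):
            c12, c13 = streams_true[name]
            if name.startswith(("ref_", "sample_")) and truth.noise.delta_permil > 0:
                c13 = c13 * (1.0 + truth.noise.delta_permil / 1000.0 * rng.standard_normal())
            rows.append({
                "time": t0 + 20.0 * v - 5.0,  # centre of the averaged last 10 s
                "valve": v,
                "stream": name,
                "c12_raw": (c12 - ins.offset12) / g12,
                "c13_raw": (c13 - ins.offset13) / g13,
            })
    tdl = pd.DataFrame(rows)

    glog = []
    n_logs = int(cond.n_cycles * cond.cycle_period_s / cond.log_interval_s)
    for i in range(n_logs):
        t_log = (i + 0.5) * cond.log_interval_s
        for ch, tr in chamber_truth.items():
            noise = lambda: 1.0 + truth.noise.gasex_frac * rng.standard_normal()
            glog.append({
                "time": t_log, "chamber": ch,
                "A": tr["a"] * noise(), "Ci": tr["ci"] * noise(),
                "Ca": tr["ca"], "gsw": tr["gsw"] * noise(), "E": tr["e"] * noise(),
                "Qin": cond.qin, "Tleaf": cond.tleaf_c,
                "PhiPS2": float("nan"), "CO2_r": cond.ca,
            })
    gasex = pd.DataFrame(glog)
    return TDLSession(tdl=tdl, gasex=gasex, truth=chamber_truth)


def generate_cohort(truth: TruthSpec, seed: int) -> tuple:
    """Draw per-replicate anatomy and derived gm for a WT + events cohort.

    Traits are drawn per biological replicate from normal distributions
    with the configured means × genotype multipliers and common CV; gm is
    then composed forward through the serial conductance model, so the
    cohort supports both the partition round trip and genotype contrasts.
    Returns ``(anatomy_table, gm_table)`` as DataFrames (anatomy rows are
    technical replicates).
    """
    des = truth.cohort
    if len(des.genotypes) < 2 or des.wt_label not in des.genotypes:
        raise InvalidArgumentError("cohort needs >= 2 genotypes incl. the WT label")
    rng = np.random.default_rng(seed)
    pc = truth.constants.physical
    tleaf = truth.iso.tleaf_c
    anat_rows, gm_rows = [], []

    def draw(mean):
        return mean * max(0.2, 1.0 + des.cv * rng.standard_normal())

    for gt in des.genotypes:
        m = (lambda k: 1.0) if gt == des.wt_label else (lambda k: des.mult.get(k, 1.0))
        for rep in range(1, des.n_replicates + 1):
            t_cw = draw(des.t_cw_nm * m("t_cw_nm"))
            f_ias = min(0.95, draw(des.f_ias * m("f_ias")))
            t_mes = draw(des.t_mes_um * m("t_mes_um"))
            s_c = draw(des.s_c * m("s_c"))
            p_tau = draw(des.p_over_tau * m("p_over_tau"))
            g_ias = airspace_conductance(f_ias, t_mes, pc, tleaf)
            g_mem = membrane_conductance(s_c, pc, tleaf)
            g_cw = wall_conductance_from_porosity(p_tau, t_cw, s_c, pc, tleaf)
            gm = compose_gm(g_ias, g_cw, g_mem)
            # section geometry consistent with the drawn S_c and Sc/Sm
            lc = s_c * des.w_um / des.curvature_f
            lmes = lc / des.sc_over_sm
            for tech in range(1, des.n_technical + 1):
                jitter = 1.0 + 0.02 * rng.standard_normal()
                anat_rows.append({
                    "genotype": gt, "replicate": f"{gt}-r{rep}", "technical": tech,
                    "Lmes_um": lmes * jitter, "Lc_um": lc * jitter,
                    "W_um": des.w_um, "F": des.curvature_f,
                    "wall_area_nm2": t_cw * jitter * 6500.0,
                    "wall_length_nm": 6500.0,
                    "Tcw_nm": t_cw * jitter, "Tmes_um": t_mes, "f_ias": f_ias,
                })
            gm_rows.append({
                "genotype": gt, "replicate": f"{gt}-r{rep}", "gm": gm,
                "g_ias_true": g_ias, "g_cw_true": g_cw, "g_mem_true": g_mem,
                "p_over_tau_true": p_tau, "Tcw_nm": t_cw, "Tmes_um": t_mes,
                "f_ias": f_ias, "S_c": s_c, "Tleaf": tleaf,
            })
    return pd.DataFrame(anat_rows), pd.DataFrame(gm_rows)
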