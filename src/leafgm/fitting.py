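"""Fitting measured CO2-response curves.

Two estimators are provided:

* :func:`fit_aci` — the classical A–Ci fit with mesophyll conductance set
  to infinity (Cc = Ci), yielding *apparent* FvCB parameters;
* :func:`fit_variable_j` — the variable-J method, in which the
  fluorescence-based electron transport rate J_F = τ·Qin·φPSII is combined
  with measured A to infer chloroplastic CO2 per point,

      Cc = Γ* (J_F + 8 (A + Rd)) / (J_F − 4 (A + Rd)),

  giving per-point mesophyll conductance gm = A / (Ci − Cc).  Five unknowns
  (Vcmax25, J25, Rd25, Tp25, τ) are chosen to minimize the squared mismatch
  between measured A and the FvCB prediction at the inferred Cc.

Both objectives are multimodal, so fits use Latin-hypercube multistart of
bounded trust-region least squares.  Points at the variable-J pole
(J_F ≤ 4(A+Rd)) are excluded from the objective, never clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .constants import KineticConstants
from .errors import (
    FitFailureError,
    InvalidArgumentError,
    MissingOperatingPointError,
    SingularPointError,
)
from .fvcb import FvCBParams, arrhenius_scale, gamma_star

__all__ = [
    "ResponseCurve",
    "FitConfig",
    "FitResult",
    "fit_aci",
    "fit_variable_j",
    "cc_from_variable_j",
    "gm_at_reference",
    "value_at_reference",
]

_PENALTY = 50.0  # residual assigned to singular points to steer the optimizer


@dataclass
class ResponseCurve:
    """One measured CO2-response curve (ordered as logged).

    Arrays are aligned per logged point.  ``co2_r`` is the reference-CO2
    setpoint sequence as measured, including repeated 400 recovery steps.
    """

    a: np.ndarray  # net assimilation, umol m^-2 s^-1
    ci: np.ndarray  # intercellular CO2, umol mol^-1
    ca: np.ndarray  # ambient CO2, umol mol^-1
    gsw: np.ndarray  # stomatal conductance to water, mol m^-2 s^-1
    qin: np.ndarray  # incident PPFD, umol m^-2 s^-1
    tleaf_c: np.ndarray  # leaf temperature, degC
    phipsii: np.ndarray | None = None  # PSII operating efficiency
    co2_r: np.ndarray | None = None  # reference CO2 setpoint
    e: np.ndarray | None = None  # transpiration, mol m^-2 s^-1
    o2: float = 210.0  # mmol mol^-1
    time: np.ndarray | None = None
    plant_id: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        for name in ("a", "ci", "ca", "gsw", "qin", "tleaf_c", "phipsii", "co2_r", "e", "time"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))
        n = len(self.a)
        for name in ("ci", "ca", "gsw", "qin", "tleaf_c"):
            if len(getattr(self, name)) != n:
                raise InvalidArgumentError(f"column '{name}' length mismatch")
        if np.any(self.ci <= 0):
            raise InvalidArgumentError("Ci must be positive")

    def __len__(self) -> int:
        return len(self.a)


@dataclass
class FitConfig:
    """Optimizer settings with bounds bracketing values plausible for C3 leaves."""

    bounds: dict = field(
        default_factory=lambda: {
            "Vcmax25": (5.0, 500.0),
            "J25": (10.0, 600.0),
            "Rd25": (0.0, 10.0),
            "Tp25": (1.0, 40.0),
            "tau": (0.2, 0.6),
        }
    )
    n_starts: int = 10
    seed: int = 0
    weights: np.ndarray | None = None
    fit_tpu: bool = True
    max_singular_fraction: float = 0.25
    recovery_pair_tolerance: float = 0.10  # relative spread allowed for 400-400 pair
    j_consistency_weight: float = 1.0
    xtol: float = 1e-12
    ftol: float = 1e-12


@dataclass
class FitResult:
    """Fitted parameters plus per-point diagnostics."""

    params: FvCBParams
    stderr: dict
    cc: np.ndarray
    gm: np.ndarray
    limiting_process: np.ndarray
    residuals: np.ndarray
    objective: float
    success: bool
    n_starts_converged: int
    n_singular: int
    flags: list
    curve: ResponseCurve
    param_names: tuple = ()
    rm: float = math.nan  # common mesophyll resistance from the J-consistency block

    @property
    def nonphysical_gm_at_operating_point(self) -> bool:
        return "nonphysical gm at operating point" in self.flags


def cc_from_variable_j(a, rd, gamma_star_, j_f):
    """Chloroplastic CO2 from the variable-J (Harley-style) relation.

    Cc = Γ*(J_F + 8(A + Rd)) / (J_F − 4(A + Rd)).  Raises
    :class:`SingularPointError` at or beyond the pole J_F = 4(A + Rd) for
    scalar input; array input returns NaN at singular points.
    """
    a = np.asarray(a, dtype=float)
    j_f = np.asarray(j_f, dtype=float)
    gross = a + rd
    denom = j_f - 4.0 * gross
    singular = denom <= 0
    if np.ndim(a) == 0:
        if singular:
            raise SingularPointError(
                f"J_F = {float(j_f):.3g} <= 4(A + Rd) = {float(4 * gross):.3g}"
            )
        return float(gamma_star_ * (j_f + 8.0 * gross) / denom)
    cc = np.where(singular, np.nan, gamma_star_ * (j_f + 8.0 * gross) / np.where(singular, 1.0, denom))
    return cc


def _scaled_terms(curve: ResponseCurve, constants: KineticConstants):
    """Per-point temperature factors and kinetic constants for a curve."""
    t = curve.tleaf_c
    f_v = arrhenius_scale(1.0, constants.Ea_Vcmax, t)
    f_j = arrhenius_scale(1.0, constants.Ea_J, t)
    f_r = arrhenius_scale(1.0, constants.Ea_Rd, t)
    f_p = arrhenius_scale(1.0, constants.Ea_Tp, t)
    kc = arrhenius_scale(constants.Kc25, constants.Ea_Kc, t)
    ko = arrhenius_scale(constants.Ko25, constants.Ea_Ko, t)
    gstar = np.array([gamma_star(curve.o2, tc, constants) for tc in np.atleast_1d(t)])
    km = kc * (1.0 + curve.o2 / ko)
    return np.atleast_1d(f_v), np.atleast_1d(f_j), np.atleast_1d(f_r), np.atleast_1d(f_p), np.atleast_1d(km), gstar


def _an_model(cc, vcmax, j, rd, tp, gstar, km):
    """Vectorized FvCB net rate at temperature-scaled parameter arrays."""
    wc = vcmax * (cc - gstar) / (cc + km)
    wj = j * (cc - gstar) / (4.0 * cc + 8.0 * gstar)
    w = np.minimum(wc, wj)
    if tp is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            wp = np.where(cc > gstar, 3.0 * tp * np.ones_like(cc), np.inf)
        w = np.minimum(w, wp)
    return w - rd


def _limiting(cc, vcmax, j, rd, tp, gstar, km):
    wc = vcmax * (cc - gstar) / (cc + km)
    wj = j * (cc - gstar) / (4.0 * cc + 8.0 * gstar)
    wp = np.where(cc > gstar, 3.0 * tp, np.inf) if tp is not None else np.full_like(cc, np.inf)
    return np.array(["Wc", "Wj", "Wp"])[np.argmin(np.stack([wc, wj, wp]), axis=0)]


def _multistart(residual_fn, names, config: FitConfig, extra_starts=()):
    lo = np.array([config.bounds[n][0] for n in names])
    hi = np.array([config.bounds[n][1] for n in names])
    sampler = qmc.LatinHypercube(d=len(names), seed=config.seed)
    starts = qmc.scale(sampler.random(config.n_starts), lo, hi)
    if len(extra_starts):
        extra = np.clip(np.atleast_2d(extra_starts), lo, hi)
        starts = np.vstack([extra, starts])
    best = None
    n_ok = 0
    for x0 in starts:
        try:
            res = least_squares(
                residual_fn, x0, bounds=(lo, hi), method="trf",
                xtol=config.xtol, ftol=config.ftol, gtol=1e-12,
            )
        except Exception:  # numerical breakdown on a bad start: try the next
            continue
        if res.status > 0:
            n_ok += 1
            if best is None or res.cost < best.cost:
                best = res
    if best is None:
        raise FitFailureError(f"no start converged out of {config.n_starts}")
    # high-precision polish from the best start (the objective can have
    # long flat valleys where default tolerances stop early)
    try:
        polished = least_squares(
            residual_fn, best.x, bounds=(lo, hi), method="trf",
            xtol=2.3e-16, ftol=2.3e-16, gtol=None, x_scale="jac", max_nfev=400,
        )
        if polished.status > 0 and polished.cost <= best.cost:
            best = polished
    except Exception:
        pass
    return best, n_ok


def _stderr(res, names):
    """Asymptotic standard errors from the Jacobian at the optimum."""
    m, p = res.jac.shape
    dof = max(m - p, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.pinv(res.jac.T @ res.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return dict(zip(names, se))


def _heuristic_start(curve, f_v, f_j, f_r, f_p, km, gstar, fit_tpu):
    """Data-driven initial guess: Rd from a fixed fraction of peak A, J from
    the light/CO2-saturated plateau, Vcmax from the steepest low-Ci point
    evaluated at Cc = Ci, Tp from the plateau."""
    a_max = float(np.max(curve.a))
    rd0 = max(0.02 * a_max, 0.1)
    j0 = 4.2 * (a_max + rd0) / float(np.median(f_j))
    low = int(np.argmin(curve.ci))
    ci_low = curve.ci[low]
    denom = max(ci_low - gstar[low], 5.0)
    vc0 = (curve.a[low] + rd0) * (ci_low + km[low]) / denom / f_v[low]
    if not np.isfinite(vc0) or vc0 <= 0:
        vc0 = 100.0
    start = [vc0, j0, rd0]
    if fit_tpu:
        start.append((a_max + rd0) / 3.0 / float(np.median(f_p)))
    return start


def fit_aci(
    curve: ResponseCurve,
    constants: KineticConstants | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit the FvCB model on an intercellular-CO2 basis (gm = ∞, Cc = Ci).

    Returns *apparent* parameters at 25 °C.  If every point of the best fit
    sits in a single limiting regime, the parameters governing the other
    regimes are flagged as weakly identified.
    """
    constants = constants or KineticConstants()
    config = config or FitConfig()
    if len(curve) < 6:
        raise InvalidArgumentError("need >= 6 points to fit a response curve")
    f_v, f_j, f_r, f_p, km, gstar = _scaled_terms(curve, constants)
    cc = curve.ci
    a_meas = curve.a
    w = config.weights if config.weights is not None else np.ones_like(a_meas)
    names = ("Vcmax25", "J25", "Rd25", "Tp25") if config.fit_tpu else ("Vcmax25", "J25", "Rd25")

    def residual(x):
        vc, j, rd = x[0] * f_v, x[1] * f_j, x[2] * f_r
        tp = x[3] * f_p if config.fit_tpu else None
        return w * (_an_model(cc, vc, j, rd, tp, gstar, km) - a_meas)

    start = _heuristic_start(curve, f_v, f_j, f_r, f_p, km, gstar, config.fit_tpu)
    best, n_ok = _multistart(residual, names, config, extra_starts=[start])
    x = best.x
    tp25 = x[3] if config.fit_tpu else math.inf
    params = FvCBParams(Vcmax25=x[0], J25=x[1], Rd25=x[2], Tp25=tp25)
    tp_t = x[3] * f_p if config.fit_tpu else None
    labels = _limiting(cc, x[0] * f_v, x[1] * f_j, x[2] * f_r, tp_t, gstar, km)
    flags = _identifiability_flags(labels, config.fit_tpu)
    return FitResult(
        params=params,
        stderr=_stderr(best, names),
        cc=cc.copy(),
        gm=np.full_like(cc, np.inf),
        limiting_process=labels,
        residuals=best.fun / w,
        objective=float(2.0 * best.cost),
        success=True,
        n_starts_converged=n_ok,
        n_singular=0,
        flags=flags,
        curve=curve,
        param_names=names,
    )


def _identifiability_flags(labels, fit_tpu):
    flags = []
    present = set(labels.tolist())
    if "Wc" not in present:
        flags.append("Vcmax25 weakly identified")
    if "Wj" not in present:
        flags.append("J25 weakly identified")
    if fit_tpu and "Wp" not in present:
        flags.append("Tp25 weakly identified")
    return flags


def fit_variable_j(
    curve: ResponseCurve,
    constants: KineticConstants | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Variable-J fit: recover (Vcmax25, J25, Rd25, Tp25, τ), Cc(Ci) and gm(Ci).

    For each candidate parameter vector, per-point J_F = τ·Qin·φPSII gives
    Cc through :func:`cc_from_variable_j`; the residual is the mismatch
    between measured A and the FvCB prediction at that Cc.  Singular points
    receive a fixed penalty during optimization and are reported (not
    clipped).  Fails if more than ``max_singular_fraction`` of points are
    singular at the optimum.
    """
    constants = constants or KineticConstants()
    config = config or FitConfig()
    if curve.phipsii is None:
        raise InvalidArgumentError("variable-J fit requires phiPSII per point")
    if len(curve) < 6:
        raise InvalidArgumentError("need >= 6 points to fit a response curve")
    f_v, f_j, f_r, f_p, km, gstar = _scaled_terms(curve, constants)
    a_meas = curve.a
    ci = curve.ci
    qphi = curve.qin * curve.phipsii
    w = config.weights if config.weights is not None else np.ones_like(a_meas)
    lam = config.j_consistency_weight
    names = ("Vcmax25", "J25", "Rd25", "Tp25", "tau")
    if lam > 0:
        names = names + ("rm",)
        if "rm" not in config.bounds:
            config.bounds = dict(config.bounds, rm=(1e-4, 50.0))
    # J-consistency is evaluated on the well-lit part of the curve only
    good0 = a_meas > 0.25 * np.max(a_meas)

    def split(x):
        vc, j, rd = x[0] * f_v, x[1] * f_j, x[2] * f_r
        tp = x[3] * f_p if config.fit_tpu else None
        jf = x[4] * qphi
        gross = a_meas + rd
        denom = jf - 4.0 * gross
        ok = denom > 0
        cc = np.where(ok, gstar * (jf + 8.0 * gross) / np.where(ok, denom, 1.0), np.nan)
        return vc, j, rd, tp, jf, cc, ok, denom

    def residual(x):
        vc, j, rd, tp, jf, cc, ok, denom = split(x)
        an = _an_model(np.where(ok, cc, gstar), vc, j, rd, tp, gstar, km)
        r = w * (an - a_meas)
        viol = np.where(ok, 0.0, -denom / np.maximum(jf, 1e-9))
        r_a = np.where(ok, r, _PENALTY * (1.0 + viol))
        if lam <= 0:
            return r_a
        # J-consistency term.  The A-only objective has an exact flat
        # direction: on Rubisco-limited points J_F is linear in (A + Rd),
        # so an Rd shift is absorbed by Vcmax and Tp with A residuals
        # unchanged while the implied gm drifts freely.  This block pins
        # the physical point on that ridge by requiring the measured
        # fluorescence J to match the electron transport implied by a
        # common mesophyll resistance rm (supply-line Cc = Ci − A·rm):
        #     J_pred = (A + Rd)(4 Cc_s + 8 Γ*)/(Cc_s − Γ*).
        # It is formulated in J-space because measured Qin·φPSII enters
        # linearly there, so the noise does not bias the ridge position.
        gross = a_meas + rd
        cc_s = ci - a_meas * x[5]
        den_s = np.maximum(cc_s - gstar, 0.5)  # continuous barrier at Γ*
        jf_pred = gross * (4.0 * cc_s + 8.0 * gstar) / den_s
        r_j = np.where(good0, lam * (jf - jf_pred), 0.0)
        return np.concatenate([r_a, r_j])

    start = _heuristic_start(curve, f_v, f_j, f_r, f_p, km, gstar, fit_tpu=True)
    start = start + [0.4] + ([3.0] if lam > 0 else [])
    best, n_ok = _multistart(residual, names, config, extra_starts=[start])
    x = best.x
    vc, j, rd, tp, jf, cc, ok, _ = split(x)
    n_singular = int(np.sum(~ok))
    if n_singular > config.max_singular_fraction * len(curve):
        raise FitFailureError(
            f"{n_singular}/{len(curve)} points singular at the optimum"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        gm = np.where(ok, a_meas / (ci - cc), np.nan)
    params = FvCBParams(
        Vcmax25=x[0], J25=x[1], Rd25=x[2],
        Tp25=x[3] if config.fit_tpu else math.inf, tau=x[4],
    )
    labels = _limiting(np.where(ok, cc, gstar), vc, j, rd, tp, gstar, km)
    flags = _identifiability_flags(labels[ok], config.fit_tpu)
    result = FitResult(
        params=params,
        stderr=_stderr(best, names),
        cc=cc,
        gm=gm,
        limiting_process=labels,
        residuals=np.where(ok, best.fun[: len(curve)] / w, np.nan),
        objective=float(2.0 * best.cost),
        success=True,
        n_starts_converged=n_ok,
        n_singular=n_singular,
        flags=flags,
        curve=curve,
        param_names=names,
        rm=float(x[5]) if lam > 0 else math.nan,
    )
    try:
        gm_op = gm_at_reference(result)
        if not math.isfinite(gm_op) or gm_op <= 0:
            result.flags.append("nonphysical gm at operating point")
    except MissingOperatingPointError:
        pass
    return result


def value_at_reference(
    co2_r: np.ndarray,
    values: np.ndarray,
    reference: float = 400.0,
    rtol: float = 0.02,
    pair_tolerance: float = 0.10,
) -> float:
    """Operating-point value from the logged setpoint sequence.

    With a single matching setpoint, that point's value is returned.  With
    the standard descending-then-ascending protocol (a pre-ramp 400 step
    plus a mid-sequence 400,400 recovery pair) the recovery pair is averaged
    when its two values agree to ``pair_tolerance`` (relative); otherwise
    the pre-ramp point is used as the stable estimate.
    """
    co2_r = np.asarray(co2_r, dtype=float)
    idx = np.flatnonzero(np.abs(co2_r - reference) <= rtol * reference)
    if idx.size == 0:
        raise MissingOperatingPointError(f"no logged point near setpoint {reference}")
    if idx.size == 1:
        return float(values[idx[0]])
    pre = idx[0]
    later = idx[1:]
    # consecutive later points form the recovery pair
    pairs = [(i, j) for i, j in zip(later[:-1], later[1:]) if j == i + 1]
    if pairs:
        i, j = pairs[0]
        v1, v2 = float(values[i]), float(values[j])
        mean = 0.5 * (v1 + v2)
        if mean != 0 and abs(v1 - v2) / abs(mean) < pair_tolerance:
            return mean
        return float(values[pre])
    return float(np.nanmean(values[idx]))


def gm_at_reference(fit: FitResult, reference: float = 400.0) -> float:
    """Mesophyll conductance at the reference (operating) CO2 setpoint."""
    if fit.curve.co2_r is None:
        raise MissingOperatingPointError("curve carries no setpoint column")
    return value_at_reference(
        fit.curve.co2_r, fit.gm, reference=reference,
    )
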