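"""Farquhar–von Caemmerer–Berry C3 assimilation model.

Net assimilation is the minimum of three potential carboxylation rates —
Rubisco-limited (Wc), RuBP-regeneration-limited (Wj) and triose-phosphate-
utilization-limited (Wp) — minus day respiration:

    Wc = Vcmax (Cc − Γ*) / (Cc + Kc (1 + O/Ko))
    Wj = J (Cc − Γ*) / (4 Cc + 8 Γ*)
    Wp = 3 Tp (Cc − Γ*) / (Cc − (1 + 3α) Γ*)   for Cc > (1 + 3α) Γ*
    An = min(Wc, Wj, Wp) − Rd

with all parameters Arrhenius-scaled from their 25 °C values.  The minimum
is a strict minimum (no hyperbolic smoothing) so that the limiting-process
label of every point is well defined.  α is the fraction of glycolate
carbon not returned to the chloroplast and defaults to 0, in which case Wp
reduces to the constant 3·Tp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import KineticConstants, R_GAS, T_REF_K, celsius_to_kelvin
from .errors import InvalidArgumentError

__all__ = [
    "FvCBParams",
    "LeafEnvironment",
    "AssimilationResult",
    "arrhenius_scale",
    "gamma_star",
    "fvcb_assimilation",
    "electron_transport_from_fluorescence",
]

_LIMITING_LABELS = np.array(["Wc", "Wj", "Wp"])


@dataclass
class FvCBParams:
    """FvCB parameter set at the 25 °C reference.

    Rates in μmol m⁻² s⁻¹.  ``tau`` is the product of leaf absorptance and
    the fraction of absorbed quanta reaching photosystem II; it converts
    incident light × φPSII into the fluorescence-based electron transport
    rate and is only used by the variable-J machinery.
    """

    Vcmax25: float
    J25: float
    Rd25: float
    Tp25: float = math.inf
    alpha_glycolate: float = 0.0
    tau: float = 0.42

    def __post_init__(self) -> None:
        for name in ("Vcmax25", "J25", "Rd25", "Tp25"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if not 0.0 <= self.alpha_glycolate <= 1.0:
            raise InvalidArgumentError("alpha_glycolate must be in [0, 1]")
        if not 0.0 < self.tau < 1.0:
            raise InvalidArgumentError("tau must be in (0, 1)")


@dataclass
class LeafEnvironment:
    """Chamber/leaf state for one or more evaluation points.

    ``cc`` is chloroplastic CO2 (μmol mol⁻¹); O2 in mmol mol⁻¹.
    """

    cc: float | np.ndarray
    o2: float = 210.0
    tleaf_c: float = 25.0
    qin: float = 1800.0
    pressure_kpa: float | None = None

    def __post_init__(self) -> None:
        cc = np.asarray(self.cc, dtype=float)
        if np.any(cc < 0) or not np.all(np.isfinite(cc)):
            raise InvalidArgumentError("Cc must be finite and >= 0")
        if self.o2 < 0:
            raise InvalidArgumentError("O2 must be >= 0")
        if not -10.0 <= self.tleaf_c <= 50.0:
            raise InvalidArgumentError("Tleaf outside -10..50 degC")


@dataclass
class AssimilationResult:
    An: np.ndarray
    Wc: np.ndarray
    Wj: np.ndarray
    Wp: np.ndarray
    limiting_process: np.ndarray
    Rd: float
    GammaStar: float


def arrhenius_scale(value25, Ea: float, tleaf_c) -> np.ndarray | float:
    """Scale a 25 °C rate to leaf temperature with an Arrhenius factor.

    ``value25 · exp[Ea (T − 298.15) / (298.15 · R · T)]`` — identically 1
    at 25 °C for any activation energy.
    """
    if not (np.all(np.isfinite(value25)) and np.isfinite(Ea) and np.all(np.isfinite(tleaf_c))):
        raise InvalidArgumentError("arrhenius_scale requires finite inputs")
    t_k = celsius_to_kelvin(np.asarray(tleaf_c, dtype=float))
    if np.any(t_k <= 0):
        raise InvalidArgumentError("temperature below 0 K")
    factor = np.exp(Ea * (t_k - T_REF_K) / (T_REF_K * R_GAS * t_k))
    out = value25 * factor
    return float(out) if np.ndim(out) == 0 else out


def gamma_star(
    o2_mmol: float, tleaf_c: float, constants: KineticConstants | None = None
) -> float:
    """Photorespiratory CO2 compensation point Γ* (μmol mol⁻¹).

    Depends on the configured ``gamma_star_mode``:

    * ``"specificity"`` — from the liquid-phase Rubisco specificity and the
      temperature-dependent CO2/O2 solubility ratio:
      Γ* = 0.5 · O / (S_co · kh_CO2/kh_O2), O as gas mole fraction.
    * ``"arrhenius"`` — Arrhenius scaling of the tabulated Γ*25 (only valid
      at 21% O2) — Γ*25 · f(T).
    """
    constants = constants or KineticConstants()
    if o2_mmol < 0:
        raise InvalidArgumentError("O2 must be >= 0")
    if constants.S_co <= 0:
        raise InvalidArgumentError("Rubisco specificity must be positive")
    if constants.gamma_star_mode == "arrhenius":
        return arrhenius_scale(constants.GammaStar25, constants.Ea_GammaStar, tleaf_c)
    s_gas = constants.S_co * constants.solubility.ratio_co2_over_o2(tleaf_c)
    o2_frac = o2_mmol * 1e-3
    return 0.5 * o2_frac / s_gas * 1e6


def fvcb_assimilation(
    env: LeafEnvironment,
    params: FvCBParams,
    constants: KineticConstants | None = None,
) -> AssimilationResult:
    """Evaluate the FvCB model at chloroplastic CO2 ``env.cc``.

    Temperature scaling of Vcmax, J, Rd, Tp, Kc, Ko (and Γ* in Arrhenius
    mode) happens internally.  Returns per-point gross rates, net
    assimilation and the limiting-process label (argmin of the three
    gross rates).
    """
    constants = constants or KineticConstants()
    cc = np.atleast_1d(np.asarray(env.cc, dtype=float))
    t = env.tleaf_c

    vcmax = arrhenius_scale(params.Vcmax25, constants.Ea_Vcmax, t)
    j = arrhenius_scale(params.J25, constants.Ea_J, t)
    rd = arrhenius_scale(params.Rd25, constants.Ea_Rd, t)
    kc = arrhenius_scale(constants.Kc25, constants.Ea_Kc, t)
    ko = arrhenius_scale(constants.Ko25, constants.Ea_Ko, t)
    gstar = gamma_star(env.o2, t, constants)
    alpha = params.alpha_glycolate

    km = kc * (1.0 + env.o2 / ko)
    wc = vcmax * (cc - gstar) / (cc + km)
    wj = j * (cc - gstar) / (4.0 * cc + 8.0 * gstar)

    wp = np.full_like(cc, np.inf)
    if np.isfinite(params.Tp25):
        tp = arrhenius_scale(params.Tp25, constants.Ea_Tp, t)
        thresh = (1.0 + 3.0 * alpha) * gstar
        active = cc > thresh
        wp[active] = 3.0 * tp * (cc[active] - gstar) / (cc[active] - thresh)
        # at the compensation point the TPU rate vanishes with the others
        wp[np.isclose(cc, gstar)] = 0.0

    rates = np.stack([wc, wj, wp])
    idx = np.argmin(rates, axis=0)
    w = np.take_along_axis(rates, idx[None, :], axis=0)[0]
    an = w - rd
    res = AssimilationResult(
        An=an,
        Wc=wc,
        Wj=wj,
        Wp=wp,
        limiting_process=_LIMITING_LABELS[idx],
        Rd=rd,
        GammaStar=gstar,
    )
    return res


def electron_transport_from_fluorescence(qin, phipsii, tau: float):
    """Fluorescence-based electron transport estimate J_F = τ·Qin·φPSII."""
    if not 0.0 < tau < 1.0:
        raise InvalidArgumentError("tau must be in (0, 1)")
    qin = np.asarray(qin, dtype=float)
    phipsii = np.asarray(phipsii, dtype=float)
    if np.any(qin < 0):
        raise InvalidArgumentError("Qin must be >= 0")
    if np.any((phipsii < 0) | (phipsii > 1)):
        raise InvalidArgumentError("phiPSII must be in [0, 1]")
    out = tau * qin * phipsii
    return float(out) if np.ndim(out) == 0 else out
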