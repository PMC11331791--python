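"""Editable registries of physical, kinetic and isotopic constants.

All defaults live here rather than in the computational code so that a user
can swap a different temperature-response parameterization, solubility
function or fractionation set without touching any algorithm.  Registries
serialize to/from plain YAML key-value files.

Unit conventions used throughout the package:

* gas concentrations are mole fractions in dry air (μmol mol⁻¹ for CO₂,
  mmol mol⁻¹ for O₂) at a configurable total pressure (default 1 atm);
* fluxes and conductances are molar, per unit projected leaf area
  (μmol m⁻² s⁻¹ and mol m⁻² s⁻¹);
* temperatures enter in °C at API boundaries and are converted to Kelvin
  internally.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidArgumentError

R_GAS = 8.314462618  # J mol^-1 K^-1
T_REF_K = 298.15  # 25 degC reference for all Arrhenius scalings
ATM_PA = 101325.0


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


@dataclass
class SolubilityModel:
    """Van't Hoff Henry's-law solubilities for CO2 and O2 in water.

    ``kh(T) = kh298 * exp(c * (1/T - 1/298.15))`` with ``kh`` in M atm⁻¹.
    The CO2/O2 solubility ratio converts the liquid-phase Rubisco
    specificity to a gas mole-fraction basis, and the CO2 solubility also
    provides the dimensionless gas/liquid partition coefficient used by the
    anatomical conductance model.
    """

    kh298_co2: float = 0.034  # M atm^-1
    vanthoff_co2: float = 2400.0  # K
    kh298_o2: float = 0.0013  # M atm^-1
    vanthoff_o2: float = 1700.0  # K

    def kh_co2(self, tleaf_c: float) -> float:
        t = celsius_to_kelvin(tleaf_c)
        return self.kh298_co2 * math.exp(self.vanthoff_co2 * (1.0 / t - 1.0 / T_REF_K))

    def kh_o2(self, tleaf_c: float) -> float:
        t = celsius_to_kelvin(tleaf_c)
        return self.kh298_o2 * math.exp(self.vanthoff_o2 * (1.0 / t - 1.0 / T_REF_K))

    def ratio_co2_over_o2(self, tleaf_c: float) -> float:
        return self.kh_co2(tleaf_c) / self.kh_o2(tleaf_c)

    def henry_dimensionless_co2(self, tleaf_c: float) -> float:
        """C_aq / C_gas for CO2 (≈0.83 at 25 °C)."""
        t = celsius_to_kelvin(tleaf_c)
        # kh [mol L^-1 atm^-1] * R [L atm mol^-1 K^-1] * T
        return self.kh_co2(tleaf_c) * 0.0820573661 * t


@dataclass
class KineticConstants:
    """Rubisco kinetics and Arrhenius activation energies.

    Defaults are the Bernacchi-style mole-fraction values commonly used for
    C3 temperature scaling.  ``S_co`` is the liquid-phase Rubisco
    CO2/O2 specificity (M M⁻¹).
    """

    Kc25: float = 404.9  # umol mol^-1
    Ko25: float = 278.4  # mmol mol^-1
    GammaStar25: float = 42.75  # umol mol^-1 (21% O2; Arrhenius mode)
    Ea_Kc: float = 79430.0  # J mol^-1
    Ea_Ko: float = 36380.0
    Ea_GammaStar: float = 37830.0
    Ea_Vcmax: float = 65330.0
    Ea_J: float = 43540.0
    Ea_Rd: float = 46390.0
    Ea_Tp: float = 53100.0
    S_co: float = 97.3  # M M^-1, liquid-phase Rubisco specificity
    R: float = R_GAS
    gamma_star_mode: str = "specificity"  # "specificity" | "arrhenius"
    solubility: SolubilityModel = field(default_factory=SolubilityModel)

    def __post_init__(self) -> None:
        for name in ("Kc25", "Ko25", "GammaStar25", "S_co", "R"):
            if getattr(self, name) <= 0 or not math.isfinite(getattr(self, name)):
                raise InvalidArgumentError(f"{name} must be positive and finite")
        if self.gamma_star_mode not in ("specificity", "arrhenius"):
            raise InvalidArgumentError(
                "gamma_star_mode must be 'specificity' or 'arrhenius'"
            )


@dataclass
class FractionationParams:
    """Isotopic fractionation constants for the 13C discrimination model.

    All fractionations in per mil; ``R_std`` is the VPDB 13C/12C ratio.
    ``delta_substrate`` is the δ¹³C signature of the respiratory substrate
    (typically recent assimilate formed under growth conditions) and
    ``delta_measurement_co2`` that of the CO2 supplied during measurement;
    their offset drives the apparent respiratory fractionation e*.
    """

    a_b: float = 2.9  # boundary layer diffusion, per mil
    a: float = 4.4  # diffusion in air, per mil
    a_m: float = 1.8  # dissolution + diffusion in water, per mil
    b: float = 29.0  # Rubisco carboxylation (incl. PEPc contribution), per mil
    f: float = 11.0  # photorespiratory fractionation, per mil
    e: float = 0.0  # intrinsic day-respiratory fractionation, per mil
    delta_substrate: float = -28.0  # per mil vs VPDB
    delta_measurement_co2: float = -8.5  # per mil vs VPDB
    R_std: float = 0.0111797  # VPDB 13C/12C

    def __post_init__(self) -> None:
        if self.R_std <= 0:
            raise InvalidArgumentError("R_std must be positive")
        for f_ in dataclasses.fields(self):
            v = getattr(self, f_.name)
            if not math.isfinite(v):
                raise InvalidArgumentError(f"{f_.name} must be finite")


@dataclass
class PhysicalConstants:
    """Constants for the serial conductance (anatomy) model.

    CO2 diffusivities follow simple temperature power laws / Arrhenius forms
    anchored at 25 °C; the dimensionless Henry partition coefficient comes
    from the shared :class:`SolubilityModel`.
    """

    D_air_25: float = 1.59e-5  # m^2 s^-1, CO2 in air at 25 degC
    D_air_T_exponent: float = 1.75
    D_water_25: float = 1.92e-9  # m^2 s^-1, CO2 in water at 25 degC
    Ea_D_water: float = 16900.0  # J mol^-1
    P_mem: float = 3.5e-3  # m s^-1, single-membrane CO2 permeability
    gamma_mem: float = 1.0  # membrane conductance enhancement factor (>= 1)
    n_membranes: int = 2  # plasma membrane + chloroplast envelope in series
    ias_path_fraction: float = 0.5  # L_ias = fraction * T_mes
    pressure: float = ATM_PA  # Pa
    solubility: SolubilityModel = field(default_factory=SolubilityModel)

    def __post_init__(self) -> None:
        if self.gamma_mem < 1.0:
            raise InvalidArgumentError("gamma_mem must be >= 1")
        for name in ("D_air_25", "D_water_25", "P_mem", "pressure", "ias_path_fraction"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if self.n_membranes < 1:
            raise InvalidArgumentError("n_membranes must be >= 1")

    def d_air(self, tleaf_c: float) -> float:
        t = celsius_to_kelvin(tleaf_c)
        return self.D_air_25 * (t / T_REF_K) ** self.D_air_T_exponent

    def d_water(self, tleaf_c: float) -> float:
        t = celsius_to_kelvin(tleaf_c)
        return self.D_water_25 * math.exp(
            self.Ea_D_water * (t - T_REF_K) / (T_REF_K * R_GAS * t)
        )

    def molar_density(self, tleaf_c: float) -> float:
        """mol m⁻³ of gas at total pressure, converts m s⁻¹ to mol m⁻² s⁻¹."""
        return self.pressure / (R_GAS * celsius_to_kelvin(tleaf_c))

    def henry_dimensionless(self, tleaf_c: float) -> float:
        return self.solubility.henry_dimensionless_co2(tleaf_c)


@dataclass
class ConstantsRegistry:
    """Bundle of all constant sets, YAML-serializable."""

    kinetics: KineticConstants = field(default_factory=KineticConstants)
    fractionation: FractionationParams = field(default_factory=FractionationParams)
    physical: PhysicalConstants = field(default_factory=PhysicalConstants)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "ConstantsRegistry":
        def build(klass, sub: dict):
            sub = dict(sub or {})
            if "solubility" in sub and isinstance(sub["solubility"], dict):
                sub["solubility"] = SolubilityModel(**sub["solubility"])
            return klass(**sub)

        return cls(
            kinetics=build(KineticConstants, d.get("kinetics", {})),
            fractionation=build(FractionationParams, d.get("fractionation", {})),
            physical=build(PhysicalConstants, d.get("physical", {})),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ConstantsRegistry":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
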