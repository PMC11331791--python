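"""Anatomical traits, serial conductance partitioning and cell-wall porosity.

Mesophyll conductance is treated as three diffusive barriers in series on a
projected-leaf-area basis:

    1/gm = 1/g_ias + 1/g_cw + 1/g_mem

* intercellular airspace: gas-phase diffusion through the porous mesophyll,
  g_ias = (D_air · f_ias / L_ias) · ρ, with ρ = P/(R·T) mol m⁻³ converting
  a velocity to a molar conductance and L_ias the effective path length
  (default half the mesophyll thickness);
* cell wall: liquid-phase diffusion through the water-filled wall pores,
  g_cw = (p/τ) · D_water · H / T_cw · ρ · S_c — proportional to the
  effective porosity (porosity/tortuosity) and inversely to wall thickness,
  scaled from wall-area to leaf-area basis by S_c; H is the dimensionless
  gas/liquid partition coefficient of CO2;
* membranes: g_mem = γ · P_mem · H · ρ · S_c / n_membranes for n membranes
  (plasma membrane + chloroplast envelope) in series, with enhancement
  factor γ.

The single gas↔liquid conversion (H·ρ) lives in one helper so that basis
conventions cannot diverge between components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .constants import PhysicalConstants
from .errors import InvalidArgumentError, NonphysicalPartitionError

__all__ = [
    "AnatomySample",
    "ConductanceComponents",
    "surface_areas_from_micrograph",
    "wall_thickness",
    "airspace_conductance",
    "membrane_conductance",
    "wall_conductance_from_porosity",
    "compose_gm",
    "partition_conductances",
    "effective_porosity",
    "average_technical_replicates",
]


@dataclass
class AnatomySample:
    """Averaged anatomy for one biological replicate."""

    lmes_um: float  # mesophyll length exposed to IAS per section, um
    lc_um: float  # chloroplast length exposed to IAS, um
    w_um: float  # section width, um
    curvature_f: float  # curvature correction factor (required input)
    t_cw_nm: float  # cell wall thickness, nm
    t_mes_um: float  # mesophyll thickness, um
    f_ias: float  # fraction of intercellular airspace
    genotype: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.lc_um > self.lmes_um:
            raise InvalidArgumentError("Lc must not exceed Lmes")
        if not 0.0 <= self.f_ias < 1.0:
            raise InvalidArgumentError("f_ias must be in [0, 1)")


@dataclass
class ConductanceComponents:
    """Partitioned CO2 conductances (mol m⁻² s⁻¹, leaf-area basis)."""

    gm: float
    g_ias: float
    g_cw: float
    g_mem: float
    p_over_tau: float
    s_c: float
    plausible: bool = True

    def series_residual(self) -> float:
        """Relative error of the series identity 1/gm = Σ 1/g_i."""
        lhs = 1.0 / self.gm
        rhs = 1.0 / self.g_ias + 1.0 / self.g_cw + 1.0 / self.g_mem
        return abs(lhs - rhs) / lhs


def surface_areas_from_micrograph(
    lmes_um: float, lc_um: float, w_um: float, curvature_f: float
) -> dict:
    """Mesophyll and chloroplast surface area exposed to airspace per leaf area.

    From light-micrograph traces: S = (L / W) · F with F the curvature
    correction for the three-dimensional shape of cells seen in section.
    """
    if w_um <= 0:
        raise InvalidArgumentError("section width must be positive")
    if not 0.0 <= lc_um <= lmes_um:
        raise InvalidArgumentError("need 0 <= Lc <= Lmes")
    s_m = lmes_um / w_um * curvature_f
    s_c = lc_um / w_um * curvature_f
    return {"s_m": s_m, "s_c": s_c, "sc_over_sm": s_c / s_m if s_m > 0 else math.nan}


def wall_thickness(area_nm2: float, length_nm: float) -> float:
    """Cell-wall thickness (nm) as traced wall area divided by wall length."""
    if length_nm <= 0:
        raise InvalidArgumentError("wall length must be positive")
    return area_nm2 / length_nm


def average_technical_replicates(
    table: pd.DataFrame, by=("genotype", "replicate"), columns=None
) -> pd.DataFrame:
    """Average technical replicates to one row per biological replicate."""
    cols = list(columns) if columns is not None else [
        c for c in table.columns if c not in by and pd.api.types.is_numeric_dtype(table[c])
    ]
    return table.groupby(list(by), sort=True)[cols].mean().reset_index()


def _gas_liquid_factor(pc: PhysicalConstants, tleaf_c: float) -> float:
    """H·ρ — converts a liquid-phase velocity (m s⁻¹) referenced to the
    equilibrium gas mole fraction into mol m⁻² s⁻¹ per mole fraction."""
    return pc.henry_dimensionless(tleaf_c) * pc.molar_density(tleaf_c)


def airspace_conductance(
    f_ias: float, t_mes_um: float, pc: PhysicalConstants, tleaf_c: float = 25.0
) -> float:
    if f_ias <= 0 or t_mes_um <= 0:
        raise InvalidArgumentError("f_ias and T_mes must be positive")
    l_ias = pc.ias_path_fraction * t_mes_um * 1e-6  # m
    return pc.d_air(tleaf_c) * f_ias / l_ias * pc.molar_density(tleaf_c)


def membrane_conductance(
    s_c: float, pc: PhysicalConstants, tleaf_c: float = 25.0
) -> float:
    if s_c <= 0:
        raise InvalidArgumentError("S_c must be positive")
    return (
        pc.gamma_mem * pc.P_mem * _gas_liquid_factor(pc, tleaf_c) * s_c / pc.n_membranes
    )


def wall_conductance_from_porosity(
    p_over_tau: float, t_cw_nm: float, s_c: float,
    pc: PhysicalConstants, tleaf_c: float = 25.0,
) -> float:
    if min(p_over_tau, t_cw_nm, s_c) <= 0:
        raise InvalidArgumentError("p/tau, T_cw and S_c must be positive")
    return (
        p_over_tau * pc.d_water(tleaf_c) / (t_cw_nm * 1e-9)
        * _gas_liquid_factor(pc, tleaf_c) * s_c
    )


def compose_gm(g_ias: float, g_cw: float, g_mem: float) -> float:
    """Series combination of the three component conductances."""
    if min(g_ias, g_cw, g_mem) <= 0:
        raise InvalidArgumentError("component conductances must be positive")
    return 1.0 / (1.0 / g_ias + 1.0 / g_cw + 1.0 / g_mem)


def partition_conductances(
    gm: float,
    f_ias: float,
    t_cw_nm: float,
    t_mes_um: float,
    s_c: float,
    pc: PhysicalConstants | None = None,
    tleaf_c: float = 25.0,
) -> ConductanceComponents:
    """Partition measured gm into airspace, wall and membrane conductances.

    g_ias and g_mem follow from anatomy and the physical constants; the
    wall term is obtained by series subtraction
    1/g_cw = 1/gm − 1/g_ias − 1/g_mem, and effective porosity by inverting
    the wall-conductance model.  Raises
    :class:`NonphysicalPartitionError`, naming the binding component, when
    the subtraction leaves nothing for the wall.
    """
    pc = pc or PhysicalConstants()
    if gm <= 0:
        raise InvalidArgumentError("gm must be positive")
    g_ias = airspace_conductance(f_ias, t_mes_um, pc, tleaf_c)
    g_mem = membrane_conductance(s_c, pc, tleaf_c)
    inv_cw = 1.0 / gm - 1.0 / g_ias - 1.0 / g_mem
    if inv_cw <= 0:
        binding = "g_ias" if 1.0 / g_ias >= 1.0 / g_mem else "g_mem"
        raise NonphysicalPartitionError(
            f"series subtraction non-positive: gm={gm:.4g} exceeds what the "
            f"other barriers allow (binding component {binding})"
        )
    g_cw = 1.0 / inv_cw
    p_over_tau = effective_porosity(g_cw, t_cw_nm, s_c, pc, tleaf_c)
    return ConductanceComponents(
        gm=gm, g_ias=g_ias, g_cw=g_cw, g_mem=g_mem,
        p_over_tau=p_over_tau, s_c=s_c,
        plausible=0.0 < p_over_tau <= 1.0,
    )


def effective_porosity(
    g_cw: float, t_cw_nm: float, s_c: float,
    pc: PhysicalConstants | None = None, tleaf_c: float = 25.0,
) -> float:
    """Cell-wall effective porosity p/τ from the leaf-area wall conductance.

    p/τ = (g_cw / S_c) · T_cw / (D_water · H · ρ); strictly increasing in
    both g_cw and T_cw.  Values above 1 are physically implausible and are
    flagged by the caller.
    """
    pc = pc or PhysicalConstants()
    if min(g_cw, t_cw_nm, s_c) <= 0:
        raise InvalidArgumentError("g_cw, T_cw and S_c must be positive")
    return (
        g_cw / s_c * (t_cw_nm * 1e-9)
        / (pc.d_water(tleaf_c) * _gas_liquid_factor(pc, tleaf_c))
    )
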