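"""Top-level analysis pipeline chaining readers, fits/inversions and contrasts.

A pipeline run is configured by a plain dictionary (usually loaded from
YAML) with keys::

    mode: aci | variable-j | isotope | partition
    inputs:
      gasexchange: <path>        # aci / variable-j / isotope
      tdl: <path>                # isotope
      anatomy: <path>            # partition
      gm: <path>                 # partition (per-replicate gm table)
    constants: <yaml path>       # optional constants registry override
    contrast: {traits: [...], wt_label: WT}   # optional
    out: <directory>
    seed: <int>
    plots: true|false

Outputs are delimited-text tables plus a run log recording settings and
the package version; rerunning with identical inputs and seed reproduces
the tables byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anatomy import average_technical_replicates, partition_conductances, wall_thickness
from .constants import ConstantsRegistry
from .errors import ConfigurationError, NonphysicalPartitionError
from .fitting import FitConfig, fit_aci, fit_variable_j, gm_at_reference, value_at_reference
from .fvcb import arrhenius_scale, gamma_star
from .io import (
    fit_result_tables,
    pair_tdl_with_gasexchange,
    read_anatomy_table,
    read_gasexchange_log,
    read_tdl_log,
)
from .isotope import TankSet, gm_from_discrimination
from .stats import genotype_contrast

log = logging.getLogger("leafgm")

_CSV_KW = dict(index=False, float_format="%.12g")


def run_full_pipeline(config: dict) -> pd.DataFrame:
    """Run one analysis mode end to end; returns the cohort result table."""
    mode = config.get("mode")
    if mode not in ("aci", "variable-j", "isotope", "partition"):
        raise ConfigurationError(f"unknown or missing mode: {mode!r}")
    out = Path(config.get("out", "."))
    out.mkdir(parents=True, exist_ok=True)
    constants = (
        ConstantsRegistry.load(config["constants"])
        if config.get("constants")
        else ConstantsRegistry()
    )
    if mode in ("aci", "variable-j"):
        table = _run_curve_fits(config, constants, out, variable_j=(mode == "variable-j"))
    elif mode == "isotope":
        table = _run_isotope(config, constants, out)
    else:
        table = _run_partition(config, constants, out)

    table.to_csv(out / "results.csv", **_CSV_KW)
    contrast_cfg = config.get("contrast")
    if contrast_cfg:
        rows = []
        for trait in contrast_cfg.get("traits", []):
            res = genotype_contrast(
                table, trait, wt_label=contrast_cfg.get("wt_label", "WT")
            )
            t = res.table.assign(trait=trait, average_pct_change=res.average_pct_change)
            rows.append(t)
        pd.concat(rows).to_csv(out / "contrasts.csv", **_CSV_KW)
    (out / "run_log.json").write_text(
        json.dumps({"version": __version__, "config": _jsonable(config)}, indent=2)
    )
    return table


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _run_curve_fits(config, constants, out, variable_j):
    path = (config.get("inputs") or {}).get("gasexchange")
    if not path:
        raise ConfigurationError("mode requires inputs.gasexchange")
    curves = read_gasexchange_log(path)
    if not curves:
        raise ConfigurationError("no usable curves in input")
    fit_config = FitConfig(seed=int(config.get("seed", 0)), **(config.get("fit") or {}))
    fits = []
    rows = []
    for curve in curves:
        fit = (fit_variable_j if variable_j else fit_aci)(curve, constants.kinetics, fit_config)
        fits.append(fit)
        row = {
            "plant_id": curve.plant_id, "genotype": curve.genotype,
            "Vcmax25": fit.params.Vcmax25, "J25": fit.params.J25,
            "Rd25": fit.params.Rd25, "Tp25": fit.params.Tp25,
            "flags": ";".join(fit.flags),
        }
        if curve.co2_r is not None:
            row["A_400"] = value_at_reference(curve.co2_r, curve.a)
            row["gsw_400"] = value_at_reference(curve.co2_r, curve.gsw)
            row["iwue_400"] = row["A_400"] / row["gsw_400"]
        if variable_j:
            row["tau"] = fit.params.tau
            try:
                row["gm_400"] = gm_at_reference(fit)
            except Exception:
                row["gm_400"] = np.nan
        rows.append(row)
    params_tbl, points_tbl = fit_result_tables(fits)
    params_tbl.to_csv(out / "fit_parameters.csv", **_CSV_KW)
    points_tbl.to_csv(out / "fit_points.csv", **_CSV_KW)
    if config.get("plots"):
        _plot_fits(fits, out)
    return pd.DataFrame(rows)


def _run_isotope(config, constants, out):
    inputs = config.get("inputs") or {}
    if not inputs.get("tdl") or not inputs.get("gasexchange"):
        raise ConfigurationError("isotope mode requires inputs.tdl and inputs.gasexchange")
    cycles = read_tdl_log(inputs["tdl"])
    if not cycles:
        raise ConfigurationError("no complete TDL cycles in input")
    gasex = pd.read_csv(inputs["gasexchange"], sep=None, engine="python")
    tanks = TankSet(**(config.get("tanks") or {}))
    points = pair_tdl_with_gasexchange(
        cycles, gasex, tanks, window_s=float(config.get("pairing_window_s", 90.0))
    )
    kin = constants.kinetics
    rd25 = float(config.get("rd25", 1.0))  # post-program dark measurement
    o2 = float(config.get("o2", 20.0))
    rows = []
    for p in points:
        p.o2 = o2
        gstar = gamma_star(o2, p.tleaf_c, kin)
        rd = arrhenius_scale(rd25, kin.Ea_Rd, p.tleaf_c)
        res = gm_from_discrimination(p, constants.fractionation, gstar, rd)
        rows.append({
            "chamber": p.chamber, "A": p.a, "Ci": p.ci, "Ca": p.ca,
            "gsw": p.gsw, **{k: res[k] for k in (
                "delta_obs", "xi", "t", "delta_i", "e_star", "gm", "cc",
                "drawdown", "gm_over_gsw", "iwue", "nonphysical")},
        })
    tbl = pd.DataFrame(rows)
    tbl.to_csv(out / "isotope_points.csv", **_CSV_KW)
    summary = (
        tbl[~tbl["nonphysical"]]
        .groupby("chamber")[["gm", "cc", "drawdown", "gm_over_gsw", "iwue", "A", "gsw"]]
        .median()
        .reset_index()
    )
    return summary


def _run_partition(config, constants, out):
    inputs = config.get("inputs") or {}
    if not inputs.get("anatomy") or not inputs.get("gm"):
        raise ConfigurationError("partition mode requires inputs.anatomy and inputs.gm")
    anat = read_anatomy_table(inputs["anatomy"])
    if "Tcw_nm" not in anat.columns and {"wall_area_nm2", "wall_length_nm"} <= set(anat.columns):
        anat = anat.assign(
            Tcw_nm=[wall_thickness(a, l) for a, l in zip(anat["wall_area_nm2"], anat["wall_length_nm"])]
        )
    bio = average_technical_replicates(anat)
    if {"Lc_um", "W_um", "F"} <= set(bio.columns):
        bio = bio.assign(S_c=bio["Lc_um"] / bio["W_um"] * bio["F"])
    gm_tbl = pd.read_csv(inputs["gm"], sep=None, engine="python")
    merged = bio.merge(
        gm_tbl[["genotype", "replicate", "gm"] + (["Tleaf"] if "Tleaf" in gm_tbl else [])],
        on=["genotype", "replicate"],
    )
    rows = []
    for _, r in merged.iterrows():
        tleaf = float(r.get("Tleaf", 25.0))
        try:
            comp = partition_conductances(
                gm=float(r["gm"]), f_ias=float(r["f_ias"]),
                t_cw_nm=float(r["Tcw_nm"]), t_mes_um=float(r["Tmes_um"]),
                s_c=float(r["S_c"]), pc=constants.physical, tleaf_c=tleaf,
            )
            rows.append({
                "genotype": r["genotype"], "replicate": r["replicate"],
                "gm": comp.gm, "g_ias": comp.g_ias, "g_cw": comp.g_cw,
                "g_mem": comp.g_mem, "p_over_tau": comp.p_over_tau,
                "plausible": comp.plausible,
            })
        except NonphysicalPartitionError as exc:
            log.warning("partition failed for %s/%s: %s", r["genotype"], r["replicate"], exc)
    tbl = pd.DataFrame(rows)
    tbl.to_csv(out / "partition_components.csv", **_CSV_KW)
    per_geno = tbl.groupby("genotype")[["gm", "g_ias", "g_cw", "g_mem", "p_over_tau"]].mean().reset_index()
    per_geno.to_csv(out / "partition_by_genotype.csv", **_CSV_KW)
    return tbl


def _plot_fits(fits, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for fit in fits:
        c = fit.curve
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(c.ci, c.a, "o", label="measured")
        order = np.argsort(c.ci)
        ax.plot(c.ci[order], (c.a - fit.residuals)[order], "-", label="modelled")
        ax.set_xlabel("Ci (umol mol$^{-1}$)")
        ax.set_ylabel("A (umol m$^{-2}$ s$^{-1}$)")
        ax.set_title(f"{c.plant_id} {c.genotype}".strip())
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / f"fit_{c.plant_id}.png", dpi=100)
        plt.close(fig)
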