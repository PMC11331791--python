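"""Readers and writers for the three tabular input classes.

All formats are delimited text (comma or tab, sniffed) with one header row.
Vendor column names are normalized through an alias map that can be
extended via configuration.  Malformed rows are dropped with a logged
count, never silently.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import MalformedCycleError, SchemaError
from .fitting import FitResult, ResponseCurve
from .isotope import STREAM_SEQUENCE, PairedPoint, TDLCycle, calibrate_tdl_cycle

log = logging.getLogger("leafgm")

#: default vendor-name → canonical-name map for gas-exchange logs
GASEX_ALIASES = {
    "A": "A", "Photo": "A", "a": "A",
    "Ci": "Ci", "ci": "Ci",
    "Ca": "Ca", "CO2S": "Ca",
    "gsw": "gsw", "Cond": "gsw", "GSW": "gsw",
    "E": "E", "Trmmol": "E",
    "Qin": "Qin", "PARi": "Qin", "Q": "Qin",
    "Tleaf": "Tleaf", "TleafC": "Tleaf",
    "PhiPS2": "PhiPS2", "PhiPSII": "PhiPS2", "phiPSII": "PhiPS2",
    "CO2_r": "CO2_r", "CO2R": "CO2_r",
    "time": "time", "TIME": "time", "elapsed": "time",
    "plant_id": "plant_id", "plant": "plant_id", "curve_id": "plant_id",
    "genotype": "genotype", "chamber": "chamber",
    "O2": "O2", "Oxygen": "O2",
}

GASEX_MANDATORY = ("A", "Ci", "Ca", "gsw", "Qin", "Tleaf")

TDL_ALIASES = {
    "time": "time", "timestamp": "time", "TIMESTAMP": "time",
    "valve": "valve", "site": "valve",
    "c12_raw": "c12_raw", "Conc12C": "c12_raw",
    "c13_raw": "c13_raw", "Conc13C": "c13_raw",
}


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", comment="#")


def _normalize(df: pd.DataFrame, aliases: dict) -> pd.DataFrame:
    return df.rename(columns={c: aliases[c] for c in df.columns if c in aliases})


def read_gasexchange_log(path, aliases: dict | None = None) -> list[ResponseCurve]:
    """Read a gas-exchange log into one :class:`ResponseCurve` per plant/curve.

    Rows with non-numeric values in any mandatory column are dropped with a
    logged count.  A missing mandatory column raises :class:`SchemaError`
    naming the column.
    """
    df = _normalize(_read_table(path), {**GASEX_ALIASES, **(aliases or {})})
    for col in GASEX_MANDATORY:
        if col not in df.columns:
            raise SchemaError(f"gas-exchange log missing mandatory column '{col}'")
    numeric_cols = [c for c in df.columns if c not in ("plant_id", "genotype")]
    for c in numeric_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    bad = df[list(GASEX_MANDATORY)].isna().any(axis=1)
    if bad.any():
        log.warning("%s: dropped %d malformed row(s)", path, int(bad.sum()))
        df = df[~bad]
    if "plant_id" not in df.columns:
        df = df.assign(plant_id="curve-1")
    curves = []
    for pid, grp in df.groupby("plant_id", sort=False):
        curves.append(
            ResponseCurve(
                a=grp["A"], ci=grp["Ci"], ca=grp["Ca"], gsw=grp["gsw"],
                qin=grp["Qin"], tleaf_c=grp["Tleaf"],
                phipsii=grp["PhiPS2"] if "PhiPS2" in grp else None,
                co2_r=grp["CO2_r"] if "CO2_r" in grp else None,
                e=grp["E"] if "E" in grp else None,
                o2=float(grp["O2"].iloc[0]) if "O2" in grp else 210.0,
                time=grp["time"] if "time" in grp else None,
                plant_id=str(pid),
                genotype=str(grp["genotype"].iloc[0]) if "genotype" in grp else "",
            )
        )
    return curves


def write_gasexchange_log(curves, path) -> None:
    rows = []
    for c in curves:
        for i in range(len(c)):
            rows.append({
                "plant_id": c.plant_id, "genotype": c.genotype,
                "A": c.a[i], "Ci": c.ci[i], "Ca": c.ca[i], "gsw": c.gsw[i],
                "E": c.e[i] if c.e is not None else np.nan,
                "Qin": c.qin[i], "Tleaf": c.tleaf_c[i],
                "PhiPS2": c.phipsii[i] if c.phipsii is not None else np.nan,
                "CO2_r": c.co2_r[i] if c.co2_r is not None else np.nan,
                "O2": c.o2,
                "time": c.time[i] if c.time is not None else np.nan,
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_tdl_log(path, aliases: dict | None = None, strict: bool = False) -> list[TDLCycle]:
    """Group TDL rows into complete nine-stream cycles.

    Rows must carry valve ids 1..9 in sequence order.  An out-of-sequence
    or incomplete cycle raises :class:`MalformedCycleError` (``strict``) or
    is discarded with a logged warning (default); the incomplete trailing
    cycle is always discarded.
    """
    df = _normalize(_read_table(path), {**TDL_ALIASES, **(aliases or {})})
    for col in ("time", "valve", "c12_raw", "c13_raw"):
        if col not in df.columns:
            raise SchemaError(f"TDL log missing mandatory column '{col}'")
    cycles = []
    buf = []
    n_dropped = 0
    idx = 0
    for _, row in df.iterrows():
        v = int(row["valve"])
        expected = len(buf) + 1
        if v != expected:
            if buf:
                idx += 1
                if strict:
                    raise MalformedCycleError(
                        f"cycle {idx}: valve {v} where {expected} expected"
                    )
                n_dropped += 1
                buf = []
            if v != 1:
                continue
        buf.append(row)
        if len(buf) == 9:
            idx += 1
            cycles.append(
                TDLCycle(
                    c12_raw={s: float(r["c12_raw"]) for s, r in zip(STREAM_SEQUENCE, buf)},
                    c13_raw={s: float(r["c13_raw"]) for s, r in zip(STREAM_SEQUENCE, buf)},
                    timestamps={s: float(r["time"]) for s, r in zip(STREAM_SEQUENCE, buf)},
                    index=idx,
                )
            )
            buf = []
    if buf:
        n_dropped += 1
    if n_dropped:
        log.warning("%s: discarded %d incomplete/malformed cycle(s)", path, n_dropped)
    return cycles


def read_anatomy_table(path) -> pd.DataFrame:
    """Anatomy measurement table, one row per technical replicate."""
    df = _read_table(path)
    for col in ("genotype", "replicate"):
        if col not in df.columns:
            raise SchemaError(f"anatomy table missing mandatory column '{col}'")
    return df


def pair_tdl_with_gasexchange(
    cycles, gasex: pd.DataFrame, tanks, window_s: float = 90.0, gbw: float = np.inf
) -> list[PairedPoint]:
    """Calibrate each cycle and match chamber streams to log entries.

    Each chamber's calibrated in/out pair is matched to the gas-exchange
    row of the same chamber whose timestamp is nearest the sample-stream
    time, within ``window_s``; unmatched cycles are skipped with a log
    entry.
    """
    points = []
    n_unmatched = 0
    for cyc in cycles:
        _, streams = calibrate_tdl_cycle(cyc, tanks)
        for ch in (1, 2):
            ref, samp = streams.get(f"ref_{ch}"), streams.get(f"sample_{ch}")
            t_s = cyc.timestamps[f"sample_{ch}"]
            rows = gasex[gasex["chamber"] == ch] if "chamber" in gasex else gasex
            if not len(rows):
                continue
            gaps = (rows["time"] - t_s).abs()
            i = gaps.idxmin()
            if gaps.loc[i] > window_s:
                n_unmatched += 1
                continue
            r = rows.loc[i]
            points.append(
                PairedPoint(
                    c12_in=ref[0], c13_in=ref[1], c12_out=samp[0], c13_out=samp[1],
                    a=float(r["A"]), gsw=float(r["gsw"]), e=float(r["E"]),
                    ci=float(r["Ci"]), ca=float(r["Ca"]),
                    tleaf_c=float(r["Tleaf"]), chamber=ch,
                    time_gap_s=float(gaps.loc[i]), gbw=gbw,
                )
            )
    if n_unmatched:
        log.warning("pairing: %d chamber stream(s) had no log entry in window", n_unmatched)
    return points


def fit_result_tables(fits: list[FitResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parameter table (one row per curve) and per-point diagnostic table."""
    prows, pprows = [], []
    for fit in fits:
        c = fit.curve
        row = {"plant_id": c.plant_id, "genotype": c.genotype,
               "objective": fit.objective, "n_singular": fit.n_singular,
               "flags": ";".join(fit.flags)}
        for name in fit.param_names:
            row[name] = getattr(fit.params, name, getattr(fit, name, np.nan))
            row[f"{name}_se"] = fit.stderr.get(name, np.nan)
        prows.append(row)
        for i in range(len(c)):
            pprows.append({
                "plant_id": c.plant_id, "point": i,
                "CO2_r": c.co2_r[i] if c.co2_r is not None else np.nan,
                "Ci": c.ci[i], "A": c.a[i], "Cc": fit.cc[i], "gm": fit.gm[i],
                "limiting": fit.limiting_process[i],
                "residual": fit.residuals[i],
            })
    return pd.DataFrame(prows), pd.DataFrame(pprows)
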