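"""Plate-reader BRET processing.

Two corrections are implemented: the double-baseline correction for kinetic
ligand-stimulation traces (per-well pre-stimulation baseline, then the
time-matched mean vehicle trace), and the donor-only background correction
yielding net BRET against net acceptor fluorescence for titration series.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DataError

KINETIC_COLUMNS = ["well", "condition", "time_s", "bret_ratio"]
TITRATION_COLUMNS = ["well", "condition", "fluorescence", "bret_ratio"]


def delta_bret(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Double-baseline-corrected Delta-BRET kinetics.

    Expects a tidy table (well, condition, time_s, bret_ratio) with
    pre-stimulation reads at ``time_s < 0`` and vehicle wells labelled
    ``"vehicle"``. Each well is corrected by its own mean pre-stimulation
    ratio, then by the per-time-point mean of the baseline-corrected vehicle
    wells. Returns (per-well Delta-BRET table, per-time summary with n and
    SEM over stimulated wells).
    """
    missing = [c for c in KINETIC_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"kinetic table missing columns: {missing}")
    df = table.copy()
    pre = df[df["time_s"] < 0]
    if pre.empty:
        raise DataError("no pre-stimulation reads (time_s < 0) in the table")
    baselines = pre.groupby("well")["bret_ratio"].mean()
    if not set(df["well"]) <= set(baselines.index):
        raise DataError("some wells have no pre-stimulation reads")
    df["corrected"] = df["bret_ratio"] - df["well"].map(baselines)
    vehicle = df[df["condition"] == "vehicle"]
    if vehicle.empty:
        raise DataError("no vehicle wells on the plate; cannot double-baseline correct")
    vehicle_trace = vehicle.groupby("time_s")["corrected"].mean()
    df["delta_bret"] = df["corrected"] - df["time_s"].map(vehicle_trace)
    stim = df[df["condition"] != "vehicle"]
    summary = (
        stim.groupby(["condition", "time_s"])["delta_bret"]
        .agg(mean="mean", n="count", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0)
        .reset_index()
    )
    out = df[["well", "condition", "time_s", "delta_bret"]].copy()
    return out, summary


def net_bret(titration: pd.DataFrame, donor_only_label: str = "donor_only") -> pd.DataFrame:
    """Net BRET vs net acceptor fluorescence from an acceptor titration.

    Subtracts the mean donor-only fluorescence (background fluorescence) from
    all fluorescence readings and the mean donor-only BRET ratio (background
    BRET at 0% acceptor expression) from all ratios.
    """
    missing = [c for c in TITRATION_COLUMNS if c not in titration.columns]
    if missing:
        raise DataError(f"titration table missing columns: {missing}")
    donor_only = titration[titration["condition"] == donor_only_label]
    if donor_only.empty:
        raise DataError("no donor-only wells (0% acceptor) in the titration")
    bg_fluor = donor_only["fluorescence"].mean()
    bg_bret = donor_only["bret_ratio"].mean()
    out = titration.copy()
    out["net_fluorescence"] = out["fluorescence"] - bg_fluor
    out["net_bret"] = out["bret_ratio"] - bg_bret
    return out


def fit_saturation(net_fluorescence: np.ndarray, net_bret_values: np.ndarray) -> tuple[float, float]:
    """Fit ``net_bret = bmax * x / (k + x)``; returns (bmax, k)."""
    x = np.asarray(net_fluorescence, dtype=float)
    y = np.asarray(net_bret_values, dtype=float)
    keep = x > 0
    if keep.sum() < 3:
        raise DataError("need >= 3 positive-acceptor points to fit a saturation curve")
    x, y = x[keep], y[keep]
    p0 = (float(np.max(y)), float(np.median(x)))
    popt, _ = curve_fit(lambda xx, bmax, k: bmax * xx / (k + xx), x, y, p0=p0, maxfev=10000)
    return float(popt[0]), float(popt[1])
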