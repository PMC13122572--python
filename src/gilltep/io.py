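"""CSV readers and writers for the package's three table schemas.

All files are plain UTF-8 CSV with a header row and "." decimal separator.
Units are embedded in the column names to prevent silent unit drift:
potentials in mV, water ions in umol/L, flux-water sodium in umol/L
(converted to nmol/L internally), masses in g, volumes in L, times in h.

Schemas
-------
water:  name, pH, DOC_mg_L, DIC_mg_L, Na_umol_L, Ca_umol_L, K_umol_L,
        Mg_umol_L, Cl_umol_L, NH4_umol_L, conductivity_uS_cm, temp_C
flux:   fish_id, temp_C, mass_g, volume_L, t0_h, tf_h, R0_cpm_per_L,
        Rf_cpm_per_L, Na0_umol_per_L, Naf_umol_per_L
tep:    fish_id, series, condition, order, rep1_mV, rep2_mV, rep3_mV,
        junction_mV
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .experiment_stats import TEPMeasurement, TEPSeries
from .tracer_flux import FluxExperimentRecord, FluxRates
from .water_chem import WaterComposition

WATER_COLUMNS = [
    "name", "pH", "DOC_mg_L", "DIC_mg_L", "Na_umol_L", "Ca_umol_L", "K_umol_L",
    "Mg_umol_L", "Cl_umol_L", "NH4_umol_L", "conductivity_uS_cm", "temp_C",
]
FLUX_COLUMNS = [
    "fish_id", "temp_C", "mass_g", "volume_L", "t0_h", "tf_h",
    "R0_cpm_per_L", "Rf_cpm_per_L", "Na0_umol_per_L", "Naf_umol_per_L",
]
TEP_COLUMNS = [
    "fish_id", "series", "condition", "order",
    "rep1_mV", "rep2_mV", "rep3_mV", "junction_mV",
]

_ION_COLUMNS = {"Na": "Na_umol_L", "Ca": "Ca_umol_L", "K": "K_umol_L",
                "Mg": "Mg_umol_L", "Cl": "Cl_umol_L", "NH4": "NH4_umol_L"}


def packaged_data(filename: str) -> Path:
    """Path to a data file shipped inside the package."""
    return Path(str(importlib.resources.files("gilltep").joinpath("data", filename)))


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path: object) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing required columns {missing}")


def read_water_csv(path) -> dict[str, WaterComposition]:
    """Read a water-chemistry table into name -> WaterComposition."""
    frame = pd.read_csv(path)
    _require_columns(frame, ["name", "pH"], path)
    waters: dict[str, WaterComposition] = {}
    for _, row in frame.iterrows():
        ions = {}
        for ion, col in _ION_COLUMNS.items():
            if col in frame.columns and pd.notna(row[col]):
                ions[ion] = float(row[col])
        cond = row.get("conductivity_uS_cm")
        waters[str(row["name"])] = WaterComposition(
            name=str(row["name"]),
            ph=float(row["pH"]),
            doc_mg_l=float(row.get("DOC_mg_L", 0.0) or 0.0),
            dic_mg_l=float(row.get("DIC_mg_L", 0.0) or 0.0),
            ions=ions,
            conductivity_us_cm=float(cond) if pd.notna(cond) else None,
            temperature=float(row.get("temp_C", 27.0)),
        )
    return waters


def write_water_csv(waters: Iterable[WaterComposition], path) -> None:
    rows = []
    for w in waters:
        row = {
            "name": w.name, "pH": w.ph, "DOC_mg_L": w.doc_mg_l, "DIC_mg_L": w.dic_mg_l,
            "conductivity_uS_cm": w.conductivity_us_cm, "temp_C": w.temperature,
        }
        for ion, col in _ION_COLUMNS.items():
            row[col] = w.ions.get(ion, np.nan)  # absent ion -> empty cell
        rows.append(row)
    pd.DataFrame(rows, columns=WATER_COLUMNS).to_csv(path, index=False)


def read_flux_csv(path) -> list[FluxExperimentRecord]:
    """Read a flux-experiment table; water [Na] columns are umol/L on disk."""
    frame = pd.read_csv(path)
    _require_columns(frame, FLUX_COLUMNS, path)
    records = []
    for idx, row in frame.iterrows():
        try:
            records.append(
                FluxExperimentRecord(
                    fish_id=str(row["fish_id"]),
                    mass=float(row["mass_g"]),
                    volume=float(row["volume_L"]),
                    duration=float(row["tf_h"]) - float(row["t0_h"]),
                    r_initial=float(row["R0_cpm_per_L"]),
                    r_final=float(row["Rf_cpm_per_L"]),
                    na_initial=float(row["Na0_umol_per_L"]) * 1000.0,
                    na_final=float(row["Naf_umol_per_L"]) * 1000.0,
                    temperature=float(row["temp_C"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise InvalidInputError(f"{path}: row {idx + 2}: {exc}") from exc
    return records


def write_flux_csv(records: Iterable[FluxExperimentRecord], path) -> None:
    rows = [
        {
            "fish_id": r.fish_id, "temp_C": r.temperature, "mass_g": r.mass,
            "volume_L": r.volume, "t0_h": 0.0, "tf_h": r.duration,
            "R0_cpm_per_L": r.r_initial, "Rf_cpm_per_L": r.r_final,
            "Na0_umol_per_L": r.na_initial / 1000.0, "Naf_umol_per_L": r.na_final / 1000.0,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=FLUX_COLUMNS).to_csv(path, index=False)


def flux_results_frame(
    records: Sequence[FluxExperimentRecord], rates: Sequence[FluxRates]
) -> pd.DataFrame:
    """Per-fish flux rates plus a group mean +/- SEM summary row block."""
    rows = [
        {
            "fish_id": rec.fish_id, "temp_C": rec.temperature,
            "J_in_nmol_g_h": rt.j_in, "J_out_nmol_g_h": rt.j_out, "J_net_nmol_g_h": rt.j_net,
        }
        for rec, rt in zip(records, rates)
    ]
    frame = pd.DataFrame(rows)
    summary_rows = []
    for stat in ("mean", "sem"):
        row = {"fish_id": stat, "temp_C": np.nan}
        for col in ("J_in_nmol_g_h", "J_out_nmol_g_h", "J_net_nmol_g_h"):
            vals = frame[col].to_numpy()
            if stat == "mean":
                row[col] = float(vals.mean())
            else:
                row[col] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        summary_rows.append(row)
    return pd.concat([frame, pd.DataFrame(summary_rows)], ignore_index=True)


def read_tep_csv(path) -> TEPSeries:
    """Read a triplicate TEP table into a TEPSeries."""
    frame = pd.read_csv(path)
    _require_columns(frame, TEP_COLUMNS, path)
    measurements = []
    for idx, row in frame.iterrows():
        try:
            measurements.append(
                TEPMeasurement(
                    fish_id=str(row["fish_id"]),
                    series=str(row["series"]),
                    condition=str(row["condition"]),
                    replicates=(float(row["rep1_mV"]), float(row["rep2_mV"]), float(row["rep3_mV"])),
                    junction_offset=float(row["junction_mV"]),
                    order_index=int(row["order"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise InvalidInputError(f"{path}: row {idx + 2}: {exc}") from exc
    n_conditions = len({m.condition for m in measurements})
    design = "paired" if n_conditions == 2 else "repeated"
    return TEPSeries(measurements=tuple(measurements), design=design)


def write_tep_csv(series: TEPSeries, path) -> None:
    rows = [
        {
            "fish_id": m.fish_id, "series": m.series, "condition": m.condition,
            "order": m.order_index, "rep1_mV": m.replicates[0], "rep2_mV": m.replicates[1],
            "rep3_mV": m.replicates[2], "junction_mV": m.junction_offset,
        }
        for m in series.measurements
    ]
    pd.DataFrame(rows, columns=TEP_COLUMNS).to_csv(path, index=False)


def condition_summary_frame(series: TEPSeries, letters: dict[str, str] | None = None) -> pd.DataFrame:
    """Tidy per-condition summary: condition, mean_mV, sem_mV, n, letter."""
    frame = series.to_frame()
    grouped = frame.groupby("condition")["tep_mV"]
    out = pd.DataFrame(
        {
            "condition": grouped.mean().index,
            "mean_mV": grouped.mean().to_numpy(),
            "sem_mV": grouped.sem().to_numpy(),
            "n": grouped.count().to_numpy(),
        }
    )
    out["letter"] = [letters.get(c, "") if letters else "" for c in out["condition"]]
    return out.sort_values("mean_mV").reset_index(drop=True)
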