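"""Dataset schema, CSV readers/writers, and feature extraction.

There is no standard interchange format for a wrist heat/PPG sensor bundle,
so the project defines a plain CSV schema with the measurement unit embedded
in every column name — the cheapest defence against the two unit mistakes
that silently destroy this model (kelvin vs Celsius, fraction vs percent
humidity):

    record_id, subject_id, timepoint_label,
    Tr_K, tw_C, ts_C, He_frac, BF_pu,
    ppg_file | (HR_bpm, SpO2_pct),
    BG_ref_mmolL            (optional)

Each row must either point at a two-channel PPG sidecar CSV (columns
``red,ir`` preceded by a ``# Fs=<Hz>`` comment line) or carry precomputed
vitals.  Rows failing validation are reported with their row numbers, never
silently dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import EnergyConstants, DEFAULT_CONSTANTS, SensorFrame, metabolic_heat
from .ppg import AbsorptionCoefficients, DEFAULT_COEFFICIENTS, PPGWaveform, vitals_from_waveform

__all__ = [
    "SchemaError",
    "DatasetTable",
    "MANDATORY_COLUMNS",
    "read_dataset",
    "write_dataset",
    "read_ppg_csv",
    "write_ppg_csv",
    "extract_features",
    "write_cohort",
]


class SchemaError(ValueError):
    """Dataset does not match the project CSV schema."""


MANDATORY_COLUMNS = (
    "record_id",
    "subject_id",
    "timepoint_label",
    "Tr_K",
    "tw_C",
    "ts_C",
    "He_frac",
    "BF_pu",
)
VITALS_COLUMNS = ("HR_bpm", "SpO2_pct")
OPTIONAL_COLUMNS = ("ppg_file", "HR_bpm", "SpO2_pct", "BG_ref_mmolL")


@dataclass
class DatasetTable:
    """A validated dataset: the table plus per-row validation findings."""

    df: pd.DataFrame
    path: Path | None = None
    row_errors: list[tuple[int, str]] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def valid_rows(self) -> pd.DataFrame:
        bad = {i for i, _ in self.row_errors}
        return self.df.loc[[i for i in self.df.index if i not in bad]]


def _validate_rows(df: pd.DataFrame) -> list[tuple[int, str]]:
    errors: list[tuple[int, str]] = []
    has_vitals = all(c in df.columns for c in VITALS_COLUMNS)
    has_ppg = "ppg_file" in df.columns
    for i, row in df.iterrows():
        try:
            SensorFrame(
                Tr=float(row["Tr_K"]),
                tw=float(row["tw_C"]),
                ts=float(row["ts_C"]),
                He=float(row["He_frac"]),
                BF=float(row["BF_pu"]),
            )
        except (ValueError, TypeError) as exc:
            errors.append((i, f"sensor frame invalid: {exc}"))
            continue
        row_has_vitals = has_vitals and np.isfinite(
            [row["HR_bpm"], row["SpO2_pct"]]
        ).all()
        row_has_ppg = has_ppg and isinstance(row.get("ppg_file"), str) and row["ppg_file"]
        if not (row_has_vitals or row_has_ppg):
            errors.append((i, "row carries neither a ppg_file nor HR_bpm+SpO2_pct"))
    return errors


def read_dataset(path) -> DatasetTable:
    """Read and validate a dataset CSV.

    Raises :class:`SchemaError` when a mandatory column is missing; row-level
    physical-validation failures are collected on the returned table (with
    row indices) rather than dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"dataset {path} missing mandatory column(s): {', '.join(missing)}")
    if "ppg_file" not in df.columns and not all(c in df.columns for c in VITALS_COLUMNS):
        raise SchemaError(
            "dataset needs either a ppg_file column or both HR_bpm and SpO2_pct"
        )
    return DatasetTable(df=df, path=path, row_errors=_validate_rows(df))


def write_dataset(df: pd.DataFrame, path) -> None:
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"refusing to write dataset missing column(s): {', '.join(missing)}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_ppg_csv(waveform: PPGWaveform, path) -> None:
    """Write a two-channel waveform with its sampling rate in a comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# Fs={waveform.Fs:g}\n")
        pd.DataFrame({"red": waveform.red, "ir": waveform.ir}).to_csv(fh, index=False)


def read_ppg_csv(path) -> PPGWaveform:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# Fs="):
            raise SchemaError(f"PPG file {path} lacks the '# Fs=<Hz>' header line")
        Fs = float(first.split("=", 1)[1])
        df = pd.read_csv(fh)
    if not {"red", "ir"} <= set(df.columns):
        raise SchemaError(f"PPG file {path} must have 'red' and 'ir' columns")
    return PPGWaveform(red=df["red"].to_numpy(), ir=df["ir"].to_numpy(), Fs=Fs)


def extract_features(
    table: DatasetTable,
    constants: EnergyConstants = DEFAULT_CONSTANTS,
    coefficients: AbsorptionCoefficients = DEFAULT_COEFFICIENTS,
    strict: bool = False,
) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Per-row predictor extraction: H from the energy balance, HR/SpO2 from
    PPG (or passed through when precomputed), BF copied.

    Returns ``(features, errors)`` where ``errors`` lists (row index,
    message) for rows that could not be processed; with ``strict=True`` the
    first failure aborts instead.  An empty table yields an empty frame.
    """
    base = table.path.parent if table.path is not None else Path(".")
    errors: list[tuple[int, str]] = list(table.row_errors)
    if strict and errors:
        i, msg = errors[0]
        raise ValueError(f"row {i}: {msg}")
    rows = []
    for i, row in table.valid_rows.iterrows():
        try:
            frame = SensorFrame(
                Tr=float(row["Tr_K"]),
                tw=float(row["tw_C"]),
                ts=float(row["ts_C"]),
                He=float(row["He_frac"]),
                BF=float(row["BF_pu"]),
            )
            H = metabolic_heat(frame, constants).H
            if (
                "HR_bpm" in row.index
                and "SpO2_pct" in row.index
                and np.isfinite([row["HR_bpm"], row["SpO2_pct"]]).all()
            ):
                hr, spo2 = float(row["HR_bpm"]), float(row["SpO2_pct"])
            else:
                wave = read_ppg_csv(base / row["ppg_file"])
                vitals = vitals_from_waveform(wave, coefficients)
                hr, spo2 = vitals.HR, vitals.SpO2
            rec = {
                "record_id": row["record_id"],
                "H": H,
                "SpO2": spo2,
                "HR": hr,
                "BF": float(row["BF_pu"]),
            }
            if "BG_ref_mmolL" in row.index and np.isfinite(row["BG_ref_mmolL"]):
                rec["BG_ref"] = float(row["BG_ref_mmolL"])
            rows.append(rec)
        except (ValueError, FileNotFoundError) as exc:
            if strict:
                raise ValueError(f"row {i}: {exc}") from exc
            errors.append((i, str(exc)))
    columns = ["record_id", "H", "SpO2", "HR", "BF", "BG_ref"]
    feats = pd.DataFrame(rows)
    if feats.empty:
        feats = pd.DataFrame(columns=columns[:-1])
    return feats, errors


def write_cohort(records, outdir, config=None) -> Path:
    """Materialise a synthetic cohort as dataset.csv + PPG sidecars + manifest.

    Returns the dataset path.  The manifest records the seed and generator
    configuration so the output is regenerable bit-for-bit.
    """
    outdir = Path(outdir)
    (outdir / "ppg").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        ppg_rel = f"ppg/record_{rec.record_id:04d}.csv"
        write_ppg_csv(rec.waveform, outdir / ppg_rel)
        rows.append(
            {
                "record_id": rec.record_id,
                "subject_id": rec.subject_id,
                "timepoint_label": rec.timepoint_label,
                "Tr_K": rec.frame.Tr,
                "tw_C": rec.frame.tw,
                "ts_C": rec.frame.ts,
                "He_frac": rec.frame.He,
                "BF_pu": rec.BF,
                "ppg_file": ppg_rel,
                "BG_ref_mmolL": rec.BG_ref,
            }
        )
    df = pd.DataFrame(rows)
    dataset_path = outdir / "dataset.csv"
    write_dataset(df, dataset_path)
    manifest = {
        "n_records": len(records),
        "seed": records[0].seed if records else None,
        "dataset": dataset_path.name,
    }
    if config is not None:
        cfg = {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if isinstance(v, (int, float, str, list, tuple))
        }
        manifest["config"] = {k: list(v) if isinstance(v, tuple) else v for k, v in cfg.items()}
        manifest["config_hash"] = hashlib.sha256(
            json.dumps(manifest["config"], sort_keys=True).encode()
        ).hexdigest()[:16]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return dataset_path
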