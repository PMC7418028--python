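"""Delimited-text I/O with explicit header contracts.

All tabular interchange is plain CSV.  Replicate-level files carry either
pre-reduced raw δ/Δ values, optionally accompanied by a per-cycle intensity
file, and are joined on ``replicate_id``.  Sample-level files carry the
(Δ47, Δ48) pairs with 2 SE used by the thermometry front end.  Numeric
output columns are rounded for reading (4 d.p.) with full-precision
machine columns alongside.
"""
from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .isotopologue import CycleIntensities, RawClumpedValues
from .reduction import (
    AcceptedStandards,
    ReplicateRecord,
    SessionResult,
    StandardValue,
)

__all__ = [
    "MalformedInputError",
    "REPLICATE_COLUMNS",
    "CYCLE_COLUMNS",
    "SAMPLE_COLUMNS",
    "read_samples",
    "write_samples",
    "read_replicates",
    "write_replicates",
    "write_cycles",
    "read_standards",
    "write_session_result",
]

REPLICATE_COLUMNS = [
    "replicate_id", "sample_id", "role", "session_id", "timestamp_h",
    "d45", "d46", "d47", "d48", "d49",
    "D47_raw", "D48_raw", "D49_raw", "d13C", "d18O",
]
CYCLE_COLUMNS = [
    "replicate_id", "cycle", "side",
    "i44", "i45", "i46", "i47", "i48", "i49", "i47_5",
]
SAMPLE_COLUMNS = ["sample_id", "d47", "se47_2", "d48", "se48_2", "n"]
STANDARD_COLUMNS = ["standard", "d47", "se47_2", "sd47", "d48", "se48_2", "sd48", "n"]


class MalformedInputError(ValueError):
    """An input CSV is missing required columns or is empty."""


def _read_csv(path, required: list[str], label: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise MalformedInputError(f"{label} file {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedInputError(
            f"{label} file {path} is missing required columns: {', '.join(missing)} "
            f"(found: {', '.join(df.columns)})"
        )
    if df.empty:
        raise MalformedInputError(f"{label} file {path} contains no data rows")
    return df


def read_samples(path) -> pd.DataFrame:
    """Sample-level (Δ47, Δ48) pairs; optional growth temperature/process."""
    df = _read_csv(path, SAMPLE_COLUMNS, "sample")
    for col in ("growth_temperature_C", "process"):
        if col not in df.columns:
            df[col] = np.nan if col == "growth_temperature_C" else "none"
    df["process"] = df["process"].fillna("none")
    return df


def write_samples(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_replicates(path, cycles_path=None) -> list[ReplicateRecord]:
    """Replicate records from a replicate CSV (+ optional cycle CSV)."""
    df = _read_csv(path, REPLICATE_COLUMNS, "replicate")
    cycles_by_rep: dict[str, dict[str, list[CycleIntensities]]] = {}
    if cycles_path is not None:
        cdf = _read_csv(cycles_path, CYCLE_COLUMNS, "cycle")
        for (rep, side), sub in cdf.groupby(["replicate_id", "side"]):
            sub = sub.sort_values("cycle")
            cycles_by_rep.setdefault(str(rep), {})[str(side)] = [
                CycleIntensities(
                    i44=row.i44, i45=row.i45, i46=row.i46,
                    i47=row.i47, i48=row.i48, i49=row.i49,
                    i47_5=None if math.isnan(row.i47_5) else row.i47_5,
                    side=str(side),
                )
                for row in sub.itertuples()
            ]

    records = []
    for row in df.itertuples():
        rep_id = str(row.replicate_id)
        raw = RawClumpedValues(
            d45=row.d45, d46=row.d46, d47=row.d47, d48=row.d48, d49=row.d49,
            D47_raw=row.D47_raw, D48_raw=row.D48_raw, D49_raw=row.D49_raw,
            d13c=row.d13C, d18o=row.d18O,
        )
        cyc = cycles_by_rep.get(rep_id, {})
        records.append(
            ReplicateRecord(
                replicate_id=rep_id,
                sample_id=str(row.sample_id),
                role=str(row.role),
                timestamp_h=float(row.timestamp_h),
                session_id=str(row.session_id),
                raw=raw,
                sample_cycles=cyc.get("sample"),
                wg_cycles=cyc.get("working_gas"),
            )
        )
    return records


def write_replicates(records: list[ReplicateRecord], path) -> None:
    """Write replicate records (raw values only) to CSV.

    Records carrying only cycle data are written with NaN raw columns; use
    :func:`write_cycles` alongside.
    """
    rows = []
    for rec in records:
        raw = rec.raw
        rows.append({
            "replicate_id": rec.replicate_id,
            "sample_id": rec.sample_id,
            "role": rec.role,
            "session_id": rec.session_id,
            "timestamp_h": rec.timestamp_h,
            "d45": raw.d45 if raw else np.nan,
            "d46": raw.d46 if raw else np.nan,
            "d47": raw.d47 if raw else np.nan,
            "d48": raw.d48 if raw else np.nan,
            "d49": raw.d49 if raw else np.nan,
            "D47_raw": raw.D47_raw if raw else np.nan,
            "D48_raw": raw.D48_raw if raw else np.nan,
            "D49_raw": raw.D49_raw if raw else np.nan,
            "d13C": raw.d13c if raw else np.nan,
            "d18O": raw.d18o if raw else np.nan,
        })
    pd.DataFrame(rows, columns=REPLICATE_COLUMNS).to_csv(path, index=False)


def write_cycles(records: list[ReplicateRecord], path) -> None:
    rows = []
    for rec in records:
        if not rec.has_cycles:
            continue
        for side, cycles in (("sample", rec.sample_cycles),
                             ("working_gas", rec.wg_cycles)):
            for k, c in enumerate(cycles):
                rows.append({
                    "replicate_id": rec.replicate_id, "cycle": k, "side": side,
                    "i44": c.i44, "i45": c.i45, "i46": c.i46,
                    "i47": c.i47, "i48": c.i48, "i49": c.i49,
                    "i47_5": np.nan if c.i47_5 is None else c.i47_5,
                })
    pd.DataFrame(rows, columns=CYCLE_COLUMNS).to_csv(path, index=False)


def read_standards(path) -> AcceptedStandards:
    """Accepted standard values from CSV (columns: standard, d47, se47_2,
    sd47, d48, se48_2, sd48, n)."""
    df = _read_csv(path, STANDARD_COLUMNS, "standards")
    table = {
        str(row.standard).strip().upper().replace(" ", "-").replace("_", "-"):
        StandardValue(
            d47=row.d47, se47_2=row.se47_2, sd47=row.sd47,
            d48=row.d48, se48_2=row.se48_2, sd48=row.sd48, n=int(row.n),
        )
        for row in df.itertuples()
    }
    return AcceptedStandards(table=table)


def _with_display_rounding(df: pd.DataFrame, cols: list[str], ndigits: int = 4) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        if c in out.columns:
            out[f"{c}_machine"] = out[c]
            out[c] = out[c].round(ndigits)
    return out


def write_session_result(result: SessionResult, prefix) -> dict[str, Path]:
    """Write per-sample results, corrected replicates, and a fit report."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}

    samples = _with_display_rounding(
        result.samples, ["d47", "sd47", "se47_2", "d48", "sd48", "se48_2", "d13C", "d18O"]
    )
    paths["samples"] = prefix.with_suffix(".samples.csv")
    samples.to_csv(paths["samples"], index=False)

    paths["replicates"] = prefix.with_suffix(".replicates.csv")
    result.replicates.to_csv(paths["replicates"], index=False)

    lines = ["session correction report", "=" * 30]
    if result.background is not None:
        bg = result.background
        lines.append(
            f"background scaling factors: s47={bg.s47:.4f} s48={bg.s48:.4f} "
            f"s49={bg.s49:.4f} (degenerate: {bg.degenerate})"
        )
    if result.nonlinearity is not None:
        for mass, (slope, se) in result.nonlinearity.slopes.items():
            lines.append(
                f"gas non-linearity Δ{mass}: slope={slope:.5f}±{se:.5f} "
                f"applied={result.nonlinearity.needs_correction[mass]}"
            )
    if result.transfer is not None:
        for mass, (a, b) in result.transfer.channels.items():
            lines.append(f"transfer Δ{mass}: slope={a:.5f} intercept={b:.5f}")
    if result.drift is not None:
        lines.append(
            f"drift window: {result.drift.window_h:g} h; flagged: {result.drift.flagged}"
        )
    if result.qc is not None and result.qc.gas_d49_range is not None:
        lines.append(f"Δ49 gas range: {result.qc.gas_d49_range}")
    paths["report"] = prefix.with_suffix(".report.txt")
    paths["report"].write_text("\n".join(lines) + "\n")
    return paths
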