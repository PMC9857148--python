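"""CSV input/output: HR series, annotations, extraction sheets, reports.

One CSV dialect throughout: comma-separated, UTF-8, header row, ``.``
decimal. Times are seconds from recording start.

The extraction sheet mirrors the working spreadsheet a reviewer would
use: one row per 10-s section carrying the HR, the derived features,
run/threshold flags, AES membership and the annotation flags, all
chronologically on one grid.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .concordance import (
    ArtifactInterval,
    ConcordanceReport,
    GMInterval,
    build_section_mask,
)
from .extraction import AES, ExtractionConfig, find_candidate_runs
from .hr_features import HRSeries, SectionFeatures

__all__ = [
    "read_hr_csv",
    "write_hr_csv",
    "read_annotations_csv",
    "write_annotations_csv",
    "build_sheet",
    "write_sheet",
    "read_sheet",
    "write_report",
]

SHEET_COLUMNS = [
    "time_s",
    "hr",
    "mov_av_hr",
    "delta_hr",
    "pct_delta_hr",
    "in_positive_run",
    "above_threshold",
    "aes_id",
    "is_gm",
    "is_artifact",
]

_GRID_TOL_S = 1e-6


def read_hr_csv(
    path: str | Path, expected_section_seconds: float = 10.0
) -> HRSeries:
    """Read a two-column (time_s, hr_bpm) CSV into an ``HRSeries``.

    The time column must form a uniform grid at
    ``expected_section_seconds`` spacing (tolerance 1e-6 s); gaps,
    duplicates and non-positive HR values are rejected with the
    offending row named.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_s, hr_bpm)")
    times = df.iloc[:, 0].to_numpy(dtype=float)
    hr = df.iloc[:, 1].to_numpy(dtype=float)
    if times.size < 1:
        raise ValueError(f"{path}: empty HR file")
    diffs = np.diff(times)
    bad = np.flatnonzero(np.abs(diffs - expected_section_seconds) > _GRID_TOL_S)
    if bad.size:
        r = int(bad[0])
        raise ValueError(
            f"{path}: non-uniform grid at row {r + 3} "
            f"(time step {diffs[r]:g} s, expected {expected_section_seconds:g} s)"
        )
    nonpos = np.flatnonzero(~np.isfinite(hr) | (hr <= 0))
    if nonpos.size:
        raise ValueError(
            f"{path}: non-positive or missing HR at row {int(nonpos[0]) + 2}"
        )
    return HRSeries(
        hr, section_seconds=expected_section_seconds, start_time=float(times[0])
    )


def write_hr_csv(series: HRSeries, path: str | Path) -> None:
    """Write an ``HRSeries`` as the two-column CSV ``read_hr_csv`` reads."""
    df = pd.DataFrame(
        {"time_s": series.section_times(), "hr_bpm": series.values}
    )
    df.to_csv(path, index=False, float_format="%.4f")


def read_annotations_csv(
    path: str | Path,
) -> tuple[list[tuple[float, float]], list[ArtifactInterval]]:
    """Read annotation rows: columns kind (gm|artifact), start_s, end_s[, label].

    GM rows are returned raw (start, end) for ``validate_gm_intervals``
    to vet; artifact rows become ``ArtifactInterval`` directly.
    """
    df = pd.read_csv(path)
    required = {"kind", "start_s", "end_s"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: annotation CSV needs columns {sorted(required)}")
    gms: list[tuple[float, float]] = []
    artifacts: list[ArtifactInterval] = []
    for _, row in df.iterrows():
        kind = str(row["kind"]).strip().lower()
        start, end = float(row["start_s"]), float(row["end_s"])
        if kind == "gm":
            gms.append((start, end))
        elif kind == "artifact":
            label = str(row["label"]) if "label" in df.columns and pd.notna(row.get("label")) else ""
            artifacts.append(ArtifactInterval(start, end, label=label))
        else:
            raise ValueError(f"{path}: unknown annotation kind {kind!r}")
    return gms, artifacts


def write_annotations_csv(
    gm_intervals: Sequence[GMInterval],
    artifact_intervals: Sequence[ArtifactInterval],
    path: str | Path,
) -> None:
    rows = [
        {"kind": "gm", "start_s": g.start_time, "end_s": g.end_time, "label": ""}
        for g in gm_intervals
    ] + [
        {"kind": "artifact", "start_s": a.start_time, "end_s": a.end_time, "label": a.label}
        for a in artifact_intervals
    ]
    pd.DataFrame(rows, columns=["kind", "start_s", "end_s", "label"]).to_csv(
        path, index=False, float_format="%.4f"
    )


def build_sheet(
    series: HRSeries,
    features: SectionFeatures,
    aes_list: Sequence[AES],
    config: ExtractionConfig,
    gm_intervals: Sequence[GMInterval] = (),
    artifact_intervals: Sequence[ArtifactInterval] = (),
) -> pd.DataFrame:
    """Assemble the one-row-per-section extraction sheet."""
    mask = build_section_mask(series, aes_list, gm_intervals, artifact_intervals)
    n = series.n_sections
    in_run = np.zeros(n, dtype=bool)
    for run in find_candidate_runs(features, config):
        in_run[run.first_section : run.last_section + 1] = True
    above = np.zeros(n, dtype=bool)
    defined = features.defined
    above[defined] = features.pct_delta_hr[defined] > config.threshold_pct
    aes_col = np.where(mask.aes_id >= 0, mask.aes_id + 1, np.nan)  # blank outside
    return pd.DataFrame(
        {
            "time_s": series.section_times(),
            "hr": series.values,
            "mov_av_hr": features.mov_av_hr,
            "delta_hr": features.delta_hr,
            "pct_delta_hr": features.pct_delta_hr,
            "in_positive_run": in_run.astype(int),
            "above_threshold": above.astype(int),
            "aes_id": aes_col,
            "is_gm": mask.is_gm.astype(int),
            "is_artifact": mask.is_artifact.astype(int),
        },
        columns=SHEET_COLUMNS,
    )


def write_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    """Write the sheet CSV: bpm at 1 decimal, percentages at 2 decimals."""
    out = sheet.copy()
    for col in ("hr", "mov_av_hr", "delta_hr"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.1f}")
    out["pct_delta_hr"] = out["pct_delta_hr"].map(
        lambda v: "" if pd.isna(v) else f"{v:.2f}"
    )
    out["time_s"] = out["time_s"].map(lambda v: f"{v:.1f}")
    out["aes_id"] = out["aes_id"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False)


def read_sheet(path: str | Path) -> pd.DataFrame:
    """Read back a sheet written by ``write_sheet`` (blank -> NaN)."""
    df = pd.read_csv(path)
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sheet is missing columns {missing}")
    return df


def write_report(
    report: ConcordanceReport, path: str | Path, fmt: Optional[str] = None
) -> None:
    """Write a concordance report as JSON or single-row CSV (by extension)."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    d = report.to_dict()
    if fmt == "json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    elif fmt == "csv":
        pd.DataFrame([d]).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
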