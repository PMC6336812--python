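"""Tabular readers and writers for tracks, traces, expression courses and results.

All files are comma-delimited UTF-8 text with a header row, in long format
(one row per bin or timepoint).  Downstream modules consume only the domain
types; nothing else in the package touches files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    ActivityTrack,
    AnalysisConfig,
    CellTrace,
    ExpressionCourse,
    LightSchedule,
    ParseError,
    SchemaError,
)

__all__ = [
    "TrackSchema",
    "TraceSchema",
    "read_activity_table",
    "write_tracks",
    "read_trace_table",
    "write_traces",
    "read_expression_table",
    "write_expression",
    "write_results",
]


@dataclass(frozen=True)
class TrackSchema:
    """Column layout of a locomotor-track export.

    ``fill_missing_bins=False`` treats gaps in the time grid as an error;
    opting in fills them with zero distance.  Silent gap-filling corrupts
    bout lengths, so it is never the default.
    """

    animal_col: str = "animal_id"
    genotype_col: str = "genotype"
    time_col: str = "time_s"
    distance_col: str = "distance_mm"
    fill_missing_bins: bool = False


@dataclass(frozen=True)
class TraceSchema:
    cell_col: str = "cell_id"
    condition_col: str = "condition"
    time_col: str = "time_h"
    intensity_col: str = "intensity"


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: Path) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{path}: missing required column {c!r}")


def _numeric(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any() or vals.isna().any():
        row = int(np.flatnonzero(vals.isna().to_numpy())[0])
        raise ParseError(f"{path}: non-numeric value in column {col!r} at data row {row}")
    return vals.to_numpy(dtype=float)


def read_activity_table(
    path: str | Path,
    schema: TrackSchema | None = None,
    bin_width_s: float = 1.0,
    schedule: LightSchedule | None = None,
    t0_s: float = 0.0,
) -> list[ActivityTrack]:
    """Read a long-format per-bin distance table into one track per animal.

    Each row holds (animal, genotype, bin start time in seconds, distance).
    Bin times must form a dense grid at ``bin_width_s``; gaps are an error
    unless the schema opts into zero-filling.
    """
    schema = schema or TrackSchema()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ParseError(f"{path}: empty table")
    _require_columns(
        df, (schema.animal_col, schema.genotype_col, schema.time_col, schema.distance_col), path
    )
    times = _numeric(df, schema.time_col, path)
    dists = _numeric(df, schema.distance_col, path)
    neg = np.flatnonzero(dists < 0)
    if neg.size:
        raise ParseError(
            f"{path}: negative distance at data row {int(neg[0])} "
            f"(column {schema.distance_col!r})"
        )
    schedule = schedule or LightSchedule.dd()

    tracks: list[ActivityTrack] = []
    for animal, grp_idx in df.groupby(schema.animal_col, sort=False).groups.items():
        idx = np.asarray(grp_idx)
        t = times[idx]
        d = dists[idx]
        order = np.argsort(t, kind="stable")
        t, d = t[order], d[order]
        genotype = str(df[schema.genotype_col].iloc[idx[0]])
        n_expected = int(round((t[-1] - t[0]) / bin_width_s)) + 1
        on_grid = np.allclose((t - t[0]) / bin_width_s, np.round((t - t[0]) / bin_width_s), atol=1e-6)
        if not on_grid:
            raise ParseError(f"{path}: animal {animal!r}: bin times off the {bin_width_s}-s grid")
        if len(t) != n_expected:
            if not schema.fill_missing_bins:
                raise ParseError(
                    f"{path}: animal {animal!r}: missing bins "
                    f"({len(t)} present, {n_expected} expected); "
                    "set fill_missing_bins=True to zero-fill"
                )
            full = np.zeros(n_expected)
            pos = np.round((t - t[0]) / bin_width_s).astype(int)
            full[pos] = d
            d = full
        elif np.unique(np.round((t - t[0]) / bin_width_s).astype(int)).size != len(t):
            raise ParseError(f"{path}: animal {animal!r}: duplicate bin times")
        tracks.append(
            ActivityTrack(
                animal_id=str(animal),
                genotype=genotype,
                bin_width_s=bin_width_s,
                distances_mm=d,
                schedule=schedule,
                t0_s=t0_s,
            )
        )
    return tracks


def write_tracks(tracks: Sequence[ActivityTrack], path: str | Path, schema: TrackSchema | None = None) -> Path:
    """Write tracks to the long CSV layout read by :func:`read_activity_table`."""
    schema = schema or TrackSchema()
    path = Path(path)
    frames = [
        pd.DataFrame(
            {
                schema.animal_col: tr.animal_id,
                schema.genotype_col: tr.genotype,
                schema.time_col: tr.times_s,
                schema.distance_col: tr.distances_mm,
            }
        )
        for tr in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_trace_table(path: str | Path, schema: TraceSchema | None = None) -> list[CellTrace]:
    """Read per-cell bioluminescence traces; times are sorted per cell."""
    schema = schema or TraceSchema()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ParseError(f"{path}: empty table")
    _require_columns(df, (schema.cell_col, schema.condition_col, schema.time_col, schema.intensity_col), path)
    times = _numeric(df, schema.time_col, path)
    intens = _numeric(df, schema.intensity_col, path)
    traces: list[CellTrace] = []
    for cell, grp_idx in df.groupby(schema.cell_col, sort=False).groups.items():
        idx = np.asarray(grp_idx)
        t = times[idx]
        y = intens[idx]
        order = np.argsort(t, kind="stable")
        t, y = t[order], y[order]
        if np.any(np.diff(t) == 0):
            raise ParseError(f"{path}: duplicate (cell, time) rows for cell {cell!r}")
        condition = str(df[schema.condition_col].iloc[idx[0]])
        traces.append(CellTrace(cell_id=str(cell), condition=condition, times_h=t, intensities=y))
    return traces


def write_traces(traces: Sequence[CellTrace], path: str | Path, schema: TraceSchema | None = None) -> Path:
    schema = schema or TraceSchema()
    path = Path(path)
    frames = [
        pd.DataFrame(
            {
                schema.cell_col: tr.cell_id,
                schema.condition_col: tr.condition,
                schema.time_col: tr.times_h,
                schema.intensity_col: tr.intensities,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_expression_table(path: str | Path) -> list[ExpressionCourse]:
    """Read gene-expression courses (columns: gene, time_h, value)."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ParseError(f"{path}: empty table")
    _require_columns(df, ("gene", "time_h", "value"), path)
    times = _numeric(df, "time_h", path)
    vals = _numeric(df, "value", path)
    courses = []
    for gene, grp_idx in df.groupby("gene", sort=False).groups.items():
        idx = np.asarray(grp_idx)
        order = np.argsort(times[idx], kind="stable")
        courses.append(ExpressionCourse(str(gene), times[idx][order], vals[idx][order]))
    return courses


def write_expression(courses: Sequence[ExpressionCourse], path: str | Path) -> Path:
    path = Path(path)
    frames = [
        pd.DataFrame({"gene": c.gene, "time_h": c.times_h, "value": c.values}) for c in courses
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
    extra_metadata: Mapping | None = None,
) -> dict:
    """Write one CSV per named table plus a run-metadata JSON.

    Returns a manifest mapping table names to file paths.  Data files are
    deterministic for identical inputs; the metadata file carries the config
    echo and seed and is excluded from any byte-identity guarantee.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest: dict = {"tables": {}, "metadata_file": str(out_dir / "run_metadata.json")}
        for name, df in tables.items():
            f = out_dir / f"{name}.csv"
            df.to_csv(f, index=False)
            manifest["tables"][name] = str(f)
        meta = {
            "config": config.to_dict() if config is not None else None,
            "seed": seed,
            "tables": {name: int(len(df)) for name, df in tables.items()},
        }
        if extra_metadata:
            meta.update(dict(extra_metadata))
        (out_dir / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    except OSError as exc:
        raise OSError(f"cannot write results under {out_dir}: {exc}") from exc
    return manifest
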