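"""Delimited-table readers/writers and run-configuration parsing.

All interchange is plain CSV with a header row.  Writers emit a fixed column
order, `repr`-formatted floats (shortest round-trip representation, so a
written value reads back bit-identically) and `\n` newlines, which makes
outputs byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SchemaError
from .features import AreaTrace, FeatureSet, CultureSummary
from .mechanics import DivisionSchedule, SimulationParams, Trajectory
from .morphometry import CentroidSet, MatchResult
from .scaling import GrowthCurve

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ["organoid_id", "well_id", "t_h", "area_mm2"]
OPTIONAL_TRACE_COLUMNS = ["perimeter_mm"]
FRAME_INTERVAL_H = 0.5


def _format(value) -> str:
    if isinstance(value, (bool, np.bool_)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    return str(value)


def _write_csv(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    path = Path(path)
    try:
        with open(path, "w", newline="\n") as fh:
            fh.write(",".join(header) + "\n")
            for row in rows:
                fh.write(",".join(_format(v) for v in row) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write table to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Area traces
# ---------------------------------------------------------------------------

def read_trace_table(path) -> list[AreaTrace]:
    """Load projected-area traces grouped by organoid and well.

    Required columns: organoid_id, well_id, t_h, area_mm2; perimeter_mm is
    optional.  Rows with non-finite area are dropped (and counted in a
    warning); the frame interval is checked against the 30-min default.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty input file: {path}") from exc
    for col in TRACE_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    has_perimeter = "perimeter_mm" in frame.columns
    if not has_perimeter:
        logger.warning(
            "%s has no perimeter_mm column: circularity will be unavailable", path
        )
    n_bad = int((~np.isfinite(frame["area_mm2"])).sum())
    if n_bad:
        logger.warning("dropping %d rows with non-finite area from %s", n_bad, path)
        frame = frame[np.isfinite(frame["area_mm2"])]
    if frame.empty:
        raise SchemaError(f"no usable rows in {path}")

    traces = []
    for (well, organoid), grp in frame.groupby(["well_id", "organoid_id"], sort=True):
        grp = grp.sort_values("t_h")
        times = grp["t_h"].to_numpy(dtype=float)
        if len(times) > 1:
            dt = np.diff(times)
            if not np.allclose(dt, FRAME_INTERVAL_H, rtol=0.01):
                logger.warning(
                    "organoid %s: frame interval deviates from %.1f h",
                    organoid, FRAME_INTERVAL_H,
                )
        traces.append(
            AreaTrace(
                str(organoid),
                str(well),
                times,
                grp["area_mm2"].to_numpy(dtype=float),
                perimeter=(
                    grp["perimeter_mm"].to_numpy(dtype=float)
                    if has_perimeter
                    else None
                ),
            )
        )
    return traces


def write_trace_table(path, traces: list[AreaTrace]) -> None:
    has_perimeter = any(tr.perimeter is not None for tr in traces)
    header = list(TRACE_COLUMNS) + (["perimeter_mm"] if has_perimeter else [])
    rows = []
    for tr in traces:
        raw = tr.area_raw if tr.area_raw is not None else tr.area
        for k in range(tr.n_frames):
            row = [tr.organoid_id, tr.well_id, tr.times[k], raw[k]]
            if has_perimeter:
                row.append(tr.perimeter[k] if tr.perimeter is not None else "")
            rows.append(row)
    _write_csv(path, header, rows)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = [
    "organoid_id", "well_id", "n_declines", "n_expansions", "n_events",
    "initial_area", "final_area", "min_area", "max_area",
    "avg_expansion", "max_expansion", "mean_circularity", "excluded", "outlier",
]


def write_features(path, feature_sets: list[FeatureSet]) -> None:
    rows = []
    for fs in feature_sets:
        circ = (
            float(np.mean(fs.circularity)) if fs.circularity is not None else ""
        )
        rows.append(
            [
                fs.organoid_id, fs.well_id, len(fs.declines), len(fs.expansions),
                fs.n_events, fs.initial_area, fs.final_area, fs.min_area,
                fs.max_area,
                "" if fs.avg_expansion is None else fs.avg_expansion,
                "" if fs.max_expansion is None else fs.max_expansion,
                circ, fs.excluded, fs.outlier,
            ]
        )
    _write_csv(path, FEATURE_COLUMNS, rows)


def write_well_summary(path, summary: CultureSummary) -> None:
    header = [
        "well_id", "n_organoids", "median_final_area", "q1_final_area",
        "q3_final_area", "median_avg_expansion", "q1_avg_expansion",
        "q3_avg_expansion", "kruskal_h", "kruskal_p",
    ]
    h = "" if summary.kruskal_h is None else summary.kruskal_h
    p = "" if summary.kruskal_p is None else summary.kruskal_p
    rows = []
    for w in summary.wells:
        rows.append(
            [
                w.well_id, w.n_organoids, w.median_final_area,
                w.iqr_final_area[0], w.iqr_final_area[1],
                "" if w.median_avg_expansion is None else w.median_avg_expansion,
                "" if w.iqr_avg_expansion is None else w.iqr_avg_expansion[0],
                "" if w.iqr_avg_expansion is None else w.iqr_avg_expansion[1],
                h, p,
            ]
        )
    _write_csv(path, header, rows)


# ---------------------------------------------------------------------------
# Trajectories, centroids, growth curves, match results
# ---------------------------------------------------------------------------

TRAJECTORY_COLUMNS = [
    "t", "N", "V_lumen", "R_fit", "n", "sealed", "rupture_event", "pressure",
]


def write_trajectory(path, trajectory: Trajectory) -> None:
    rows = zip(
        trajectory.time, trajectory.n_cells, trajectory.v_lumen,
        trajectory.r_fit, trajectory.n_substance, trajectory.sealed,
        trajectory.rupture_event, trajectory.pressure,
    )
    _write_csv(path, TRAJECTORY_COLUMNS, rows)


def write_match(path, result: MatchResult) -> None:
    _write_csv(
        path,
        ["tp", "fp", "fn", "recall", "precision", "f_score"],
        [[result.tp, result.fp, result.fn, result.recall, result.precision,
          result.f_score]],
    )


def read_centroids(path) -> CentroidSet:
    """Centroid CSV with columns id, t, x_vox, y_vox, z_vox."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty input file: {path}") from exc
    for col in ("x_vox", "y_vox", "z_vox"):
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    return CentroidSet(frame[["x_vox", "y_vox", "z_vox"]].to_numpy(dtype=float))


def write_centroids(path, centroids: CentroidSet, time_label: str = "0") -> None:
    rows = [
        [i, time_label, p[0], p[1], p[2]]
        for i, p in enumerate(centroids.points)
    ]
    _write_csv(path, ["id", "t", "x_vox", "y_vox", "z_vox"], rows)


def read_growth_curve(path, kind: str = "count") -> GrowthCurve:
    """Growth-curve CSV with columns t, value."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty input file: {path}") from exc
    for col in ("t", "value"):
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    frame = frame.sort_values("t")
    return GrowthCurve(
        frame["t"].to_numpy(dtype=float), frame["value"].to_numpy(dtype=float),
        kind=kind,
    )


def write_growth_curve(path, curve: GrowthCurve) -> None:
    _write_csv(path, ["t", "value"], zip(curve.times, curve.values))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_SIMULATE_KEYS = {"t_end", "n0", "r0", "record_every", "jitter"}


def load_config(path) -> dict:
    """Parse a YAML run configuration, rejecting unknown keys by name.

    Recognised sections: ``params`` (SimulationParams fields), ``schedule``
    (DivisionSchedule fields) and ``simulate`` (t_end, n0, r0, record_every,
    jitter).
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration root must be a mapping in {path}")
    known_sections = {"params", "schedule", "simulate"}
    for key in raw:
        if key not in known_sections:
            raise ConfigError(f"unknown configuration section {key!r} in {path}")
    param_fields = {f.name for f in dataclasses.fields(SimulationParams)}
    schedule_fields = {f.name for f in dataclasses.fields(DivisionSchedule)}
    for section, allowed in (
        ("params", param_fields),
        ("schedule", schedule_fields),
        ("simulate", _SIMULATE_KEYS),
    ):
        for key in raw.get(section) or {}:
            if key not in allowed:
                raise ConfigError(
                    f"unknown key {key!r} in section {section!r} of {path}"
                )
    return raw


def build_simulation(config: dict, seed: int | None = None):
    """Instantiate (params, schedule, simulate-kwargs) from a parsed config."""
    params_kwargs = dict(config.get("params") or {})
    if seed is not None:
        params_kwargs["seed"] = seed
    schedule_kwargs = dict(config.get("schedule") or {})
    if "table" in schedule_kwargs and schedule_kwargs["table"] is not None:
        schedule_kwargs["table"] = [
            (float(t), float(c)) for t, c in schedule_kwargs["table"]
        ]
    params = SimulationParams(**params_kwargs)
    schedule = DivisionSchedule(**schedule_kwargs)
    sim_kwargs = dict(config.get("simulate") or {})
    return params, schedule, sim_kwargs
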