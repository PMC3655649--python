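"""Readers and writers: marker-track CSV, calibration YAML, results CSV/JSON.

Track CSV schema (one row per marker per step, header required, UTF-8,
'.' decimal separator):

    marker_id, step_id, x_mm, y_mm                      -- pre-fused global
    marker_id, step_id, stage_x_mm, stage_y_mm,
                        cam_x_px, cam_y_px              -- raw, needs calibration

If global columns are present they are used directly; otherwise the raw
columns require a calibration (theta, pixel scale). Image row coordinates
typically increase downward, so the camera y-axis is flipped to the
mathematical convention at ingest unless the calibration file says
otherwise. The step labelled ``initial`` is the reference configuration;
all other steps are evaluated against it in order of first appearance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationParams, StageCameraObservation, to_global
from .errors import SchemaError
from .geometry import MarkerQuad
from .poisson import PoissonResult

__all__ = [
    "read_calibration",
    "write_calibration",
    "read_tracks",
    "write_tracks",
    "read_observations",
    "results_to_frame",
    "write_results_csv",
    "write_results_json",
]

GLOBAL_COLUMNS = ("marker_id", "step_id", "x_mm", "y_mm")
RAW_COLUMNS = ("marker_id", "step_id", "stage_x_mm", "stage_y_mm", "cam_x_px", "cam_y_px")
INITIAL_STEP = "initial"


def read_calibration(path) -> tuple[CalibrationParams, bool]:
    """Load a calibration YAML; returns (params, flip_camera_y)."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise SchemaError(f"calibration file {path} is not a key-value mapping")
    try:
        theta_deg = float(data["theta_s_c_deg"])
        pixel_scale = float(data["pixel_scale_mm_per_px"])
    except KeyError as exc:
        raise SchemaError(f"calibration file {path} missing key {exc.args[0]!r}") from exc
    offset = tuple(float(v) for v in data.get("camera_origin_offset_mm", (0.0, 0.0)))
    flip = bool(data.get("flip_camera_y", True))
    params = CalibrationParams(
        theta_s_c=np.deg2rad(theta_deg), pixel_scale=pixel_scale, camera_origin_offset=offset
    )
    return params, flip


def write_calibration(
    path,
    theta_s_c_deg: float,
    pixel_scale_mm_per_px: float,
    flip_camera_y: bool = True,
    **extras,
) -> None:
    doc = {
        "theta_s_c_deg": float(theta_s_c_deg),
        "pixel_scale_mm_per_px": float(pixel_scale_mm_per_px),
        "flip_camera_y": bool(flip_camera_y),
    }
    doc.update({k: (float(v) if isinstance(v, (int, float, np.floating)) else v) for k, v in extras.items()})
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _read_csv(path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, dtype={"marker_id": str, "step_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise SchemaError(f"cannot parse CSV {path}: {exc}") from exc
    return frame


def read_tracks(
    path,
    calibration: CalibrationParams | None = None,
    flip_camera_y: bool = True,
) -> tuple[MarkerQuad, list[str], list[MarkerQuad]]:
    """Read a marker-track CSV into (initial quad, step ids, step quads)."""
    frame = _read_csv(path)
    cols = set(frame.columns)
    if {"x_mm", "y_mm"}.issubset(cols):
        needed = set(GLOBAL_COLUMNS)
        if not needed.issubset(cols):
            raise SchemaError(f"{path}: missing columns {sorted(needed - cols)}")
        frame = frame.copy()
    elif set(RAW_COLUMNS).issubset(cols):
        if calibration is None:
            raise SchemaError(
                f"{path}: raw stage/camera columns present but no calibration supplied"
            )
        frame = frame.copy()
        cam_y = -frame["cam_y_px"] if flip_camera_y else frame["cam_y_px"]
        fused = [
            to_global(
                StageCameraObservation(
                    stage_pos=(sx, sy), camera_pos=(cx, cy), marker_id=str(m), step_id=str(s)
                ),
                calibration,
            )
            for sx, sy, cx, cy, m, s in zip(
                frame["stage_x_mm"], frame["stage_y_mm"], frame["cam_x_px"], cam_y,
                frame["marker_id"], frame["step_id"],
            )
        ]
        frame["x_mm"] = [p.x for p in fused]
        frame["y_mm"] = [p.y for p in fused]
    else:
        raise SchemaError(
            f"{path}: need either columns {GLOBAL_COLUMNS} or {RAW_COLUMNS}, got {sorted(cols)}"
        )

    if frame["marker_id"].isna().any() or frame["step_id"].isna().any():
        raise SchemaError(f"{path}: empty marker_id/step_id entries")

    quads: dict[str, MarkerQuad] = {}
    step_order: list[str] = []
    for step_id, grp in frame.groupby("step_id", sort=False):
        if len(grp) != 4:
            raise SchemaError(f"{path}: step {step_id!r} has {len(grp)} markers, expected 4")
        if grp["marker_id"].duplicated().any():
            raise SchemaError(f"{path}: step {step_id!r} repeats a marker_id")
        quads[str(step_id)] = MarkerQuad(
            grp[["x_mm", "y_mm"]].to_numpy(float), list(grp["marker_id"])
        )
        step_order.append(str(step_id))

    if INITIAL_STEP not in quads:
        raise SchemaError(f"{path}: no step labelled {INITIAL_STEP!r}")
    initial = quads.pop(INITIAL_STEP)
    step_ids = [s for s in step_order if s != INITIAL_STEP]
    if not step_ids:
        raise SchemaError(f"{path}: no deformed steps besides {INITIAL_STEP!r}")
    for sid in step_ids:
        if set(quads[sid].labels) != set(initial.labels):
            raise SchemaError(f"{path}: step {sid!r} marker labels differ from the initial step")
    return initial, step_ids, [quads[s] for s in step_ids]


def write_tracks(path, initial: MarkerQuad, steps: Sequence[tuple[str, MarkerQuad]]) -> None:
    """Write quads to the global-coordinate track CSV schema."""
    rows = []
    for step_id, quad in [(INITIAL_STEP, initial), *steps]:
        for lab, (x, y) in zip(quad.labels, quad.vertices):
            rows.append({"marker_id": lab, "step_id": step_id, "x_mm": repr(float(x)), "y_mm": repr(float(y))})
    pd.DataFrame(rows, columns=list(GLOBAL_COLUMNS)).to_csv(path, index=False)


def read_observations(path) -> pd.DataFrame:
    """Read a calibration-sweep CSV (raw schema, optional ``axis`` column)."""
    frame = _read_csv(path)
    needed = {"cam_x_px", "cam_y_px"}
    if not needed.issubset(frame.columns):
        raise SchemaError(f"{path}: calibration sweep needs columns {sorted(needed)}")
    return frame


def results_to_frame(results: Sequence[PoissonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "step_id": r.step_id,
                "eps1": r.eps1,
                "eps2": r.eps2,
                "principal_angle_deg": r.principal_angle_deg,
                "nu": round(r.nu, 4) if np.isfinite(r.nu) else r.nu,
                "elongation_pct": r.elongation_pct,
                "heterogeneity": r.heterogeneity,
                "method": r.method,
                "status": r.status,
                "message": r.message,
            }
        )
    return pd.DataFrame(rows)


def write_results_csv(results: Sequence[PoissonResult], path) -> None:
    results_to_frame(results).to_csv(path, index=False)


def write_results_json(results: Sequence[PoissonResult], path, meta: dict | None = None) -> None:
    """Full-precision results with diagnostics (the CSV rounds nu to 4 dp)."""
    payload = {
        "meta": meta or {},
        "results": [
            {
                "step_id": r.step_id,
                "method": r.method,
                "status": r.status,
                "message": r.message,
                "nu": _jsonable(r.nu),
                "eps1": _jsonable(r.eps1),
                "eps2": _jsonable(r.eps2),
                "principal_angle_deg": _jsonable(r.principal_angle_deg),
                "elongation_pct": _jsonable(r.elongation_pct),
                "heterogeneity": _jsonable(r.heterogeneity),
                "misalignment_deg": _jsonable(r.misalignment_deg),
                "warnings": list(r.warnings),
            }
            for r in results
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def _jsonable(x: float):
    return float(x) if np.isfinite(x) else None
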