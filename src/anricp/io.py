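"""File formats: ASCII PLY/OBJ point clouds, landmark CSV, YAML run config.

Clouds round-trip losslessly at full float64 precision and preserve point
order; when a cloud carries grid topology, the PLY header records it in a
``comment grid_shape rows cols`` line (OBJ has no comment-metadata
convention, so grid shape survives only through PLY).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aniso import NoiseModel
from .core import ConfigError, InvalidInputError, LandmarkSet, PointCloud
from .nricp import RegistrationConfig
from .synth import FixtureSpec

_FLOAT_FMT = "%.17g"

LANDMARK_COLUMNS = ["source_index", "target_index", "role", "marker_row", "marker_col", "corner_id"]


class ParseError(InvalidInputError):
    """Malformed cloud or landmark file; message names the offending line."""


# ---------------------------------------------------------------- point clouds

def write_cloud(cloud: PointCloud, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".obj":
        _write_obj(cloud, path)
    else:
        _write_ply(cloud, path)


def read_cloud(path) -> PointCloud:
    path = Path(path)
    if path.suffix.lower() == ".obj":
        return _read_obj(path)
    return _read_ply(path)


def _write_ply(cloud: PointCloud, path: Path) -> None:
    lines = ["ply", "format ascii 1.0"]
    if cloud.grid_shape is not None:
        lines.append(f"comment grid_shape {cloud.grid_shape[0]} {cloud.grid_shape[1]}")
    lines += [
        f"element vertex {cloud.n}",
        "property double x",
        "property double y",
        "property double z",
        "end_header",
    ]
    body = "\n".join(" ".join(_FLOAT_FMT % v for v in p) for p in cloud.points)
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def _read_ply(path: Path) -> PointCloud:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ParseError(f"{path}:1: not an ascii PLY file")
    n_vertex = None
    grid_shape = None
    header_end = None
    for i, line in enumerate(lines[1:], start=2):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format" and tok[1] != "ascii":
            raise ParseError(f"{path}:{i}: only ascii PLY is supported")
        if tok[0] == "comment" and len(tok) == 4 and tok[1] == "grid_shape":
            grid_shape = (int(tok[2]), int(tok[3]))
        if tok[0] == "element":
            if tok[1] != "vertex":
                raise ParseError(f"{path}:{i}: unsupported element {tok[1]!r}")
            n_vertex = int(tok[2])
        if tok[0] == "end_header":
            header_end = i
            break
    if header_end is None or n_vertex is None:
        raise ParseError(f"{path}: missing end_header or vertex element")
    rows = []
    for i, line in enumerate(lines[header_end : header_end + n_vertex], start=header_end + 1):
        tok = line.split()
        if len(tok) < 3:
            raise ParseError(f"{path}:{i}: expected 3 vertex coordinates")
        try:
            rows.append([float(tok[0]), float(tok[1]), float(tok[2])])
        except ValueError:
            raise ParseError(f"{path}:{i}: non-numeric vertex coordinate") from None
    if len(rows) != n_vertex:
        raise ParseError(f"{path}: header promises {n_vertex} vertices, found {len(rows)}")
    return PointCloud(np.asarray(rows), grid_shape)


def _write_obj(cloud: PointCloud, path: Path) -> None:
    body = "\n".join("v " + " ".join(_FLOAT_FMT % v for v in p) for p in cloud.points)
    path.write_text(body + "\n")


def _read_obj(path: Path) -> PointCloud:
    import logging

    rows = []
    ignored = 0
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines, start=1):
        tok = line.split()
        if not tok or tok[0].startswith("#"):
            continue
        if tok[0] == "v":
            if len(tok) < 4:
                raise ParseError(f"{path}:{i}: 'v' record needs 3 coordinates")
            try:
                rows.append([float(tok[1]), float(tok[2]), float(tok[3])])
            except ValueError:
                raise ParseError(f"{path}:{i}: non-numeric vertex coordinate") from None
        else:
            ignored += 1
    if ignored:
        logging.getLogger("anricp").warning(
            "%s: ignored %d non-vertex OBJ records (faces/normals)", path, ignored
        )
    if not rows:
        raise ParseError(f"{path}: no vertex records found")
    return PointCloud(np.asarray(rows))


# ------------------------------------------------------------------- landmarks

def write_landmarks(landmarks: LandmarkSet, path) -> None:
    n = len(landmarks)
    df = pd.DataFrame(
        {
            "source_index": landmarks.source_index,
            "target_index": landmarks.target_index,
            "role": landmarks.role,
            "marker_row": landmarks.marker_row if landmarks.marker_row is not None else [""] * n,
            "marker_col": landmarks.marker_col if landmarks.marker_col is not None else [""] * n,
            "corner_id": landmarks.corner_id if landmarks.corner_id is not None else [""] * n,
        }
    )
    df.to_csv(path, index=False)


def read_landmarks(path) -> LandmarkSet:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return LandmarkSet()
    if df.empty:
        return LandmarkSet()
    missing = {"source_index", "target_index", "role"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing landmark columns {sorted(missing)}")

    def opt(col):
        if col not in df.columns or df[col].isna().all():
            return None
        return df[col].to_numpy(dtype=np.int64)

    return LandmarkSet(
        source_index=df["source_index"].to_numpy(dtype=np.int64),
        target_index=df["target_index"].to_numpy(dtype=np.int64),
        role=df["role"].to_numpy(dtype=object),
        marker_row=opt("marker_row"),
        marker_col=opt("marker_col"),
        corner_id=opt("corner_id"),
    )


# ---------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """Validated union of registration, noise, and fixture settings."""

    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    fixture: FixtureSpec = field(default_factory=FixtureSpec)
    output_dir: str = "."
    log_level: str = "INFO"


def _build(cls, mapping: dict, context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown {context} keys: {sorted(unknown)}")
    return cls(**mapping)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    unknown = set(raw) - {"registration", "noise", "fixture", "output_dir", "log_level"}
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    noise = _build(NoiseModel, raw.get("noise", {}) or {}, "noise")
    reg_map = dict(raw.get("registration", {}) or {})
    reg_map["noise"] = noise
    fix_map = dict(raw.get("fixture", {}) or {})
    fix_map["noise"] = noise
    if "x_bounds" in fix_map:
        fix_map["x_bounds"] = tuple(fix_map["x_bounds"])
    if "y_bounds" in fix_map:
        fix_map["y_bounds"] = tuple(fix_map["y_bounds"])
    if "marker_centers" in fix_map:
        fix_map["marker_centers"] = tuple(fix_map["marker_centers"])
    try:
        registration = _build(RegistrationConfig, reg_map, "registration")
        fixture = _build(FixtureSpec, fix_map, "fixture")
    except TypeError as exc:
        raise ConfigError(str(exc)) from None
    return RunConfig(
        registration=registration,
        fixture=fixture,
        output_dir=str(raw.get("output_dir", ".")),
        log_level=str(raw.get("log_level", "INFO")),
    )


def config_to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["registration"]["noise"]["camera_origin"] = list(
        map(float, d["registration"]["noise"]["camera_origin"])
    )
    d["fixture"]["noise"]["camera_origin"] = list(
        map(float, d["fixture"]["noise"]["camera_origin"])
    )
    return d


# --------------------------------------------------------------- JSON schema

def load_report_schema() -> dict:
    return json.loads(resources.files("anricp").joinpath("report_schema.json").read_text())


def validate_report(doc: dict, schema: dict | None = None, path: str = "$") -> None:
    """Validate a report dict against the shipped schema subset.

    Supports the schema features the reports use: type, properties, required,
    items, and nullable unions expressed as a list of types.  Raises
    InvalidInputError naming the offending path.
    """
    schema = schema if schema is not None else load_report_schema()
    types = schema.get("type")
    if types is not None:
        if isinstance(types, str):
            types = [types]
        if not any(_type_ok(doc, t) for t in types):
            raise InvalidInputError(f"{path}: expected type {types}, got {type(doc).__name__}")
    if isinstance(doc, dict):
        for key in schema.get("required", []):
            if key not in doc:
                raise InvalidInputError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in doc:
                validate_report(doc[key], sub, f"{path}.{key}")
    if isinstance(doc, list) and "items" in schema:
        for i, item in enumerate(doc):
            validate_report(item, schema["items"], f"{path}[{i}]")


def _type_ok(value, t: str) -> bool:
    table = {
        "object": dict,
        "array": list,
        "string": str,
        "number": (int, float),
        "integer": int,
        "boolean": bool,
        "null": type(None),
    }
    if t == "number" and isinstance(value, bool):
        return False
    return isinstance(value, table[t])
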