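"""Reading and writing the package's file formats.

Reflectivity curves travel as plain ASCII columns — ``q R [dR]`` or
``angle R`` — with ``#`` comment lines, the lingua franca of reflectometry
beamlines.  Written files carry ORSO-style ``#`` header comments (columns,
units, provenance) while remaining readable by any column parser.  Fit and
composition reports serialize to JSON; configuration to YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .stack_model import Instrument, ReflectivityCurve, qz_from_angle

log = logging.getLogger("lipidxrr")

__all__ = [
    "read_reflectivity",
    "write_reflectivity",
    "write_json",
    "read_json",
    "load_config",
    "config_hash",
]

DIALECTS = ("q_R", "q_R_dR", "angle_R")


class FormatError(ValueError):
    """Unparseable or insufficient curve data."""


def _parse_ascii_columns(path) -> np.ndarray:
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise FormatError(f"{path}: cannot parse line {raw!r}") from exc
    if not rows:
        raise FormatError(f"{path}: no data rows found")
    width = min(len(r) for r in rows)
    if width < 2:
        raise FormatError(f"{path}: need at least two columns")
    return np.array([r[:width] for r in rows], dtype=float)


def read_reflectivity(
    path,
    dialect: str = "q_R",
    instrument: Instrument | None = None,
) -> ReflectivityCurve:
    """Read an ASCII reflectivity curve.

    Dialects: ``q_R`` (two columns, extra columns ignored), ``q_R_dR``
    (three columns), ``angle_R`` (first column in degrees, converted with
    the supplied instrument wavelength).  Non-monotonic rows are sorted
    with a warning; non-positive reflectivities are dropped and counted.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    data = _parse_ascii_columns(path)
    if dialect == "q_R_dR" and data.shape[1] < 3:
        raise FormatError(f"{path}: dialect q_R_dR requires three columns")

    x = data[:, 0]
    if dialect == "angle_R":
        instrument = instrument or Instrument()
        q = qz_from_angle(x, instrument)
    else:
        q = x
    R = data[:, 1]
    dR = data[:, 2] if dialect == "q_R_dR" else None

    keep = (R > 0) & (q > 0)
    if dR is not None:
        keep &= dR > 0
    dropped = int((~keep).sum())
    if dropped:
        log.warning("%s: dropped %d rows with non-positive q, R or dR", path, dropped)
    q, R = q[keep], R[keep]
    if dR is not None:
        dR = dR[keep]
    if q.size < 2:
        raise FormatError(f"{path}: fewer than 2 usable rows")

    order = np.argsort(q)
    if not np.array_equal(order, np.arange(q.size)):
        log.warning("%s: q not monotonic; rows sorted", path)
        q, R = q[order], R[order]
        if dR is not None:
            dR = dR[order]
    if np.any(np.diff(q) == 0):
        keep = np.concatenate([[True], np.diff(q) > 0])
        log.warning("%s: dropped %d duplicate q rows", path, int((~keep).sum()))
        q, R = q[keep], R[keep]
        if dR is not None:
            dR = dR[keep]
    return ReflectivityCurve(q, R, dR)


def write_reflectivity(
    curve: ReflectivityCurve, path, metadata: dict | None = None
) -> None:
    """Write a curve as ASCII columns with ORSO-style '#' headers."""
    lines = [
        "# # ORSO reflectivity data file | 1.0 standard | YAML encoding | "
        "https://www.reflectometry.org/",
        "# data_source:",
        "#   measurement:",
        "#     scheme: angle-dispersive",
    ]
    for key, value in (metadata or {}).items():
        lines.append(f"#   {key}: {value}")
    cols = "q_z (1/angstrom)  R ()" + ("  dR ()" if curve.dR is not None else "")
    lines.append(f"# columns: {cols}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for i in range(len(curve)):
            row = f"{curve.q[i]:.8e} {curve.R[i]:.8e}"
            if curve.dR is not None:
                row += f" {curve.dR[i]:.8e}"
            fh.write(row + "\n")


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def load_config(path) -> dict:
    """Load a flat YAML run configuration."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


def config_hash(obj) -> str:
    """Stable short hash of a configuration (for artifact provenance)."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
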