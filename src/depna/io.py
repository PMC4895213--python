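"""Delimited-text I/O for panels, matrices, manifests and graph exports.

All on-disk formats are plain text: CSV/TSV for signal panels and
matrices, CSV manifests listing a study's panel files, YAML/JSON for
simulation configs, GraphML plus BrainNet Viewer ``.node``/``.edge``
text files for graphs.  Every file the package writes can be read back
by the package.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .core import DegreeProfile
from .timeseries import NodeTimeSeries

__all__ = [
    "read_timeseries_table",
    "write_timeseries_table",
    "read_matrix",
    "write_matrix",
    "write_degrees",
    "read_manifest",
    "write_manifest",
    "load_condition_panels",
    "load_config",
    "write_graphml",
    "write_brainnet_node",
    "write_brainnet_edge",
    "circular_layout",
]

MANIFEST_VERSION = "1"
Orientation = Literal["nodes_as_columns", "nodes_as_rows"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_timeseries_table(
    path,
    orientation: Orientation = "nodes_as_columns",
    sampling_interval: float | None = None,
) -> NodeTimeSeries:
    """Read a delimited signal table with a header of node labels.

    Default orientation: columns are nodes, rows are timepoints.
    Errors name the offending node/line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"time-series file not found: {path}")
    if orientation not in ("nodes_as_columns", "nodes_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path)
    try:
        frame = pd.read_csv(path, sep=sep, header=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table: {exc}") from None
    if frame.isna().any().any():
        row = int(frame.isna().any(axis=1).idxmax())
        raise ValueError(
            f"{path}: ragged or missing cell at data line {row + 2}"
        )
    if orientation == "nodes_as_columns":
        labels = [str(c) for c in frame.columns]
        data = frame
    else:
        labels = [str(v) for v in frame.iloc[:, 0]]
        data = frame.iloc[:, 1:]
    numeric = data.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        mask = numeric.isna()
        row = int(mask.any(axis=1).idxmax())
        col = mask.loc[row].idxmax()
        raise ValueError(
            f"{path}: non-numeric value {data.loc[row, col]!r} in column "
            f"{col!r} at data line {row + 2}"
        )
    # numpy's string conversion is correctly rounded (bit-exact round trips)
    samples = data.to_numpy(dtype=float)
    if orientation == "nodes_as_columns":
        samples = samples.T
    try:
        return NodeTimeSeries(labels, samples, sampling_interval)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_timeseries_table(ts: NodeTimeSeries, path) -> Path:
    """Write a panel with nodes as columns, full float precision."""
    path = Path(path)
    frame = pd.DataFrame(ts.samples.T, columns=list(ts.node_ids))
    frame.to_csv(path, sep=_sep_for(path), index=False,
                 float_format="%.17g")
    return path


def read_matrix(path) -> tuple[list[str], np.ndarray]:
    """Read a labeled square matrix (labels in header and first column)."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                        float_precision="round_trip")
    labels = [str(c) for c in frame.columns]
    if [str(i) for i in frame.index] != labels:
        raise ValueError(f"{path}: row and column labels disagree")
    return labels, frame.to_numpy(dtype=float)


def write_matrix(node_ids: Sequence[str], values: np.ndarray, path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(values, index=list(node_ids), columns=list(node_ids))
    frame.to_csv(path, sep=_sep_for(path), float_format="%.17g")
    return path


def write_degrees(profile: DegreeProfile, out_dir, prefix: str = "") -> list[Path]:
    """Write each degree measure as a two-column (node, value) table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for measure in ("influencing", "influenced"):
        frame = pd.DataFrame(
            {"node": list(profile.node_ids),
             "value": getattr(profile, measure)}
        )
        p = out_dir / f"{prefix}{measure}_degree.csv"
        frame.to_csv(p, index=False, float_format="%.17g")
        written.append(p)
    return written


def write_manifest(rows: pd.DataFrame, path) -> Path:
    """Write a study manifest (subject, condition, block, file)."""
    required = ["subject", "condition", "block", "file"]
    missing = [c for c in required if c not in rows.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    path = Path(path)
    out = rows[required].copy()
    out.insert(0, "version", MANIFEST_VERSION)
    out.to_csv(path, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    """Read and validate a study manifest; file paths are resolved
    relative to the manifest's directory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    rows = pd.read_csv(path, dtype={"subject": str, "condition": str})
    required = ["subject", "condition", "block", "file"]
    missing = [c for c in required if c not in rows.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns: {missing}")
    dup = rows.duplicated(["subject", "condition", "block"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (subject, condition, block) at data line "
            f"{int(dup.idxmax()) + 2}"
        )
    rows["file"] = [
        str((path.parent / f).resolve()) if not Path(f).is_absolute() else f
        for f in rows["file"]
    ]
    for f in rows["file"]:
        if not Path(f).exists():
            raise FileNotFoundError(f"{path}: referenced panel missing: {f}")
    return rows


def load_condition_panels(
    manifest: pd.DataFrame,
    condition: str | None = None,
    blocks: Literal["average", "concatenate", "separate"] = "average",
) -> dict[str, list[NodeTimeSeries]]:
    """Load one condition's panels grouped by subject.

    ``blocks`` controls how a subject's repeated blocks are combined:
    pointwise average (default), concatenation along time, or kept
    separate.
    """
    from . import signal as _signal

    rows = manifest
    if condition is not None:
        rows = rows[rows["condition"] == condition]
        if rows.empty:
            raise ValueError(f"condition {condition!r} not in manifest")
    out: dict[str, list[NodeTimeSeries]] = {}
    for subject, grp in rows.groupby("subject", sort=True):
        panels = [
            read_timeseries_table(f)
            for f in grp.sort_values("block")["file"]
        ]
        if blocks == "average":
            out[subject] = [_signal.average_condition_blocks(panels)]
        elif blocks == "concatenate":
            out[subject] = [_signal.concatenate_blocks(panels)]
        else:
            out[subject] = panels
    labels = {tuple(p.node_ids) for ps in out.values() for p in ps}
    if len(labels) > 1:
        raise ValueError("manifest panels do not share node labels")
    return out


def load_config(path) -> dict:
    """Read a YAML or JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_graphml(graph: nx.DiGraph, path) -> Path:
    path = Path(path)
    nx.write_graphml(graph, path)
    return path


def circular_layout(node_ids: Sequence[str], radius: float = 50.0) -> np.ndarray:
    """Evenly spaced (x, y, z=0) coordinates on a circle, the default
    when no anatomical coordinate table is supplied."""
    n = len(node_ids)
    angles = 2 * np.pi * np.arange(n) / n
    return np.column_stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(n)]
    )


def write_brainnet_node(
    path,
    node_ids: Sequence[str],
    color_values: np.ndarray,
    size_values: np.ndarray | None = None,
    coordinates: np.ndarray | None = None,
) -> Path:
    """BrainNet Viewer ``.node`` file: x y z color size label."""
    path = Path(path)
    n = len(node_ids)
    if coordinates is None:
        coordinates = circular_layout(node_ids)
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != (n, 3):
        raise ValueError(f"coordinates must be ({n}, 3)")
    color_values = np.asarray(color_values, dtype=float)
    if size_values is None:
        size_values = color_values
    size_values = np.asarray(size_values, dtype=float)
    lines = []
    for i, label in enumerate(node_ids):
        x, y, z = coordinates[i]
        lines.append(
            f"{x:.4f}\t{y:.4f}\t{z:.4f}\t{color_values[i]:.6g}"
            f"\t{size_values[i]:.6g}\t{label}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_brainnet_edge(path, t_matrix: np.ndarray) -> Path:
    """BrainNet Viewer ``.edge`` file: square signed matrix, zeros for
    edges below threshold."""
    path = Path(path)
    t_matrix = np.asarray(t_matrix, dtype=float)
    if t_matrix.ndim != 2 or t_matrix.shape[0] != t_matrix.shape[1]:
        raise ValueError("edge matrix must be square")
    np.savetxt(path, t_matrix, fmt="%.6g", delimiter="\t")
    return path
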