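"""Delimited-text input, labelled CSV output, and condensed-tree JSON export."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .branches import FLASCResult

RESULT_HEADER = (
    "point,cluster_label,branch_label,label,"
    "cluster_probability,branch_probability,probability"
)


def read_matrix(path, delimiter: str = ",", header: bool = False) -> np.ndarray:
    """Read a rectangular numeric matrix; rows preserve file order.

    Raises a parse error naming the offending row for ragged or non-numeric
    input (rows are counted from 1, including any header line).
    """
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if header and lineno == 1:
                continue
            cells = line.split(delimiter)
            if width is None:
                width = len(cells)
            elif len(cells) != width:
                raise ValueError(
                    f"{path}: row {lineno} has {len(cells)} fields, expected {width}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as err:
                raise ValueError(f"{path}: row {lineno} is not numeric: {err}") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(rows, dtype=np.float64)


def write_result(result: FLASCResult, path) -> None:
    """Write one CSV row per point, in input order, with the fixed header."""
    n = len(result.labels)
    frame = pd.DataFrame(
        {
            "point": np.arange(n),
            "cluster_label": result.cluster_labels,
            "branch_label": result.branch_labels,
            "label": result.labels,
            "cluster_probability": result.cluster_probabilities,
            "branch_probability": result.branch_probabilities,
            "probability": result.probabilities,
        }
    )
    frame.to_csv(path, index=False)


def read_result(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_trees(result: FLASCResult, directory) -> list[Path]:
    """Emit the density condensed tree and each cluster's branch hierarchy
    as JSON sidecars; branch-tree point ids are global dataset indices."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    p = directory / "condensed_tree.json"
    p.write_text(result.condensed_tree.to_json())
    written.append(p)
    for ci, br in enumerate(result.branch_results):
        p = directory / f"branch_tree_cluster{ci}.json"
        doc = br.tree.to_dict(point_ids=br.graph.members, include_persistence=True)
        p.write_text(json.dumps(doc, indent=1))
        written.append(p)
    return written


def write_matrix(X: np.ndarray, path, labels: np.ndarray | None = None, delimiter: str = ",") -> None:
    """Write a point matrix (and optionally a companion label file)."""
    np.savetxt(path, X, delimiter=delimiter, fmt="%.10g")
    if labels is not None:
        np.savetxt(str(path) + ".labels", labels, fmt="%d")
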