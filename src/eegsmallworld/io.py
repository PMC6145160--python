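"""Plain-text I/O for cohorts, connectivity matrices and graphs.

Signals are stored as tab-delimited text (one row per channel), cohorts
as a directory of signal files plus a CSV manifest, connectivity
matrices as tab-delimited square matrices with a CSV index, and binary
graphs as "i j" edge lists with a JSON provenance sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .filtering import BinaryGraph
from .synthetic import SubjectRecording

MANIFEST_NAME = "manifest.csv"


class CohortIOError(IOError):
    pass


def write_cohort(cohort: list[SubjectRecording], directory: str | Path) -> Path:
    """Write one signal file per subject plus a manifest CSV; returns
    the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        rec.validate()
        fname = f"{rec.subject_id}.tsv"
        np.savetxt(directory / fname, rec.data, fmt="%.8e", delimiter="\t")
        rows.append({
            "subject_id": rec.subject_id,
            "group": rec.group,
            "fs": rec.fs,
            "n_channels": rec.data.shape[0],
            "channel_labels": "|".join(rec.channel_labels),
            "executive_time_s": rec.executive_time_s,
            "error_count": rec.error_count,
            "theta_coupling_deficit": (
                "" if rec.theta_coupling_deficit is None else rec.theta_coupling_deficit),
            "file": fname,
        })
    manifest = directory / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(directory: str | Path) -> list[SubjectRecording]:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = directory / MANIFEST_NAME
    if not manifest.exists():
        raise CohortIOError(f"manifest not found: {manifest}")
    try:
        table = pd.read_csv(manifest)
    except Exception as exc:  # malformed CSV
        raise CohortIOError(f"malformed manifest {manifest}: {exc}") from exc
    required = {"subject_id", "group", "fs", "n_channels", "executive_time_s",
                "error_count", "file"}
    missing = required - set(table.columns)
    if missing:
        raise CohortIOError(f"manifest {manifest} missing columns: {sorted(missing)}")
    cohort = []
    for row in table.itertuples(index=False):
        path = directory / row.file
        if not path.exists():
            raise CohortIOError(f"signal file missing: {path}")
        data = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
        if data.shape[0] != int(row.n_channels):
            raise CohortIOError(
                f"{path}: expected {int(row.n_channels)} channel rows, got {data.shape[0]}")
        labels = (str(row.channel_labels).split("|")
                  if "channel_labels" in table.columns and isinstance(row.channel_labels, str)
                  else [f"ch{c + 1:02d}" for c in range(data.shape[0])])
        deficit = getattr(row, "theta_coupling_deficit", None)
        deficit = None if deficit is None or (isinstance(deficit, float) and np.isnan(deficit)) else float(deficit)
        cohort.append(SubjectRecording(
            subject_id=str(row.subject_id), group=str(row.group), data=data,
            fs=float(row.fs), channel_labels=labels,
            executive_time_s=float(row.executive_time_s),
            error_count=int(row.error_count),
            theta_coupling_deficit=deficit,
        ))
    return cohort


def write_connectivity(m: ConnectivityMatrix, path: str | Path) -> None:
    np.savetxt(path, m.values, fmt="%.10e", delimiter="\t")


def read_connectivity(path: str | Path, band: str = "", subject_id: str = "") -> ConnectivityMatrix:
    values = np.loadtxt(path, delimiter="\t")
    m = ConnectivityMatrix(values=values, band=band, subject_id=subject_id)
    m.validate()
    return m


def write_graph(g: BinaryGraph, path: str | Path) -> None:
    """Edge list ("i j" per line, 0-based) plus a .json provenance
    sidecar recording n_nodes and how the graph was produced."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, j in g.edges:
            fh.write(f"{i} {j}\n")
    sidecar = {"n_nodes": g.n_nodes, **g.provenance}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_graph(path: str | Path) -> BinaryGraph:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise CohortIOError(f"provenance sidecar missing: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    n_nodes = int(sidecar.pop("n_nodes"))
    edges = []
    for line in path.read_text().splitlines():
        if line.strip():
            i, j = line.split()
            edges.append((int(i), int(j)))
    return BinaryGraph(n_nodes, tuple(sorted(edges)), sidecar)
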