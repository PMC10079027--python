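"""File formats: matrix TSV (+ JSON sidecar), endpoint TSV, NIfTI labels,
ranking and summary CSV.

All round-trips are lossless: floats are written with 17 significant digits
(numeric agreement to 1e-12), labels exactly.  Matrices are validated on
read (symmetry to a 1e-9 relative tolerance, zero diagonal, non-negative)
and malformed files are rejected with line-numbered errors.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .build import ConnectivityMatrix
from .centrality import RankingTable
from .synthetic import EndpointRecordSet, LabelVolume

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_endpoints",
    "read_endpoints",
    "write_label_volume",
    "read_label_volume",
    "write_rankings",
]

_FLOAT_FMT = "%.17g"


# -- connectivity matrices ---------------------------------------------------


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_matrix(matrix: ConnectivityMatrix, path, provenance: dict | None = None) -> None:
    """TSV with structure names as first row/column, plus a JSON sidecar
    carrying kind, node labels and provenance."""
    path = Path(path)
    names = list(matrix.node_names)
    with open(path, "w") as fh:
        fh.write("name\t" + "\t".join(names) + "\n")
        for name, row in zip(names, matrix.weights):
            fh.write(name + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")
    meta = {
        "kind": matrix.kind,
        "node_labels": [int(x) for x in matrix.node_labels],
        "provenance": provenance or {},
    }
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_matrix(path, sym_tol: float = 1e-9) -> ConnectivityMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "name":
            raise ValueError(f"{path}:1: expected header starting with 'name'")
        names = header[1:]
        n = len(names)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {n + 1} fields, got {len(parts)}"
                )
            if parts[0] != names[len(rows)]:
                raise ValueError(
                    f"{path}:{lineno}: row name {parts[0]!r} does not match "
                    f"column order ({names[len(rows)]!r} expected)"
                )
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric entry ({exc})") from None
    if len(rows) != n:
        raise ValueError(f"{path}: expected {n} rows, got {len(rows)}")
    w = np.array(rows)
    scale = max(1.0, float(np.abs(w).max()) if w.size else 1.0)
    if not np.allclose(w, w.T, rtol=0.0, atol=sym_tol * scale):
        raise ValueError(f"{path}: matrix is not symmetric within tolerance {sym_tol}")

    kind, labels = "raw", np.arange(1, n + 1, dtype=np.int64)
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        kind = meta.get("kind", "raw")
        if "node_labels" in meta:
            labels = np.asarray(meta["node_labels"], dtype=np.int64)
            if len(labels) != n:
                raise ValueError(f"{side}: node_labels length {len(labels)} != {n}")
    return ConnectivityMatrix(
        weights=w, node_labels=labels, node_names=tuple(names), kind=kind
    )


# -- endpoint records --------------------------------------------------------

_EP_COLS = ["subject", "run", "streamline_id", "x1", "y1", "z1", "x2", "y2", "z2", "traversed"]


def write_endpoints(record_sets: list[EndpointRecordSet] | EndpointRecordSet, path) -> None:
    """One TSV row per streamline; traversed labels semicolon-separated."""
    if isinstance(record_sets, EndpointRecordSet):
        record_sets = [record_sets]
    frames = []
    for rs in record_sets:
        n = len(rs)
        frames.append(
            pd.DataFrame(
                {
                    "subject": rs.subject_id,
                    "run": rs.run_id,
                    "streamline_id": np.arange(n),
                    "x1": rs.first_points[:, 0],
                    "y1": rs.first_points[:, 1],
                    "z1": rs.first_points[:, 2],
                    "x2": rs.last_points[:, 0],
                    "y2": rs.last_points[:, 1],
                    "z2": rs.last_points[:, 2],
                    "traversed": [
                        ";".join(str(x) for x in sorted(t)) for t in rs.traversed
                    ],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_endpoints(path) -> list[EndpointRecordSet]:
    """Read a TSV of endpoint records, grouped into one record set per
    (subject, run)."""
    df = pd.read_csv(path, sep="\t", dtype={"traversed": str}, keep_default_na=False)
    missing = [c for c in _EP_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for (subj, run), grp in df.groupby(["subject", "run"], sort=True):
        traversed = tuple(
            frozenset(int(x) for x in t.split(";") if x) for t in grp["traversed"]
        )
        out.append(
            EndpointRecordSet(
                first_points=grp[["x1", "y1", "z1"]].to_numpy(dtype=float),
                last_points=grp[["x2", "y2", "z2"]].to_numpy(dtype=float),
                traversed=traversed,
                subject_id=int(subj),
                run_id=int(run),
            )
        )
    return out


# -- label volumes -----------------------------------------------------------


def write_label_volume(label_volume: LabelVolume, path) -> None:
    img = nib.Nifti1Image(label_volume.grid.astype(np.int16), label_volume.affine)
    nib.save(img, str(path))


def read_label_volume(path) -> LabelVolume:
    img = nib.load(str(path))
    grid = np.asanyarray(img.dataobj).astype(np.int16)
    return LabelVolume(grid=grid, affine=np.asarray(img.affine, dtype=float))


# -- tables ------------------------------------------------------------------


def write_rankings(tables: list[RankingTable], path) -> None:
    """Concatenate ranking tables into one CSV (measure column present)."""
    pd.concat([t.rows for t in tables], ignore_index=True).to_csv(path, index=False)
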