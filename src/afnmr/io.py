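"""Text-format plumbing: spectra CSV, bucket TSV, library YAML, pathway JSON.

Dialects
--------
* Spectra matrix: CSV, first column ``ppm`` (ascending or descending;
  normalized to ascending internally), one column per sample.
* Group labels: TSV with columns ``sample_id`` and ``group``.
* Bucket table: TSV, first column ``sample_id``, remaining columns
  labelled ``lo-hi`` in ppm (4 decimals).
* Metabolite library: YAML list of records (name, multiplets, mean_conc, cv).
* Pathway DB: JSON with compound lists and edge lists per pathway.

Numbers are serialized with 12 significant digits so canonical files
round-trip byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .pathway import PathwayDB
from .preprocess import BucketTable, SpectraMatrix
from .synth import MetaboliteSpec, Multiplet

__all__ = [
    "read_spectra_csv", "write_spectra_csv",
    "read_labels_tsv", "write_labels_tsv",
    "read_bucket_tsv", "write_bucket_tsv",
    "read_library", "write_library",
    "read_pathway_db", "write_pathway_db",
]

_FMT = "%.12g"


def _fmt(x: float) -> str:
    return _FMT % x


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def write_spectra_csv(path: str | Path, matrix: SpectraMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("ppm," + ",".join(matrix.sample_ids) + "\n")
        for j in range(matrix.ppm.size):
            row = [_fmt(matrix.ppm[j])] + [
                _fmt(v) for v in matrix.intensities[:, j]
            ]
            fh.write(",".join(row) + "\n")


def read_spectra_csv(
    path: str | Path, groups: dict[str, str] | None = None
) -> SpectraMatrix:
    """Parse a spectra CSV; raises with a line number on ragged rows,
    non-monotone ppm, or duplicate sample ids."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        if header[0] != "ppm":
            raise ValueError(f"{path}: line 1: first column must be 'ppm'")
        ids = header[1:]
        dup = {s for s in ids if ids.count(s) > 1}
        if dup:
            raise ValueError(f"{path}: line 1: duplicate sample id {sorted(dup)[0]!r}")
        ncol = len(header)
        ppm, rows = [], []
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(",")
            if len(parts) != ncol:
                raise ValueError(
                    f"{path}: line {ln}: expected {ncol} fields, got {len(parts)}"
                )
            ppm.append(float(parts[0]))
            rows.append([float(v) for v in parts[1:]])
    ppm_arr = np.array(ppm)
    d = np.diff(ppm_arr)
    if not (np.all(d > 0) or np.all(d < 0)):
        bad = int(np.argmax(~(d > 0) if d[0] > 0 else ~(d < 0))) + 3
        raise ValueError(f"{path}: line {bad}: ppm column not monotone")
    X = np.array(rows).T  # samples x points
    if ppm_arr[0] > ppm_arr[-1]:  # normalize to ascending
        ppm_arr = ppm_arr[::-1].copy()
        X = X[:, ::-1].copy()
    grp = [groups.get(s, "term") if groups else "term" for s in ids]
    return SpectraMatrix(ppm=ppm_arr, intensities=X, sample_ids=ids, groups=grp)


def write_labels_tsv(path: str | Path, sample_ids: list[str], groups: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in zip(sample_ids, groups):
            fh.write(f"{s}\t{g}\n")


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["sample_id", "group"]:
        raise ValueError(f"{path}: expected columns sample_id, group")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return dict(zip(df["sample_id"], df["group"]))


# ---------------------------------------------------------------------------
# Bucket tables
# ---------------------------------------------------------------------------

def write_bucket_tsv(path: str | Path, table: BucketTable) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(table.labels) + "\n")
        for i, sid in enumerate(table.sample_ids):
            fh.write(sid + "\t" + "\t".join(_fmt(v) for v in table.values[i]) + "\n")


def read_bucket_tsv(
    path: str | Path, groups: dict[str, str] | None = None
) -> BucketTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    buckets = []
    for label in df.columns:
        lo, hi = label.rsplit("-", 1)
        buckets.append((float(lo), float(hi)))
    ids = [str(s) for s in df.index]
    return BucketTable(
        buckets=buckets,
        values=df.to_numpy(dtype=float),
        sample_ids=ids,
        groups=[groups.get(s, "term") if groups else "term" for s in ids],
    )


# ---------------------------------------------------------------------------
# Metabolite library
# ---------------------------------------------------------------------------

def write_library(path: str | Path, library: list[MetaboliteSpec]) -> None:
    records = [
        {
            "name": m.name,
            "mean_conc": m.mean_conc,
            "cv": m.cv,
            "multiplets": [
                {
                    "center_ppm": mu.center_ppm,
                    "relative_area": mu.relative_area,
                    "peak_count": mu.peak_count,
                    "splitting_hz": mu.splitting_hz,
                    "linewidth_hz": mu.linewidth_hz,
                }
                for mu in m.multiplets
            ],
        }
        for m in library
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(records, fh, sort_keys=False)


def read_library(path: str | Path) -> list[MetaboliteSpec]:
    with open(path) as fh:
        records = yaml.safe_load(fh)
    return [
        MetaboliteSpec(
            name=r["name"],
            mean_conc=float(r["mean_conc"]),
            cv=float(r.get("cv", 0.25)),
            multiplets=tuple(
                Multiplet(
                    center_ppm=float(mu["center_ppm"]),
                    relative_area=float(mu["relative_area"]),
                    peak_count=int(mu.get("peak_count", 1)),
                    splitting_hz=float(mu.get("splitting_hz", 0.0)),
                    linewidth_hz=float(mu.get("linewidth_hz", 1.5)),
                )
                for mu in r["multiplets"]
            ),
        )
        for r in records
    ]


# ---------------------------------------------------------------------------
# Pathway DB
# ---------------------------------------------------------------------------

def write_pathway_db(path: str | Path, db: PathwayDB) -> None:
    payload = {
        "universe": sorted(db.universe),
        "pathways": {
            name: {
                "compounds": sorted(members),
                "edges": sorted(
                    [sorted(e) for e in db.graphs[name].edges]
                ) if name in db.graphs else [],
            }
            for name, members in db.pathways.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_pathway_db(path: str | Path) -> PathwayDB:
    with open(path) as fh:
        payload = json.load(fh)
    pathways, graphs = {}, {}
    for name, rec in payload["pathways"].items():
        members = set(rec["compounds"])
        pathways[name] = members
        g = nx.Graph()
        g.add_nodes_from(sorted(members))
        g.add_edges_from(rec.get("edges", []))
        graphs[name] = g
    return PathwayDB(pathways=pathways, universe=set(payload["universe"]), graphs=graphs)
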