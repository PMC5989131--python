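"""Tabular, FASTQ and NEXUS input/output.

All tables are UTF-8 tab-separated with '.' decimals.  Count matrices are
feature rows x sample columns with the feature id in the first column;
distance matrices are written both as square TSV and PHYLIP-style lower
triangle; split systems go to a SplitsTree-compatible NEXUS Splits block.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio.stats.distance import DistanceMatrix

from .neighbornet import CircularSplitSystem

__all__ = [
    "read_count_matrix", "write_count_matrix",
    "read_metadata", "write_metadata",
    "read_distance_matrix", "write_distance_matrix", "write_phylip_lower",
    "read_fastq", "write_fastq",
    "write_nexus_splits", "read_nexus_splits", "write_edge_list",
]


def read_count_matrix(path) -> pd.DataFrame:
    """Read a feature-by-sample TSV, validating shape and values."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    ncol = len(header)
    if len(set(header[1:])) != ncol - 1:
        raise ValueError(f"{path}: duplicate sample ids in header")
    ids, data = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise ValueError(f"{path}:{lineno}: ragged row "
                             f"({len(row)} fields, expected {ncol})")
        ids.append(row[0])
        try:
            vals = [float(v) for v in row[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
        for j, v in enumerate(vals):
            if v < 0:
                raise ValueError(f"{path}:{lineno}: negative value in "
                                 f"column {header[j + 1]!r}")
        data.append(vals)
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate feature ids")
    return pd.DataFrame(data, index=pd.Index(ids, name=header[0] or "taxon"),
                        columns=header[1:], dtype=float)


def write_count_matrix(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t", index_label=m.index.name or "taxon")


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: metadata needs a sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    df = df.set_index("sample_id")
    if "replicate" in df.columns:
        df["replicate"] = df["replicate"].astype(int)
    return df


def write_metadata(md: pd.DataFrame, path) -> None:
    md.to_csv(path, sep="\t", index_label="sample_id")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.values, ids=[str(c) for c in df.columns])


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="sample_id")


def write_phylip_lower(dm: DistanceMatrix, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for i, sid in enumerate(dm.ids):
            vals = "\t".join(f"{dm.data[i, j]:.9g}" for j in range(i))
            fh.write(f"{sid}\t{vals}\n" if i else f"{sid}\n")


def read_fastq(path):
    """Parse FASTQ with record-indexed error reporting."""
    records = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            records.append(rec)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FASTQ near record "
                         f"{len(records) + 1}: {exc}") from exc
    return records


def write_fastq(records, path) -> None:
    SeqIO.write(records, str(path), "fastq")


def write_nexus_splits(css: CircularSplitSystem, path) -> None:
    """SplitsTree-compatible NEXUS with Taxa and weighted Splits blocks."""
    n = css.n
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("#NEXUS\n\nBEGIN Taxa;\n")
        fh.write(f"DIMENSIONS ntax={n};\nTAXLABELS\n")
        for i, sid in enumerate(css.ordering, 1):
            fh.write(f"[{i}] '{sid}'\n")
        fh.write(";\nEND;\n\nBEGIN Splits;\n")
        fh.write(f"DIMENSIONS ntax={n} nsplits={len(css.splits)};\n")
        fh.write("FORMAT labels=no weights=yes confidences=no intervals=no;\n")
        fh.write("CYCLE " + " ".join(str(i) for i in range(1, n + 1)) + ";\n")
        fh.write("MATRIX\n")
        for a, b, w in css.splits:
            side = " ".join(str(i + 1) for i in range(a, b + 1))
            fh.write(f"\t{w:.12g}\t{side},\n")
        fh.write(";\nEND;\n")


def read_nexus_splits(path) -> CircularSplitSystem:
    """Parse the NEXUS written by :func:`write_nexus_splits`."""
    taxa: list[str] = []
    splits: list[tuple[int, int, float]] = []
    mode = None
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if line.upper().startswith("TAXLABELS"):
            mode = "taxa"
            continue
        if line.upper().startswith("MATRIX"):
            mode = "splits"
            continue
        if line == ";":
            mode = None
            continue
        if mode == "taxa" and line.startswith("["):
            taxa.append(line.split("'")[1])
        elif mode == "splits" and line:
            body = line.rstrip(",")
            parts = body.split()
            w = float(parts[0])
            side = sorted(int(p) - 1 for p in parts[1:])
            if side != list(range(side[0], side[-1] + 1)):
                raise ValueError(f"split side {side} is not an interval")
            splits.append((side[0], side[-1], w))
    return CircularSplitSystem(ordering=taxa, splits=splits)


def write_edge_list(graph, path) -> None:
    """Splits-graph edges as TSV (node1, node2, weight, split_id)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("node1\tnode2\tweight\tsplit_id\n")
        for u, v, attrs in graph.edges(data=True):
            fh.write(f"{u}\t{v}\t{attrs['weight']:.12g}\t{attrs['split']}\n")
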