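"""Plain-text I/O: expression matrices and graphs as TSV/CSV.

Expression matrices are tabular, one row per gene, first column the gene
label, header row of timepoint labels; the delimiter follows the file
extension (.csv -> comma, anything else -> tab).  Graphs travel either as a
labelled square adjacency matrix or as a three-column edge list
(node, node, weight); triangular adjacency input is completed by symmetry
and full-precision decimal serialization makes write/read round trips exact.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .network import WeightedGraph

__all__ = [
    "RunConfig",
    "read_timeseries",
    "write_timeseries",
    "read_graph",
    "write_graph",
]


class DataError(ValueError):
    """Malformed input data (bad cell, ragged row, inconsistent graph...)."""


@dataclass
class RunConfig:
    """A full description of one inference run, serializable to plain text.

    Round-trips through a flat ``key=value`` format so that any result can
    be reproduced from its logged configuration plus the seed.  Parameter
    validity is delegated to the owning modules (MicParams,
    SoftThresholdConfig, ...) when the values are used.
    """

    measure: str = "dtwmic"
    mic_alpha: float = 0.6
    mic_c: float = 15.0
    beta: float = 6.0
    tau: float | None = None
    seed: int | None = None
    verbosity: int = 0

    def to_text(self) -> str:
        lines = []
        for key, value in vars(self).items():
            lines.append(f"{key}={'' if value is None else value}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        casts = {f.name: f for f in fields(cls)}
        kwargs: dict[str, object] = {}
        for ln, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise DataError(f"config line {ln}: expected key=value, got {raw!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key not in casts:
                raise DataError(f"config line {ln}: unknown key {key!r}")
            if value == "":
                kwargs[key] = None
            elif key == "measure":
                kwargs[key] = value
            elif key in ("seed", "verbosity"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)

    def save(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_text(Path(path).read_text())


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_timeseries(path, transpose: bool = False) -> pd.DataFrame:
    """Read a gene-by-timepoint matrix; genes in rows unless `transpose`."""
    path = Path(path)
    sep = _sep_for(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except Exception as exc:
        raise DataError(f"{path}: cannot parse table: {exc}") from exc
    if transpose:
        df = df.T
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"{path}: duplicate gene labels {dups}")
    if df.shape[1] < 2:
        raise DataError(f"{path}: need at least 2 timepoints, found {df.shape[1]}")
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"{path}: non-numeric or missing cell at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    # python float() is correctly rounded, so write/read round trips exactly
    return df.map(float)


def write_timeseries(data: pd.DataFrame, path) -> None:
    path = Path(path)
    data.to_csv(path, sep=_sep_for(path), float_format=None)


def _looks_like_edgelist(path: Path, sep: str) -> bool:
    with open(path, newline="") as fh:
        first = next(csv.reader(fh, delimiter=sep), None)
    if first is None:
        raise DataError(f"{path}: empty file")
    # adjacency header starts with an empty corner cell; edge lists have
    # exactly three populated fields per line
    return len(first) == 3 and first[0] != ""


def read_graph(path, fmt: str | None = None, nodes=None) -> WeightedGraph:
    """Read a graph from an adjacency matrix or an edge list.

    fmt
        'adjacency', 'edgelist', or None to auto-detect.
    nodes
        Optional node label order; required to place isolated nodes when
        reading an edge list, and used to validate endpoints.
    """
    path = Path(path)
    sep = _sep_for(path)
    if fmt is None:
        fmt = "edgelist" if _looks_like_edgelist(path, sep) else "adjacency"
    if fmt == "adjacency":
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        if [str(x) for x in df.index] != [str(x) for x in df.columns]:
            raise DataError(f"{path}: adjacency row and column labels differ")
        a = df.to_numpy(dtype=float)
        lower, upper = np.tril(a, -1), np.triu(a, 1)
        if not np.count_nonzero(lower):
            a = upper + upper.T
        elif not np.count_nonzero(upper):
            a = lower + lower.T
        elif not np.allclose(a, a.T, atol=1e-9):
            raise DataError(f"{path}: adjacency matrix is not symmetric")
        np.fill_diagonal(a, 0.0)
        try:
            return WeightedGraph(a, tuple(str(x) for x in df.index))
        except ValueError as exc:
            raise DataError(f"{path}: {exc}") from exc
    if fmt != "edgelist":
        raise ValueError(f"unknown graph format {fmt!r}")

    weights: dict[tuple[str, str], float] = {}
    order: list[str] = list(nodes) if nodes is not None else []
    known = set(order)
    with open(path, newline="") as fh:
        for ln, row in enumerate(csv.reader(fh, delimiter=sep), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise DataError(f"{path}:{ln}: expected 'node node weight'")
            u, v, w = row[0].strip(), row[1].strip(), row[2].strip()
            if ln == 1 and u.lower() in ("node1", "source", "from"):
                continue  # optional header
            try:
                weight = float(w)
            except ValueError as exc:
                raise DataError(f"{path}:{ln}: bad weight {w!r}") from exc
            if u == v:
                raise DataError(f"{path}:{ln}: self-loop on node {u!r}")
            for node in (u, v):
                if nodes is not None:
                    if node not in known:
                        raise DataError(f"{path}:{ln}: unknown node {node!r}")
                elif node not in known:
                    known.add(node)
                    order.append(node)
            key = (u, v) if u <= v else (v, u)
            if key in weights and weights[key] != weight:
                raise DataError(
                    f"{path}:{ln}: conflicting duplicate weight for edge {u}-{v}"
                )
            weights[key] = weight
    if len(order) < 2:
        raise DataError(f"{path}: graph needs at least 2 nodes")
    index = {lab: i for i, lab in enumerate(order)}
    a = np.zeros((len(order), len(order)))
    for (u, v), weight in weights.items():
        a[index[u], index[v]] = a[index[v], index[u]] = weight
    try:
        return WeightedGraph(a, tuple(order))
    except ValueError as exc:
        raise DataError(f"{path}: {exc}") from exc


def graph_text(G: WeightedGraph, fmt: str = "adjacency", sep: str = "\t") -> str:
    """Serialize a graph with full-precision decimal weights."""
    lines = []
    if fmt == "adjacency":
        lines.append(sep.join([""] + list(G.labels)))
        for lab, row in zip(G.labels, G.adjacency):
            lines.append(sep.join([lab] + [repr(float(w)) for w in row]))
    elif fmt == "edgelist":
        n = G.n
        for i in range(n):
            for j in range(i + 1, n):
                w = G.adjacency[i, j]
                if w != 0.0:
                    lines.append(sep.join([G.labels[i], G.labels[j], repr(float(w))]))
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
    return "\n".join(lines) + "\n"


def write_graph(G: WeightedGraph, path, fmt: str = "adjacency") -> None:
    """Write a graph with full-precision decimal weights."""
    path = Path(path)
    path.write_text(graph_text(G, fmt, _sep_for(path)))
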