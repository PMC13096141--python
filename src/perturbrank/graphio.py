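"""Directed molecular interaction graphs and pathway gene sets.

The interaction graph is the substrate every downstream stage works on:
feature propagation runs over its row-normalized adjacency, topological
features use its shortest paths, and the enrichment score uses its node
count as the hypergeometric population size M.

Edges are typed (ppi, signaling, regulatory, ligand_receptor, unknown) and
optionally signed (+1 activation, -1 inhibition, 0 unknown). Types and signs
are stored as metadata; propagation itself uses a single unsigned adjacency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

EDGE_TYPES = ("ppi", "signaling", "regulatory", "ligand_receptor", "unknown")

_SIGN_ALIASES = {
    "+1": 1, "1": 1, "activation": 1, "+": 1,
    "-1": -1, "−1": -1, "inhibition": -1, "-": -1,
    "0": 0, "unknown": 0, "": 0,
}


class GraphFormatError(ValueError):
    """Raised when an edge table or GMT file violates the expected dialect."""


@dataclass
class InteractionGraph:
    """Directed protein graph with typed, optionally signed edges.

    ``node_ids`` fixes the node ordering (first appearance in the edge
    table); every adjacency matrix and feature-matrix row downstream uses
    this ordering. Duplicate (source, target, type) triples are collapsed.
    """

    node_ids: list[str]
    edges: list[tuple[int, int, str, int]]  # (src_idx, tgt_idx, type, sign)

    def __post_init__(self) -> None:
        if len(set(self.node_ids)) != len(self.node_ids):
            raise GraphFormatError("node identifiers must be unique")
        n = len(self.node_ids)
        seen: set[tuple[int, int, str]] = set()
        deduped = []
        for s, t, typ, sign in self.edges:
            if not (0 <= s < n and 0 <= t < n):
                raise GraphFormatError(f"edge endpoint out of range: ({s}, {t})")
            key = (s, t, typ)
            if key in seen:
                continue
            seen.add(key)
            deduped.append((s, t, typ, sign))
        self.edges = deduped
        self._index = {nid: i for i, nid in enumerate(self.node_ids)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, node_id: str) -> int:
        return self._index[node_id]

    def adjacency(self, signed: bool = False) -> sp.csr_matrix:
        """Sparse adjacency; unsigned entries are 1, signed use edge sign.

        Edges with unknown sign contribute +1 in signed mode so that they
        still carry influence (an unsigned interaction is treated as
        activating for ground-truth simulation purposes).
        """
        n = self.n_nodes
        if not self.edges:
            return sp.csr_matrix((n, n))
        rows, cols, vals = [], [], []
        for s, t, _typ, sign in self.edges:
            rows.append(s)
            cols.append(t)
            vals.append(float(sign) if (signed and sign != 0) else 1.0)
        # duplicate (s,t) pairs across types sum; clip unsigned back to 1
        mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        if not signed:
            mat.data = np.minimum(mat.data, 1.0)
        return mat

    def out_neighbors(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        seen = set()
        for s, t, _typ, _sign in self.edges:
            if (s, t) not in seen:
                seen.add((s, t))
                adj[s].append(t)
        return adj


@dataclass
class NormalizedAdjacency:
    """Row-stochastic (random-walk) normalized adjacency.

    Every row either sums to 1 or is all-zero (sink nodes in the chosen
    direction). ``direction='reverse'`` normalizes the transposed edge
    structure, i.e. propagation against edge direction.
    """

    direction: str
    matrix: sp.csr_matrix
    mode: str = "row_stochastic"

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def normalize_adjacency(
    graph: InteractionGraph, direction: str = "forward"
) -> NormalizedAdjacency:
    """Row-normalize the (possibly transposed) unsigned adjacency."""
    if graph.n_nodes == 0:
        raise GraphFormatError("cannot normalize an empty graph")
    if direction not in ("forward", "reverse"):
        raise ValueError(f"direction must be forward or reverse, got {direction!r}")
    A = graph.adjacency(signed=False)
    if direction == "reverse":
        A = A.T.tocsr()
    return NormalizedAdjacency(direction, _row_normalize(A))


def _row_normalize(A: sp.spmatrix) -> sp.csr_matrix:
    A = sp.csr_matrix(A, dtype=float)
    rowsum = np.asarray(abs(A).sum(axis=1)).ravel()
    inv = np.divide(1.0, rowsum, out=np.zeros_like(rowsum), where=rowsum > 0)
    return sp.diags(inv) @ A


# ---------------------------------------------------------------------------
# Edge-table I/O
# ---------------------------------------------------------------------------

def read_edge_table(
    path: str | Path,
    id_columns: Mapping[str, str] | None = None,
) -> InteractionGraph:
    """Read a delimited edge table into an :class:`InteractionGraph`.

    Requires ``source`` and ``target`` columns (renameable through
    ``id_columns``); optional ``type`` and ``sign`` columns. Unrecognized
    type/sign values map to ``unknown``/0. Node ordering follows first
    appearance scanning rows top to bottom, source before target.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    if id_columns:
        df = df.rename(columns=dict(id_columns))
    if df.empty:
        raise GraphFormatError(f"{path}: empty edge table")
    for col in ("source", "target"):
        if col not in df.columns:
            raise GraphFormatError(f"{path}: missing required column {col!r}")
    return _graph_from_frame(df)


def _graph_from_frame(df: pd.DataFrame) -> InteractionGraph:
    node_ids: list[str] = []
    index: dict[str, int] = {}

    def intern(nid: str) -> int:
        if nid not in index:
            index[nid] = len(node_ids)
            node_ids.append(nid)
        return index[nid]

    has_type = "type" in df.columns
    has_sign = "sign" in df.columns
    edges = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        s = intern(str(d["source"]))
        t = intern(str(d["target"]))
        typ = str(d["type"]).strip().lower() if has_type else "unknown"
        if typ not in EDGE_TYPES:
            typ = "unknown"
        sign = _SIGN_ALIASES.get(str(d["sign"]).strip().lower(), 0) if has_sign else 0
        edges.append((s, t, typ, sign))
    return InteractionGraph(node_ids, edges)


def write_edge_table(graph: InteractionGraph, path: str | Path) -> None:
    path = Path(path)
    rows = [
        {
            "source": graph.node_ids[s],
            "target": graph.node_ids[t],
            "type": typ,
            "sign": sign,
        }
        for s, t, typ, sign in graph.edges
    ]
    pd.DataFrame(rows, columns=["source", "target", "type", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def graph_summary(graph: InteractionGraph) -> dict:
    """JSON-serializable summary: node/edge counts plus out-degree histogram."""
    out_deg = np.zeros(graph.n_nodes, dtype=int)
    for s, _t, _typ, _sign in graph.edges:
        out_deg[s] += 1
    hist: dict[str, int] = {}
    for d in out_deg:
        hist[str(int(d))] = hist.get(str(int(d)), 0) + 1
    return {
        "n_nodes": graph.n_nodes,
        "n_edges": graph.n_edges,
        "out_degree_histogram": hist,
    }


def write_graph_summary(graph: InteractionGraph, path: str | Path) -> None:
    Path(path).write_text(json.dumps(graph_summary(graph), indent=2))


# ---------------------------------------------------------------------------
# Pathway gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class PathwayCollection:
    """Named gene sets (pathway_id -> member proteins) with a role label.

    Members outside the graph's node set are allowed; consumers intersect
    with the graph at use time. Empty gene sets are rejected.
    """

    gene_sets: dict[str, set[str]]
    label: str = "pathways"

    def __post_init__(self) -> None:
        for name, members in self.gene_sets.items():
            if not members:
                raise GraphFormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.gene_sets)

    def membership_matrix(self, node_ids: Sequence[str]) -> np.ndarray:
        """Dense n_nodes x n_sets 0/1 membership matrix in graph order."""
        idx = {nid: i for i, nid in enumerate(node_ids)}
        M = np.zeros((len(node_ids), len(self.gene_sets)))
        for j, members in enumerate(self.gene_sets.values()):
            for m in members:
                if m in idx:
                    M[idx[m], j] = 1.0
        return M


def read_gene_sets(path: str | Path, label: str | None = None) -> PathwayCollection:
    """Read a standard GMT file: name TAB description TAB member TAB member..."""
    path = Path(path)
    gene_sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GraphFormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name = fields[0]
            gene_sets[name] = {f for f in fields[2:] if f}
    return PathwayCollection(gene_sets, label or path.stem)


def write_gene_sets(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.gene_sets.items():
            fh.write("\t".join([name, collection.label, *sorted(members)]) + "\n")
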