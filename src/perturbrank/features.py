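"""Per-protein feature engineering: propagation, topology, expansion, scaling.

Stage 1 of the framework. From a (graph, initial state, DETF set) triple it
builds one feature row per protein:

1. base features X: baseline expression and the signed DETF status label;
2. SIGN-style propagation Z = [X | A_fwd^1 X .. A_fwd^K X | A_rev^1 X .. A_rev^K X];
3. eight row-wise summary statistics over the propagated block, per base feature;
4. three topological features relating each protein to the DETF source set;
5. full degree-2 polynomial expansion;
6. constant-column pruning and column-wise min-max normalization;
7. optional cluster-balanced row subsampling for training-set construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import json
import numpy as np
import pandas as pd
from sklearn.cluster import MiniBatchKMeans

from .graphio import InteractionGraph, NormalizedAdjacency, PathwayCollection

_EPS_LFC = 1e-6
CONST_TOL = 1e-12

STAGES = ("raw", "propagated", "summarized", "expanded", "normalized", "decoded", "latent")


class AlignmentError(ValueError):
    """Inputs indexed over mismatched protein universes or dimensions."""


@dataclass
class DETFSet:
    """Signed differentially-expressed-TF labels (+1 up, -1 down).

    Proteins absent from ``labels`` are implicitly 0. When ``capped`` the
    set has been subsampled to at most the propagation source cap.
    """

    labels: dict[str, int]
    tf_universe: set[str]
    capped: bool = False
    cap_seed: int | None = None

    def __post_init__(self) -> None:
        bad = set(self.labels) - self.tf_universe
        if bad:
            raise AlignmentError(f"DETF labels outside TF universe: {sorted(bad)[:5]}")
        if any(v not in (-1, 1) for v in self.labels.values()):
            raise ValueError("DETF labels must be +1 or -1")

    def __len__(self) -> int:
        return len(self.labels)

    def label_vector(self, node_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.labels.get(nid, 0) for nid in node_ids], dtype=float)


@dataclass
class FeatureMatrix:
    """Protein-by-feature matrix with a pipeline stage tag.

    ``col_bounds`` holds fitted per-column (min, max) after normalization so
    held-out rows can be transformed consistently (and clipped to [0, 1]).
    """

    row_ids: list[str]
    col_names: list[str]
    values: np.ndarray
    stage: str = "raw"
    col_bounds: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.row_ids), len(self.col_names)):
            raise AlignmentError(
                f"shape {self.values.shape} != ({len(self.row_ids)}, {len(self.col_names)})"
            )
        if len(set(self.col_names)) != len(self.col_names):
            raise ValueError("column names must be unique")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.row_ids, columns=self.col_names)
        df.index.name = "protein_id"
        df.to_csv(path, sep="\t")
        sidecar = {"stage": self.stage}
        if self.col_bounds is not None:
            sidecar["col_min"] = self.col_bounds[0].tolist()
            sidecar["col_max"] = self.col_bounds[1].tolist()
        Path(str(path) + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        sidecar_path = Path(str(path) + ".json")
        stage, bounds = "raw", None
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            stage = meta.get("stage", "raw")
            if "col_min" in meta:
                bounds = (np.array(meta["col_min"]), np.array(meta["col_max"]))
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy(),
                   stage=stage, col_bounds=bounds)


# ---------------------------------------------------------------------------
# DETF derivation and capping
# ---------------------------------------------------------------------------

def compute_detfs(
    initial_state: Mapping[str, float] | pd.Series,
    final_state: Mapping[str, float] | pd.Series,
    tf_universe: set[str],
    lfc_threshold: float = 1.0,
    min_expr: float = 0.0,
) -> DETFSet:
    """Label TFs up (+1) / down (-1) by thresholded log2 fold change.

    A TF is labeled +1 when log2((final+eps)/(initial+eps)) >= lfc_threshold
    and -1 at <= -lfc_threshold; proteins whose expression is below
    ``min_expr`` in both states are never labeled.
    """
    init = pd.Series(initial_state, dtype=float)
    fin = pd.Series(final_state, dtype=float)
    if set(init.index) != set(fin.index):
        raise AlignmentError("initial and final states cover different proteins")
    fin = fin.reindex(init.index)
    labels: dict[str, int] = {}
    for tf in tf_universe:
        if tf not in init.index:
            continue
        a, b = init[tf], fin[tf]
        if a < min_expr and b < min_expr:
            continue
        lfc = np.log2((b + _EPS_LFC) / (a + _EPS_LFC))
        if lfc >= lfc_threshold:
            labels[tf] = 1
        elif lfc <= -lfc_threshold:
            labels[tf] = -1
    return DETFSet(labels, set(tf_universe))


def cap_detfs(detfs: DETFSet, max_sources: int = 100, seed: int = 0) -> DETFSet:
    """Randomly subsample the DETF set to at most ``max_sources`` labels.

    Too many simultaneous propagation sources saturate the graph; the cap
    keeps downstream nodes distinguishable by signaling proximity.
    """
    if max_sources < 1:
        raise ValueError("max_sources must be >= 1")
    if len(detfs) <= max_sources:
        return replace(detfs, capped=True, cap_seed=seed)
    rng = np.random.default_rng(seed)
    keys = sorted(detfs.labels)
    keep = rng.choice(len(keys), size=max_sources, replace=False)
    kept = {keys[i]: detfs.labels[keys[i]] for i in sorted(keep)}
    return DETFSet(kept, set(detfs.tf_universe), capped=True, cap_seed=seed)


# ---------------------------------------------------------------------------
# Propagation and summaries
# ---------------------------------------------------------------------------

def base_features(
    graph: InteractionGraph,
    expression: Mapping[str, float] | pd.Series,
    detfs: DETFSet,
) -> FeatureMatrix:
    """Two-column base matrix X: baseline expression and DETF status."""
    expr = pd.Series(expression, dtype=float)
    missing = [n for n in graph.node_ids if n not in expr.index]
    if missing:
        raise AlignmentError(f"expression missing for nodes: {missing[:5]}")
    X = np.column_stack(
        [expr.reindex(graph.node_ids).to_numpy(), detfs.label_vector(graph.node_ids)]
    )
    return FeatureMatrix(list(graph.node_ids), ["expr", "detf"], X, stage="raw")


def propagate(
    X: FeatureMatrix,
    A_fwd: NormalizedAdjacency,
    A_rev: NormalizedAdjacency,
    K: int = 5,
) -> FeatureMatrix:
    """SIGN-style multi-hop embedding Z = [X | {A_fwd^k X} | {A_rev^k X}].

    Output width is d*(2K+1) for d base columns; column names encode
    direction, hop and base feature. Directions follow the message-passing
    convention: a ``fwd`` hop gathers values from successors (so the
    downstream influence of a DETF on the nodes below it shows up in the
    ``rev`` columns, which gather from predecessors).
    """
    n, d = X.shape
    if A_fwd.n != n or A_rev.n != n:
        raise AlignmentError("adjacency dimension does not match feature rows")
    blocks = [X.values]
    names = list(X.col_names)
    for direction, A in (("fwd", A_fwd.matrix), ("rev", A_rev.matrix)):
        cur = X.values
        for k in range(1, K + 1):
            cur = A @ cur
            blocks.append(cur)
            names.extend(f"{direction}{k}_{c}" for c in X.col_names)
    return FeatureMatrix(list(X.row_ids), names, np.hstack(blocks), stage="propagated")


def summarize_propagation(Z: FeatureMatrix) -> FeatureMatrix:
    """Append 8 row-wise statistics over each base feature's propagated columns.

    Statistics: sum, mean, max, min, median, population standard deviation,
    25th and 75th percentiles (linear interpolation), computed across the
    2K propagated columns of each base feature (the raw X block excluded).
    """
    if Z.stage != "propagated":
        raise ValueError("summarize_propagation expects a propagated matrix")
    base = [c for c in Z.col_names if not (c.startswith("fwd") or c.startswith("rev"))]
    out_vals = [Z.values]
    out_names = list(Z.col_names)
    for b in base:
        cols = [i for i, c in enumerate(Z.col_names)
                if (c.startswith("fwd") or c.startswith("rev")) and c.endswith("_" + b)]
        if not cols:
            raise ValueError(f"no propagated columns found for base feature {b!r}")
        block = Z.values[:, cols]
        stats = np.column_stack([
            block.sum(axis=1),
            block.mean(axis=1),
            block.max(axis=1),
            block.min(axis=1),
            np.median(block, axis=1),
            block.std(axis=1),  # population form
            np.percentile(block, 25, axis=1),
            np.percentile(block, 75, axis=1),
        ])
        out_vals.append(stats)
        out_names.extend(
            f"{b}_{s}" for s in ("sum", "mean", "max", "min", "median", "std", "p25", "p75")
        )
    return FeatureMatrix(list(Z.row_ids), out_names, np.hstack(out_vals), stage="summarized")


# ---------------------------------------------------------------------------
# Topological features
# ---------------------------------------------------------------------------

def topological_features(
    graph: InteractionGraph,
    detfs: DETFSet,
    pathways: PathwayCollection | Sequence[PathwayCollection],
) -> FeatureMatrix:
    """Three DETF-relative network features per protein.

    * ``shared_pathways`` — sum over DETFs of the number of gene sets
      containing both the protein and that DETF;
    * ``min_path`` — shortest directed path length from the protein to the
      nearest reachable DETF (sentinel = n_nodes when none is reachable);
    * ``reachable_pct`` — percentage of DETFs reachable from the protein.

    An empty DETF set yields all-zero features (degenerate but valid input).
    """
    n = graph.n_nodes
    node_ids = graph.node_ids
    vals = np.zeros((n, 3))
    vals[:, 1] = 0.0
    if len(detfs) > 0:
        collections = [pathways] if isinstance(pathways, PathwayCollection) else list(pathways)
        detf_idx = [graph.index_of(t) for t in sorted(detfs.labels) if t in graph._index]

        # (i) shared pathway counts: membership @ membership^T restricted to DETFs
        shared = np.zeros(n)
        for coll in collections:
            if len(coll) == 0:
                continue
            memb = coll.membership_matrix(node_ids)  # n x n_sets
            if detf_idx:
                shared += memb @ memb[detf_idx].sum(axis=0)
        vals[:, 0] = shared

        # (ii)+(iii) distances: BFS from each DETF over reversed edges gives
        # the directed distance from every protein to that DETF
        rev_adj: list[list[int]] = [[] for _ in range(n)]
        for s, t, _typ, _sign in graph.edges:
            rev_adj[t].append(s)
        min_dist = np.full(n, np.inf)
        reach_count = np.zeros(n)
        for src in detf_idx:
            dist = np.full(n, -1, dtype=int)
            dist[src] = 0
            frontier = [src]
            while frontier:
                nxt = []
                for u in frontier:
                    for v in rev_adj[u]:
                        if dist[v] < 0:
                            dist[v] = dist[u] + 1
                            nxt.append(v)
                frontier = nxt
            reached = dist >= 0
            reach_count += reached
            min_dist = np.where(reached, np.minimum(min_dist, dist), min_dist)
        n_detf_in_graph = len(detf_idx)
        if n_detf_in_graph:
            vals[:, 1] = np.where(np.isfinite(min_dist), min_dist, n)
            vals[:, 2] = 100.0 * reach_count / len(detfs)
        else:
            vals[:, 1] = n
    return FeatureMatrix(
        list(node_ids), ["shared_pathways", "min_path", "reachable_pct"], vals,
        stage="summarized",
    )


def concat_features(*mats: FeatureMatrix, stage: str | None = None) -> FeatureMatrix:
    """Column-concatenate feature matrices sharing identical row ids."""
    first = mats[0]
    for m in mats[1:]:
        if m.row_ids != first.row_ids:
            raise AlignmentError("row ids differ between concatenated matrices")
    return FeatureMatrix(
        list(first.row_ids),
        [c for m in mats for c in m.col_names],
        np.hstack([m.values for m in mats]),
        stage=stage or first.stage,
    )


# ---------------------------------------------------------------------------
# Expansion, pruning, scaling, subsampling
# ---------------------------------------------------------------------------

def polynomial_expand(F: FeatureMatrix, degree: int = 2) -> FeatureMatrix:
    """Full degree-2 polynomial basis: bias, linear, squares and interactions."""
    if degree != 2:
        raise ValueError("only degree-2 expansion is supported")
    if F.stage != "summarized":
        raise ValueError("polynomial_expand expects a summarized matrix")
    from sklearn.preprocessing import PolynomialFeatures

    poly = PolynomialFeatures(degree=2, interaction_only=False, include_bias=True)
    vals = poly.fit_transform(F.values)
    names = [n.replace(" ", "*") for n in poly.get_feature_names_out(F.col_names)]
    return FeatureMatrix(list(F.row_ids), names, vals, stage="expanded")


def drop_constant_features(F: FeatureMatrix) -> FeatureMatrix:
    """Remove columns whose range (max - min) is below tolerance."""
    rng = F.values.max(axis=0) - F.values.min(axis=0)
    keep = np.where(rng > CONST_TOL)[0]
    if keep.size == 0:
        raise ValueError("all feature columns are constant")
    return FeatureMatrix(
        list(F.row_ids), [F.col_names[i] for i in keep], F.values[:, keep], stage=F.stage
    )


def minmax_normalize(F: FeatureMatrix) -> FeatureMatrix:
    """Column-wise min-max scaling to [0, 1]; fitted bounds retained."""
    lo = F.values.min(axis=0)
    hi = F.values.max(axis=0)
    if np.any(hi - lo <= CONST_TOL):
        bad = [F.col_names[i] for i in np.where(hi - lo <= CONST_TOL)[0][:3]]
        raise ZeroDivisionError(
            f"constant columns {bad}; run drop_constant_features first"
        )
    vals = (F.values - lo) / (hi - lo)
    return FeatureMatrix(list(F.row_ids), list(F.col_names), vals,
                         stage="normalized", col_bounds=(lo, hi))


def apply_normalization(F: FeatureMatrix, fitted: FeatureMatrix) -> FeatureMatrix:
    """Transform held-out rows with bounds fitted elsewhere (clipped to [0,1])."""
    if fitted.col_bounds is None:
        raise ValueError("fitted matrix carries no column bounds")
    if F.col_names != fitted.col_names:
        raise AlignmentError("column names differ from the fitted matrix")
    lo, hi = fitted.col_bounds
    vals = np.clip((F.values - lo) / (hi - lo), 0.0, 1.0)
    return FeatureMatrix(list(F.row_ids), list(F.col_names), vals,
                         stage="normalized", col_bounds=(lo, hi))


def cluster_subsample(
    F: FeatureMatrix,
    k: int = 50,
    per_cluster: int | None = 100,
    seed: int = 0,
) -> np.ndarray:
    """Cluster-balanced row subsample via seeded mini-batch k-means.

    Returns sorted row indices; ``per_cluster=None`` keeps every row (the
    identity subsample). From each non-empty cluster, min(per_cluster, size)
    rows are drawn without replacement.
    """
    n = F.shape[0]
    if per_cluster is None:
        return np.arange(n)
    if per_cluster < 1:
        raise ValueError("per_cluster must be >= 1")
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    km = MiniBatchKMeans(n_clusters=k, random_state=seed, n_init=3, batch_size=256)
    assign = km.fit_predict(F.values)
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for c in range(k):
        members = np.where(assign == c)[0]
        if members.size == 0:
            continue
        take = min(per_cluster, members.size)
        chosen.append(rng.choice(members, size=take, replace=False))
    return np.sort(np.concatenate(chosen))


# ---------------------------------------------------------------------------
# Stage-1 pipeline
# ---------------------------------------------------------------------------

def build_feature_matrix(
    graph: InteractionGraph,
    expression: Mapping[str, float] | pd.Series,
    detfs: DETFSet,
    pathways: PathwayCollection | Sequence[PathwayCollection],
    A_fwd: NormalizedAdjacency,
    A_rev: NormalizedAdjacency,
    K: int = 5,
    detf_cap: int = 100,
    cap_seed: int = 0,
) -> FeatureMatrix:
    """Run the full embedding pipeline up to the expanded (un-normalized) stage.

    Normalization is deliberately left to the caller: training stacks rows
    from many perturbation datasets, prunes constants and fits the min-max
    bounds jointly, then applies them to held-out datasets.
    """
    capped = cap_detfs(detfs, max_sources=detf_cap, seed=cap_seed)
    X = base_features(graph, expression, capped)
    Z = propagate(X, A_fwd, A_rev, K=K)
    S = summarize_propagation(Z)
    T = topological_features(graph, capped, pathways)
    combined = concat_features(S, T, stage="summarized")
    return polynomial_expand(combined)
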