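"""Synthetic signaling worlds with planted drug targets and ground truth.

The generator emulates the statistical shape of the framework's real
inputs — a dense, heavy-tailed signed signaling graph; pathway gene sets;
drugs with a handful of annotated direct targets; and perturbation
transcriptomes whose differentially expressed TFs arise causally from the
planted targets — so that every pipeline stage and the full benchmark run
without any external download.

Mechanics: each drug's targets receive their annotated effect (+1/-1);
signed influence propagates along the row-normalized signed adjacency for
K = 5 hops with a 0.5 decay per hop; final expression multiplies initial
(log-normal) expression by 2^(signal_strength * influence), with optional
multiplicative log-normal noise. DETFs are then derived from the two
states exactly as the real pipeline derives them, which is what makes
target recovery a well-posed inverse problem: a protein's DETF footprint
is its multi-hop downstream TF neighborhood, and the classifier must learn
to invert that map. Ground-truth propagation deliberately uses edge signs
even though the framework's features do not, so sign structure must be
inferred rather than read off.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .features import DETFSet, compute_detfs
from .graphio import (
    InteractionGraph,
    PathwayCollection,
    _row_normalize,
    read_edge_table,
    read_gene_sets,
    write_edge_table,
    write_gene_sets,
)
from .scoring import DrugAnnotation, read_drug_annotations, write_drug_annotations

PROPAGATION_DECAY = 0.5
PROPAGATION_HOPS = 5
SIGN_POS_PROB = 0.7
PATHWAY_DROPOUT = 0.1
EXPR_SIGMA = 0.5


@dataclass
class GeneratorParams:
    """Desk-scale defaults for the synthetic benchmark.

    ``signal_strength`` (24) and ``lfc_threshold`` (0.2) are matched so
    that TFs up to two hops downstream of a planted target cross the DETF
    cutoff at zero noise: per-hop influence shrinks by decay/out-degree
    (a factor ~1/8 per hop here), so a permissive fold-change cutoff is
    what exposes second-hop responders and gives each perturbation a
    multi-TF footprint (about 5 DETFs per dataset) like real signatures.
    ``mean_out_degree`` 4 mirrors the ~1.4% edge density of real curated
    interactomes at this node count. Drug targets are sampled from the TF
    universe (``targets_from_tfs``): perturbagens whose effects are read
    out transcriptomically act through regulators, and at desk scale a
    directly perturbed TF is what leaves a first-order mark in the DETF
    set — a non-regulator target on a 300-node graph leaves a footprint
    that is not uniquely attributable to its source.
    """

    n_proteins: int = 300
    n_tfs: int = 30
    n_drugs: int = 60
    targets_per_drug: int = 5
    targets_from_tfs: bool = True
    mean_out_degree: float = 4.0
    signal_strength: float = 24.0
    noise_rate: float = 0.05
    lfc_threshold: float = 0.2
    min_expr: float = 0.0
    decoy_fraction: float = 0.0
    n_train: int = 40
    n_test: int = 8
    seed: int = 1


@dataclass
class PerturbationDataset:
    """One training/test unit: states, derived DETFs, and true labels."""

    drug_id: str
    initial: pd.Series
    final: pd.Series
    detfs: DETFSet
    true_labels: np.ndarray  # per-protein in {0, 1, -1}, graph order


@dataclass
class SyntheticWorld:
    graph: InteractionGraph
    pathways: list[PathwayCollection]
    tf_universe: set[str]
    drugs: list[DrugAnnotation]
    params: GeneratorParams

    def drug(self, drug_id: str) -> DrugAnnotation:
        for d in self.drugs:
            if d.drug_id == drug_id:
                return d
        raise KeyError(drug_id)


# ---------------------------------------------------------------------------
# Network, pathways, drugs
# ---------------------------------------------------------------------------

def simulate_network(
    n_proteins: int,
    n_tfs: int,
    mean_out_degree: float = 4.0,
    seed: int = 0,
) -> tuple[InteractionGraph, set[str], list[PathwayCollection]]:
    """Random signed digraph with preferential attachment, TFs and pathways.

    Out-degrees are 1 + Poisson(mean_out_degree - 1); edge heads are drawn
    with probability proportional to (in-degree + 1), producing heavy-tailed
    in-degrees. Signs are +1 with probability 0.7. Pathways are noisy 2-hop
    out-neighborhoods of random seed nodes (10% member dropout), organized
    into three collections playing the GOBP/Reactome/KEGG roles.
    """
    if n_tfs > n_proteins:
        raise ValueError("n_tfs must be <= n_proteins")
    if n_proteins < 2 or mean_out_degree <= 0:
        raise ValueError("need >= 2 proteins and positive mean_out_degree")
    rng = np.random.default_rng(seed)
    width = len(str(n_proteins))
    node_ids = [f"P{i:0{width}d}" for i in range(n_proteins)]
    in_deg = np.ones(n_proteins)  # +1 smoothing doubles as the base weight
    edges: list[tuple[int, int, str, int]] = []
    seen: set[tuple[int, int]] = set()
    types = ("ppi", "signaling", "regulatory", "ligand_receptor")
    for src in range(n_proteins):
        d = 1 + rng.poisson(max(0.0, mean_out_degree - 1.0))
        probs = in_deg / in_deg.sum()
        heads = rng.choice(n_proteins, size=min(d, n_proteins), replace=False, p=probs)
        for tgt in heads:
            tgt = int(tgt)
            if (src, tgt) in seen:
                continue
            seen.add((src, tgt))
            sign = 1 if rng.random() < SIGN_POS_PROB else -1
            typ = types[rng.integers(len(types))]
            edges.append((src, tgt, typ, sign))
            in_deg[tgt] += 1
    graph = InteractionGraph(node_ids, edges)
    tf_universe = set(rng.choice(node_ids, size=n_tfs, replace=False).tolist())

    out_adj = graph.out_neighbors()
    collections = []
    n_sets = max(8, n_proteins // 15)
    for label in ("gobp_like", "reactome_like", "kegg_like"):
        gene_sets: dict[str, set[str]] = {}
        for j in range(n_sets):
            seed_node = int(rng.integers(n_proteins))
            hood = {seed_node}
            for u in out_adj[seed_node]:
                hood.add(u)
                hood.update(out_adj[u])
            members = {
                node_ids[u] for u in hood
                if u == seed_node or rng.random() >= PATHWAY_DROPOUT
            }
            gene_sets[f"{label}_{j:03d}"] = members
        collections.append(PathwayCollection(gene_sets, label))
    return graph, tf_universe, collections


def simulate_drugs(
    graph: InteractionGraph,
    n_drugs: int,
    targets_per_drug: int = 3,
    seed: int = 0,
    decoy_fraction: float = 0.0,
    mechanism_nodes: set[str] | None = None,
    target_pool: list[str] | None = None,
) -> list[DrugAnnotation]:
    """Drugs with uniformly sampled distinct targets and random +/-1 effects.

    Targets are drawn without replacement from ``target_pool`` (default:
    every graph node). A ``decoy_fraction`` of drugs is constrained to
    share no target with ``mechanism_nodes`` (the planted positive
    mechanism), when given.
    """
    if targets_per_drug < 1:
        raise ValueError("targets_per_drug must be >= 1")
    if targets_per_drug > graph.n_nodes:
        raise ValueError("more targets per drug than proteins")
    rng = np.random.default_rng(seed)
    n_decoys = int(round(decoy_fraction * n_drugs))
    pool = sorted(target_pool) if target_pool is not None else list(graph.node_ids)
    decoy_pool = [n for n in pool if not mechanism_nodes or n not in mechanism_nodes]
    drugs = []
    for i in range(n_drugs):
        source = decoy_pool if i < n_decoys else pool
        if len(source) < targets_per_drug:
            raise ValueError("decoy pool too small for targets_per_drug")
        targets = rng.choice(source, size=targets_per_drug, replace=False)
        effects = rng.choice([1, -1], size=targets_per_drug)
        drugs.append(
            DrugAnnotation(
                f"D{i:03d}",
                {t: int(e) for t, e in zip(targets, effects)},
                metadata={"decoy": i < n_decoys},
            )
        )
    return drugs


# ---------------------------------------------------------------------------
# Perturbation datasets
# ---------------------------------------------------------------------------

def signed_influence(
    graph: InteractionGraph,
    drug: DrugAnnotation,
    hops: int = PROPAGATION_HOPS,
    decay: float = PROPAGATION_DECAY,
) -> np.ndarray:
    """Ground-truth influence field of a drug's targets on every protein.

    influence = sum_{k=0..hops} decay^k (S^T)^k v0 with S the row-normalized
    signed adjacency and v0 the annotated target effects.
    """
    S = _row_normalize(graph.adjacency(signed=True))
    v = np.zeros(graph.n_nodes)
    for t, eff in drug.known_targets.items():
        e = eff if eff in (1, -1) else 1
        v[graph.index_of(t)] = e
    acc = v.copy()
    cur = v
    St = S.T.tocsr()
    for _ in range(hops):
        cur = decay * (St @ cur)
        acc += cur
    return acc


def simulate_perturbation_dataset(
    world: SyntheticWorld,
    drug: DrugAnnotation | str,
    signal_strength: float | None = None,
    noise_rate: float | None = None,
    seed: int = 0,
) -> PerturbationDataset:
    """Simulate initial/final expression states for one drug treatment."""
    if isinstance(drug, str):
        drug = world.drug(drug)
    p = world.params
    signal = p.signal_strength if signal_strength is None else signal_strength
    noise = p.noise_rate if noise_rate is None else noise_rate
    rng = np.random.default_rng(seed)
    n = world.graph.n_nodes
    initial = rng.lognormal(0.0, EXPR_SIGMA, size=n)
    influence = signed_influence(world.graph, drug)
    final = initial * np.power(2.0, signal * influence)
    if noise > 0:
        final = final * rng.lognormal(0.0, noise, size=n)
    init_s = pd.Series(initial, index=world.graph.node_ids)
    fin_s = pd.Series(final, index=world.graph.node_ids)
    detfs = compute_detfs(
        init_s, fin_s, world.tf_universe,
        lfc_threshold=p.lfc_threshold, min_expr=p.min_expr,
    )
    truth = np.zeros(n, dtype=int)
    for t, eff in drug.known_targets.items():
        truth[world.graph.index_of(t)] = eff if eff in (1, -1) else 0
    return PerturbationDataset(drug.drug_id, init_s, fin_s, detfs, truth)


# ---------------------------------------------------------------------------
# Full benchmark worlds
# ---------------------------------------------------------------------------

@dataclass
class Benchmark:
    world: SyntheticWorld
    train: list[PerturbationDataset]
    test: list[PerturbationDataset]
    manifest: dict


def make_benchmark(params: GeneratorParams | None = None) -> Benchmark:
    """Generate a world plus train/test datasets from disjoint drug subsets."""
    p = params or GeneratorParams()
    if p.n_train + p.n_test > p.n_drugs:
        raise ValueError("drug pool too small for disjoint train/test splits")
    rng = np.random.default_rng(p.seed)
    graph, tfs, pathways = simulate_network(
        p.n_proteins, p.n_tfs, p.mean_out_degree, seed=p.seed
    )
    drugs = simulate_drugs(
        graph, p.n_drugs, p.targets_per_drug,
        seed=p.seed + 1, decoy_fraction=p.decoy_fraction,
        target_pool=sorted(tfs) if p.targets_from_tfs else None,
    )
    world = SyntheticWorld(graph, pathways, tfs, drugs, p)
    order = rng.permutation(p.n_drugs)
    train_ids = [drugs[i].drug_id for i in order[: p.n_train]]
    test_ids = [drugs[i].drug_id for i in order[p.n_train : p.n_train + p.n_test]]
    train = [
        simulate_perturbation_dataset(world, d, seed=p.seed + 1000 + i)
        for i, d in enumerate(train_ids)
    ]
    test = [
        simulate_perturbation_dataset(world, d, seed=p.seed + 2000 + i)
        for i, d in enumerate(test_ids)
    ]
    manifest = {
        "params": asdict(p),
        "train_drugs": train_ids,
        "test_drugs": test_ids,
        "n_nodes": graph.n_nodes,
        "n_edges": graph.n_edges,
        "detf_counts": {d.drug_id: len(d.detfs) for d in train + test},
    }
    return Benchmark(world, train, test, manifest)


def write_benchmark(bench: Benchmark, outdir: str | Path) -> None:
    """Serialize a benchmark to the module's plain-text directory layout."""
    outdir = Path(outdir)
    if outdir.exists():
        shutil.rmtree(outdir)
    outdir.mkdir(parents=True)
    write_edge_table(bench.world.graph, outdir / "edges.tsv")
    # node order is generator-defined, not first-appearance; store it
    (outdir / "nodes.txt").write_text("\n".join(bench.world.graph.node_ids) + "\n")
    for suffix, coll in zip("abc", bench.world.pathways):
        write_gene_sets(coll, outdir / f"pathways_{suffix}.gmt")
    (outdir / "tfs.txt").write_text(
        "\n".join(sorted(bench.world.tf_universe)) + "\n"
    )
    write_drug_annotations(bench.world.drugs, outdir / "drugs.tsv")
    ds_dir = outdir / "datasets"
    for split, datasets in (("train", bench.train), ("test", bench.test)):
        for i, ds in enumerate(datasets):
            d = ds_dir / f"{split}_{i:03d}"
            d.mkdir(parents=True)
            _write_state(ds.initial, d / "initial.tsv")
            _write_state(ds.final, d / "final.tsv")
            truth = pd.DataFrame(
                {"protein_id": bench.world.graph.node_ids, "label": ds.true_labels}
            )
            truth.to_csv(d / "truth.tsv", sep="\t", index=False)
            (d / "meta.json").write_text(json.dumps({"drug_id": ds.drug_id}))
    (outdir / "manifest.json").write_text(json.dumps(bench.manifest, indent=2))


def read_benchmark(outdir: str | Path) -> Benchmark:
    """Reconstruct a benchmark from its directory (inverse of write)."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    p = GeneratorParams(**manifest["params"])
    graph = read_edge_table(outdir / "edges.tsv")
    nodes_file = outdir / "nodes.txt"
    if nodes_file.exists():
        order = nodes_file.read_text().split()
        remap = {graph.index_of(nid): i for i, nid in enumerate(order)}
        graph = InteractionGraph(
            order,
            [(remap[s], remap[t], ty, sg) for s, t, ty, sg in graph.edges],
        )
    pathways = [
        read_gene_sets(outdir / f"pathways_{s}.gmt",
                       label=["gobp_like", "reactome_like", "kegg_like"][i])
        for i, s in enumerate("abc")
    ]
    tfs = set((outdir / "tfs.txt").read_text().split())
    drugs = read_drug_annotations(outdir / "drugs.tsv")
    world = SyntheticWorld(graph, pathways, tfs, drugs, p)
    train, test = [], []
    for d in sorted((outdir / "datasets").iterdir()):
        meta = json.loads((d / "meta.json").read_text())
        init = _read_state(d / "initial.tsv")
        fin = _read_state(d / "final.tsv")
        truth_df = pd.read_csv(d / "truth.tsv", sep="\t")
        truth = truth_df.set_index("protein_id").loc[graph.node_ids, "label"].to_numpy()
        detfs = compute_detfs(init, fin, tfs, lfc_threshold=p.lfc_threshold,
                              min_expr=p.min_expr)
        ds = PerturbationDataset(meta["drug_id"], init, fin, detfs, truth)
        (train if d.name.startswith("train") else test).append(ds)
    return Benchmark(world, train, test, manifest)


def _write_state(s: pd.Series, path: Path) -> None:
    df = pd.DataFrame({"protein_id": s.index, "value": s.to_numpy()})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _read_state(path: Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["value"].to_numpy(), index=df["protein_id"].astype(str))
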