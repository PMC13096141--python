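"""Comparison baselines and early-recall evaluation.

Two baselines frame the framework's performance: an over-representation
(ORA/GSEA-style) target predictor — DETFs are tested against pathway gene
sets with a one-sided hypergeometric test, Benjamini–Hochberg adjusted per
collection, and differentially expressed genes inside the enriched pathways
become the predicted targets — and a uniformly random drug ranking.

All methods are compared by early recall: the fraction of known-positive
drugs ranked within the top q percent of the candidate list, with a ceil
cutoff and tie-inclusive boundary handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .graphio import PathwayCollection
from .scoring import hypergeom_pvalue

DEFAULT_ALPHAS = (0.05, 0.001, 0.005)  # GOBP-, Reactome-, KEGG-role defaults
DEFAULT_PERCENTILES = (0.5, 1.0, 2.0, 2.5, 5.0, 10.0)


# ---------------------------------------------------------------------------
# Over-representation baseline
# ---------------------------------------------------------------------------

def ora_enrich(
    query: set[str],
    collections: Sequence[PathwayCollection],
    universe: set[str],
    alphas: Sequence[float] = DEFAULT_ALPHAS,
) -> list[tuple[str, str, float]]:
    """One-sided hypergeometric over-representation with per-collection BH.

    Returns (collection_label, pathway_id, adjusted_p) for every gene set
    passing its collection's adjusted-p cutoff.
    """
    if len(alphas) != len(collections):
        raise ValueError("need one alpha per collection")
    q = query & universe
    M = len(universe)
    enriched: list[tuple[str, str, float]] = []
    for coll, alpha in zip(collections, alphas):
        names, pvals = [], []
        for name, members in coll.gene_sets.items():
            hits = members & universe
            k = len(hits & q)
            pvals.append(hypergeom_pvalue(M, len(hits), len(q), k) if hits else 1.0)
            names.append(name)
        if not names:
            continue
        _, adj, _, _ = multipletests(pvals, method="fdr_bh")
        for name, p in zip(names, adj):
            if p <= alpha:
                enriched.append((coll.label, name, float(p)))
    return enriched


def gsea_baseline_targets(
    degs: set[str],
    enriched: Sequence[tuple[str, str, float]],
    collections: Sequence[PathwayCollection],
) -> set[str]:
    """Predicted targets = DEGs inside the union of enriched gene sets."""
    by_label = {c.label: c for c in collections}
    members: set[str] = set()
    for label, name, _p in enriched:
        members |= by_label[label].gene_sets[name]
    return degs & members


# ---------------------------------------------------------------------------
# Random baseline
# ---------------------------------------------------------------------------

def random_ranking(drug_ids: Sequence[str], seed: int = 0) -> pd.DataFrame:
    """Uniform random permutation of the drug pool; rank = position."""
    if not len(drug_ids):
        raise ValueError("drug pool is empty")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(drug_ids))
    return pd.DataFrame(
        {
            "drug_id": [drug_ids[i] for i in order],
            "rank": np.arange(1, len(drug_ids) + 1),
        }
    )


# ---------------------------------------------------------------------------
# Early-recall evaluation
# ---------------------------------------------------------------------------

def recall_at_percentile(
    ranked: pd.DataFrame, positives: set[str], q: float
) -> float:
    """Fraction of positives within the top q%% of ranks (ceil cutoff).

    Boundary ties are included: every drug sharing the min-method rank of
    the drug at the cutoff position counts as inside the cutoff.
    """
    if not positives:
        raise ValueError("positives must be non-empty")
    if not 0.0 < q <= 100.0:
        raise ValueError("q must be in (0, 100]")
    missing = positives - set(ranked["drug_id"])
    if missing:
        raise ValueError(f"positives absent from ranking: {sorted(missing)[:5]}")
    n = len(ranked)
    cutoff = ceil(q / 100.0 * n)
    ranks = ranked.sort_values("rank", kind="mergesort")
    boundary_rank = int(ranks["rank"].iloc[cutoff - 1])
    top = set(ranks.loc[ranks["rank"] <= boundary_rank, "drug_id"])
    return len(positives & top) / len(positives)


def select_top_percentile(ranked: pd.DataFrame, q: float = 2.5) -> set[str]:
    """Candidate set: rank <= ceil(q%% of pool), excluding zero-BES drugs.

    Duplicated drug ids (e.g. the same drug surfacing from several runs)
    collapse to one candidate.
    """
    n = len(ranked)
    cutoff = ceil(q / 100.0 * n)
    sel = ranked[ranked["rank"] <= cutoff]
    if "bes" in sel.columns:
        sel = sel[sel["bes"] > 0]
    return set(sel["drug_id"])


@dataclass
class RecallCurve:
    percentiles: list[float]
    per_dataset: dict[str, list[float]]  # dataset id -> recall per grid point

    @property
    def mean_recall(self) -> list[float]:
        arr = np.array(list(self.per_dataset.values()))
        return arr.mean(axis=0).tolist()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_dataset, index=self.percentiles)
        df.index.name = "percentile"
        df["mean"] = df.mean(axis=1)
        return df


@dataclass
class BenchmarkResult:
    method: str
    curve: RecallCurve
    ranked_tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def build_recall_curve(
    ranked_tables: Mapping[str, pd.DataFrame],
    positives: Mapping[str, set[str]],
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
) -> RecallCurve:
    """Recall grid across datasets; one ranked table + positive set each."""
    per_dataset = {
        ds: [recall_at_percentile(table, positives[ds], q) for q in percentiles]
        for ds, table in ranked_tables.items()
    }
    return RecallCurve(list(percentiles), per_dataset)


def plot_recall_curves(results: Sequence[BenchmarkResult], path) -> None:
    """Mean recall vs percentile for each method (one PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for res in results:
        ax.plot(res.curve.percentiles, res.curve.mean_recall, marker="o",
                label=res.method)
    ax.set_xlabel("top percentile (%)")
    ax.set_ylabel("mean recall")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
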