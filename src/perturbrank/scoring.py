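"""Per-drug Bayesian enrichment scoring and ranking.

For each candidate drug with known direct targets, four ingredients are
combined into a single Bayesian enrichment score (BES):

* a one-sided hypergeometric p-value for the overlap k between the drug's
  n known targets and the N predicted target proteins in an M-protein
  network;
* an empirical p-value p_emp from a permutation null — the fraction of
  row-shuffled feature matrices under which the drug is still "predicted"
  (at least one known target gets a nonzero consensus label);
* a posterior confidence 1 - pi0 * p_emp under a prior that only 1% of
  drugs are true positives (pi0 = 0.99), modulated by the soft exponential
  confidence weighting factor exp(-lambda * (1 - p_emp));
* the normalized rank of the hypergeometric p-value (1 = best).

BES = w_post * posterior * CWF + w_hyp * (1 - p_hyp) + w_rank * r_hyp, with
default weights (20, 1, 1). Drugs with hypergeometric p = 1 (no single
target predicted) are assigned BES = 0 outright. Final ranks are descending
BES with min-method ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import FNN, EnsemblePrediction, predict_targets
from .features import FeatureMatrix

DEFAULT_PI0 = 0.99
DEFAULT_LAMBDA = 1.0
DEFAULT_WEIGHTS = (20.0, 1.0, 1.0)  # (posterior, hypergeo, hypergeo-rank)
DEFAULT_TRIALS = 100


@dataclass
class DrugAnnotation:
    """A drug and its known direct protein targets.

    Effects: 1 activation, -1 inhibition, 2 unknown/ambiguous direction.
    """

    drug_id: str
    known_targets: dict[str, int]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.known_targets:
            raise ValueError(f"drug {self.drug_id!r} has no annotated targets")
        bad = {e for e in self.known_targets.values() if e not in (1, -1, 2)}
        if bad:
            raise ValueError(f"drug {self.drug_id!r}: invalid effects {bad}")


@dataclass
class DrugScore:
    drug_id: str
    k: int
    n: int
    N: int
    M: int
    p_hypergeo: float
    p_emp: float
    posterior: float
    cwf: float
    s_posterior: float
    r_hypergeo: float
    bes: float
    rank: int = 0


def hypergeom_pvalue(M: int, n: int, N: int, k: int) -> float:
    """One-sided upper-tail hypergeometric p-value P(overlap >= k).

    M = network size, n = known targets, N = predicted targets, k = overlap.
    Computed via the survival function (log-space internally), so it is
    stable for large M; k = 0 or N = 0 give exactly 1.
    """
    if not (0 <= k <= min(n, N) <= M and n <= M and N <= M):
        raise ValueError(f"invalid hypergeometric bounds M={M} n={n} N={N} k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, M, n, N))


def empirical_pvalue(
    members: list[FNN],
    F_decoded: FeatureMatrix,
    drugs: Sequence[DrugAnnotation],
    trials: int = DEFAULT_TRIALS,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation-null robustness p-value per drug.

    Each trial permutes the assignment of feature rows to protein
    identities (protein ids keep their positions; the rows are shuffled),
    reruns the ensemble, and calls a drug "predicted" if at least one of
    its known targets receives a nonzero consensus label. p_emp is the
    fraction of trials in which the drug is predicted, so small values mean
    the original prediction is unlikely under uninformative features.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    idx = {pid: i for i, pid in enumerate(F_decoded.row_ids)}
    target_idx = {
        d.drug_id: [idx[t] for t in d.known_targets if t in idx] for d in drugs
    }
    hits = {d.drug_id: 0 for d in drugs}
    n = F_decoded.shape[0]
    for _ in range(trials):
        perm = rng.permutation(n)
        shuffled = FeatureMatrix(
            list(F_decoded.row_ids), list(F_decoded.col_names),
            F_decoded.values[perm], stage=F_decoded.stage,
        )
        pred = predict_targets(members, shuffled)
        nonzero = pred.consensus != 0
        for drug_id, tidx in target_idx.items():
            if tidx and nonzero[tidx].any():
                hits[drug_id] += 1
    return {d: h / trials for d, h in hits.items()}


def posterior(p_emp: float, pi0: float = DEFAULT_PI0) -> float:
    """Posterior confidence 1 - pi0 * p_emp (prior: 1% true positives)."""
    if not 0.0 <= p_emp <= 1.0:
        raise ValueError("p_emp must be in [0, 1]")
    return 1.0 - pi0 * p_emp


def confidence_weight(p_emp: float, lam: float = DEFAULT_LAMBDA) -> float:
    """Soft exponential confidence weighting factor exp(-lam * (1 - p_emp))."""
    if not 0.0 <= p_emp <= 1.0:
        raise ValueError("p_emp must be in [0, 1]")
    return float(np.exp(-lam * (1.0 - p_emp)))


def _normalized_rank(p_values: np.ndarray) -> np.ndarray:
    """Normalized hypergeometric-p rank: best (smallest p) -> 1, worst -> 0.

    Min-method ties: tied p-values share the rank value of their group's
    smallest rank; a single drug gets 1.0.
    """
    m = len(p_values)
    if m == 1:
        return np.ones(1)
    ranks = stats.rankdata(p_values, method="min")  # 1 = smallest p = best
    return 1.0 - (ranks - 1) / (m - 1)


def bayesian_enrichment_score(
    components: Sequence[Mapping],
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    pi0: float = DEFAULT_PI0,
    lam: float = DEFAULT_LAMBDA,
) -> list[DrugScore]:
    """Assemble DrugScore records with BES and min-method descending ranks.

    ``components`` holds one mapping per drug with keys drug_id, k, n, N, M,
    p_hypergeo, p_emp. The zero rule applies before weighting: a drug whose
    hypergeometric p-value is 1 (no known target predicted) scores 0.
    """
    required = {"drug_id", "k", "n", "N", "M", "p_hypergeo", "p_emp"}
    for comp in components:
        missing = required - set(comp)
        if missing:
            raise KeyError(
                f"drug {comp.get('drug_id', '?')!r}: missing components {sorted(missing)}"
            )
    w_post, w_hyp, w_rank = weights
    p_hyp = np.array([c["p_hypergeo"] for c in components], dtype=float)
    r_hyp = _normalized_rank(p_hyp) if len(p_hyp) else np.array([])
    scores: list[DrugScore] = []
    for comp, r in zip(components, r_hyp):
        post = posterior(comp["p_emp"], pi0)
        cwf = confidence_weight(comp["p_emp"], lam)
        s_post = post * cwf
        if comp["p_hypergeo"] >= 1.0 - 1e-15:
            bes = 0.0
        else:
            bes = w_post * s_post + w_hyp * (1.0 - comp["p_hypergeo"]) + w_rank * r
        scores.append(
            DrugScore(
                drug_id=comp["drug_id"], k=int(comp["k"]), n=int(comp["n"]),
                N=int(comp["N"]), M=int(comp["M"]),
                p_hypergeo=float(comp["p_hypergeo"]), p_emp=float(comp["p_emp"]),
                posterior=post, cwf=cwf, s_posterior=s_post,
                r_hypergeo=float(r), bes=float(bes),
            )
        )
    bes_vals = np.array([s.bes for s in scores])
    ranks = stats.rankdata(-bes_vals, method="min").astype(int)
    for s, r in zip(scores, ranks):
        s.rank = int(r)
    return scores


def score_drugs(
    prediction: EnsemblePrediction,
    node_ids: Sequence[str],
    drugs: Sequence[DrugAnnotation],
    p_emp: Mapping[str, float],
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    pi0: float = DEFAULT_PI0,
    lam: float = DEFAULT_LAMBDA,
    direction_matched: bool = False,
) -> list[DrugScore]:
    """Score every drug against an ensemble prediction.

    The predicted target set is every protein with a nonzero consensus
    label. Overlap counting is direction-agnostic by default (a known
    inhibition target counts even if predicted activated); with
    ``direction_matched`` the consensus sign must equal the annotated
    effect (ambiguous annotations, effect 2, match either sign).
    """
    M = len(node_ids)
    idx = {pid: i for i, pid in enumerate(node_ids)}
    consensus = prediction.consensus
    N = int((consensus != 0).sum())
    components = []
    for drug in drugs:
        k = 0
        for t, eff in drug.known_targets.items():
            if t not in idx:
                continue
            c = consensus[idx[t]]
            if c == 0:
                continue
            if direction_matched and eff in (1, -1) and c != eff:
                continue
            k += 1
        n = len(drug.known_targets)
        components.append(
            {
                "drug_id": drug.drug_id, "k": k, "n": min(n, M), "N": N, "M": M,
                "p_hypergeo": hypergeom_pvalue(M, min(n, M), N, k),
                "p_emp": float(p_emp[drug.drug_id]),
            }
        )
    return bayesian_enrichment_score(components, weights=weights, pi0=pi0, lam=lam)


def predicted_set_scores(
    predicted: set[str],
    node_ids: Sequence[str],
    drugs: Sequence[DrugAnnotation],
    p_emp: Mapping[str, float] | float = 1.0,
    **kwargs,
) -> list[DrugScore]:
    """Score drugs against an explicit predicted-target set.

    Used by the enrichment-analysis baseline, which produces a target set
    rather than an ensemble prediction; a constant p_emp (default 1, i.e.
    no permutation null) keeps the ranking comparable.
    """
    M = len(node_ids)
    universe = set(node_ids)
    pred = predicted & universe
    N = len(pred)
    components = []
    for drug in drugs:
        targets_in = {t for t in drug.known_targets if t in universe}
        k = len(targets_in & pred)
        n = len(drug.known_targets)
        pe = p_emp[drug.drug_id] if isinstance(p_emp, Mapping) else float(p_emp)
        components.append(
            {
                "drug_id": drug.drug_id, "k": k, "n": min(n, M), "N": N, "M": M,
                "p_hypergeo": hypergeom_pvalue(M, min(n, M), N, k),
                "p_emp": pe,
            }
        )
    return bayesian_enrichment_score(components, **kwargs)


def scores_to_frame(scores: Sequence[DrugScore]) -> pd.DataFrame:
    """Ranked table (ascending rank) with every scoring component."""
    df = pd.DataFrame(
        [
            {
                "drug_id": s.drug_id, "k": s.k, "n": s.n, "N": s.N, "M": s.M,
                "p_hypergeo": s.p_hypergeo, "p_emp": s.p_emp,
                "posterior": s.posterior, "cwf": s.cwf,
                "s_posterior": s.s_posterior, "r_hypergeo": s.r_hypergeo,
                "bes": s.bes, "rank": s.rank,
            }
            for s in scores
        ]
    )
    return df.sort_values(["rank", "drug_id"], kind="mergesort").reset_index(drop=True)


def read_drug_annotations(path) -> list[DrugAnnotation]:
    """Read a TSV/CSV with columns drug_id, target, effect in {1,-1,2}."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    needed = {"drug_id", "target", "effect"}
    if not needed.issubset(df.columns):
        raise ValueError(f"drug table needs columns {sorted(needed)}")
    drugs: dict[str, dict[str, int]] = {}
    for row in df.itertuples(index=False):
        drugs.setdefault(str(row.drug_id), {})[str(row.target)] = int(row.effect)
    return [DrugAnnotation(d, t) for d, t in drugs.items()]


def write_drug_annotations(drugs: Sequence[DrugAnnotation], path) -> None:
    rows = [
        {"drug_id": d.drug_id, "target": t, "effect": e}
        for d in drugs
        for t, e in d.known_targets.items()
    ]
    pd.DataFrame(rows, columns=["drug_id", "target", "effect"]).to_csv(
        path, sep="\t", index=False
    )
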