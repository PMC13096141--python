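"""End-to-end orchestration: featurize -> VAE -> ensemble -> score -> rank.

A :class:`RunConfig` collects every stage parameter with the framework's
reference defaults. One global seed fans out deterministically to per-stage
seeds (crc32 of the stage name mixed through a SeedSequence), so any stage
can be rerun independently yet reproducibly; two runs with the same config
and seed produce byte-identical ranked tables.

`desk_config` returns the reduced network sizes used for laptop-scale
synthetic benchmarks; the statistical procedure is identical, only layer
widths, latent size and epoch counts shrink with the problem.
"""

from __future__ import annotations

import json
import pickle
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import baselines, features, scoring, synth
from .classifier import (
    FNN,
    FNNConfig,
    balance_classes,
    classification_metrics,
    default_member_configs,
    predict_targets,
    train_ensemble,
)
from .features import FeatureMatrix
from .graphio import InteractionGraph, NormalizedAdjacency, PathwayCollection, normalize_adjacency
from .scoring import DrugAnnotation, empirical_pvalue, score_drugs, scores_to_frame
from .synth import Benchmark, PerturbationDataset
from .vae import VAE, VAEConfig, denoise, train_vae


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    mix = zlib.crc32(stage.encode())
    ss = np.random.SeedSequence([int(global_seed) % 2**31, mix])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """All stage parameters with the framework's reference defaults."""

    # stage 1
    K: int = 5
    detf_cap: int = 100
    lfc_threshold: float = 1.0
    min_expr: float = 0.0
    subsample_k: int = 50
    subsample_per_cluster: int | None = None  # None keeps every row
    # stage 2 (VAE)
    vae_initial_hidden: int = 1500
    vae_layers: int = 5
    vae_latent: int = 100
    vae_beta: float = 0.001
    vae_batch: int = 1024
    vae_lr: float = 0.001
    vae_epochs: int = 30
    # stage 3 (ensemble)
    fnn_initial_hidden: int = 1500
    fnn_layers: int = 5
    fnn_decay: float = 0.5
    fnn_lr: float = 0.005
    fnn_dropout: float = 0.0
    fnn_epochs: int = 30
    fnn_batches: tuple[int, int, int] = (1024, 2048, 2048)
    fnn_l1: float = 0.2   # member 2 only
    fnn_l2: float = 0.1   # member 2 only
    # stage 4 (scoring)
    trials: int = 100
    pi0: float = 0.99
    lam: float = 1.0
    weights: tuple[float, float, float] = (20.0, 1.0, 1.0)
    percentile_q: float = 2.5
    # evaluation
    recall_percentiles: tuple[float, ...] = baselines.DEFAULT_PERCENTILES
    ora_alphas: tuple[float, ...] = baselines.DEFAULT_ALPHAS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        for name in ("fnn_batches", "weights", "recall_percentiles", "ora_alphas"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def desk_config(seed: int = 0) -> RunConfig:
    """Laptop-scale profile for the synthetic benchmark (~10^4 rows)."""
    return RunConfig(
        vae_initial_hidden=512, vae_layers=3, vae_latent=64,
        vae_batch=256, vae_epochs=80,
        fnn_initial_hidden=512, fnn_layers=3, fnn_lr=0.002, fnn_epochs=60,
        fnn_batches=(256, 256, 256), fnn_l1=1e-6, fnn_l2=1e-5,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Stage 1 over dataset collections
# ---------------------------------------------------------------------------

def featurize_dataset(
    graph: InteractionGraph,
    pathways: Sequence[PathwayCollection],
    A_fwd: NormalizedAdjacency,
    A_rev: NormalizedAdjacency,
    ds: PerturbationDataset,
    config: RunConfig,
    cap_seed: int,
) -> FeatureMatrix:
    """Expanded (pre-normalization) feature matrix for one dataset."""
    return features.build_feature_matrix(
        graph, ds.initial, ds.detfs, pathways, A_fwd, A_rev,
        K=config.K, detf_cap=config.detf_cap, cap_seed=cap_seed,
    )


def _subset_columns(F: FeatureMatrix, cols: list[str]) -> FeatureMatrix:
    pos = {c: i for i, c in enumerate(F.col_names)}
    idx = [pos[c] for c in cols]
    return FeatureMatrix(list(F.row_ids), list(cols), F.values[:, idx], stage=F.stage)


@dataclass
class TrainedFramework:
    """Everything needed to score an unseen perturbation dataset."""

    graph: InteractionGraph
    pathways: list[PathwayCollection]
    A_fwd: NormalizedAdjacency
    A_rev: NormalizedAdjacency
    feature_template: FeatureMatrix  # fitted columns + min-max bounds
    vae: VAE
    members: list[FNN]
    member_metrics: list[dict]
    ensemble_metrics: dict
    config: RunConfig

    def prepare(self, ds: PerturbationDataset) -> FeatureMatrix:
        """Featurize + align + normalize + VAE-denoise one dataset."""
        raw = featurize_dataset(
            self.graph, self.pathways, self.A_fwd, self.A_rev, ds, self.config,
            cap_seed=stage_seed(self.config.seed, f"cap:{ds.drug_id}"),
        )
        aligned = _subset_columns(raw, self.feature_template.col_names)
        norm = features.apply_normalization(aligned, self.feature_template)
        return denoise(self.vae, norm)

    def predict(self, ds: PerturbationDataset):
        decoded = self.prepare(ds)
        return decoded, predict_targets(self.members, decoded)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        Path(str(path) + ".json").write_text(
            json.dumps({"config": self.config.to_dict(),
                        "member_metrics": self.member_metrics,
                        "ensemble_metrics": self.ensemble_metrics}, indent=2)
        )

    @staticmethod
    def load(path: str | Path) -> "TrainedFramework":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def train_framework(
    world: synth.SyntheticWorld,
    train_datasets: Sequence[PerturbationDataset],
    config: RunConfig,
) -> TrainedFramework:
    """Run stages 1-3 on a collection of training datasets."""
    graph = world.graph
    A_fwd = normalize_adjacency(graph, "forward")
    A_rev = normalize_adjacency(graph, "reverse")

    mats, labels = [], []
    for i, ds in enumerate(train_datasets):
        F = featurize_dataset(
            graph, world.pathways, A_fwd, A_rev, ds, config,
            cap_seed=stage_seed(config.seed, f"cap:{ds.drug_id}"),
        )
        mats.append(F)
        labels.append(ds.true_labels)
    cols = mats[0].col_names
    stacked = FeatureMatrix(
        [r for m in mats for r in m.row_ids], list(cols),
        np.vstack([m.values for m in mats]), stage="expanded",
    )
    y = np.concatenate(labels)

    pruned = features.drop_constant_features(stacked)
    if config.subsample_per_cluster is not None:
        # cluster balance on the pre-normalization matrix, as in training-set
        # construction; normalization bounds are then fitted on the subsample
        tmp = features.minmax_normalize(pruned)
        idx = features.cluster_subsample(
            tmp, k=config.subsample_k, per_cluster=config.subsample_per_cluster,
            seed=stage_seed(config.seed, "subsample"),
        )
        pruned = FeatureMatrix(
            [pruned.row_ids[i] for i in idx], list(pruned.col_names),
            pruned.values[idx], stage="expanded",
        )
        pruned = features.drop_constant_features(pruned)
        y = y[idx]
    norm = features.minmax_normalize(pruned)

    vcfg = VAEConfig(
        input_dim=norm.shape[1],
        initial_hidden=config.vae_initial_hidden,
        n_encoder_layers=config.vae_layers,
        latent_dim=config.vae_latent,
        beta=config.vae_beta,
        batch_size=config.vae_batch,
        learning_rate=config.vae_lr,
        max_epochs=config.vae_epochs,
        seed=stage_seed(config.seed, "vae"),
    )
    model = train_vae(norm, vcfg)
    decoded = denoise(model, norm)

    Xb, yb, prov = balance_classes(
        decoded, y, model, seed=stage_seed(config.seed, "balance"), F_source=norm,
    )
    member_cfgs = default_member_configs(
        input_dim=decoded.shape[1], seed=stage_seed(config.seed, "fnn"),
        initial_hidden=config.fnn_initial_hidden, n_layers=config.fnn_layers,
        decay_factor=config.fnn_decay, learning_rate=config.fnn_lr,
        dropout=config.fnn_dropout, max_epochs=config.fnn_epochs,
    )
    for cfg, bs in zip(member_cfgs, config.fnn_batches):
        cfg.batch_size = bs
    member_cfgs[1].l1 = config.fnn_l1
    member_cfgs[1].l2 = config.fnn_l2
    members, member_metrics = train_ensemble(Xb, yb, member_cfgs)

    # held-in fit: ensemble consensus over the full balanced training pool
    # (synthetic rows carry their generating class as ground truth); the
    # stricter real-rows-only view is reported alongside
    Fpool = FeatureMatrix(
        [f"b{i}" for i in range(len(yb))], list(decoded.col_names),
        Xb, stage="decoded",
    )
    consensus = predict_targets(members, Fpool).consensus
    real = ~prov
    ensemble_metrics = classification_metrics(consensus, yb)
    ensemble_metrics["real_rows"] = classification_metrics(
        consensus[real], yb[real]
    )

    template = FeatureMatrix(
        ["_template"], list(norm.col_names),
        np.zeros((1, norm.shape[1])), stage="normalized", col_bounds=norm.col_bounds,
    )
    return TrainedFramework(
        graph, list(world.pathways), A_fwd, A_rev, template, model,
        members, member_metrics, ensemble_metrics, config,
    )


# ---------------------------------------------------------------------------
# Stage 4 + evaluation
# ---------------------------------------------------------------------------

def score_dataset(
    framework: TrainedFramework,
    ds: PerturbationDataset,
    drugs: Sequence[DrugAnnotation],
) -> pd.DataFrame:
    """Ranked drug table for one perturbation dataset."""
    cfg = framework.config
    decoded, pred = framework.predict(ds)
    p_emp = empirical_pvalue(
        framework.members, decoded, drugs, trials=cfg.trials,
        seed=stage_seed(cfg.seed, f"pemp:{ds.drug_id}"),
    )
    scores = score_drugs(
        pred, framework.graph.node_ids, drugs, p_emp,
        weights=cfg.weights, pi0=cfg.pi0, lam=cfg.lam,
    )
    return scores_to_frame(scores)


def gsea_baseline_ranking(
    world: synth.SyntheticWorld,
    ds: PerturbationDataset,
    config: RunConfig,
) -> pd.DataFrame:
    """ORA-based ranked table: DEGs in enriched pathways as targets."""
    universe = set(world.graph.node_ids)
    query = set(ds.detfs.labels)
    enriched = baselines.ora_enrich(
        query, world.pathways, universe, alphas=config.ora_alphas
    )
    lfc = np.log2((ds.final + 1e-6) / (ds.initial + 1e-6))
    degs = set(lfc.index[np.abs(lfc.to_numpy()) >= world.params.lfc_threshold])
    predicted = baselines.gsea_baseline_targets(degs, enriched, world.pathways)
    scores = scoring.predicted_set_scores(
        predicted, world.graph.node_ids, world.drugs,
        weights=config.weights, pi0=config.pi0, lam=config.lam,
    )
    return scores_to_frame(scores)


def run_benchmark(bench: Benchmark, config: RunConfig) -> dict:
    """Train on the benchmark's training split and compare three methods.

    Returns per-method recall curves, per-dataset ranked tables, ensemble
    metrics and the top-percentile candidate set of the trained framework.
    """
    framework = train_framework(bench.world, bench.train, config)
    drugs = bench.world.drugs
    drug_ids = [d.drug_id for d in drugs]

    dl_tables, gsea_tables, rand_tables = {}, {}, {}
    positives = {}
    for i, ds in enumerate(bench.test):
        name = f"test_{i:03d}"
        positives[name] = {ds.drug_id}
        dl_tables[name] = score_dataset(framework, ds, drugs)
        gsea_tables[name] = gsea_baseline_ranking(bench.world, ds, config)
        rand_tables[name] = baselines.random_ranking(
            drug_ids, seed=stage_seed(config.seed, f"random:{name}")
        )

    results = [
        baselines.BenchmarkResult(
            "dl_framework",
            baselines.build_recall_curve(dl_tables, positives, config.recall_percentiles),
            dl_tables,
        ),
        baselines.BenchmarkResult(
            "gsea_baseline",
            baselines.build_recall_curve(gsea_tables, positives, config.recall_percentiles),
            gsea_tables,
        ),
        baselines.BenchmarkResult(
            "random",
            baselines.build_recall_curve(rand_tables, positives, config.recall_percentiles),
            rand_tables,
        ),
    ]
    candidates = {
        name: sorted(baselines.select_top_percentile(tab, config.percentile_q))
        for name, tab in dl_tables.items()
    }
    return {
        "framework": framework,
        "results": results,
        "positives": positives,
        "candidates": candidates,
        "ensemble_metrics": framework.ensemble_metrics,
        "member_metrics": framework.member_metrics,
    }


def write_benchmark_outputs(outcome: dict, outdir: str | Path, config: RunConfig) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config": config.to_dict(),
        "ensemble_metrics": outcome["ensemble_metrics"],
        "member_metrics": outcome["member_metrics"],
        "candidates": outcome["candidates"],
        "methods": {},
    }
    for res in outcome["results"]:
        mdir = outdir / res.method
        mdir.mkdir(exist_ok=True)
        for name, tab in res.ranked_tables.items():
            tab.to_csv(mdir / f"{name}.tsv", sep="\t", index=False)
        summary["methods"][res.method] = {
            "percentiles": res.curve.percentiles,
            "mean_recall": res.curve.mean_recall,
            "per_dataset": res.curve.per_dataset,
        }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    try:
        baselines.plot_recall_curves(outcome["results"], outdir / "recall_curves.png")
    except Exception:
        pass  # plotting is best-effort; benchmarks must not fail on backends
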