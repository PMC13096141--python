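"""Ensemble of decaying-width feedforward classifiers for per-protein labels.

Each protein receives one of three perturbation labels — 1 activation,
-1 inhibition, 0 no effect (ambiguous drug-target annotations, label 2, are
excluded from training). Three independently seeded networks are trained on
class-balanced, VAE-decoded features and combined by majority vote; a
three-way split falls back to 0 (no effect) so that disagreement never
produces a target call.

Class balancing follows the mean-of-class-sizes rule: the target count is
the mean of the observed class sizes; over-represented classes are
downsampled without replacement and under-represented ones are topped up
with synthetic rows obtained by encoding real rows of that class, sampling
the latent posterior, and decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from ._nn import Adam, Dense, Sequential, cross_entropy, mlp, softmax
from .features import FeatureMatrix
from .vae import VAE, TrainingDivergence

# integer encoding used for training: label -> class index
LABEL_TO_CLASS = {0: 0, 1: 1, -1: 2}
CLASS_TO_LABEL = {0: 0, 1: 1, 2: -1}
AMBIGUOUS = 2


class ClassCoverageError(ValueError):
    """A class with zero real rows cannot be balanced by synthesis."""


@dataclass
class FNNConfig:
    input_dim: int
    initial_hidden: int = 1500
    n_layers: int = 5
    decay_factor: float = 0.5
    dropout: float = 0.0
    learning_rate: float = 0.005
    batch_size: int = 1024
    l1: float = 0.0
    l2: float = 0.0
    weight_decay: float = 0.0
    max_epochs: int = 30
    n_classes: int = 3
    seed: int = 0

    def widths(self) -> list[int]:
        w = [max(1, int(self.initial_hidden * self.decay_factor**i))
             for i in range(self.n_layers)]
        if any(b > a for a, b in zip(w[:-1], w[1:])):
            raise ValueError("widths must be non-increasing")
        return w

    def validate(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.widths()


class FNN:
    """One ensemble member: Dense+BatchNorm+LeakyReLU+Dropout blocks."""

    LEAKY_SLOPE = 0.01

    def __init__(self, config: FNNConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths = config.widths()
        self.trunk = mlp([config.input_dim, *widths], rng, batch_norm=True,
                         slope=self.LEAKY_SLOPE, dropout=config.dropout)
        self.head = Dense(widths[-1], config.n_classes, rng)
        self.history: list[dict] = []

    def logits(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head.forward(self.trunk.forward(X, train=train), train=train)

    def predict(self, X: np.ndarray) -> np.ndarray:
        cls = self.logits(X, train=False).argmax(axis=1)
        return np.vectorize(CLASS_TO_LABEL.get)(cls)


def default_member_configs(input_dim: int, seed: int = 0, **overrides) -> list[FNNConfig]:
    """The three final member configurations (shared lr/width/depth).

    Member 1: batch 1024, no regularization; member 2: batch 2048 with
    L1 = 0.2 and L2 = 0.1; member 3: batch 2048, no regularization.
    """
    specs = [
        dict(batch_size=1024),
        dict(batch_size=2048, l1=0.2, l2=0.1),
        dict(batch_size=2048),
    ]
    return [
        FNNConfig(input_dim=input_dim, seed=seed + 101 * (i + 1), **{**spec, **overrides})
        for i, spec in enumerate(specs)
    ]


# ---------------------------------------------------------------------------
# Class balancing
# ---------------------------------------------------------------------------

def balance_classes(
    F: FeatureMatrix,
    y: np.ndarray,
    vae: VAE,
    seed: int = 0,
    F_source: FeatureMatrix | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Balance the three classes to the mean class size.

    Returns ``(X, y, provenance)`` where provenance marks each row as real
    or synthetic. Synthetic rows are VAE posterior samples decoded from real
    rows of the same class; ``F_source`` (default: F itself) supplies the
    rows fed to the encoder, letting callers synthesize from the original
    normalized features rather than already-decoded ones.
    """
    y = np.asarray(y)
    if AMBIGUOUS in set(y.tolist()):
        raise ValueError("ambiguous labels (2) must be excluded before balancing")
    src = F_source if F_source is not None else F
    if src.shape[0] != F.shape[0]:
        raise ValueError("F_source must be row-aligned with F")
    classes = [0, 1, -1]
    sizes = {c: int((y == c).sum()) for c in classes}
    missing = [c for c in classes if sizes[c] == 0]
    if missing:
        raise ClassCoverageError(
            f"class(es) {missing} have no real rows; cannot synthesize"
        )
    T = int(round(np.mean(list(sizes.values()))))
    rng = np.random.default_rng(seed)
    X_out, y_out, prov = [], [], []
    from .vae import decode, encode  # local import avoids cycle at module load

    for c in classes:
        idx = np.where(y == c)[0]
        if len(idx) >= T:
            keep = rng.choice(idx, size=T, replace=False)
            X_out.append(F.values[keep])
            y_out.append(np.full(T, c))
            prov.append(np.zeros(T, dtype=bool))
        else:
            X_out.append(F.values[idx])
            y_out.append(np.full(len(idx), c))
            prov.append(np.zeros(len(idx), dtype=bool))
            n_syn = T - len(idx)
            pick = rng.choice(idx, size=n_syn, replace=True)
            src_rows = FeatureMatrix(
                [f"syn{i}" for i in range(n_syn)],
                list(src.col_names),
                src.values[pick],
                stage=src.stage if src.stage in ("normalized", "decoded") else "decoded",
            )
            z = encode(vae, src_rows, sample=True, seed=int(rng.integers(2**31)))
            syn = decode(vae, z)
            X_out.append(syn.values)
            y_out.append(np.full(n_syn, c))
            prov.append(np.ones(n_syn, dtype=bool))
    return np.vstack(X_out), np.concatenate(y_out), np.concatenate(prov)


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

def train_fnn(
    X: np.ndarray,
    y: np.ndarray,
    config: FNNConfig,
    holdout_fraction: float = 0.10,
) -> tuple[FNN, dict]:
    """Train one member on balanced data with a seeded 10% validation split."""
    y = np.asarray(y)
    if AMBIGUOUS in set(y.tolist()):
        raise ValueError("ambiguous labels must never reach a training batch")
    model = FNN(config)
    rng = np.random.default_rng(config.seed + 7)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(holdout_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]
    enc = np.vectorize(LABEL_TO_CLASS.get)
    ytr_c = enc(ytr)
    opt = Adam([model.trunk, model.head], lr=config.learning_rate,
               l1=config.l1, l2=config.l2, weight_decay=config.weight_decay)
    bs = config.batch_size
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(Xtr))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(Xtr), bs):
            sel = order[start : start + bs]
            if sel.size < 2:
                continue
            logits = model.logits(Xtr[sel], train=True)
            loss, grad = cross_entropy(logits, ytr_c[sel])
            if not np.isfinite(loss):
                raise TrainingDivergence(f"non-finite loss at epoch {epoch}")
            model.trunk.backward(model.head.backward(grad))
            opt.step()
            epoch_loss += loss
            n_batches += 1
        model.history.append({"epoch": epoch, "train_loss": epoch_loss / max(1, n_batches)})
    metrics = classification_metrics(model.predict(Xval), yval)
    return model, metrics


@dataclass
class EnsemblePrediction:
    member_labels: np.ndarray  # (3, n_proteins) in {0, 1, -1}
    consensus: np.ndarray      # (n_proteins,) in {0, 1, -1}
    vote_margin: np.ndarray    # agreeing member count: 3, 2, or 0 on splits

    @property
    def predicted_set(self) -> np.ndarray:
        """Indices of proteins with a nonzero consensus label."""
        return np.where(self.consensus != 0)[0]


def predict_targets(members: list[FNN], F: FeatureMatrix) -> EnsemblePrediction:
    """Majority vote over exactly three members; 3-way splits give 0."""
    if len(members) != 3:
        raise ValueError("the ensemble uses exactly three members (ties excluded)")
    labels = np.stack([m.predict(F.values) for m in members])
    n = labels.shape[1]
    consensus = np.zeros(n, dtype=int)
    margin = np.zeros(n, dtype=int)
    for j in range(n):
        vals, counts = np.unique(labels[:, j], return_counts=True)
        top = counts.max()
        if top >= 2:
            consensus[j] = int(vals[counts.argmax()])
            margin[j] = int(top)
        else:  # three distinct labels: conservative no-effect call
            consensus[j] = 0
            margin[j] = 0
    return EnsemblePrediction(labels, consensus, margin)


def classification_metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Macro-averaged one-vs-rest F1, FPR and FNR over the three classes.

    Classes absent from both prediction and truth contribute 0 to the macro
    averages and are reported in ``degenerate_classes``.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.size == 0 or pred.shape != truth.shape:
        raise ValueError("prediction and truth must be equal-length, non-empty")
    if AMBIGUOUS in set(truth.tolist()):
        raise ValueError("truth must exclude the ambiguous class")
    f1s, fprs, fnrs, degenerate = [], [], [], []
    for c in (0, 1, -1):
        tp = int(((pred == c) & (truth == c)).sum())
        fp = int(((pred == c) & (truth != c)).sum())
        fn = int(((pred != c) & (truth == c)).sum())
        tn = int(((pred != c) & (truth != c)).sum())
        if tp + fp + fn == 0:
            f1s.append(0.0)
            degenerate.append(c)
        else:
            f1s.append(2 * tp / (2 * tp + fp + fn))
        fprs.append(fp / (fp + tn) if fp + tn > 0 else 0.0)
        fnrs.append(fn / (fn + tp) if fn + tp > 0 else 0.0)
    return {
        "macro_f1": float(np.mean(f1s)),
        "fpr": float(np.mean(fprs)),
        "fnr": float(np.mean(fnrs)),
        "degenerate_classes": degenerate,
    }


def train_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    configs: list[FNNConfig],
    holdout_fraction: float = 0.10,
) -> tuple[list[FNN], list[dict]]:
    """Train all three members; returns (models, per-member metrics)."""
    if len(configs) != 3:
        raise ValueError("exactly three member configs required")
    models, metrics = [], []
    for cfg in configs:
        m, met = train_fnn(X, y, cfg, holdout_fraction=holdout_fraction)
        models.append(m)
        metrics.append(met)
    return models, metrics
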