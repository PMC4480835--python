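"""Two-output feed-forward networks, balanced early-stopped training, ensembles.

Each member network has a single sigmoid hidden layer and exactly two sigmoid
output units, one for 'neutral' and one for 'effect'.  Training follows a
three-step protocol designed to avoid local maxima:

* S1 — every repetition trains on a freshly drawn class-balanced sample
  (majority class down-sampled to the minority count);
* S2 — after each repetition the AUC on the cross-training fold is recorded
  and the best-scoring weight snapshot kept;
* S3 — training continues at least ten repetitions beyond the current best
  before stopping.

Ten networks are trained, one per cross-validation rotation (8 folds train,
1 cross-train, 1 test).  For new proteins all ten predict; the per-class
outputs are averaged and the final score is the difference
(effect − neutral) scaled to −100 … +100.  The binary decision applies a
threshold (default −0.05 on the raw difference scale), and the reliability
index RI = floor(10·|difference|), capped at 10, with a 0–9 display digit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .features import (
    FeatureDescriptor,
    FeatureMatrix,
    ProviderRegistry,
    Scaler,
    assemble_feature_matrix,
)
from .homology import FoldAssignment, Rotation, crossval_splits
from .io import EFFECT, NEUTRAL, PredictionResult, VariantDataset, VariantRecord

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = -0.05  # on the raw averaged-output-difference scale [-1, 1]


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of one network; ranges follow the training protocol."""

    hidden_units: int = 30
    learning_rate: float = 0.01
    momentum: float = 0.1
    seed: int = 0
    max_stagnant_rounds: int = 10
    max_repetitions: int = 100
    batch_size: int = 32

    def __post_init__(self):
        if not 10 <= self.hidden_units <= 100:
            raise ValueError("hidden_units must be in 10..100")
        if not 0.005 <= self.learning_rate <= 0.1:
            raise ValueError("learning_rate must be in 0.005..0.1")
        if not 0.01 <= self.momentum <= 0.3:
            raise ValueError("momentum must be in 0.01..0.3")
        if self.max_stagnant_rounds < 10:
            raise ValueError("early stopping requires at least 10 stagnant rounds")


def default_grid() -> list[NetworkConfig]:
    """Coarse sample of the hyperparameter ranges for desk-scale search."""
    grid = []
    for hidden in (10, 30, 50, 100):
        for lr in (0.005, 0.01, 0.05, 0.1):
            for mom in (0.01, 0.1, 0.3):
                grid.append(NetworkConfig(hidden_units=hidden, learning_rate=lr,
                                          momentum=mom))
    return grid


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


@dataclass
class NetworkModel:
    """Weight snapshot at the best cross-train AUC, plus training history."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    config: NetworkConfig
    history: list[float] = field(default_factory=list)  # cross-train AUC per repetition
    best_auc: float = float("nan")
    best_repetition: int = -1

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Outputs in [0,1]; column 0 = neutral, column 1 = effect."""
        hidden = _sigmoid(X @ self.W1 + self.b1)
        return _sigmoid(hidden @ self.W2 + self.b2)

    def difference(self, X: np.ndarray) -> np.ndarray:
        out = self.forward(X)
        return out[:, 1] - out[:, 0]


def balance_training_set(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-balanced subset (majority down-sampled to minority)."""
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("balancing requires both classes present")
    n = min(len(pos), len(neg))
    take_pos = pos if len(pos) == n else rng.choice(pos, size=n, replace=False)
    take_neg = neg if len(neg) == n else rng.choice(neg, size=n, replace=False)
    idx = np.concatenate([take_pos, take_neg])
    rng.shuffle(idx)
    return idx


def _init_network(n_in: int, config: NetworkConfig, rng: np.random.Generator):
    scale = 1.0 / np.sqrt(max(n_in, 1))
    W1 = rng.uniform(-scale, scale, size=(n_in, config.hidden_units))
    b1 = np.zeros(config.hidden_units)
    W2 = rng.uniform(-0.5, 0.5, size=(config.hidden_units, 2))
    b2 = np.zeros(2)
    return W1, b1, W2, b2


def train_network(X_train: np.ndarray, y_train: np.ndarray,
                  X_crosstrain: np.ndarray, y_crosstrain: np.ndarray,
                  config: NetworkConfig) -> NetworkModel:
    """Train with the balanced, early-stopped repetition protocol.

    One repetition is one pass (mini-batch SGD with momentum, squared-error
    loss against (neutral, effect) targets) over a freshly drawn balanced
    sample.  The returned model is the snapshot at the best cross-train AUC.
    """
    if X_train.shape[0] == 0 or X_crosstrain.shape[0] == 0:
        raise ValueError("training and cross-training sets must be non-empty")
    if X_train.shape[1] != X_crosstrain.shape[1]:
        raise ValueError("feature layouts of train and cross-train differ")
    y_train = np.asarray(y_train)
    y_crosstrain = np.asarray(y_crosstrain)
    rng = np.random.default_rng(config.seed)
    W1, b1, W2, b2 = _init_network(X_train.shape[1], config, rng)
    vW1 = np.zeros_like(W1); vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2); vb2 = np.zeros_like(b2)

    # targets: neutral -> (1, 0), effect -> (0, 1)
    targets = np.column_stack([1.0 - y_train, y_train.astype(float)])

    history: list[float] = []
    best = (-np.inf, -1, None)
    for rep in range(config.max_repetitions):
        idx = balance_training_set(y_train, rng)
        for start in range(0, len(idx), config.batch_size):
            batch = idx[start:start + config.batch_size]
            Xb, Tb = X_train[batch], targets[batch]
            hidden = _sigmoid(Xb @ W1 + b1)
            out = _sigmoid(hidden @ W2 + b2)
            err = out - Tb
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at repetition {rep} (lr={config.learning_rate}, "
                    f"hidden={config.hidden_units})")
            # cross-entropy gradient for sigmoid outputs: no saturation factor
            d_out = err
            d_hidden = (d_out @ W2.T) * hidden * (1.0 - hidden)
            # summed batch gradient == sequential per-pattern updates at this
            # rate (modulo within-batch weight staleness)
            lr = config.learning_rate
            vW2 = config.momentum * vW2 - lr * (hidden.T @ d_out)
            vb2 = config.momentum * vb2 - lr * d_out.sum(axis=0)
            vW1 = config.momentum * vW1 - lr * (Xb.T @ d_hidden)
            vb1 = config.momentum * vb1 - lr * d_hidden.sum(axis=0)
            W2 += vW2; b2 += vb2; W1 += vW1; b1 += vb1
        model = NetworkModel(W1, b1, W2, b2, config)
        auc = float(roc_auc_score(y_crosstrain, model.difference(X_crosstrain)))
        history.append(auc)
        if auc > best[0]:
            best = (auc, rep, (W1.copy(), b1.copy(), W2.copy(), b2.copy()))
        if rep - best[1] >= config.max_stagnant_rounds:
            break
    best_auc, best_rep, weights = best
    return NetworkModel(*weights, config=config, history=history,
                        best_auc=best_auc, best_repetition=best_rep)


def hyperparameter_search(X_train, y_train, X_crosstrain, y_crosstrain,
                          grid: Sequence[NetworkConfig]) -> NetworkConfig:
    """Config with maximal cross-train AUC; ties -> fewer hidden units, lower lr."""
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    scored = []
    for i, config in enumerate(grid):
        model = train_network(X_train, y_train, X_crosstrain, y_crosstrain, config)
        scored.append((-model.best_auc, config.hidden_units, config.learning_rate, i))
    scored.sort()
    return grid[scored[0][3]]


@dataclass
class EnsembleMember:
    model: NetworkModel
    scaler: Scaler
    rotation: Rotation


@dataclass
class EnsembleModel:
    """Ten trained networks plus the feature layout they share.

    ``crossval_outputs`` keeps each rotation's untouched test-fold outputs
    (variant row indices, neutral and effect outputs of that rotation's own
    network) for evaluation.
    """

    members: list[EnsembleMember]
    descriptors: list[FeatureDescriptor]
    threshold: float = DEFAULT_THRESHOLD
    crossval_outputs: list[tuple[list[int], np.ndarray]] = field(default_factory=list)

    def predict_outputs(self, X_raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Average (neutral, effect) outputs over all members for raw feature rows."""
        outs = np.zeros((X_raw.shape[0], 2))
        for member in self.members:
            outs += member.model.forward(member.scaler.transform(X_raw))
        outs /= len(self.members)
        return outs[:, 0], outs[:, 1]


def reliability_index(avg_effect: float, avg_neutral: float) -> tuple[int, int]:
    """RI = floor(10·|effect − neutral|) capped at 10; display digit caps at 9."""
    for value in (avg_effect, avg_neutral):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"network outputs must be in [0, 1], got {value}")
    ri = min(int(np.floor(10.0 * abs(avg_effect - avg_neutral))), 10)
    return ri, min(ri, 9)


def classify(difference: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    return EFFECT if difference > threshold else NEUTRAL


def _result(variant: VariantRecord, out_neutral: float, out_effect: float,
            threshold: float) -> PredictionResult:
    diff = out_effect - out_neutral
    ri, digit = reliability_index(out_effect, out_neutral)
    return PredictionResult(
        protein_id=variant.protein_id, position=variant.position,
        wt_aa=variant.wt_aa, var_aa=variant.var_aa,
        avg_output_effect=float(out_effect), avg_output_neutral=float(out_neutral),
        score=float(diff * 100.0), predicted_class=classify(diff, threshold),
        ri=ri, display_digit=digit)


def train_ensemble(dataset: VariantDataset, folds: FoldAssignment,
                   descriptors: Sequence[FeatureDescriptor],
                   registry: ProviderRegistry,
                   grid: Sequence[NetworkConfig] | NetworkConfig | None = None,
                   seed: int = 0,
                   threshold: float = DEFAULT_THRESHOLD) -> EnsembleModel:
    """Train one network per rotation on its 8 train folds, early-stopped on its
    cross-train fold; test-fold outputs are stored untouched for evaluation.

    With a multi-config grid a hyperparameter search runs per rotation on the
    rotation's own cross-training fold.  Normalization is fitted on each
    rotation's training rows only.
    """
    if isinstance(grid, NetworkConfig):
        grid = [grid]
    grid = list(grid) if grid is not None else [NetworkConfig()]
    labeled = dataset.labeled()
    if not labeled:
        raise ValueError("dataset has no labeled variants")
    fm = assemble_feature_matrix(dataset, list(descriptors), registry, variants=labeled)
    kept = [labeled[i] for i in fm.variant_indices]
    y = np.array([1 if v.label == EFFECT else 0 for v in kept])
    row_fold = np.array([folds.protein_to_fold[v.protein_id] for v in kept])

    rotations = crossval_splits(folds)
    seeds = np.random.SeedSequence(seed).generate_state(len(rotations))
    members, crossval_outputs = [], []
    for rotation, rot_seed in zip(rotations, seeds):
        train_rows = np.flatnonzero(np.isin(row_fold, rotation.train_folds))
        ct_rows = np.flatnonzero(row_fold == rotation.crosstrain_fold)
        test_rows = np.flatnonzero(row_fold == rotation.test_fold)
        if len(np.unique(y[train_rows])) < 2:
            raise ValueError(
                f"rotation with test fold {rotation.test_fold}: single-class training set")
        scaler = Scaler.fit(fm.X, train_rows)
        Xs = scaler.transform(fm.X)
        base = int(rot_seed % (2 ** 31))
        configs = [replace(c, seed=base + j) for j, c in enumerate(grid)]
        if len(configs) > 1:
            config = hyperparameter_search(Xs[train_rows], y[train_rows],
                                           Xs[ct_rows], y[ct_rows], configs)
        else:
            config = configs[0]
        model = train_network(Xs[train_rows], y[train_rows], Xs[ct_rows], y[ct_rows],
                              config)
        members.append(EnsembleMember(model=model, scaler=scaler, rotation=rotation))
        crossval_outputs.append((test_rows.tolist(), model.forward(Xs[test_rows])))
        logger.info("rotation test=%d: cross-train AUC %.4f at repetition %d",
                    rotation.test_fold, model.best_auc, model.best_repetition)
    ensemble = EnsembleModel(members=members, descriptors=list(descriptors),
                             threshold=threshold, crossval_outputs=crossval_outputs)
    ensemble._crossval_variants = kept  # evaluation convenience, not serialized
    return ensemble


def crossval_predictions(ensemble: EnsembleModel) -> list[PredictionResult]:
    """Per-rotation test-fold predictions (each variant predicted exactly once,
    by the one network that never saw it or any of its homologs)."""
    variants = getattr(ensemble, "_crossval_variants", None)
    if variants is None:
        raise ValueError("ensemble has no stored cross-validation outputs")
    results = []
    for rows, outs in ensemble.crossval_outputs:
        for i, row in enumerate(rows):
            results.append(_result(variants[row], outs[i, 0], outs[i, 1],
                                   ensemble.threshold))
    return results


def crossval_labels(ensemble: EnsembleModel) -> list[str]:
    variants = ensemble._crossval_variants
    labels = []
    for rows, _ in ensemble.crossval_outputs:
        labels.extend(variants[row].label for row in rows)
    return labels


def predict(ensemble: EnsembleModel, dataset: VariantDataset,
            registry: ProviderRegistry,
            variants: Sequence[VariantRecord] | None = None) -> list[PredictionResult]:
    """Ensemble predictions: per-class averages over all members, score, class, RI."""
    if variants is None:
        variants = dataset.variants
    fm = assemble_feature_matrix(dataset, ensemble.descriptors, registry,
                                 variants=list(variants))
    expected = len(ensemble.members[0].scaler.mean)
    if fm.X.shape[1] != expected:
        raise ValueError(
            f"feature layout mismatch: ensemble expects {expected} columns, "
            f"got {fm.X.shape[1]}")
    out_neutral, out_effect = ensemble.predict_outputs(fm.X)
    return [
        _result(variants[row], out_neutral[i], out_effect[i], ensemble.threshold)
        for i, row in enumerate(fm.variant_indices)
    ]


FORMAT_VERSION = 1


def save_ensemble(ensemble: EnsembleModel, path) -> None:
    """Serialize weights, descriptors, normalization and threshold to JSON."""
    payload = {
        "format_version": FORMAT_VERSION,
        "threshold": ensemble.threshold,
        "descriptors": [
            {"provider": d.provider, "window": d.window, "name": d.name}
            for d in ensemble.descriptors
        ],
        "members": [
            {
                "rotation": {"train": list(m.rotation.train_folds),
                             "crosstrain": m.rotation.crosstrain_fold,
                             "test": m.rotation.test_fold},
                "scaler": m.scaler.to_dict(),
                "config": {
                    "hidden_units": m.model.config.hidden_units,
                    "learning_rate": m.model.config.learning_rate,
                    "momentum": m.model.config.momentum,
                    "seed": m.model.config.seed,
                    "max_stagnant_rounds": m.model.config.max_stagnant_rounds,
                    "max_repetitions": m.model.config.max_repetitions,
                    "batch_size": m.model.config.batch_size,
                },
                "weights": {"W1": m.model.W1.tolist(), "b1": m.model.b1.tolist(),
                            "W2": m.model.W2.tolist(), "b2": m.model.b2.tolist()},
                "best_auc": m.model.best_auc,
                "best_repetition": m.model.best_repetition,
            }
            for m in ensemble.members
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_ensemble(path) -> EnsembleModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported model format {payload.get('format_version')!r}")
    descriptors = [FeatureDescriptor(provider=d["provider"], window=d["window"],
                                     name=d["name"])
                   for d in payload["descriptors"]]
    members = []
    for m in payload["members"]:
        config = NetworkConfig(**m["config"])
        model = NetworkModel(
            W1=np.array(m["weights"]["W1"]), b1=np.array(m["weights"]["b1"]),
            W2=np.array(m["weights"]["W2"]), b2=np.array(m["weights"]["b2"]),
            config=config, best_auc=m["best_auc"],
            best_repetition=m["best_repetition"])
        rotation = Rotation(tuple(m["rotation"]["train"]), m["rotation"]["crosstrain"],
                            m["rotation"]["test"])
        members.append(EnsembleMember(model=model,
                                      scaler=Scaler.from_dict(m["scaler"]),
                                      rotation=rotation))
    return EnsembleModel(members=members, descriptors=descriptors,
                         threshold=payload["threshold"])
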