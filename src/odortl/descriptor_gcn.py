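"""Multi-label odor-descriptor graph convolutional network.

A molecule is a graph of heavy atoms; three graph-convolutional layers
(symmetric-normalized neighbor aggregation with self-loops,
``H' = relu(D^{-1/2}(A+I)D^{-1/2} H W + b)``) build per-atom states, a
mean-pooling readout collapses them to a graph vector, and two dense layers
plus a sigmoid output head predict the probability of each semantic odor
descriptor ("fruity", "floral", ...). Training minimizes mean per-label
binary cross-entropy with Adam on mini-batches, with patience-based early
stopping on validation loss.

The 128-unit first dense layer doubles as the transfer representation: its
activations in inference mode (dropout off) are the molecular embedding
handed to the detection-threshold regressor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from sklearn.metrics import average_precision_score, f1_score

from . import _nn
from .chemio import (
    ATOM_FEATURE_DIM,
    FEATURE_SCHEMA_VERSION,
    DescriptorRecord,
    DescriptorVocabulary,
    MolecularGraph,
    MoleculeRecord,
    to_molecular_graph,
)


@dataclass
class GCNConfig:
    """Hyperparameters of the descriptor network.

    Defaults are the tuned values of the published model: conv stack
    64-128-64, dense stack 128-64, Adam at 0.0013, two dropout rates of 0.5,
    batch size 16, up to 300 epochs with early-stopping patience 30.
    """

    conv_units: tuple[int, ...] = (64, 128, 64)
    linear_units: tuple[int, ...] = (128, 64)
    learning_rate: float = 0.0013
    dropout_1: float = 0.5
    dropout_2: float = 0.5
    batch_size: int = 16
    max_epochs: int = 300
    patience: int = 30
    seed: int = 0

    def __post_init__(self):
        if any(u <= 0 for u in (*self.conv_units, *self.linear_units)):
            raise ValueError("all unit counts must be positive")
        for d in (self.dropout_1, self.dropout_2):
            if not 0.0 <= d < 1.0:
                raise ValueError(f"dropout must be in [0, 1), got {d}")
        if self.batch_size < 1 or self.max_epochs < 1 or self.patience < 1:
            raise ValueError("batch_size, max_epochs and patience must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "GCNConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("conv_units", "linear_units"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["conv_units"] = list(self.conv_units)
        data["linear_units"] = list(self.linear_units)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class TrainingHistory:
    """Per-epoch record of losses and validation metrics."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    auc_prc: list[float] = field(default_factory=list)
    f1: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def __len__(self) -> int:
        return len(self.train_loss)


@dataclass
class DescriptorDataset:
    """Descriptor records together with the vocabulary their labels index."""

    records: list[DescriptorRecord]
    vocabulary: DescriptorVocabulary

    def __len__(self) -> int:
        return len(self.records)

    def label_matrix(self) -> np.ndarray:
        return np.stack([r.labels for r in self.records]).astype(np.float64)


def split_dataset(records: list, fractions=(0.6, 0.2, 0.2), seed: int = 0):
    """Random disjoint split of ``records`` into len(fractions) parts.

    Sizes follow the fractions up to rounding (cumulative rounding, so the
    parts always sum to the whole). Deterministic for a given seed.
    """
    fractions = tuple(fractions)
    if any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be nonnegative and sum to 1, got {fractions}")
    n = len(records)
    perm = np.random.default_rng(seed).permutation(n)
    bounds = [int(round(c * n)) for c in np.cumsum(fractions)]
    parts, start = [], 0
    for b in bounds:
        parts.append([records[i] for i in perm[start:b]])
        start = b
    return tuple(parts)


def _normalized_adjacency(graph: MolecularGraph) -> np.ndarray:
    """D^{-1/2} (A + I) D^{-1/2} for a molecular graph."""
    n = graph.n_atoms
    a = np.eye(n)
    for i, j in graph.edges:
        a[i, j] = 1.0
        a[j, i] = 1.0
    dinv = 1.0 / np.sqrt(a.sum(axis=1))
    return a * dinv[:, None] * dinv[None, :]


class GCNModel:
    """Trained (or initialized) descriptor network.

    Holds the parameter arrays, the descriptor vocabulary and the feature
    schema version the model was built against.
    """

    def __init__(self, config: GCNConfig, vocabulary: DescriptorVocabulary,
                 feature_dim: int = ATOM_FEATURE_DIM, rng: np.random.Generator | None = None):
        if len(vocabulary) < 2:
            raise ValueError(
                f"descriptor vocabulary must contain >= 2 labels, got {len(vocabulary)}"
            )
        self.config = config
        self.vocabulary = vocabulary
        self.feature_dim = feature_dim
        self.feature_schema_version = FEATURE_SCHEMA_VERSION
        rng = rng or np.random.default_rng(config.seed)
        dims = [feature_dim, *config.conv_units]
        p: dict[str, np.ndarray] = {}
        for k in range(len(config.conv_units)):
            p[f"conv{k}_W"] = _nn.glorot(rng, dims[k], dims[k + 1])
            p[f"conv{k}_b"] = np.zeros(dims[k + 1])
        lin_dims = [config.conv_units[-1], *config.linear_units]
        for k in range(len(config.linear_units)):
            p[f"lin{k}_W"] = _nn.glorot(rng, lin_dims[k], lin_dims[k + 1])
            p[f"lin{k}_b"] = np.zeros(lin_dims[k + 1])
        p["out_W"] = _nn.glorot(rng, config.linear_units[-1], len(vocabulary))
        p["out_b"] = np.zeros(len(vocabulary))
        self.params = p

    # -- forward ------------------------------------------------------------

    def _forward_graph(self, graph: MolecularGraph, training: bool = False,
                       rng: np.random.Generator | None = None):
        """Forward pass on one graph; returns (probs, cache for backprop)."""
        if graph.node_features.shape[1] != self.feature_dim:
            raise ValueError(
                f"feature schema mismatch: model expects {self.feature_dim} features, "
                f"graph has {graph.node_features.shape[1]}"
            )
        p, cfg = self.params, self.config
        ahat = _normalized_adjacency(graph)
        h = graph.node_features
        cache = {"ahat": ahat, "conv_in": [], "conv_z": []}
        for k in range(len(cfg.conv_units)):
            ah = ahat @ h
            z = ah @ p[f"conv{k}_W"] + p[f"conv{k}_b"]
            cache["conv_in"].append(ah)
            cache["conv_z"].append(z)
            h = _nn.relu(z)
        g = h.mean(axis=0)
        cache["n_atoms"] = graph.n_atoms
        cache["pooled"] = g
        drops = (cfg.dropout_1, cfg.dropout_2)
        x = g
        cache["lin_in"], cache["lin_z"], cache["drop_mask"] = [], [], []
        for k in range(len(cfg.linear_units)):
            cache["lin_in"].append(x)
            z = x @ p[f"lin{k}_W"] + p[f"lin{k}_b"]
            cache["lin_z"].append(z)
            x = _nn.relu(z)
            if training and drops[k] > 0:
                mask = (rng.random(x.shape) >= drops[k]) / (1.0 - drops[k])
            else:
                mask = np.ones_like(x)
            cache["drop_mask"].append(mask)
            x = x * mask
        cache["head_in"] = x
        logits = x @ p["out_W"] + p["out_b"]
        probs = _nn.sigmoid(logits)
        return probs, cache

    def _backward_graph(self, probs, y, cache, grads) -> None:
        """Accumulate parameter gradients of mean per-label BCE for one graph."""
        p, cfg = self.params, self.config
        dz = (probs - y) / y.size  # sigmoid+BCE, mean over labels
        grads["out_W"] += np.outer(cache["head_in"], dz)
        grads["out_b"] += dz
        dx = p["out_W"] @ dz
        for k in reversed(range(len(cfg.linear_units))):
            dx = dx * cache["drop_mask"][k]
            dzk = dx * _nn.drelu(cache["lin_z"][k])
            grads[f"lin{k}_W"] += np.outer(cache["lin_in"][k], dzk)
            grads[f"lin{k}_b"] += dzk
            dx = p[f"lin{k}_W"] @ dzk
        # mean-pool backward: every atom row receives dg / n
        dh = np.repeat(dx[None, :] / cache["n_atoms"], cache["n_atoms"], axis=0)
        ahat = cache["ahat"]
        for k in reversed(range(len(cfg.conv_units))):
            dzk = dh * _nn.drelu(cache["conv_z"][k])
            grads[f"conv{k}_W"] += cache["conv_in"][k].T @ dzk
            grads[f"conv{k}_b"] += dzk.sum(axis=0)
            if k > 0:
                dh = ahat @ (dzk @ p[f"conv{k}_W"].T)

    def predict_proba(self, graphs: list[MolecularGraph]) -> np.ndarray:
        """Per-label descriptor probabilities, shape (n_graphs, n_labels)."""
        if not graphs:
            raise ValueError("empty batch")
        return np.stack([self._forward_graph(g)[0] for g in graphs])

    def embed(self, graph: MolecularGraph) -> np.ndarray:
        """First-dense-layer activations in inference mode (the transfer embedding)."""
        p = self.params
        _, cache = self._forward_graph(graph)
        return _nn.relu(cache["lin_z"][0])

    def _loss(self, graphs, y) -> float:
        probs = self.predict_proba(graphs)
        eps = 1e-12
        return float(
            -np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps))
        )

    # -- persistence ---------------------------------------------------------

    def save(self, path_prefix: str) -> None:
        """Write ``<prefix>.npz`` (parameters) and ``<prefix>.json`` (sidecar)."""
        np.savez(f"{path_prefix}.npz", **self.params)
        sidecar = {
            "config": {**asdict(self.config),
                       "conv_units": list(self.config.conv_units),
                       "linear_units": list(self.config.linear_units)},
            "vocabulary": list(self.vocabulary.labels),
            "feature_dim": self.feature_dim,
            "feature_schema_version": self.feature_schema_version,
        }
        with open(f"{path_prefix}.json", "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path_prefix: str) -> "GCNModel":
        with open(f"{path_prefix}.json", encoding="utf-8") as fh:
            sidecar = json.load(fh)
        if sidecar["feature_schema_version"] != FEATURE_SCHEMA_VERSION:
            raise ValueError(
                "checkpoint was produced under atom-feature schema "
                f"{sidecar['feature_schema_version']}, current is {FEATURE_SCHEMA_VERSION}"
            )
        cfg_data = dict(sidecar["config"])
        cfg_data["conv_units"] = tuple(cfg_data["conv_units"])
        cfg_data["linear_units"] = tuple(cfg_data["linear_units"])
        model = cls(GCNConfig(**cfg_data), DescriptorVocabulary(tuple(sidecar["vocabulary"])),
                    feature_dim=sidecar["feature_dim"])
        with np.load(f"{path_prefix}.npz") as data:
            for k in model.params:
                model.params[k][...] = data[k]
        return model


def gcn_forward(graphs: list[MolecularGraph], model: GCNModel) -> np.ndarray:
    """Inference-mode forward pass: per-label probabilities in [0, 1]."""
    return model.predict_proba(graphs)


def train_gcn(dataset: DescriptorDataset, config: GCNConfig,
              val_dataset: DescriptorDataset | None = None):
    """Train the descriptor network.

    When no explicit validation set is given the dataset is split
    60/20/20 into train/validation/test with the config seed; the test part
    is held out untouched. Early stopping monitors validation loss and the
    parameters from the best epoch are restored before returning.

    Returns ``(model, history)``.
    """
    if len(dataset.vocabulary) < 2:
        raise ValueError("descriptor vocabulary must contain at least 2 labels")
    rng = np.random.default_rng(config.seed)
    if val_dataset is None:
        train_recs, val_recs, _test = split_dataset(dataset.records, (0.6, 0.2, 0.2), config.seed)
    else:
        train_recs, val_recs = dataset.records, val_dataset.records
    if not train_recs or not val_recs:
        raise ValueError("training and validation sets must be non-empty")

    graphs_tr = [to_molecular_graph(r.molecule) for r in train_recs]
    y_tr = np.stack([r.labels for r in train_recs]).astype(np.float64)
    graphs_va = [to_molecular_graph(r.molecule) for r in val_recs]
    y_va = np.stack([r.labels for r in val_recs]).astype(np.float64)

    model = GCNModel(config, dataset.vocabulary, rng=rng)
    opt = _nn.Adam(model.params, lr=config.learning_rate)
    stopper = _nn.EarlyStopper(config.patience)
    history = TrainingHistory()
    best_params = _nn.snapshot(model.params)

    n = len(graphs_tr)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            grads = {k: np.zeros_like(v) for k, v in model.params.items()}
            batch_loss = 0.0
            for i in idx:
                probs, cache = model._forward_graph(graphs_tr[i], training=True, rng=rng)
                eps = 1e-12
                batch_loss += float(-np.mean(
                    y_tr[i] * np.log(probs + eps) + (1 - y_tr[i]) * np.log(1 - probs + eps)))
                model._backward_graph(probs, y_tr[i], cache, grads)
            for k in grads:
                grads[k] /= len(idx)
            opt.step(grads)
            epoch_loss += batch_loss
        epoch_loss /= n
        if not np.isfinite(epoch_loss):
            raise RuntimeError(
                f"training aborted: non-finite loss at epoch {epoch} "
                f"(lr={config.learning_rate}); inspect inputs or lower the learning rate"
            )
        val_loss = model._loss(graphs_va, y_va)
        val_probs = model.predict_proba(graphs_va)
        history.train_loss.append(epoch_loss)
        history.val_loss.append(val_loss)
        history.auc_prc.append(_safe_metric(auc_prc, y_va, val_probs))
        history.f1.append(_safe_metric(f1, y_va, val_probs))
        improved = val_loss < stopper.best_loss
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_params = _nn.snapshot(model.params)
        if stop:
            break
    _nn.restore(model.params, best_params)
    history.best_epoch = stopper.best_epoch
    return model, history


def _safe_metric(fn, y_true, y_score) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return fn(y_true, y_score)
        except ValueError:
            return float("nan")


def auc_prc(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """Macro-averaged area under the precision-recall curve.

    Average precision (step-interpolated PR area) is computed per label and
    averaged; degenerate labels (all-positive or all-negative in ``y_true``)
    are skipped with a warning since their PR curve is undefined.
    """
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_score = np.atleast_2d(np.asarray(y_score, dtype=float))
    if y_true.shape != y_score.shape:
        raise ValueError("y_true and y_score shapes differ")
    vals = []
    for j in range(y_true.shape[1]):
        col = y_true[:, j]
        if col.min() == col.max():
            warnings.warn(f"label {j} is degenerate (all {int(col[0])}); skipped",
                          stacklevel=2)
            continue
        vals.append(average_precision_score(col, y_score[:, j]))
    if not vals:
        raise ValueError("no label with both a positive and a negative example")
    return float(np.mean(vals))


def f1(y_true: np.ndarray, y_prob: np.ndarray, threshold: float = 0.5) -> float:
    """Micro-averaged F1 over all (molecule, label) pairs after thresholding."""
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = (np.asarray(y_prob, dtype=float).ravel() >= threshold).astype(int)
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_prob sizes differ")
    if y_true.sum() == 0 and y_pred.sum() == 0:
        warnings.warn("no true and no predicted positives; F1 defined as 0", stacklevel=2)
        return 0.0
    return float(f1_score(y_true, y_pred, zero_division=0))


def extract_embeddings(model: GCNModel, molecules) -> list[np.ndarray]:
    """Transfer embeddings (128 values per molecule) from a trained model.

    Accepts :class:`MoleculeRecord` or :class:`MolecularGraph` inputs.
    Deterministic: dropout is off and the forward pass is pure NumPy.
    """
    out = []
    for m in molecules:
        graph = m if isinstance(m, MolecularGraph) else to_molecular_graph(m)
        out.append(model.embed(graph))
    return out


def embedding_matrix(model: GCNModel, records: list[MoleculeRecord]) -> np.ndarray:
    """Stack transfer embeddings into an (n_molecules, 128) matrix."""
    return np.stack(extract_embeddings(model, records))
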