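"""Feedforward regressors for odor detection thresholds.

Two variants share this architecture and differ only in their input:

* transfer model — 128-dim molecular embeddings from the descriptor GCN;
* benchmark model — 1024-bit Morgan fingerprints (ECFP4).

Thresholds span several orders of magnitude and must stay positive, so the
network is fitted on natural-log targets with MSE loss and predictions are
mapped back through ``exp``. Hidden layers use ReLU; the output layer is
linear in log space. Training uses Adam with early stopping (best-validation
parameters restored). Hyperparameters (1-3 hidden layers, 96-512 units in
steps of 32, learning rate in {1e-3, 1e-4, 1e-5}) are searched with
Hyperband (successive halving, budget 100 epochs, reduction factor 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import _nn

UNIT_MIN, UNIT_MAX, UNIT_STEP = 96, 512, 32
ALLOWED_LEARNING_RATES = (1e-3, 1e-4, 1e-5)
ALLOWED_INPUT_DIMS = (128, 1024)


def count_layer_parameters(n_in: int, n_out: int) -> int:
    """Trainable parameters of one dense layer with bias: n_in*n_out + n_out."""
    if n_in < 1 or n_out < 1:
        raise ValueError(f"layer dimensions must be >= 1, got ({n_in}, {n_out})")
    return n_in * n_out + n_out


@dataclass
class FNNConfig:
    """Threshold-regressor hyperparameters.

    Defaults are the tuned transfer-model values (three hidden layers
    480/352/416 on the 128-dim embedding input, Adam at 1e-3, 150 epochs with
    patience 10). ``benchmark_default`` gives the tuned fingerprint
    counterpart (448/512/416 on 1024 bits).
    """

    input_dim: int = 128
    hidden_units: tuple[int, ...] = (480, 352, 416)
    learning_rate: float = 1e-3
    max_epochs: int = 150
    patience: int = 10
    batch_size: int | None = None  # None = full batch (datasets are tiny)
    seed: int = 0

    def __post_init__(self):
        self.hidden_units = tuple(self.hidden_units)
        if self.input_dim not in ALLOWED_INPUT_DIMS:
            raise ValueError(
                f"input_dim must be one of {ALLOWED_INPUT_DIMS} "
                f"(embedding or fingerprint width), got {self.input_dim}"
            )
        if not 1 <= len(self.hidden_units) <= 3:
            raise ValueError("hidden_units must have between 1 and 3 layers")
        for u in self.hidden_units:
            if not (UNIT_MIN <= u <= UNIT_MAX) or (u - UNIT_MIN) % UNIT_STEP != 0:
                raise ValueError(
                    f"hidden layer width {u} outside search bounds "
                    f"[{UNIT_MIN}, {UNIT_MAX}] step {UNIT_STEP}"
                )
        if not any(math.isclose(self.learning_rate, lr) for lr in ALLOWED_LEARNING_RATES):
            raise ValueError(
                f"learning_rate must be one of {ALLOWED_LEARNING_RATES}, got {self.learning_rate}"
            )
        if self.max_epochs < 1 or self.patience < 1:
            raise ValueError("max_epochs and patience must be >= 1")

    @classmethod
    def benchmark_default(cls, **overrides) -> "FNNConfig":
        base = dict(input_dim=1024, hidden_units=(448, 512, 416))
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "FNNConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "hidden_units" in data:
            data["hidden_units"] = tuple(data["hidden_units"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["hidden_units"] = list(self.hidden_units)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class RegressionHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def __len__(self) -> int:
        return len(self.train_loss)


class ODTModel:
    """A (possibly trained) threshold regressor.

    ``input_kind`` records whether the model consumes embeddings or
    fingerprints. ``log_output=True`` (the default) means the network
    regresses ln(ODT/ppm) and :func:`predict_odt` exponentiates, so
    predictions are strictly positive by construction.
    """

    def __init__(self, config: FNNConfig, input_kind: str = "embedding",
                 log_output: bool = True, rng: np.random.Generator | None = None):
        self.config = config
        self.input_kind = input_kind
        self.log_output = log_output
        rng = rng or np.random.default_rng(config.seed)
        dims = [config.input_dim, *config.hidden_units, 1]
        self.params: dict[str, np.ndarray] = {}
        for k in range(len(dims) - 1):
            self.params[f"W{k}"] = _nn.glorot(rng, dims[k], dims[k + 1])
            self.params[f"b{k}"] = np.zeros(dims[k + 1])
        self.n_layers = len(dims) - 1

    @property
    def layer_parameter_counts(self) -> list[int]:
        """Per-layer trainable parameter counts, hidden layers then output."""
        dims = [self.config.input_dim, *self.config.hidden_units, 1]
        return [count_layer_parameters(dims[k], dims[k + 1]) for k in range(len(dims) - 1)]

    @property
    def n_parameters(self) -> int:
        return sum(self.layer_parameter_counts)

    def forward(self, X: np.ndarray):
        """Network output in model (log) space; returns (out, cache)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"input has {X.shape[1]} columns, model expects {self.config.input_dim}"
            )
        h = X
        cache = {"acts": [X], "zs": []}
        for k in range(self.n_layers - 1):
            z = h @ self.params[f"W{k}"] + self.params[f"b{k}"]
            h = _nn.relu(z)
            cache["zs"].append(z)
            cache["acts"].append(h)
        k = self.n_layers - 1
        out = (h @ self.params[f"W{k}"] + self.params[f"b{k}"]).ravel()
        return out, cache

    def _backward(self, dout: np.ndarray, cache) -> dict[str, np.ndarray]:
        grads = {}
        k = self.n_layers - 1
        h = cache["acts"][-1]
        grads[f"W{k}"] = h.T @ dout[:, None]
        grads[f"b{k}"] = dout.sum(keepdims=True)
        dh = dout[:, None] @ self.params[f"W{k}"].T
        for k in reversed(range(self.n_layers - 1)):
            dz = dh * _nn.drelu(cache["zs"][k])
            grads[f"W{k}"] = cache["acts"][k].T @ dz
            grads[f"b{k}"] = dz.sum(axis=0)
            dh = dz @ self.params[f"W{k}"].T
        return grads


def build_fnn(config: FNNConfig, input_kind: str | None = None,
              log_output: bool = True) -> ODTModel:
    """Instantiate an untrained regressor from a validated config.

    ``input_kind`` defaults from the input width: 128 → "embedding",
    1024 → "fingerprint".
    """
    if input_kind is None:
        input_kind = "embedding" if config.input_dim == 128 else "fingerprint"
    return ODTModel(config, input_kind=input_kind, log_output=log_output)


def predict_odt(model: ODTModel, X: np.ndarray) -> np.ndarray:
    """Predict detection thresholds in ppm (strictly positive).

    The network output is in log space; exponentiation maps it back, which
    guarantees positivity for any parameters and any input.
    """
    out, _ = model.forward(X)
    return np.exp(out) if model.log_output else out


def _fit(model: ODTModel, X_tr, y_tr, X_va, y_va, max_epochs: int,
         patience: int, rng: np.random.Generator) -> RegressionHistory:
    """Adam/MSE training loop with early stopping; mutates model in place."""
    opt = _nn.Adam(model.params, lr=model.config.learning_rate)
    stopper = _nn.EarlyStopper(patience)
    history = RegressionHistory()
    best = _nn.snapshot(model.params)
    n = len(y_tr)
    bs = model.config.batch_size or n
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            out, cache = model.forward(X_tr[idx])
            resid = out - y_tr[idx]
            loss = float(np.mean(resid**2))
            grads = model._backward(2.0 * resid / len(idx), cache)
            opt.step(grads)
            epoch_loss += loss * len(idx)
        epoch_loss /= n
        if not np.isfinite(epoch_loss):
            raise RuntimeError(f"training aborted: non-finite loss at epoch {epoch}")
        val_out, _ = model.forward(X_va)
        val_loss = float(np.mean((val_out - y_va) ** 2))
        history.train_loss.append(epoch_loss)
        history.val_loss.append(val_loss)
        improved = val_loss < stopper.best_loss
        stop = stopper.update(epoch, val_loss)
        if improved:
            best = _nn.snapshot(model.params)
        if stop:
            break
    _nn.restore(model.params, best)
    history.best_epoch = stopper.best_epoch
    return history


def _train_val_split(n: int, seed: int, val_fraction: float = 0.4):
    perm = np.random.default_rng(seed).permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    return perm[n_val:], perm[:n_val]


def train_odt_fnn(X: np.ndarray, odt_ppm: np.ndarray, config: FNNConfig,
                  log_transform: bool = True,
                  split: tuple[np.ndarray, np.ndarray] | None = None):
    """Train a threshold regressor.

    Targets must be strictly positive (ppm); they are converted to natural
    logs for fitting and predictions are exponentiated back. The data are
    split 60/40 into train/validation with the config seed unless an explicit
    ``split`` of index arrays is supplied. Early stopping restores the
    parameters of the best validation epoch.

    ``log_transform=False`` fits the raw targets with an identity output
    transform (training is then step-for-step identical to fitting ln-targets
    with the default pipeline under the same seed).

    Returns ``(model, history)``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(odt_ppm, dtype=np.float64)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but {y.shape[0]} targets given")
    if y.shape[0] < 3:
        raise ValueError(f"need at least 3 samples to fit, got {y.shape[0]}")
    if log_transform:
        if np.any(y <= 0):
            bad = np.flatnonzero(y <= 0)
            raise ValueError(f"all thresholds must be > 0 ppm; offending rows: {bad.tolist()}")
        t = np.log(y)
    else:
        t = y
    tr, va = split if split is not None else _train_val_split(len(y), config.seed)
    rng = np.random.default_rng(config.seed + 1)  # init + batch order
    model = build_fnn(config, log_output=log_transform)
    history = _fit(model, X[tr], t[tr], X[va], t[va],
                   config.max_epochs, config.patience, rng)
    return model, history


# ---------------------------------------------------------------------------
# Hyperband
# ---------------------------------------------------------------------------


@dataclass
class HyperbandSettings:
    """Budget parameters of the Hyperband search."""

    max_epochs_per_model: int = 100
    reduction_factor: int = 3
    # objective: validation MSE in log space, fixed split across candidates

    def __post_init__(self):
        if self.reduction_factor < 2:
            raise ValueError("reduction_factor must be >= 2")
        if self.max_epochs_per_model < 1:
            raise ValueError("max_epochs_per_model must be >= 1")


@dataclass
class FNNSearchSpace:
    """Discrete hyperparameter space for :func:`hyperband_search`."""

    input_dim: int = 128
    n_layers: tuple[int, int] = (1, 3)
    units: tuple[int, int, int] = (UNIT_MIN, UNIT_MAX, UNIT_STEP)  # (lo, hi, step)
    learning_rates: tuple[float, ...] = ALLOWED_LEARNING_RATES

    def __post_init__(self):
        lo, hi = self.n_layers
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid layer-count bounds {self.n_layers}")
        if not self.learning_rates:
            raise ValueError("empty learning-rate grid")
        ulo, uhi, ustep = self.units
        if uhi < ulo or ustep < 1 or (uhi - ulo) % ustep != 0:
            raise ValueError(f"invalid unit bounds {self.units}")

    @property
    def n_configurations(self) -> int:
        ulo, uhi, ustep = self.units
        n_units = (uhi - ulo) // ustep + 1
        lo, hi = self.n_layers
        return len(self.learning_rates) * sum(n_units**d for d in range(lo, hi + 1))

    def sample(self, rng: np.random.Generator, **config_overrides) -> FNNConfig:
        ulo, uhi, ustep = self.units
        depth = int(rng.integers(self.n_layers[0], self.n_layers[1] + 1))
        units = tuple(int(rng.integers(0, (uhi - ulo) // ustep + 1)) * ustep + ulo
                      for _ in range(depth))
        lr = float(rng.choice(np.asarray(self.learning_rates)))
        return FNNConfig(input_dim=self.input_dim, hidden_units=units,
                         learning_rate=lr, **config_overrides)


def hyperband_schedule(R: int, eta: int) -> list[list[tuple[int, int]]]:
    """Analytic Hyperband bracket schedule for budget ``R`` and factor ``eta``.

    Returns one list per bracket of ``(n_models, epochs_each)`` rungs.
    """
    s_max = int(math.floor(math.log(R) / math.log(eta)))
    brackets = []
    for s in range(s_max, -1, -1):
        n = int(math.ceil((s_max + 1) * eta**s / (s + 1)))
        r = R * eta**-s
        rungs = []
        for i in range(s + 1):
            n_i = int(math.floor(n * eta**-i))
            r_i = int(round(r * eta**i))
            rungs.append((n_i, max(1, r_i)))
        brackets.append(rungs)
    return brackets


@dataclass
class HyperbandResult:
    best_config: FNNConfig
    best_val_mse: float
    total_epochs_trained: int
    n_configs_evaluated: int


def hyperband_search(X: np.ndarray, odt_ppm: np.ndarray, space: FNNSearchSpace,
                     settings: HyperbandSettings | None = None, seed: int = 0,
                     return_result: bool = False):
    """Hyperband hyperparameter search for the threshold regressor.

    Successive-halving brackets with reduction factor ``eta`` and per-model
    budget cap ``R`` epochs; candidates are sampled uniformly from ``space``
    and retrained from scratch at each rung (models are tiny, so resume
    bookkeeping is not worth its complexity). The 40% validation partition is
    drawn once from ``seed`` and shared by every candidate so validation
    losses (MSE on ln-scale targets) are comparable. Returns the evaluated
    configuration with the lowest validation MSE (the full ``HyperbandResult``
    when ``return_result`` is set).
    """
    settings = settings or HyperbandSettings()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(odt_ppm, dtype=np.float64)
    if np.any(y <= 0):
        raise ValueError("all thresholds must be > 0 ppm")
    t = np.log(y)
    tr, va = _train_val_split(len(y), seed)
    rng = np.random.default_rng(seed)

    R, eta = settings.max_epochs_per_model, settings.reduction_factor
    best_cfg, best_mse = None, np.inf
    total_epochs = 0
    n_evaluated = 0
    for rungs in hyperband_schedule(R, eta):
        n0 = rungs[0][0]
        candidates = [space.sample(rng) for _ in range(n0)]
        n_evaluated += len(candidates)
        scores = None
        for n_i, r_i in rungs:
            if scores is not None:  # keep the top n_i from the previous rung
                order = np.argsort(scores)[:n_i]
                candidates = [candidates[j] for j in order]
            scores = []
            for cfg in candidates:
                model = build_fnn(cfg)
                hist = _fit(model, X[tr], t[tr], X[va], t[va],
                            max_epochs=r_i, patience=max(cfg.patience, r_i),
                            rng=np.random.default_rng(seed + 1))
                total_epochs += len(hist)
                val_mse = hist.val_loss[hist.best_epoch]
                scores.append(val_mse)
                if val_mse < best_mse:
                    best_mse, best_cfg = val_mse, cfg
    result = HyperbandResult(best_config=best_cfg, best_val_mse=float(best_mse),
                             total_epochs_trained=total_epochs,
                             n_configs_evaluated=n_evaluated)
    return result if return_result else best_cfg
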