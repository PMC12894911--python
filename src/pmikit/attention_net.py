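"""Attention-gated feed-forward regression of the post-mortem interval.

The model is a dense feed-forward network whose optional first layer is
a per-feature *attention gate*: feature ``i`` is passed through its own
single node,

    a_i = relu(w_i * x_i + b_i),

with no cross-feature mixing. The gate acts as data-driven feature
selection — a feature whose weight is driven to zero is switched off —
and its activations are what the downstream trajectory analysis
correlates with PMI. The gate is followed by 1-4 dense ReLU layers with
dropout and a single linear output node (days).

Everything is implemented directly on numpy arrays: forward pass,
backpropagation, Adam, minibatch training with early stopping (patience
on the validation loss, best weights restored), and a seeded random
hyperparameter search. Training is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .tables import FeatureTable, NormalizationParams

HP_RANGES = {
    "n_hidden_layers": (1, 4),
    "nodes": (32, 512),
    "dropout": (0.05, 0.5),
    "learning_rate": (1e-4, 1e-2),
}


class ModelConfigError(ValueError):
    pass


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class HyperParams:
    """One point of the search space.

    Ranges: 1-4 hidden layers of 32-512 nodes, per-layer dropout in
    [0.05, 0.5], learning rate in [1e-4, 1e-2]. The default instance is
    the selected architecture: attention gate, one 288-node dense layer
    with dropout 0.15, learning rate 5e-3.
    """

    use_attention: bool = True
    n_hidden_layers: int = 1
    nodes_per_layer: tuple[int, ...] = (288,)
    dropout_per_layer: tuple[float, ...] = (0.15,)
    learning_rate: float = 5e-3
    seed: int = 0
    loss: str = "mse"  # or "mae"
    batch_size: int = 64
    output_activation: str = "linear"  # or "relu"
    attention_bias: bool = True

    def __post_init__(self) -> None:
        lo, hi = HP_RANGES["n_hidden_layers"]
        if not lo <= self.n_hidden_layers <= hi:
            raise ModelConfigError(
                f"n_hidden_layers must be in [{lo},{hi}], got {self.n_hidden_layers}"
            )
        if len(self.nodes_per_layer) != self.n_hidden_layers:
            raise ModelConfigError("nodes_per_layer length != n_hidden_layers")
        if len(self.dropout_per_layer) != self.n_hidden_layers:
            raise ModelConfigError("dropout_per_layer length != n_hidden_layers")
        lo, hi = HP_RANGES["nodes"]
        if any(not lo <= n <= hi for n in self.nodes_per_layer):
            raise ModelConfigError(f"hidden nodes must be in [{lo},{hi}]")
        lo, hi = HP_RANGES["dropout"]
        if any(not lo <= d <= hi for d in self.dropout_per_layer):
            raise ModelConfigError(f"dropout must be in [{lo},{hi}]")
        lo, hi = HP_RANGES["learning_rate"]
        if not lo <= self.learning_rate <= hi:
            raise ModelConfigError(f"learning rate must be in [{lo},{hi}]")
        if self.loss not in ("mse", "mae"):
            raise ModelConfigError(f"unknown loss {self.loss!r}")
        if self.output_activation not in ("linear", "relu"):
            raise ModelConfigError(
                f"unknown output activation {self.output_activation!r}"
            )


def attention_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-feature gate ``relu(w_i * x_i + b_i)``; no cross-feature mixing.

    ``x`` may be a vector or a (samples x features) matrix.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    b = np.asarray(b, dtype=float)
    if x.shape[-1] != w.shape[0] or w.shape != b.shape:
        raise ModelConfigError(
            f"length mismatch: x has {x.shape[-1]} features, "
            f"w has {w.shape[0]}, b has {b.shape[0]}"
        )
    return np.maximum(w * x + b, 0.0)


class EarlyStopper:
    """Patience-based stopping that tracks the best epoch.

    ``update`` returns True when the validation loss has not improved
    for ``patience`` consecutive epochs; the best epoch and loss are
    retained so the caller can restore the corresponding weights.
    """

    def __init__(self, patience: int = 25, min_delta: float = 0.0) -> None:
        self.patience = patience
        self.min_delta = min_delta
        self.best_loss = np.inf
        self.best_epoch = -1
        self._since_best = 0

    def update(self, epoch: int, loss: float) -> bool:
        if loss < self.best_loss - self.min_delta:
            self.best_loss = loss
            self.best_epoch = epoch
            self._since_best = 0
        else:
            self._since_best += 1
        return self._since_best >= self.patience


class PMIRegressor:
    """The attention-gated FFNN, trained with Adam on minibatches."""

    def __init__(self, hp: HyperParams, n_features: int) -> None:
        if n_features < 1:
            raise ModelConfigError("n_features must be >= 1")
        self.hp = hp
        self.n_features = n_features
        self.rng = np.random.default_rng(hp.seed)
        self.params: dict[str, np.ndarray] = {}
        self._init_params()
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "val_mae": []}
        self.best_epoch: int | None = None
        self.best_val_loss: float | None = None
        self.stopped_epoch: int | None = None
        self.feature_order: list[str] | None = None
        self.normalization: NormalizationParams | None = None

    # -- construction ---------------------------------------------------
    def _init_params(self) -> None:
        p = self.params
        if self.hp.use_attention:
            # identity-at-init gate: starts as a plain ReLU pass-through
            p["att_w"] = np.ones(self.n_features)
            p["att_b"] = np.zeros(self.n_features)
        fan_in = self.n_features
        for layer, n_out in enumerate(self.hp.nodes_per_layer):
            p[f"W{layer}"] = self.rng.normal(
                scale=np.sqrt(2.0 / fan_in), size=(fan_in, n_out)
            )
            p[f"b{layer}"] = np.zeros(n_out)
            fan_in = n_out
        p["W_out"] = self.rng.normal(scale=np.sqrt(2.0 / fan_in), size=(fan_in, 1))
        p["b_out"] = np.zeros(1)

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward / backward ---------------------------------------------
    def _forward(
        self, X: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ) -> dict:
        cache: dict = {"X": X}
        h = X
        if self.hp.use_attention:
            pre = self.params["att_w"] * X + self.params["att_b"]
            h = np.maximum(pre, 0.0)
            cache["att_pre"] = pre
        cache["h_in"] = h
        hs, zs, masks = [], [], []
        for layer, drop in enumerate(self.hp.dropout_per_layer):
            z = h @ self.params[f"W{layer}"] + self.params[f"b{layer}"]
            h = np.maximum(z, 0.0)
            if training and drop > 0:
                mask = (rng.uniform(size=h.shape) >= drop) / (1.0 - drop)
                h = h * mask
            else:
                mask = None
            zs.append(z)
            masks.append(mask)
            hs.append(h)
        out = h @ self.params["W_out"] + self.params["b_out"]
        if self.hp.output_activation == "relu":
            cache["out_pre"] = out
            out = np.maximum(out, 0.0)
        cache.update(hs=hs, zs=zs, masks=masks, out=out)
        return cache

    def _loss(self, out: np.ndarray, y: np.ndarray) -> float:
        r = out.ravel() - y
        return float(np.mean(r**2) if self.hp.loss == "mse" else np.mean(np.abs(r)))

    def _backward(self, cache: dict, y: np.ndarray) -> dict[str, np.ndarray]:
        X = cache["X"]
        n = X.shape[0]
        r = cache["out"].ravel() - y
        if self.hp.loss == "mse":
            dout = (2.0 * r / n)[:, None]
        else:
            dout = (np.sign(r) / n)[:, None]
        if self.hp.output_activation == "relu":
            dout = dout * (cache["out_pre"] > 0)
        grads: dict[str, np.ndarray] = {}
        h_last = cache["hs"][-1] if cache["hs"] else cache["h_in"]
        grads["W_out"] = h_last.T @ dout
        grads["b_out"] = dout.sum(axis=0)
        dh = dout @ self.params["W_out"].T
        for layer in range(self.hp.n_hidden_layers - 1, -1, -1):
            mask = cache["masks"][layer]
            if mask is not None:
                dh = dh * mask
            dz = dh * (cache["zs"][layer] > 0)
            h_prev = cache["hs"][layer - 1] if layer > 0 else cache["h_in"]
            grads[f"W{layer}"] = h_prev.T @ dz
            grads[f"b{layer}"] = dz.sum(axis=0)
            dh = dz @ self.params[f"W{layer}"].T
        if self.hp.use_attention:
            datt = dh * (cache["att_pre"] > 0)
            grads["att_w"] = (datt * X).sum(axis=0)
            grads["att_b"] = datt.sum(axis=0)
        return grads

    def loss_and_gradients(
        self, X: np.ndarray, y: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Dropout-free loss and analytic gradients (for verification)."""
        cache = self._forward(np.asarray(X, dtype=float), training=False)
        y = np.asarray(y, dtype=float)
        return self._loss(cache["out"], y), self._backward(cache, y)

    # -- flat parameter view (finite-difference checks, snapshots) ------
    def get_flat_params(self) -> np.ndarray:
        return np.concatenate([self.params[k].ravel() for k in sorted(self.params)])

    def set_flat_params(self, flat: np.ndarray) -> None:
        i = 0
        for k in sorted(self.params):
            size = self.params[k].size
            self.params[k] = flat[i : i + size].reshape(self.params[k].shape).copy()
            i += size

    def flatten_gradients(self, grads: dict[str, np.ndarray]) -> np.ndarray:
        return np.concatenate([grads[k].ravel() for k in sorted(self.params)])

    # -- training --------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        patience: int = 25,
        max_epochs: int = 500,
    ) -> "PMIRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        X_val = np.asarray(X_val, dtype=float)
        y_val = np.asarray(y_val, dtype=float)
        if X.shape[1] != self.n_features:
            raise ModelConfigError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(val) for k, val in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = self.hp.learning_rate
        t = 0
        stopper = EarlyStopper(patience=patience)
        best_snapshot = {k: val.copy() for k, val in self.params.items()}
        n = X.shape[0]
        for epoch in range(max_epochs):
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.hp.batch_size):
                idx = order[start : start + self.hp.batch_size]
                cache = self._forward(X[idx], training=True, rng=self.rng)
                loss = self._loss(cache["out"], y[idx])
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite training loss at epoch {epoch}; "
                        f"lr={lr}, batch={start // self.hp.batch_size}"
                    )
                grads = self._backward(cache, y[idx])
                t += 1
                for k in self.params:
                    g = grads[k]
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g**2
                    mhat = m[k] / (1 - beta1**t)
                    vhat = v[k] / (1 - beta2**t)
                    self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
                epoch_loss += loss * len(idx)
            val_out = self._forward(X_val, training=False)["out"].ravel()
            val_loss = self._loss(val_out[:, None], y_val)
            if not np.isfinite(val_loss):
                raise TrainingDivergedError(
                    f"non-finite validation loss at epoch {epoch}"
                )
            self.history["train_loss"].append(epoch_loss / n)
            self.history["val_loss"].append(val_loss)
            self.history["val_mae"].append(float(np.mean(np.abs(val_out - y_val))))
            improved = val_loss < stopper.best_loss
            stop = stopper.update(epoch, val_loss)
            if improved:
                best_snapshot = {k: val.copy() for k, val in self.params.items()}
            if stop:
                break
        self.params = best_snapshot
        self.best_epoch = stopper.best_epoch
        self.best_val_loss = float(stopper.best_loss)
        self.stopped_epoch = len(self.history["val_loss"]) - 1
        return self

    # -- inference -------------------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass (dropout disabled), days."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ModelConfigError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        return self._forward(X, training=False)["out"].ravel()

    def attention_activations(self, X: np.ndarray) -> np.ndarray:
        """Gate outputs a_i per sample per feature."""
        if not self.hp.use_attention:
            raise ModelConfigError("model has no attention layer")
        return attention_forward(X, self.params["att_w"], self.params["att_b"])

    # -- persistence -----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arch = {
            "hyperparams": {
                "use_attention": self.hp.use_attention,
                "n_hidden_layers": self.hp.n_hidden_layers,
                "nodes_per_layer": list(self.hp.nodes_per_layer),
                "dropout_per_layer": list(self.hp.dropout_per_layer),
                "learning_rate": self.hp.learning_rate,
                "seed": self.hp.seed,
                "loss": self.hp.loss,
                "batch_size": self.hp.batch_size,
                "output_activation": self.hp.output_activation,
                "attention_bias": self.hp.attention_bias,
            },
            "n_features": self.n_features,
            "best_epoch": self.best_epoch,
            "best_val_loss": self.best_val_loss,
            "stopped_epoch": self.stopped_epoch,
            "feature_order": self.feature_order,
            "history": self.history,
        }
        (directory / "architecture.json").write_text(json.dumps(arch))
        np.savez(directory / "weights.npz", **self.params)
        if self.normalization is not None:
            self.normalization.to_json(directory / "normalization.json")

    @classmethod
    def load(cls, directory: str | Path) -> "PMIRegressor":
        directory = Path(directory)
        arch = json.loads((directory / "architecture.json").read_text())
        hpd = arch["hyperparams"]
        hp = HyperParams(
            use_attention=hpd["use_attention"],
            n_hidden_layers=hpd["n_hidden_layers"],
            nodes_per_layer=tuple(hpd["nodes_per_layer"]),
            dropout_per_layer=tuple(hpd["dropout_per_layer"]),
            learning_rate=hpd["learning_rate"],
            seed=hpd["seed"],
            loss=hpd["loss"],
            batch_size=hpd["batch_size"],
            output_activation=hpd["output_activation"],
            attention_bias=hpd["attention_bias"],
        )
        model = cls(hp, arch["n_features"])
        with np.load(directory / "weights.npz") as npz:
            model.params = {k: npz[k].copy() for k in npz.files}
        model.best_epoch = arch["best_epoch"]
        model.best_val_loss = arch["best_val_loss"]
        model.stopped_epoch = arch["stopped_epoch"]
        model.feature_order = arch["feature_order"]
        model.history = arch["history"]
        norm_path = directory / "normalization.json"
        if norm_path.exists():
            model.normalization = NormalizationParams.from_json(norm_path)
        return model


def build_model(hp: HyperParams, n_features: int) -> PMIRegressor:
    """Untrained network for the given hyperparameters."""
    return PMIRegressor(hp, n_features)


def train(
    model: PMIRegressor,
    train_table: FeatureTable,
    val_table: FeatureTable,
    patience: int = 25,
    max_epochs: int = 500,
) -> PMIRegressor:
    """Fit on standardized tables; PMI (days) is the regression target."""
    if list(train_table.feature_ids) != list(val_table.feature_ids):
        raise ModelConfigError("train and validation feature orders differ")
    model.feature_order = list(train_table.feature_ids)
    return model.fit(
        train_table.values(),
        train_table.pmi.astype(float),
        val_table.values(),
        val_table.pmi.astype(float),
        patience=patience,
        max_epochs=max_epochs,
    )


def predict(model: PMIRegressor, table: FeatureTable) -> np.ndarray:
    if model.feature_order is not None and list(table.feature_ids) != model.feature_order:
        raise ModelConfigError("table feature order does not match the model")
    return model.predict(table.values())


def attention_activations(model: PMIRegressor, table: FeatureTable) -> np.ndarray:
    if model.feature_order is not None and list(table.feature_ids) != model.feature_order:
        raise ModelConfigError("table feature order does not match the model")
    return model.attention_activations(table.values())


# ---------------------------------------------------------------------------
# Random hyperparameter search
# ---------------------------------------------------------------------------

@dataclass
class SearchEntry:
    hp: HyperParams
    val_maes: list[float]
    best_repeat: int

    @property
    def score(self) -> float:
        return min(self.val_maes)


@dataclass
class SearchResult:
    """Configurations sorted ascending by best-repeat validation MAE."""

    entries: list[SearchEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def best(self) -> SearchEntry:
        return self.entries[0]

    def ranks_by_attention(self) -> tuple[list[int], list[int]]:
        """1-based ranks of attention vs non-attention configs."""
        with_att = [i + 1 for i, e in enumerate(self.entries) if e.hp.use_attention]
        without = [i + 1 for i, e in enumerate(self.entries) if not e.hp.use_attention]
        return with_att, without


def sample_hyperparams(
    rng: np.random.Generator, use_attention: bool, seed: int
) -> HyperParams:
    """Uniform draw over the search ranges; log-uniform learning rate."""
    n_layers = int(rng.integers(HP_RANGES["n_hidden_layers"][0], HP_RANGES["n_hidden_layers"][1] + 1))
    nodes = tuple(int(rng.integers(HP_RANGES["nodes"][0], HP_RANGES["nodes"][1] + 1)) for _ in range(n_layers))
    dropout = tuple(float(rng.uniform(*HP_RANGES["dropout"])) for _ in range(n_layers))
    lr = float(np.exp(rng.uniform(*np.log(HP_RANGES["learning_rate"]))))
    return HyperParams(
        use_attention=use_attention,
        n_hidden_layers=n_layers,
        nodes_per_layer=nodes,
        dropout_per_layer=dropout,
        learning_rate=lr,
        seed=seed,
    )


def hyperparameter_search(
    train_table: FeatureTable,
    val_table: FeatureTable,
    n_configs: int = 30,
    repeats: int = 3,
    seed: int = 0,
    patience: int = 25,
    max_epochs: int = 500,
) -> SearchResult:
    """Seeded random search over architectures, with and without the gate.

    The attention flag alternates across the drawn configurations so
    both variants are represented at any ``n_configs``; the remaining
    hyperparameters are sampled independently per configuration. Each
    configuration is trained ``repeats`` times (fresh seeds) and scored
    by its best repeat's validation MAE.
    """
    rng = np.random.default_rng(seed)
    n_features = train_table.n_features
    entries: list[SearchEntry] = []
    for cfg_i in range(n_configs):
        use_attention = cfg_i % 2 == 0
        hp = sample_hyperparams(rng, use_attention, seed=int(rng.integers(2**31)))
        maes: list[float] = []
        for rep in range(repeats):
            hp_rep = replace(hp, seed=int(rng.integers(2**31)))
            model = PMIRegressor(hp_rep, n_features)
            train(model, train_table, val_table, patience=patience, max_epochs=max_epochs)
            # MAE of the restored (best-validation-loss) weights
            maes.append(model.history["val_mae"][model.best_epoch])
        entries.append(SearchEntry(hp=hp, val_maes=maes, best_repeat=int(np.argmin(maes))))
    entries.sort(key=lambda e: e.score)
    return SearchResult(entries=entries)
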