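"""The two sequence classifiers and the experiment grid.

Two architectures operate on 1-second raw-acceleration windows (100, 3):

* ``lstm`` — one fully connected LSTM layer, one dense ReLU layer with
  dropout, and a softmax output layer.
* ``bilstm`` — the stacked variant: one convolution layer, one pooling
  layer, one bidirectional LSTM layer, two LSTM layers, then the same dense
  ReLU + dropout head and softmax output.

Tasks: two- or three-way wear-site detection (hip/wrist, hip/wrist/chest)
and four-way intensity classification; the intensity task optionally
receives standardized age/height/weight covariates, concatenated to the
recurrent feature vector before the dense head.  Training minimizes
multi-class cross-entropy with the adaptive-moment optimizer for a fixed
number of epochs (default 20) and is deterministic given the config seed.

The source study left hidden sizes, optimizer, and batch size unstated;
this module's defaults are conventional values sized for 1-second windows
on a single CPU core and are all overridable through :class:`ModelConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .groundtruth import INTENSITIES
from .nn.layers import (Adam, Bidirectional, Conv1D, Dense, Dropout, Layer,
                        LSTM, MaxPool1D, softmax, softmax_cross_entropy)
from .synthdata import ADULT, CHEST, CHILD, HIP, WRIST
from .windowing import LabeledWindowSet, attach_covariates, split

TASK_CLASSES = {
    "site2": (HIP, WRIST),
    "site3": (HIP, WRIST, CHEST),
    "intensity4": INTENSITIES,
}


@dataclass(frozen=True)
class ModelConfig:
    architecture: str = "lstm"          # "lstm" | "bilstm"
    task: str = "intensity4"            # "site2" | "site3" | "intensity4"
    recurrent_units: int = 32
    dense_units: int = 32
    dropout_rate: float = 0.5
    conv_filters: int = 16
    conv_kernel: int = 5
    pool_size: int = 2
    use_covariates: bool = False
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 1e-3
    # step decay: lr * lr_decay^(epoch // lr_decay_every); dampens the
    # late-epoch oscillation of validation accuracy under heavy dropout
    lr_decay: float = 0.5
    lr_decay_every: int = 8
    window_len: int = 100
    n_channels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("lstm", "bilstm"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.task not in TASK_CLASSES:
            raise ValueError(f"unknown task {self.task!r}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @property
    def classes(self) -> tuple[str, ...]:
        return TASK_CLASSES[self.task]

    @property
    def n_classes(self) -> int:
        return len(self.classes)


class SequenceClassifier:
    """Feature layers over (B, T, C) windows, then a dense softmax head.

    When covariates are used, the 3-vector is concatenated to the flattened
    recurrent output before the dense layer.
    """

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
        u, C = config.recurrent_units, config.n_channels
        if config.architecture == "lstm":
            self.feature_layers: list[Layer] = [
                LSTM(C, u, return_sequences=False, rng=rng)]
            feat_dim = u
        else:
            self.feature_layers = [
                Conv1D(C, config.conv_filters, config.conv_kernel, rng=rng),
                MaxPool1D(config.pool_size),
                Bidirectional(config.conv_filters, u, return_sequences=True,
                              rng=rng),
                LSTM(2 * u, u, return_sequences=True, rng=rng),
                LSTM(u, u, return_sequences=False, rng=rng),
            ]
            feat_dim = u
        self.head_dim_in = feat_dim + (3 if config.use_covariates else 0)
        self.head_layers: list[Layer] = [
            Dense(self.head_dim_in, config.dense_units, activation="relu",
                  rng=rng),
            Dropout(config.dropout_rate),
            Dense(config.dense_units, config.n_classes, rng=rng),
        ]

    @property
    def layers(self) -> list[Layer]:
        return self.feature_layers + self.head_layers

    def forward(self, x: np.ndarray, covariates: np.ndarray | None,
                train: bool, rng: np.random.Generator | None = None
                ) -> np.ndarray:
        h = np.asarray(x, dtype=np.float64)
        for layer in self.feature_layers:
            h = layer.forward(h, train, rng)
        if self.config.use_covariates:
            if covariates is None:
                raise ValueError("model expects covariates")
            h = np.concatenate([h, np.asarray(covariates, dtype=np.float64)],
                               axis=1)
        self._feat_dim = h.shape[1] - (3 if self.config.use_covariates else 0)
        for layer in self.head_layers:
            h = layer.forward(h, train, rng)
        return h

    def backward(self, grad_logits: np.ndarray) -> None:
        g = grad_logits
        for layer in reversed(self.head_layers):
            g = layer.backward(g)
        if self.config.use_covariates:
            g = g[:, :self._feat_dim]
        for layer in reversed(self.feature_layers):
            g = layer.backward(g)


@dataclass
class TrainedModel:
    config: ModelConfig
    network: SequenceClassifier
    history: dict[str, list[float]]
    classes: tuple[str, ...]
    covariate_stats: dict | None = None

    @property
    def final_val_accuracy(self) -> float:
        return self.history["val_accuracy"][-1]


def build_model(config: ModelConfig) -> SequenceClassifier:
    """Instantiate an untrained classifier for the configured task."""
    return SequenceClassifier(config)


def _labels_for_task(window_set: LabeledWindowSet, task: str) -> np.ndarray:
    src = window_set.intensity if task == "intensity4" else window_set.site
    classes = TASK_CLASSES[task]
    lut = {c: i for i, c in enumerate(classes)}
    unknown = set(np.unique(src)) - set(classes)
    if unknown:
        raise ValueError(
            f"labels {sorted(unknown)} outside task {task!r} classes "
            f"{classes}; filter the window set first")
    return np.array([lut[v] for v in src], dtype=np.int64)


def _batched_logits(net: SequenceClassifier, x: np.ndarray,
                    cov: np.ndarray | None, batch: int = 512) -> np.ndarray:
    outs = []
    for i in range(0, x.shape[0], batch):
        c = None if cov is None else cov[i:i + batch]
        outs.append(net.forward(x[i:i + batch], c, train=False))
    return np.concatenate(outs, axis=0)


def train(network: SequenceClassifier, train_set: LabeledWindowSet,
          val_set: LabeledWindowSet,
          config: ModelConfig | None = None) -> TrainedModel:
    """Train for ``config.epochs`` epochs of minibatch cross-entropy descent.

    Validation data is only ever used for scoring (never for updates).
    History records per-epoch training loss/accuracy (running over batches)
    and validation loss/accuracy in inference mode.
    """
    config = config or network.config
    if len(train_set) == 0:
        raise ValueError("empty training set")
    y_train = _labels_for_task(train_set, config.task)
    y_val = _labels_for_task(val_set, config.task)
    if np.unique(y_train).size < 2:
        raise ValueError("training set contains a single class")
    use_cov = config.use_covariates
    if use_cov and (train_set.covariates is None or val_set.covariates is None):
        raise ValueError("use_covariates=True requires covariates on both sets")
    x_tr = train_set.windows
    x_va = val_set.windows
    c_tr = train_set.covariates if use_cov else None
    c_va = val_set.covariates if use_cov else None
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    opt = Adam(network.layers, learning_rate=config.learning_rate)
    history = {k: [] for k in
               ("loss", "accuracy", "val_loss", "val_accuracy")}
    n = x_tr.shape[0]
    for epoch in range(config.epochs):
        if config.lr_decay_every > 0:
            opt.lr = config.learning_rate * (
                config.lr_decay ** (epoch // config.lr_decay_every))
        perm = rng.permutation(n)
        ep_loss, ep_hits = 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = perm[i:i + config.batch_size]
            xb = x_tr[idx]
            cb = None if c_tr is None else c_tr[idx]
            logits = network.forward(xb, cb, train=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, y_train[idx])
            network.backward(dlogits)
            opt.step()
            ep_loss += loss * idx.size
            ep_hits += int((logits.argmax(axis=1) == y_train[idx]).sum())
        vlogits = _batched_logits(network, x_va, c_va)
        vloss, _ = softmax_cross_entropy(vlogits, y_val)
        history["loss"].append(ep_loss / n)
        history["accuracy"].append(ep_hits / n)
        history["val_loss"].append(vloss)
        history["val_accuracy"].append(
            float((vlogits.argmax(axis=1) == y_val).mean()))
    return TrainedModel(config=config, network=network, history=history,
                        classes=config.classes,
                        covariate_stats=getattr(train_set, "covariate_stats",
                                                None))


def predict(model: TrainedModel, windows: np.ndarray,
            covariates: np.ndarray | None = None
            ) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels (ties -> lowest class index)."""
    cfg = model.config
    windows = np.asarray(windows)
    if windows.ndim != 3 or windows.shape[1:] != (cfg.window_len,
                                                  cfg.n_channels):
        raise ValueError(
            f"windows must be (n, {cfg.window_len}, {cfg.n_channels}), "
            f"got {windows.shape}")
    if cfg.use_covariates and covariates is None:
        raise ValueError("model expects covariates")
    if not cfg.use_covariates and covariates is not None:
        raise ValueError("model was trained without covariates")
    logits = _batched_logits(model.network, windows, covariates)
    probs = softmax(logits)
    labels = np.asarray(model.classes, dtype=object)[probs.argmax(axis=1)]
    return probs, labels


# --------------------------------------------------------------------------
# Experiment grid
# --------------------------------------------------------------------------

SITE_SCOPES = {"two_site": (HIP, WRIST), "three_site": (HIP, WRIST, CHEST)}
PURPOSES = ("wear_site", "intensity", "intensity_covariates")


def _filter(window_set: LabeledWindowSet, sites: tuple[str, ...],
            group: str) -> LabeledWindowSet:
    mask = np.isin(window_set.site, sites)
    if group != "combined":
        mask &= window_set.group == group
    return window_set.subset(np.where(mask)[0])


def run_experiment_grid(window_set: LabeledWindowSet, profiles: list,
                        seed: int = 0,
                        base_config: ModelConfig = ModelConfig(),
                        architectures: tuple[str, ...] = ("lstm", "bilstm"),
                        groups: tuple[str, ...] = (ADULT, CHILD, "combined"),
                        purposes: tuple[str, ...] = PURPOSES,
                        scopes: tuple[str, ...] = ("two_site", "three_site"),
                        train_fraction: float = 0.9,
                        split_scheme: str = "window_random") -> pd.DataFrame:
    """Train one model per grid cell and tabulate validation accuracies.

    Grid: purpose (wear-site detection / intensity / intensity+covariates)
    x group (adult, child, combined) x site scope (two- or three-site)
    x architecture — the layout of the study's performance table.  Cells
    with no data or a single class are reported with NaN accuracy.
    """
    rows = []
    for purpose in purposes:
        for scope in scopes:
            sites = SITE_SCOPES[scope]
            task = ("site2" if scope == "two_site" else "site3") \
                if purpose == "wear_site" else "intensity4"
            for group in groups:
                subset = _filter(window_set, sites, group)
                for arch in architectures:
                    cell = dict(purpose=purpose, scope=scope, group=group,
                                architecture=arch, n_windows=len(subset))
                    try:
                        tr, va = split(subset, train_fraction, seed=seed,
                                       scheme=split_scheme)
                        use_cov = purpose == "intensity_covariates"
                        if use_cov:
                            tr = attach_covariates(tr, profiles,
                                                   standardize=True)
                            va = attach_covariates(va, profiles,
                                                   standardize=True,
                                                   stats=tr.covariate_stats)
                        cfg = replace(base_config, architecture=arch,
                                      task=task, use_covariates=use_cov,
                                      seed=seed)
                        model = train(build_model(cfg), tr, va, cfg)
                        cell["val_accuracy"] = model.final_val_accuracy
                    except ValueError as err:
                        cell["val_accuracy"] = np.nan
                        cell["note"] = str(err)
                    rows.append(cell)
    return pd.DataFrame(rows)
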