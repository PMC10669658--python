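"""Model zoo: expression FNN, gene-image CNN, and the fused joint network.

Three binary classifiers over the two modalities:

* **FNN** — dense stack 128 -> 64 -> 32 -> 32 (ReLU) on the selected-gene
  expression vector; the final 32-unit layer is the exported feature layer
  (t = 32).  L1+L2 kernel regularization and dropout (0.4) sit on the last
  two dense layers.
* **CNN** — six 3x3 convolutions in pairs of 32/32, 64/64, 128/128 filters,
  each pair followed by 2x2 max pooling, then two dense layers (128 -> t)
  with the same regularization/dropout; input is the per-sample gene image.
* **Fusion** — both feature vectors concatenated into R^{2t}, then
  dense 32 -> dropout 0.4 -> dense 32 -> sigmoid head, trained end-to-end
  from random initialization.

Training: Adam at 1e-4 on binary cross-entropy, batch size 30, and an
early-stopping rule that ignores the first ``min_epochs_before_stop``
epochs and then halts after ``patience`` consecutive epochs without a new
best training loss, restoring the best-loss weights.  All randomness
(initialization, shuffling, dropout) flows from one seeded generator, so a
fixed seed reproduces the loss log exactly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import layers as L
from .errors import ConfigError

FEATURE_DIM = 32  # t: width of both branches' exported feature layers
FNN_WIDTHS = (128, 64, 32, 32)
CNN_FILTERS = (32, 32, 64, 64, 128, 128)
CNN_DENSE = 128  # width of the first CNN dense layer (the second is t)
MIN_IMAGE_SIDE = 8  # three 2x max-poolings need >= 8 pixels per side


@dataclass
class NetworkSpec:
    """Architecture hyperparameters for one branch."""

    branch: str  # fnn | cnn | fusion
    input_dim: int | tuple[int, int]
    feature_dim: int = FEATURE_DIM
    dropout_rate: float = 0.4
    l1: float = 1e-5
    l2: float = 1e-4


@dataclass
class TrainConfig:
    """Optimization protocol shared by all three models."""

    learning_rate: float = 1e-4
    batch_size: int = 30
    min_epochs_before_stop: int = 250
    patience: int = 10
    max_epochs: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ConfigError("learning_rate, batch_size, max_epochs must be positive")
        if self.patience < 1:
            raise ConfigError("patience must be >= 1")
        if self.min_epochs_before_stop < 0:
            raise ConfigError("min_epochs_before_stop must be >= 0")


# ---------------------------------------------------------------------------
# early stopping (pure over the loss sequence, unit-testable without training)
# ---------------------------------------------------------------------------

class EarlyStopping:
    """Stop after `patience` consecutive non-improvements, ignoring a warmup.

    The best loss is tracked from epoch 1 (1-based); the non-improvement
    counter only advances on epochs strictly after ``warmup``.  "Improve"
    means strictly lower than the best loss seen so far.
    """

    def __init__(self, warmup: int, patience: int):
        self.warmup = warmup
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0
        self.stale = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Feed one epoch's loss; returns True when training should stop."""
        if loss < self.best_loss:
            self.best_loss = loss
            self.best_epoch = epoch
            self.stale = 0
            return False
        if epoch <= self.warmup:
            return False
        self.stale += 1
        return self.stale >= self.patience


def early_stop_epoch(losses: list[float], warmup: int, patience: int) -> tuple[int, int]:
    """Apply the stopping rule to a whole loss sequence.

    Returns (stop_epoch, best_epoch), 1-based; stop_epoch = len(losses) if
    the rule never fires.
    """
    cb = EarlyStopping(warmup, patience)
    for epoch, loss in enumerate(losses, start=1):
        if cb.update(epoch, float(loss)):
            return epoch, cb.best_epoch
    return len(losses), cb.best_epoch


# ---------------------------------------------------------------------------
# model handles
# ---------------------------------------------------------------------------

class Model:
    """A network with a feature trunk per input and a logit head."""

    def forward_logits(self, inputs, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dlogits: np.ndarray) -> None:
        raise NotImplementedError

    def params(self) -> list[L.Param]:
        raise NotImplementedError

    def reg_loss(self) -> float:
        raise NotImplementedError

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def predict_proba_raw(self, inputs) -> np.ndarray:
        rng = np.random.default_rng(0)  # unused: inference has no randomness
        return L.sigmoid(self.forward_logits(inputs, training=False, rng=rng)).reshape(-1)


class _SingleBranch(Model):
    def __init__(self, trunk: L.Sequential, head: L.Sequential):
        self.trunk = trunk
        self.head = head

    def forward_logits(self, x, training, rng):
        self._feat = self.trunk.forward(np.asarray(x, dtype=L.DTYPE), training, rng)
        return self.head.forward(self._feat, training, rng)

    def features(self, x) -> np.ndarray:
        rng = np.random.default_rng(0)
        return self.trunk.forward(np.asarray(x, dtype=L.DTYPE), False, rng)

    def backward(self, dlogits):
        self.trunk.backward(self.head.backward(dlogits))

    def params(self):
        return self.trunk.params() + self.head.params()

    def reg_loss(self):
        return self.trunk.reg_loss() + self.head.reg_loss()


class FusionModel(Model):
    """Two trunks whose t-dim features are concatenated into a joint head.

    When ``feature_mu``/``feature_sd`` are set, the concatenated vector is
    standardized with those (training-set) statistics before the head, so
    neither modality dominates the joint layers by scale alone.
    """

    def __init__(self, fnn_trunk: L.Sequential, cnn_trunk: L.Sequential,
                 head: L.Sequential, t: int):
        self.fnn_trunk = fnn_trunk
        self.cnn_trunk = cnn_trunk
        self.head = head
        self.t = t
        self.feature_mu: np.ndarray | None = None
        self.feature_sd: np.ndarray | None = None

    def fuse_features(self, inputs, training=False, rng=None) -> np.ndarray:
        rng = rng if rng is not None else np.random.default_rng(0)
        x_vec, x_img = inputs
        fa = self.fnn_trunk.forward(np.asarray(x_vec, dtype=L.DTYPE), training, rng)
        fb = self.cnn_trunk.forward(np.asarray(x_img, dtype=L.DTYPE), training, rng)
        fused = np.concatenate([fa, fb], axis=1)  # in R^{2t}
        if self.feature_mu is not None:
            fused = (fused - self.feature_mu) / self.feature_sd
        return fused

    def forward_logits(self, inputs, training, rng):
        return self.head.forward(self.fuse_features(inputs, training, rng), training, rng)

    def backward(self, dlogits):
        dfused = self.head.backward(dlogits)
        self.fnn_trunk.backward(dfused[:, : self.t])
        self.cnn_trunk.backward(dfused[:, self.t :])

    def params(self):
        return self.fnn_trunk.params() + self.cnn_trunk.params() + self.head.params()

    def reg_loss(self):
        return self.fnn_trunk.reg_loss() + self.cnn_trunk.reg_loss() + self.head.reg_loss()


class _HeadOnly(Model):
    """Adapter exposing a fusion head as a standalone trainable model."""

    def __init__(self, head: L.Sequential):
        self.head = head

    def forward_logits(self, x, training, rng):
        return self.head.forward(x, training, rng)

    def backward(self, dlogits):
        self.head.backward(dlogits)

    def params(self):
        return self.head.params()

    def reg_loss(self):
        return self.head.reg_loss()


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _fnn_trunk(spec: NetworkSpec, rng: np.random.Generator) -> L.Sequential:
    n = int(spec.input_dim)
    w1, w2, w3, w4 = FNN_WIDTHS
    return L.Sequential([
        L.Dense(n, w1, rng), L.ReLU(),
        L.Dense(w1, w2, rng), L.ReLU(),
        # regularization + dropout on the last two dense layers
        L.Dense(w2, w3, rng, l1=spec.l1, l2=spec.l2), L.ReLU(), L.Dropout(spec.dropout_rate),
        L.Dense(w3, w4, rng, l1=spec.l1, l2=spec.l2), L.ReLU(), L.Dropout(spec.dropout_rate),
    ])


def build_fnn(spec: NetworkSpec, rng: np.random.Generator | int = 0) -> _SingleBranch:
    """Dense 128-64-32-32 branch on the expression vector, sigmoid head."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if spec.feature_dim != FNN_WIDTHS[-1]:
        raise ConfigError(
            f"feature_dim {spec.feature_dim} must equal the final dense width {FNN_WIDTHS[-1]}"
        )
    return _SingleBranch(_fnn_trunk(spec, rng), L.Sequential([L.Dense(spec.feature_dim, 1, rng)]))


def _cnn_trunk(spec: NetworkSpec, rng: np.random.Generator) -> L.Sequential:
    rows, cols = spec.input_dim
    if rows < MIN_IMAGE_SIDE or cols < MIN_IMAGE_SIDE:
        raise ConfigError(
            f"image {rows}x{cols} too small for three 2x pooling stages; "
            f"minimum is {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}"
        )
    f = CNN_FILTERS
    stack: list[L.Layer] = [
        L.Conv2D(1, f[0], rng), L.ReLU(), L.Conv2D(f[0], f[1], rng), L.ReLU(), L.MaxPool2(),
        L.Conv2D(f[1], f[2], rng), L.ReLU(), L.Conv2D(f[2], f[3], rng), L.ReLU(), L.MaxPool2(),
        L.Conv2D(f[3], f[4], rng), L.ReLU(), L.Conv2D(f[4], f[5], rng), L.ReLU(), L.MaxPool2(),
        L.Flatten(),
    ]
    flat = (rows // 2 // 2 // 2) * (cols // 2 // 2 // 2) * f[5]
    stack += [
        L.Dense(flat, CNN_DENSE, rng, l1=spec.l1, l2=spec.l2), L.ReLU(), L.Dropout(spec.dropout_rate),
        L.Dense(CNN_DENSE, spec.feature_dim, rng, l1=spec.l1, l2=spec.l2), L.ReLU(),
        L.Dropout(spec.dropout_rate),
    ]
    return L.Sequential(stack)


def build_cnn(spec: NetworkSpec, rng: np.random.Generator | int = 0) -> _SingleBranch:
    """Six-convolution image branch (filters 32/32, 64/64, 128/128), sigmoid head."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    return _SingleBranch(_cnn_trunk(spec, rng), L.Sequential([L.Dense(spec.feature_dim, 1, rng)]))


def build_fusion(fnn_spec: NetworkSpec, cnn_spec: NetworkSpec,
                 rng: np.random.Generator | int = 0) -> FusionModel:
    """Joint network over both modalities: concat(2t) -> 32 -> dropout -> 32 -> head."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if fnn_spec.feature_dim != cnn_spec.feature_dim:
        raise ConfigError("branch feature dims must match for fusion")
    t = fnn_spec.feature_dim
    head = L.Sequential([
        L.Dense(2 * t, 32, rng), L.ReLU(),
        L.Dropout(fnn_spec.dropout_rate),
        L.Dense(32, 32, rng), L.ReLU(),
        L.Dense(32, 1, rng),
    ])
    return FusionModel(_fnn_trunk(fnn_spec, rng), _cnn_trunk(cnn_spec, rng), head, t)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainingLog:
    losses: list[float] = field(default_factory=list)  # per-epoch mean batch loss
    accuracies: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    best_epoch: int = 0


def _as_inputs(data, idx):
    if isinstance(data, tuple):
        return tuple(d[idx] for d in data)
    return data[idx]


def train(model: Model, data, y: np.ndarray, config: TrainConfig) -> TrainingLog:
    """Minibatch Adam on binary cross-entropy with best-weight restoration.

    ``data`` is one array (samples first) or a tuple of arrays for the
    fusion model.  The monitored loss is the epoch mean of batch losses
    (data + regularization).  On return, the model carries the weights of
    the best epoch.
    """
    config.validate()
    y = np.asarray(y).astype(int).reshape(-1)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    n = len(y)
    rng = np.random.default_rng(config.seed)
    opt = L.Adam(model.params(), lr=config.learning_rate)
    stopper = EarlyStopping(config.min_epochs_before_stop, config.patience)
    log = TrainingLog()
    best_weights = L.get_weights(model.params())
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        losses, accs = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = _as_inputs(data, idx), y[idx]
            z = model.forward_logits(xb, training=True, rng=rng)
            data_loss, dz = L.bce_with_logits(z, yb)
            opt.zero_grad()
            model.backward(dz)
            opt.step()
            losses.append(data_loss + model.reg_loss())
            accs.append(float(np.mean((z.reshape(-1) > 0) == (yb == 1))))
        epoch_loss = float(np.mean(losses))
        log.losses.append(epoch_loss)
        log.accuracies.append(float(np.mean(accs)))
        if epoch_loss < stopper.best_loss:
            best_weights = L.get_weights(model.params())
        if stopper.update(epoch, epoch_loss):
            log.stop_epoch = epoch
            break
    else:
        log.stop_epoch = config.max_epochs
    log.best_epoch = stopper.best_epoch
    L.set_weights(model.params(), best_weights)
    return log


# ---------------------------------------------------------------------------
# sklearn-style estimators
# ---------------------------------------------------------------------------

class _BaseNNClassifier(BaseEstimator, ClassifierMixin):
    def __init__(self, feature_dim=FEATURE_DIM, dropout_rate=0.4, l1=1e-5, l2=1e-4,
                 learning_rate=1e-4, batch_size=30, min_epochs_before_stop=250,
                 patience=10, max_epochs=2000, seed=0):
        self.feature_dim = feature_dim
        self.dropout_rate = dropout_rate
        self.l1 = l1
        self.l2 = l2
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.min_epochs_before_stop = min_epochs_before_stop
        self.patience = patience
        self.max_epochs = max_epochs
        self.seed = seed

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            min_epochs_before_stop=self.min_epochs_before_stop,
            patience=self.patience,
            max_epochs=self.max_epochs,
            seed=self.seed,
        )

    def _spec(self, branch: str, input_dim) -> NetworkSpec:
        return NetworkSpec(
            branch=branch,
            input_dim=input_dim,
            feature_dim=self.feature_dim,
            dropout_rate=self.dropout_rate,
            l1=self.l1,
            l2=self.l2,
        )

    def _finish_fit(self, model: Model, data, y) -> "_BaseNNClassifier":
        log = train(model, data, y, self._train_config())
        self.model_ = model
        self.loss_curve_ = log.losses
        self.training_log_ = log
        self.classes_ = np.array([0, 1])
        self.n_parameters_ = model.n_parameters()
        return self

    def predict_proba(self, X) -> np.ndarray:
        p1 = self._proba_positive(X)
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self._proba_positive(X) >= 0.5).astype(int)


class FNNClassifier(_BaseNNClassifier):
    """Feed-forward branch on selected-gene expression vectors."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        model = build_fnn(self._spec("fnn", X.shape[1]), np.random.default_rng(self.seed))
        return self._finish_fit(model, X.astype(L.DTYPE), y)

    def _proba_positive(self, X):
        return self.model_.predict_proba_raw(np.asarray(X, dtype=L.DTYPE))


class CNNClassifier(_BaseNNClassifier):
    """Convolutional branch on per-sample gene images (n, rows, cols)."""

    @staticmethod
    def _prep(X):
        X = np.asarray(X, dtype=L.DTYPE)
        if X.ndim == 3:
            X = X[..., None]  # add channel axis
        return X

    def fit(self, X, y):
        X = self._prep(X)
        model = build_cnn(self._spec("cnn", X.shape[1:3]), np.random.default_rng(self.seed))
        return self._finish_fit(model, X, y)

    def _proba_positive(self, X):
        return self.model_.predict_proba_raw(self._prep(X))


class FusionClassifier(_BaseNNClassifier):
    """Joint network consuming (expression vector, gene image) pairs.

    ``X`` is a tuple ``(X_vec, X_img)``; both arrays are sample-aligned.

    Two training regimes:

    * Without ``warm_start_models`` the whole network (both trunks and the
      joint head) is trained end-to-end from random initialization.
    * With fitted branch models passed as ``warm_start_models=(fnn, cnn)``,
      the fusion trunks take the pretrained branch weights.  If
      ``freeze_branches`` (the default in that regime), the branch output
      vectors are computed once, standardized to the training-set scale, and
      only the joint head is trained on the merged vectors — the branches
      stay frozen.  With ``freeze_branches=False`` the warm-started network
      is fine-tuned end-to-end instead.
    """

    def __init__(self, feature_dim=FEATURE_DIM, dropout_rate=0.4, l1=1e-5, l2=1e-4,
                 learning_rate=1e-4, batch_size=30, min_epochs_before_stop=250,
                 patience=10, max_epochs=2000, seed=0, warm_start_models=None,
                 freeze_branches=True):
        super().__init__(feature_dim, dropout_rate, l1, l2, learning_rate, batch_size,
                         min_epochs_before_stop, patience, max_epochs, seed)
        self.warm_start_models = warm_start_models
        self.freeze_branches = freeze_branches

    @staticmethod
    def _prep(X):
        x_vec, x_img = X
        x_vec = np.asarray(x_vec, dtype=L.DTYPE)
        x_img = CNNClassifier._prep(x_img)
        return x_vec, x_img

    def fit(self, X, y):
        x_vec, x_img = self._prep(X)
        rng = np.random.default_rng(self.seed)
        model = build_fusion(
            self._spec("fnn", x_vec.shape[1]), self._spec("cnn", x_img.shape[1:3]), rng
        )
        if self.warm_start_models is not None:
            fnn_clf, cnn_clf = self.warm_start_models
            L.set_weights(model.fnn_trunk.params(),
                          L.get_weights(fnn_clf.model_.trunk.params()))
            L.set_weights(model.cnn_trunk.params(),
                          L.get_weights(cnn_clf.model_.trunk.params()))
            if self.freeze_branches:
                fused = model.fuse_features((x_vec, x_img))
                mu = fused.mean(axis=0)
                sd = fused.std(axis=0)
                sd[sd == 0] = 1.0
                model.feature_mu = mu.astype(L.DTYPE)
                model.feature_sd = sd.astype(L.DTYPE)
                fused = ((fused - mu) / sd).astype(L.DTYPE)
                log = train(_HeadOnly(model.head), fused, y, self._train_config())
                self.model_ = model
                self.loss_curve_ = log.losses
                self.training_log_ = log
                self.classes_ = np.array([0, 1])
                self.n_parameters_ = model.n_parameters()
                return self
        return self._finish_fit(model, (x_vec, x_img), y)

    def _proba_positive(self, X):
        return self.model_.predict_proba_raw(self._prep(X))
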