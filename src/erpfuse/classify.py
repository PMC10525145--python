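"""Perceptron classifiers for single neural features and their fusion.

Architecture (one block per feature): flatten -> linear map to 2 logits ->
per-logit batch normalization.  A single-feature model feeds the normalized
logits straight into a softmax; a composite model concatenates the
normalized logit pairs of its k features and applies one fusion linear map
(2k -> 2) before the softmax.  Batch normalization exists to bring the
logits of heterogeneous features onto a common scale before fusion.

Training is plain mini-batch SGD with momentum on the cross-entropy loss
``L = -sum_x p(x) log q(x)`` (p the one-hot label, q the softmax output),
with batch statistics during training and running statistics at
evaluation.  Composite models are *transfer-initialized*: their per-feature
linear maps and normalization states are copied bit-exactly from separately
trained single-feature models, and the fusion map starts as the average of
the per-feature logit pairs — the composite begins at the ensemble of its
parts and training can only move it from there.

Gradients are derived by hand (softmax + cross-entropy backpropagates
``q - p``; batchnorm uses the standard batch-statistics backward pass) and
are verified against central finite differences in the test suite.

Labels map as frequent -> 0, rare -> 1.  Prediction ties break toward
class 0 (frequent).
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

LABEL_TO_INDEX = {"frequent": 0, "rare": 1}

BN_EPS = 1e-5
BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class TrainingConfig:
    """SGD hyperparameters (defaults: lr 1e-4, momentum 0.9)."""

    learning_rate: float = 1e-4
    momentum: float = 0.9
    batch_size: int = 50
    n_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.momentum <= 1.0:
            raise ValueError("momentum must lie in [0, 1]")
        if self.batch_size < 1 or self.n_epochs < 1:
            raise ValueError("batch_size and n_epochs must be >= 1")


class FeatureBlock:
    """flatten -> linear (d x 2) -> per-logit batchnorm, for one feature."""

    PARAMS = ("W", "b", "gamma", "beta")

    def __init__(self, dim: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(dim)
        self.dim = dim
        self.W = rng.uniform(-bound, bound, size=(dim, 2))
        self.b = np.zeros(2)
        self.gamma = np.ones(2)
        self.beta = np.zeros(2)
        self.running_mean = np.zeros(2)
        self.running_var = np.ones(2)

    def forward(self, x: np.ndarray, training: bool) -> tuple[np.ndarray, dict]:
        z = x @ self.W + self.b
        if training:
            mu = z.mean(axis=0)
            var = z.var(axis=0)  # biased, used for the gradient
            n = z.shape[0]
            unbiased = var * n / (n - 1) if n > 1 else var
            self.running_mean = (1 - BN_MOMENTUM) * self.running_mean + BN_MOMENTUM * mu
            self.running_var = (1 - BN_MOMENTUM) * self.running_var + BN_MOMENTUM * unbiased
        else:
            mu, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + BN_EPS)
        zhat = (z - mu) * inv_sd
        y = self.gamma * zhat + self.beta
        cache = {"x": x, "zhat": zhat, "inv_sd": inv_sd, "training": training}
        return y, cache

    def backward(self, dy: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        zhat, inv_sd, x = cache["zhat"], cache["inv_sd"], cache["x"]
        grads = {"gamma": (dy * zhat).sum(axis=0), "beta": dy.sum(axis=0)}
        dzhat = dy * self.gamma
        if cache["training"]:
            dz = inv_sd * (
                dzhat - dzhat.mean(axis=0) - zhat * (dzhat * zhat).mean(axis=0)
            )
        else:
            dz = dzhat * inv_sd
        grads["W"] = x.T @ dz
        grads["b"] = dz.sum(axis=0)
        return grads


class ClassifierModel:
    """Single-feature (k = 1) or composite (k in {2, 3}) perceptron.

    ``feature_kinds`` fixes the order of blocks and of the concatenated
    logits; composite models carry an additional fusion linear map
    ``(2k x 2)``.
    """

    def __init__(self, feature_dims: dict[str, int], seed: int = 0, fusion_init: str = "average"):
        if not 1 <= len(feature_dims) <= 3:
            raise ValueError("models take 1 to 3 features")
        rng = np.random.default_rng(seed)
        self.feature_kinds = list(feature_dims)
        self.blocks = {kind: FeatureBlock(dim, rng) for kind, dim in feature_dims.items()}
        k = len(self.feature_kinds)
        if k == 1:
            self.fusion_W = None
            self.fusion_b = None
        elif fusion_init == "average":
            W = np.zeros((2 * k, 2))
            for i in range(k):
                W[2 * i, 0] = 1.0 / k
                W[2 * i + 1, 1] = 1.0 / k
            self.fusion_W = W
            self.fusion_b = np.zeros(2)
        elif fusion_init == "random":
            bound = 1.0 / np.sqrt(2 * k)
            self.fusion_W = rng.uniform(-bound, bound, size=(2 * k, 2))
            self.fusion_b = np.zeros(2)
        else:
            raise ValueError(f"unknown fusion_init {fusion_init!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_kinds)

    def _check(self, X: dict[str, np.ndarray]) -> None:
        for kind in self.feature_kinds:
            if kind not in X:
                raise ValueError(f"missing feature {kind!r}")
            if X[kind].shape[1] != self.blocks[kind].dim:
                raise ValueError(
                    f"feature {kind!r}: got dim {X[kind].shape[1]}, "
                    f"model expects {self.blocks[kind].dim}"
                )

    def forward(self, X: dict[str, np.ndarray], training: bool = False):
        """Return ``(logits, probabilities, cache)`` for a batch.

        ``X`` maps feature kind to a ``(n_samples, d_kind)`` design matrix.
        """
        self._check(X)
        outs, caches = [], {}
        for kind in self.feature_kinds:
            y, cache = self.blocks[kind].forward(X[kind], training)
            outs.append(y)
            caches[kind] = cache
        if self.fusion_W is None:
            logits = outs[0]
        else:
            concat = np.concatenate(outs, axis=1)
            caches["concat"] = concat
            logits = concat @ self.fusion_W + self.fusion_b
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        probs = e / e.sum(axis=1, keepdims=True)
        return logits, probs, caches

    def backward(self, probs: np.ndarray, y_idx: np.ndarray, caches: dict) -> dict:
        """Gradients of the mean cross-entropy loss for one batch."""
        n = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(n), y_idx] -= 1.0
        dlogits /= n
        grads: dict = {}
        if self.fusion_W is None:
            per_feature = [dlogits]
        else:
            concat = caches["concat"]
            grads["fusion_W"] = concat.T @ dlogits
            grads["fusion_b"] = dlogits.sum(axis=0)
            dconcat = dlogits @ self.fusion_W.T
            per_feature = [dconcat[:, 2 * i : 2 * i + 2] for i in range(self.n_features)]
        for kind, dy in zip(self.feature_kinds, per_feature):
            grads[kind] = self.blocks[kind].backward(dy, caches[kind])
        return grads

    def loss(self, X: dict[str, np.ndarray], y_idx: np.ndarray, training: bool = False) -> float:
        """Mean cross-entropy of a batch (used by gradient checks)."""
        _, probs, _ = self.forward(X, training=training)
        p = np.clip(probs[np.arange(len(y_idx)), y_idx], 1e-300, None)
        return float(-np.mean(np.log(p)))

    def copy(self) -> "ClassifierModel":
        return copy.deepcopy(self)

    # -- persistence ---------------------------------------------------

    def save(self, path) -> None:
        """Write weights to HDF5 plus a JSON sidecar with the dimensions."""
        import h5py

        with h5py.File(path, "w") as f:
            for kind in self.feature_kinds:
                g = f.create_group(f"model/feature_{kind}")
                blk = self.blocks[kind]
                for name in ("W", "b", "gamma", "beta", "running_mean", "running_var"):
                    g.create_dataset(name, data=getattr(blk, name), track_times=False)
            if self.fusion_W is not None:
                g = f.create_group("model/fusion")
                g.create_dataset("W", data=self.fusion_W, track_times=False)
                g.create_dataset("b", data=self.fusion_b, track_times=False)
        sidecar = {
            "feature_kinds": self.feature_kinds,
            "feature_dims": {k: self.blocks[k].dim for k in self.feature_kinds},
            "has_fusion": self.fusion_W is not None,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        import h5py

        with open(str(path) + ".json") as fh:
            sidecar = json.load(fh)
        model = cls({k: int(d) for k, d in sidecar["feature_dims"].items()}, seed=0)
        with h5py.File(path, "r") as f:
            for kind in model.feature_kinds:
                g = f[f"model/feature_{kind}"]
                blk = model.blocks[kind]
                for name in ("W", "b", "gamma", "beta", "running_mean", "running_var"):
                    setattr(blk, name, g[name][()])
            if sidecar["has_fusion"]:
                model.fusion_W = f["model/fusion/W"][()]
                model.fusion_b = f["model/fusion/b"][()]
        return model


def labels_to_indices(labels) -> np.ndarray:
    """Map condition tags to class indices (frequent -> 0, rare -> 1)."""
    return np.array([LABEL_TO_INDEX[l] for l in labels], dtype=np.int64)


def train(
    model: ClassifierModel,
    X: dict[str, np.ndarray],
    y_idx: np.ndarray,
    cfg: TrainingConfig,
    eval_set: tuple[dict[str, np.ndarray], np.ndarray] | None = None,
) -> tuple[ClassifierModel, np.ndarray, np.ndarray | None]:
    """Mini-batch SGD with momentum on the cross-entropy loss.

    Data order is reshuffled every epoch from ``cfg.seed``; the whole
    trajectory is deterministic given ``(cfg, data, model init)``.  Returns
    ``(model, per-epoch mean loss, per-epoch eval accuracy or None)``;
    evaluation uses running normalization statistics.
    """
    n = len(y_idx)
    batch_size = cfg.batch_size
    if batch_size > n:
        logger.warning("batch_size %d > n_samples %d: training with a single full batch",
                       batch_size, n)
        batch_size = n
    rng = np.random.default_rng(cfg.seed)

    velocity: dict = {}
    for kind in model.feature_kinds:
        velocity[kind] = {p: np.zeros_like(getattr(model.blocks[kind], p))
                          for p in FeatureBlock.PARAMS}
    if model.fusion_W is not None:
        velocity["fusion_W"] = np.zeros_like(model.fusion_W)
        velocity["fusion_b"] = np.zeros_like(model.fusion_b)

    losses = np.empty(cfg.n_epochs)
    accs = np.empty(cfg.n_epochs) if eval_set is not None else None
    for epoch in range(cfg.n_epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            sel = perm[start : start + batch_size]
            Xb = {k: X[k][sel] for k in model.feature_kinds}
            yb = y_idx[sel]
            _, probs, caches = model.forward(Xb, training=True)
            p = np.clip(probs[np.arange(len(yb)), yb], 1e-300, None)
            epoch_loss += float(-np.log(p).sum())
            grads = model.backward(probs, yb, caches)
            for kind in model.feature_kinds:
                blk = model.blocks[kind]
                for pname in FeatureBlock.PARAMS:
                    v = velocity[kind][pname]
                    v *= cfg.momentum
                    v += grads[kind][pname]
                    setattr(blk, pname, getattr(blk, pname) - cfg.learning_rate * v)
            if model.fusion_W is not None:
                for pname in ("fusion_W", "fusion_b"):
                    v = velocity[pname]
                    v *= cfg.momentum
                    v += grads[pname]
                    setattr(model, pname, getattr(model, pname) - cfg.learning_rate * v)
        losses[epoch] = epoch_loss / n
        if eval_set is not None:
            accs[epoch] = accuracy(model, eval_set[0], eval_set[1])
    return model, losses, accs


def transfer_init(single_models: list[ClassifierModel], fusion_init: str = "average",
                  seed: int = 0) -> ClassifierModel:
    """Compose trained single-feature models into a composite classifier.

    Per-feature linear maps and normalization states (including running
    statistics) are copied bit-exactly; only the fusion map is fresh
    (averaging by default, so the composite starts at the ensemble of its
    parts).
    """
    kinds: list[str] = []
    for m in single_models:
        if m.n_features != 1:
            raise ValueError("transfer_init takes trained single-feature models")
        kinds.append(m.feature_kinds[0])
    if len(set(kinds)) != len(kinds):
        raise ValueError(f"duplicate feature kinds in {kinds}")
    dims = {k: m.blocks[k].dim for k, m in zip(kinds, single_models)}
    composite = ClassifierModel(dims, seed=seed, fusion_init=fusion_init)
    for kind, source in zip(kinds, single_models):
        composite.blocks[kind] = copy.deepcopy(source.blocks[kind])
    return composite


def predict(model: ClassifierModel, X: dict[str, np.ndarray]) -> np.ndarray:
    """Class predictions (0/1); ties go to class 0 (frequent)."""
    _, probs, _ = model.forward(X, training=False)
    return (probs[:, 1] > probs[:, 0]).astype(np.int64)


def accuracy(model: ClassifierModel, X: dict[str, np.ndarray], y_idx: np.ndarray) -> float:
    """Fraction of correctly identified samples, n_c / n_all."""
    if len(y_idx) == 0:
        raise ValueError("empty evaluation set")
    return float(np.mean(predict(model, X) == y_idx))


def numerical_gradients(model: ClassifierModel, X: dict[str, np.ndarray], y_idx: np.ndarray,
                        h: float = 1e-6) -> dict:
    """Central finite-difference gradients of the training-mode loss.

    Perturbs every trainable parameter in place (restoring it afterwards);
    the oracle for the analytic backward pass.
    """
    work = model.copy()

    def loss() -> float:
        return work.loss(X, y_idx, training=True)

    def grad_of(arr: np.ndarray) -> np.ndarray:
        g = np.zeros_like(arr)
        flat = arr.reshape(-1)
        gflat = g.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + h
            hi = loss()
            flat[i] = orig - h
            lo = loss()
            flat[i] = orig
            gflat[i] = (hi - lo) / (2 * h)
        return g

    grads: dict = {}
    for kind in work.feature_kinds:
        blk = work.blocks[kind]
        grads[kind] = {p: grad_of(getattr(blk, p)) for p in FeatureBlock.PARAMS}
    if work.fusion_W is not None:
        grads["fusion_W"] = grad_of(work.fusion_W)
        grads["fusion_b"] = grad_of(work.fusion_b)
    return grads
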