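"""Recursive neural network over the three modality embeddings.

Each modality span of the fused window vector is projected into an n-dim
leaf embedding (affine + tanh).  Child vectors are composed pairwise with a
single shared n x 2n weight matrix W:

    parent = tanh( W [left; right] )

applied recursively over the modality tree (left-deep by default:
(ambient o motion) o vision), so the same composition weights process every
internal node.  A softmax head on the root gives class probabilities.
Training is mini-batch gradient descent on the cross-entropy loss with
manually derived gradients (backpropagation through structure); everything
is deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
import zipfile
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import ParameterError, TrainingError
from .fusion import FusedWindowFeature

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Training hyperparameters; the seed fixes init and batch order."""

    n: int = 64
    epochs: int = 200
    learning_rate: float = 0.01
    batch_size: int = 32
    l2: float = 1e-4
    momentum: float = 0.9
    seed: int = 0
    tree_shape: str = "left-deep"

    def __post_init__(self) -> None:
        if min(self.n, self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ParameterError("n, epochs, batch_size, learning_rate must be positive")
        if self.tree_shape not in ("left-deep", "balanced"):
            raise ParameterError(f"unknown tree_shape {self.tree_shape!r}")


@dataclass
class RvNNParams:
    """All parameter blocks plus the input standardisation constants."""

    leaf_weights: dict  # modality -> [n, d_m]
    leaf_biases: dict  # modality -> [n]
    W: np.ndarray  # [n, 2n] shared composition matrix
    head_weight: np.ndarray  # [K, n]
    head_bias: np.ndarray  # [K]
    spans: dict  # modality -> (start, stop) in the fused vector
    classes: np.ndarray  # class ids, softmax column order
    feature_mean: np.ndarray
    feature_std: np.ndarray
    tree_shape: str = "left-deep"

    def __post_init__(self) -> None:
        n = self.W.shape[0]
        if self.W.shape != (n, 2 * n):
            raise ParameterError(f"W must be n x 2n, got {self.W.shape}")
        for block in self._blocks().values():
            if not np.all(np.isfinite(block)):
                raise ParameterError("non-finite parameter values")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def _blocks(self) -> dict:
        out = {"W": self.W, "head_weight": self.head_weight, "head_bias": self.head_bias}
        for m in self.leaf_weights:
            out[f"U_{m}"] = self.leaf_weights[m]
            out[f"b_{m}"] = self.leaf_biases[m]
        return out

    def save(self, path: str) -> None:
        """Persist as a zip of .npy arrays plus a JSON config."""
        meta = {
            "spans": {m: list(s) for m, s in self.spans.items()},
            "classes": self.classes.tolist(),
            "tree_shape": self.tree_shape,
            "modalities": list(self.leaf_weights.keys()),
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(meta))
            arrays = dict(self._blocks())
            arrays["feature_mean"] = self.feature_mean
            arrays["feature_std"] = self.feature_std
            for name, arr in arrays.items():
                import io

                buf = io.BytesIO()
                np.save(buf, np.asarray(arr))
                zf.writestr(name + ".npy", buf.getvalue())

    @classmethod
    def load(cls, path: str) -> "RvNNParams":
        import io

        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("config.json"))

            def arr(name):
                return np.load(io.BytesIO(zf.read(name + ".npy")))

            return cls(
                leaf_weights={m: arr(f"U_{m}") for m in meta["modalities"]},
                leaf_biases={m: arr(f"b_{m}") for m in meta["modalities"]},
                W=arr("W"),
                head_weight=arr("head_weight"),
                head_bias=arr("head_bias"),
                spans={m: tuple(s) for m, s in meta["spans"].items()},
                classes=np.asarray(meta["classes"]),
                feature_mean=arr("feature_mean"),
                feature_std=arr("feature_std"),
                tree_shape=meta["tree_shape"],
            )


def compose(left: np.ndarray, right: np.ndarray, W: np.ndarray) -> np.ndarray:
    """One recursive composition step: tanh(W [left; right])."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    n = W.shape[0]
    if W.shape != (n, 2 * n) or left.shape[-1] != n or right.shape[-1] != n:
        raise ParameterError(
            f"shape mismatch: W{W.shape}, left{left.shape}, right{right.shape}"
        )
    z = np.concatenate([left, right], axis=-1)
    return np.tanh(z @ W.T)


def init_params(
    spans: dict,
    classes: Sequence[int],
    cfg: TrainConfig,
    feature_mean: Optional[np.ndarray] = None,
    feature_std: Optional[np.ndarray] = None,
) -> RvNNParams:
    """Seeded Gaussian initialisation scaled by 1/sqrt(fan_in)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    classes = np.asarray(sorted(set(int(c) for c in classes)))
    dim = max(b for _, b in spans.values())
    leaf_w, leaf_b = {}, {}
    for m, (a, b) in sorted(spans.items(), key=lambda kv: kv[1]):
        d = b - a
        leaf_w[m] = rng.normal(0, 1.0 / np.sqrt(max(d, 1)), size=(n, d))
        leaf_b[m] = np.zeros(n)
    return RvNNParams(
        leaf_weights=leaf_w,
        leaf_biases=leaf_b,
        W=rng.normal(0, 1.0 / np.sqrt(2 * n), size=(n, 2 * n)),
        head_weight=rng.normal(0, 1.0 / np.sqrt(n), size=(len(classes), n)),
        head_bias=np.zeros(len(classes)),
        spans=dict(spans),
        classes=classes,
        feature_mean=np.zeros(dim) if feature_mean is None else feature_mean,
        feature_std=np.ones(dim) if feature_std is None else feature_std,
        tree_shape=cfg.tree_shape,
    )


def _modality_order(params: RvNNParams) -> list[str]:
    return [m for m, _ in sorted(params.spans.items(), key=lambda kv: kv[1])]


def _forward_batch(params: RvNNParams, X: np.ndarray) -> dict:
    """Forward pass caching every intermediate needed for backprop."""
    X = (X - params.feature_mean) / params.feature_std
    order = _modality_order(params)
    leaves = {}
    for m in order:
        a, b = params.spans[m]
        leaves[m] = np.tanh(X[:, a:b] @ params.leaf_weights[m].T + params.leaf_biases[m])
    nodes = [leaves[m] for m in order]
    steps = []  # (left, right, parent) per composition
    if params.tree_shape == "balanced" and len(nodes) == 3:
        right = compose(nodes[1], nodes[2], params.W)
        steps.append((nodes[1], nodes[2], right))
        root = compose(nodes[0], right, params.W)
        steps.append((nodes[0], right, root))
    else:  # left-deep cascade over however many leaves exist
        root = nodes[0]
        for child in nodes[1:]:
            parent = compose(root, child, params.W)
            steps.append((root, child, parent))
            root = parent
    logits = root @ params.head_weight.T + params.head_bias
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    probs = expl / expl.sum(axis=1, keepdims=True)
    if not np.all(np.isfinite(probs)):
        raise TrainingError("non-finite activations in the softmax head")
    return {
        "X": X, "order": order, "leaves": leaves, "steps": steps,
        "root": root, "probs": probs,
    }


def forward(params: RvNNParams, fused: FusedWindowFeature | np.ndarray) -> np.ndarray:
    """Class probability vector for one fused window (sums to 1)."""
    x = fused.vector if isinstance(fused, FusedWindowFeature) else np.asarray(fused, float)
    return _forward_batch(params, x[None, :])["probs"][0]


def predict(params: RvNNParams, X: np.ndarray) -> np.ndarray:
    """Predicted class ids for a [windows, dims] feature matrix."""
    probs = _forward_batch(params, np.asarray(X, dtype=float))["probs"]
    return params.classes[np.argmax(probs, axis=1)]


def loss_and_grads(
    params: RvNNParams, X: np.ndarray, y: np.ndarray, l2: float = 0.0
) -> tuple[float, dict]:
    """Mean cross-entropy loss (+ L2 on weights) and gradients per block."""
    cache = _forward_batch(params, X)
    probs, root = cache["probs"], cache["root"]
    B = len(X)
    cls_index = {c: i for i, c in enumerate(params.classes.tolist())}
    yi = np.array([cls_index[int(c)] for c in y])
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(B), yi] + eps)))
    if l2 > 0:
        loss += l2 * (
            np.sum(params.W**2)
            + np.sum(params.head_weight**2)
            + sum(np.sum(U**2) for U in params.leaf_weights.values())
        )

    dlogits = probs.copy()
    dlogits[np.arange(B), yi] -= 1.0
    dlogits /= B
    grads = {
        "head_weight": dlogits.T @ root + (2 * l2 * params.head_weight if l2 else 0.0),
        "head_bias": dlogits.sum(axis=0),
        "W": np.zeros_like(params.W),
    }
    dnode = dlogits @ params.head_weight  # gradient wrt root activation
    n = params.n
    order, leaves, steps = cache["order"], cache["leaves"], cache["steps"]
    dleaves = {m: np.zeros_like(leaves[m]) for m in order}

    if params.tree_shape == "balanced" and len(order) == 3:
        # root = compose(leaf0, inner), inner = compose(leaf1, leaf2)
        (l1, l2_, inner), (l0, inner2, root_) = steps
        da = dnode * (1 - root_**2)
        grads["W"] += da.T @ np.concatenate([l0, inner2], axis=1)
        dz = da @ params.W
        dleaves[order[0]] += dz[:, :n]
        dinner = dz[:, n:]
        da = dinner * (1 - inner**2)
        grads["W"] += da.T @ np.concatenate([l1, l2_], axis=1)
        dz = da @ params.W
        dleaves[order[1]] += dz[:, :n]
        dleaves[order[2]] += dz[:, n:]
    else:
        for si in range(len(steps) - 1, -1, -1):
            left, right, parent = steps[si]
            da = dnode * (1 - parent**2)
            grads["W"] += da.T @ np.concatenate([left, right], axis=1)
            dz = da @ params.W
            dnode = dz[:, :n]  # flows to the left child (previous parent)
            dleaves[order[si + 1]] += dz[:, n:]  # right child is leaf si+1
        dleaves[order[0]] += dnode
    if l2 > 0:
        grads["W"] += 2 * l2 * params.W

    Xs = cache["X"]
    for m in order:
        a, b = params.spans[m]
        dpre = dleaves[m] * (1 - leaves[m] ** 2)
        grads[f"U_{m}"] = dpre.T @ Xs[:, a:b]
        if l2 > 0:
            grads[f"U_{m}"] += 2 * l2 * params.leaf_weights[m]
        grads[f"b_{m}"] = dpre.sum(axis=0)
    return loss, grads


def train(
    X: np.ndarray,
    y: np.ndarray,
    spans: dict,
    cfg: Optional[TrainConfig] = None,
) -> tuple[RvNNParams, dict]:
    """Fit the RvNN by seeded mini-batch gradient descent (with momentum).

    Inputs are standardised internally (the constants are stored in the
    returned params, so inference applies the same transform).  Returns the
    fitted parameters and a report with the per-epoch loss and the final
    training accuracy.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise TrainingError("training requires at least 2 classes")
    counts = np.bincount(np.searchsorted(classes, y))
    if counts.min() < 10:
        logger.warning("fewer than 10 windows in the smallest class (%d)", counts.min())

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std < 1e-8] = 1.0
    params = init_params(spans, classes, cfg, feature_mean=mean, feature_std=std)
    rng = np.random.default_rng(cfg.seed + 1)
    velocity = {k: np.zeros_like(v) for k, v in params._blocks().items()}
    losses = []
    for epoch in range(cfg.epochs):
        idx = rng.permutation(len(X))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(X), cfg.batch_size):
            batch = idx[start: start + cfg.batch_size]
            loss, grads = loss_and_grads(params, X[batch], y[batch], l2=cfg.l2)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            blocks = params._blocks()
            for k, g in grads.items():
                velocity[k] = cfg.momentum * velocity[k] - cfg.learning_rate * g
                blocks[k] += velocity[k]
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / n_batches)
    train_acc = float(np.mean(predict(params, X) == y))
    report = {"loss_history": losses, "final_loss": losses[-1], "train_accuracy": train_acc}
    return params, report


def kfold_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    spans: dict,
    k: int = 10,
    cfg: Optional[TrainConfig] = None,
    seed: int = 0,
) -> dict:
    """Stratified k-fold cross-validation of the RvNN.

    Returns per-fold test accuracies, the pooled row-normalised confusion
    matrix, and the macro (mean per-class) accuracy.  If the smallest class
    has fewer than k windows the fold count is reduced with a warning.
    """
    from .evaluation import confusion_matrix, mean_class_accuracy

    if k < 2:
        raise ParameterError("k must be >= 2")
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    k_eff = int(min(k, counts.min()))
    if k_eff < k:
        logger.warning("smallest class has %d windows; reducing folds %d -> %d",
                       counts.min(), k, k_eff)
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    fold_acc, y_true_all, y_pred_all = [], [], []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + fold})
        params, _ = train(X[tr], y[tr], spans, fold_cfg)
        pred = predict(params, X[te])
        fold_acc.append(float(np.mean(pred == y[te])))
        y_true_all.append(y[te])
        y_pred_all.append(pred)
    cm = confusion_matrix(
        np.concatenate(y_true_all), np.concatenate(y_pred_all), classes=classes
    )
    return {
        "fold_accuracies": fold_acc,
        "confusion_matrix": cm,
        "mean_class_accuracy": mean_class_accuracy(cm),
        "n_folds": k_eff,
    }
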