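"""Dense neural-network classifier over cluster summary features.

Training-set assembly follows the encounter discipline of acoustic data:
detections separated by gaps of more than 15 minutes start a new encounter,
encounters are randomly assigned whole to train/validation/test (70/10/20) so
no encounter leaks across sets, and a balanced collection of 1,500 examples
per class is then formed (majority classes subsampled, minority classes
augmented with Gaussian feature noise) and subdivided per class into 1,000
training and 500 testing examples, the 1,000 splitting 80/20 into training
and validation.

The classifier itself is a fully-connected network — four 512-node hidden
layers with leaky-ReLU activations and 50% dropout, and a softmax output —
trained with Adam at a constant learning rate of 3e-4, batches of 100, at most
15 epochs and early stopping with 3 epochs of patience on the validation
loss. It is implemented directly on numpy with a scikit-learn estimator
interface, so training is seed-deterministic and the weights serialize
bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .features import ClusterSummary, norm01

__all__ = [
    "TrainConfig",
    "DenseClickClassifier",
    "feature_vector",
    "feature_layout",
    "split_encounters",
    "balance_classes",
    "build_and_train",
    "predict_clusters",
]


@dataclass
class TrainConfig:
    """Training-set assembly and optimization settings."""

    examples_per_class: int = 1500
    train_count: int = 1000  # per-class train+validation pool; rest is test
    val_fraction: float = 0.2
    encounter_gap_min: float = 15.0
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    batch_size: int = 100
    learning_rate: float = 3e-4
    max_epochs: int = 15
    patience: int = 3
    dropout: float = 0.5
    hidden_layers: tuple[int, ...] = (512, 512, 512, 512)
    leaky_alpha: float = 0.01
    augment_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")


# ---------------------------------------------------------------------------
# feature vectors


def feature_layout(summary: ClusterSummary, band: tuple[float, float] = (10.0, 90.0)) -> dict:
    """Layout descriptor of the concatenated feature vector."""
    if summary.freqs_khz is None:
        spec_len = summary.mean_spectrum.size
    else:
        mask = (summary.freqs_khz >= band[0]) & (summary.freqs_khz <= band[1])
        spec_len = int(mask.sum())
    return {
        "spectrum": spec_len,
        "ici": int(summary.ici_distribution.size),
        "envelope": int(summary.mean_envelope.size),
        "band_khz": list(band),
    }


def feature_vector(summary: ClusterSummary, band: tuple[float, float] = (10.0, 90.0)) -> np.ndarray:
    """Fixed-length [0, 1] vector: truncated mean spectrum, ICI histogram and
    mean envelope, each min-max normalized (a constant segment maps to
    zeros)."""
    spec = summary.mean_spectrum
    if summary.freqs_khz is not None:
        mask = (summary.freqs_khz >= band[0]) & (summary.freqs_khz <= band[1])
        spec = spec[mask]
    return np.concatenate([norm01(spec), norm01(summary.ici_distribution), norm01(summary.mean_envelope)])


# ---------------------------------------------------------------------------
# encounter splitting and balancing


def split_encounters(
    meta: pd.DataFrame,
    config: TrainConfig | None = None,
    seed=0,
) -> pd.DataFrame:
    """Assign labeled examples to train/validation/test by whole encounters.

    ``meta`` needs columns ``time_s`` and ``site``. Encounters are runs of
    examples at one site whose successive gaps never exceed the encounter gap
    (15 min); each encounter lands wholly in one set. Encounters are shuffled
    and assigned greedily to whichever set is furthest below its target
    proportion, which keeps realized example proportions near 70/10/20 when
    the encounter-size distribution allows. Returns a copy of ``meta`` with
    ``encounter_id`` and ``subset`` columns.
    """
    import warnings

    config = config or TrainConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = meta.copy()
    gap_s = config.encounter_gap_min * 60.0
    encounter_ids = np.empty(len(out), dtype=int)
    next_id = 0
    for _, site_idx in out.groupby("site", sort=True).groups.items():
        order = out.loc[site_idx].sort_values("time_s").index
        times = out.loc[order, "time_s"].to_numpy(dtype=float)
        new_enc = np.concatenate(([True], np.diff(times) > gap_s))
        ids = next_id + np.cumsum(new_enc) - 1
        next_id = int(ids[-1]) + 1
        encounter_ids[out.index.get_indexer(order)] = ids
    out["encounter_id"] = encounter_ids

    sizes = out.groupby("encounter_id").size()
    encounters = sizes.index.to_numpy()
    if encounters.size == 1:
        warnings.warn("single encounter: all examples assigned to the training set")
        out["subset"] = "train"
        return out
    rng.shuffle(encounters)
    total = float(len(out))
    targets = np.array(config.split_fractions) * total
    counts = np.zeros(3)
    names = np.array(["train", "validate", "test"])
    assign = {}
    for enc in encounters:
        deficit = (targets - counts) / targets
        k = int(np.argmax(deficit))
        assign[enc] = names[k]
        counts[k] += sizes[enc]
    out["subset"] = out["encounter_id"].map(assign)
    return out


def balance_classes(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
    seed=0,
    classes: list | None = None,
) -> dict:
    """Form a balanced per-class collection and its train/val/test splits.

    Every class ends with exactly ``examples_per_class`` examples: majority
    classes are subsampled uniformly without replacement; minority classes
    gain augmented copies (a resampled original plus Gaussian noise of sd
    ``augment_noise_sd``, clipped to [0, 1]). Each class is then subdivided
    into ``train_count`` training and the remaining testing examples, with
    the training pool split 80/20 into train and validation.

    Returns a dict with ``X_train/y_train``, ``X_val/y_val``,
    ``X_test/y_test`` and the balanced pool ``X_bal/y_bal``.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    target = config.examples_per_class
    classes = np.unique(y) if classes is None else np.asarray(classes)
    parts_X, parts_y = [], []
    split_train, split_val, split_test = [], [], []
    n_val = int(round(config.train_count * config.val_fraction))
    for c in classes:
        idx = np.flatnonzero(y == c)
        if idx.size == 0:
            raise ValueError(f"class {c!r} has no examples")
        if idx.size >= target:
            chosen = rng.choice(idx, size=target, replace=False)
            Xc = X[chosen]
        else:
            extra = target - idx.size
            base = X[rng.choice(idx, size=extra, replace=True)]
            noise = rng.normal(0.0, config.augment_noise_sd, base.shape)
            Xc = np.concatenate([X[idx], np.clip(base + noise, 0.0, 1.0)])
        perm = rng.permutation(target)
        Xc = Xc[perm]
        parts_X.append(Xc)
        parts_y.append(np.full(target, c, dtype=y.dtype))
        train_pool = Xc[: config.train_count]
        split_test.append(Xc[config.train_count :])
        split_val.append(train_pool[:n_val])
        split_train.append(train_pool[n_val:])
    yc = [np.full(len(part), c, dtype=y.dtype) for part, c in zip(split_train, classes)]
    return {
        "X_bal": np.concatenate(parts_X),
        "y_bal": np.concatenate(parts_y),
        "X_train": np.concatenate(split_train),
        "y_train": np.concatenate(yc),
        "X_val": np.concatenate(split_val),
        "y_val": np.concatenate(
            [np.full(len(p), c, dtype=y.dtype) for p, c in zip(split_val, classes)]
        ),
        "X_test": np.concatenate(split_test),
        "y_test": np.concatenate(
            [np.full(len(p), c, dtype=y.dtype) for p, c in zip(split_test, classes)]
        ),
    }


# ---------------------------------------------------------------------------
# the network


def _leaky_relu(z: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(z > 0, z, alpha * z)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class DenseClickClassifier(ClassifierMixin, BaseEstimator):
    """Feed-forward softmax classifier for cluster summary feature vectors.

    Architecture: input -> four 512-node fully-connected layers with
    leaky-ReLU activations and dropout between layers -> softmax output.
    Optimized with Adam at a constant learning rate, cross-entropy loss, and
    early stopping on validation loss. Deterministic per ``random_state``.

    Fitted attributes (trailing underscore): ``classes_``, ``coefs_``,
    ``intercepts_``, ``loss_curve_``, ``validation_loss_curve_``,
    ``n_iter_``, ``best_epoch_``, ``n_features_in_``.
    """

    def __init__(
        self,
        hidden_layers: tuple[int, ...] = (512, 512, 512, 512),
        dropout: float = 0.5,
        leaky_alpha: float = 0.01,
        learning_rate: float = 3e-4,
        batch_size: int = 100,
        max_epochs: int = 15,
        patience: int = 3,
        random_state: int = 0,
    ):
        self.hidden_layers = hidden_layers
        self.dropout = dropout
        self.leaky_alpha = leaky_alpha
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.random_state = random_state

    # -- internals ----------------------------------------------------------

    def _init_params(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        dims = [n_in, *self.hidden_layers, n_out]
        self.coefs_ = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), (dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.intercepts_ = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]

    def _forward(self, X: np.ndarray, rng: np.random.Generator | None = None) -> tuple:
        """Forward pass; with `rng` (training) applies inverted dropout."""
        acts = [X]
        masks = []
        a = X
        n_hidden = len(self.hidden_layers)
        for i in range(n_hidden):
            z = a @ self.coefs_[i] + self.intercepts_[i]
            a = _leaky_relu(z, self.leaky_alpha)
            if rng is not None and self.dropout > 0:
                mask = (rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
                a = a * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(a)
        logits = a @ self.coefs_[-1] + self.intercepts_[-1]
        return _softmax(logits), acts, masks

    def _backward(self, probs, onehot, acts, masks) -> list:
        grads = []
        n = probs.shape[0]
        delta = (probs - onehot) / n
        for i in range(len(self.coefs_) - 1, -1, -1):
            grads.append((acts[i].T @ delta, delta.sum(axis=0)))
            if i > 0:
                delta = delta @ self.coefs_[i].T
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
                delta = delta * np.where(acts[i] > 0, 1.0, self.leaky_alpha)
        return grads[::-1]

    @staticmethod
    def _xent(probs: np.ndarray, onehot: np.ndarray) -> float:
        return float(-np.mean(np.sum(onehot * np.log(probs + 1e-12), axis=1)))

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y, validation_data=None):
        """Train the network.

        ``validation_data=(X_val, y_val)`` supplies the early-stopping set;
        without it a seeded 80/20 split of ``(X, y)`` is used.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        rng = np.random.default_rng(self.random_state)
        if validation_data is None:
            perm = rng.permutation(X.shape[0])
            n_val = max(1, int(round(0.2 * X.shape[0])))
            val_idx, train_idx = perm[:n_val], perm[n_val:]
            Xv, yv_idx = X[val_idx], y_idx[val_idx]
            X, y_idx = X[train_idx], y_idx[train_idx]
        else:
            Xv = np.asarray(validation_data[0], dtype=float)
            yv = np.asarray(validation_data[1])
            yv_idx = np.searchsorted(self.classes_, yv)
            if not np.array_equal(self.classes_[yv_idx], yv):
                raise ValueError("validation labels outside the training class list")

        n_classes = self.classes_.size
        self.n_features_in_ = X.shape[1]
        self._init_params(self.n_features_in_, n_classes, rng)
        onehot = np.eye(n_classes)[y_idx]
        onehot_val = np.eye(n_classes)[yv_idx]

        m = [np.zeros_like(w) for pair in zip(self.coefs_, self.intercepts_) for w in pair]
        v = [np.zeros_like(w) for pair in zip(self.coefs_, self.intercepts_) for w in pair]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        self.loss_curve_ = []
        self.validation_loss_curve_ = []
        best_val = np.inf
        best_epoch = 0
        best_params = None
        epochs_since_improve = 0

        n = X.shape[0]
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                probs, acts, masks = self._forward(X[batch], rng)
                loss = self._xent(probs, onehot[batch])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch {epoch}; "
                        f"history: {self.loss_curve_}"
                    )
                epoch_loss += loss
                n_batches += 1
                grads = self._backward(probs, onehot[batch], acts, masks)
                step += 1
                flat = [g for pair in grads for g in pair]
                params = [p for pair in zip(self.coefs_, self.intercepts_) for p in pair]
                for k, (p, g) in enumerate(zip(params, flat)):
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g**2
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v[k] / (1 - beta2**step)
                    p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            self.loss_curve_.append(epoch_loss / max(1, n_batches))

            val_probs, _, _ = self._forward(Xv)
            val_loss = self._xent(val_probs, onehot_val)
            self.validation_loss_curve_.append(val_loss)
            if val_loss < best_val:
                best_val = val_loss
                best_epoch = epoch
                best_params = (
                    [w.copy() for w in self.coefs_],
                    [b.copy() for b in self.intercepts_],
                )
                epochs_since_improve = 0
            else:
                epochs_since_improve += 1
                if epochs_since_improve >= self.patience:
                    break

        if best_params is not None:
            self.coefs_, self.intercepts_ = best_params
        self.n_iter_ = len(self.loss_curve_)
        self.best_epoch_ = best_epoch
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature layout mismatch: model expects {self.n_features_in_} "
                f"features, got {X.shape[1]}"
            )
        probs, _, _ = self._forward(X)
        return probs

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    @property
    def n_parameters_(self) -> int:
        return int(sum(w.size for w in self.coefs_) + sum(b.size for b in self.intercepts_))

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        """Portable container: weights, class list, hyperparameters and a
        layout stamp; load/save round-trips weights bit-exactly."""
        header = json.dumps(
            {
                "params": self.get_params(),
                "classes": self.classes_.tolist(),
                "n_features_in": int(self.n_features_in_),
                "n_iter": int(self.n_iter_),
                "best_epoch": int(self.best_epoch_),
                "loss_curve": self.loss_curve_,
                "validation_loss_curve": self.validation_loss_curve_,
            }
        )
        arrays = {"header": np.frombuffer(header.encode(), dtype=np.uint8)}
        for i, (w, b) in enumerate(zip(self.coefs_, self.intercepts_)):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "DenseClickClassifier":
        with np.load(path) as data:
            header = json.loads(bytes(data["header"]).decode())
            model = cls(**{
                k: tuple(vv) if isinstance(vv, list) else vv
                for k, vv in header["params"].items()
            })
            model.classes_ = np.asarray(header["classes"])
            model.n_features_in_ = header["n_features_in"]
            model.n_iter_ = header["n_iter"]
            model.best_epoch_ = header["best_epoch"]
            model.loss_curve_ = header["loss_curve"]
            model.validation_loss_curve_ = header["validation_loss_curve"]
            n_layers = len(header["params"]["hidden_layers"]) + 1
            model.coefs_ = [data[f"W{i}"] for i in range(n_layers)]
            model.intercepts_ = [data[f"b{i}"] for i in range(n_layers)]
        return model


def build_and_train(balanced: dict, config: TrainConfig | None = None, seed=0) -> DenseClickClassifier:
    """Train a classifier on the output of :func:`balance_classes`."""
    config = config or TrainConfig()
    model = DenseClickClassifier(
        hidden_layers=config.hidden_layers,
        dropout=config.dropout,
        leaky_alpha=config.leaky_alpha,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        random_state=seed,
    )
    return model.fit(
        balanced["X_train"],
        balanced["y_train"],
        validation_data=(balanced["X_val"], balanced["y_val"]),
    )


def predict_clusters(
    model: DenseClickClassifier,
    summaries: list[ClusterSummary],
    band: tuple[float, float] = (10.0, 90.0),
) -> pd.DataFrame:
    """Classify cluster summaries: label = softmax argmax, score = maximum
    probability. Every member click of a cluster inherits the cluster label
    downstream."""
    X = np.stack([feature_vector(s, band) for s in summaries])
    probs = model.predict_proba(X)
    idx = np.argmax(probs, axis=1)
    return pd.DataFrame(
        {
            "label": model.classes_[idx],
            "score": probs[np.arange(len(idx)), idx],
        }
    )
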