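"""Supervised alcohol-vs-marijuana classification head on the tiled/TICA
feature extractor.

The model is: tiled convolution -> squared responses -> fixed topographic
neighborhood pooling -> epsilon-smoothed square root -> L2 feature
normalization -> dense softmax head.  Training is plain mini-batch gradient
descent on the cross-entropy; backpropagation passes through the smoothed
pooling and sums the tiled-convolution gradients into the shared banks.  A
dense path (no feature extractor) accepts raw flattened windows so the
image-encoding ablation can be run with the same trainer.
"""

from __future__ import annotations

import copy
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score, roc_auc_score

from .tica_net import (PoolingTopology, TiledWeights, init_tiled_weights,
                       tiled_conv_bank_gradient, tiled_conv_forward)

__all__ = [
    "CLASS_ORDER",
    "ModelSpec",
    "EvalReport",
    "GafDataset",
    "build_model",
    "split_dataset",
    "train",
    "predict_proba",
    "evaluate",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

#: Fixed class order: index 0 = alcohol, index 1 = marijuana (positive class).
CLASS_ORDER: Tuple[str, str] = ("alcohol", "marijuana")


@dataclass
class GafDataset:
    """A batch of samples: images (N, H, W, C) or raw windows (N, d...),
    with integer labels in CLASS_ORDER and per-sample subject ids."""

    X: np.ndarray
    y: np.ndarray
    subjects: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.subjects = np.asarray(self.subjects)
        if not (len(self.X) == len(self.y) == len(self.subjects)):
            raise ValueError("X, y, subjects must have equal length")

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx) -> "GafDataset":
        return GafDataset(self.X[idx], self.y[idx], self.subjects[idx])

    @classmethod
    def from_images(cls, images) -> "GafDataset":
        from .gaf import subject_of

        label_idx = {lab: i for i, lab in enumerate(CLASS_ORDER)}
        X = np.stack([im.pixels for im in images])
        y = np.array([label_idx[im.label] for im in images])
        subjects = np.array([subject_of(im) for im in images])
        return cls(X, y, subjects)


@dataclass
class ModelSpec:
    """Feature extractor + dense softmax head.

    ``weights is None`` selects the dense path: the head consumes the
    L2-normalized flattened input directly.
    """

    weights: Optional[TiledWeights]
    pooling: Optional[PoolingTopology]
    head_w: np.ndarray
    head_b: np.ndarray
    freeze_features: bool = False
    epsilon: float = 1e-8
    input_shape: Tuple[int, ...] = ()
    classes: Tuple[str, str] = CLASS_ORDER


def build_model(input_shape: Tuple[int, ...],
                weights: Optional[TiledWeights] = None,
                n_maps: int = 3, tile_k: int = 2, rf_s: int = 8,
                use_features: bool = True, freeze_features: bool = False,
                epsilon: float = 1e-8, seed: int = 0) -> ModelSpec:
    """Assemble a model for inputs of the given per-sample shape.

    When ``weights`` is omitted and ``use_features`` is set, the banks are
    randomly initialized (seeded).  The head input size is derived from the
    pooled-activation count so the two always agree.
    """
    rng = np.random.default_rng(seed)
    pooling = None
    if use_features:
        if len(input_shape) != 3:
            raise ValueError("feature path expects (H, W, C) inputs")
        H, W, C = input_shape
        if weights is None:
            weights = init_tiled_weights(n_maps, tile_k, rf_s, C,
                                         seed=int(rng.integers(2**31 - 1)))
        Ho = H - weights.rf_s + 1
        Wo = W - weights.rf_s + 1
        if Ho < 1 or Wo < 1:
            raise ValueError("receptive field exceeds input side")
        pooling = PoolingTopology(grid=(Ho, Wo), n_maps=weights.n_maps)
        n_features = pooling.n_units
    else:
        weights = None
        n_features = int(np.prod(input_shape))
    head_w = rng.normal(0.0, 0.01, size=(2, n_features))
    head_b = np.zeros(2)
    return ModelSpec(weights=weights, pooling=pooling, head_w=head_w,
                     head_b=head_b, freeze_features=freeze_features,
                     epsilon=epsilon, input_shape=tuple(input_shape))


# ---------------------------------------------------------------------------
# Forward / backward

def _forward(model: ModelSpec, X: np.ndarray) -> Dict[str, np.ndarray]:
    B = X.shape[0]
    if model.weights is not None:
        r = tiled_conv_forward(X, model.weights)          # (B, Ho, Wo, L)
        E = model.pooling.apply(r * r)
        p = np.sqrt(model.epsilon + E)
        flat = p.reshape(B, -1)
    else:
        r = p = None
        flat = X.reshape(B, -1)
    norms = np.linalg.norm(flat, axis=1, keepdims=True)
    norms = np.maximum(norms, 1e-12)
    feat = flat / norms
    z = feat @ model.head_w.T + model.head_b
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    return {"r": r, "p": p, "flat": flat, "norms": norms, "feat": feat,
            "probs": probs}


def _backward(model: ModelSpec, X: np.ndarray, y: np.ndarray,
              cache: Dict[str, np.ndarray]):
    """Cross-entropy gradients for the head and (unless frozen) the banks."""
    B = X.shape[0]
    probs = cache["probs"]
    dz = probs.copy()
    dz[np.arange(B), y] -= 1.0
    dz /= B
    feat = cache["feat"]
    d_head_w = dz.T @ feat
    d_head_b = dz.sum(axis=0)
    d_banks = None
    if model.weights is not None and not model.freeze_features:
        dfeat = dz @ model.head_w
        flat, norms = cache["flat"], cache["norms"]
        # y = flat / ||flat||  =>  dflat = (dfeat - feat * <feat, dfeat>) / ||flat||
        inner = (feat * dfeat).sum(axis=1, keepdims=True)
        dflat = (dfeat - feat * inner) / norms
        p = cache["p"]
        dp = dflat.reshape(p.shape)
        dE = dp / (2.0 * p)
        dE2 = model.pooling.apply(dE)       # box sum is self-adjoint
        dr = 2.0 * cache["r"] * dE2
        d_banks = tiled_conv_bank_gradient(X, model.weights, dr)
    return d_head_w, d_head_b, d_banks


def _xent(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-300)))


def train(model: ModelSpec, train_set: GafDataset, epochs: int = 100,
          lr: float = 0.01, batch_size: int = 16,
          seed: int = 0) -> Tuple[ModelSpec, List[float]]:
    """Mini-batch gradient descent on the cross-entropy; returns a trained
    copy of the model and the per-epoch mean loss history.  Deterministic
    per seed."""
    if len(train_set) == 0:
        raise ValueError("train set is empty")
    if len(np.unique(train_set.y)) < 2:
        raise ValueError("train set must contain both classes")
    model = copy.deepcopy(model)
    rng = np.random.default_rng(seed)
    X, y = train_set.X, train_set.y
    n = len(y)
    history: List[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = X[idx], y[idx]
            cache = _forward(model, xb)
            total += _xent(cache["probs"], yb) * len(idx)
            d_head_w, d_head_b, d_banks = _backward(model, xb, yb, cache)
            if lr != 0.0:
                model.head_w -= lr * d_head_w
                model.head_b -= lr * d_head_b
                if d_banks is not None:
                    model.weights.banks -= lr * d_banks
        history.append(total / n)
        logger.debug("epoch %d loss %.5f", epoch, history[-1])
    return model, history


def predict_proba(model: ModelSpec, X: np.ndarray,
                  chunk: int = 64) -> np.ndarray:
    """Class probabilities, evaluated in chunks to bound memory."""
    X = np.asarray(X, dtype=float)
    outs = [_forward(model, X[i:i + chunk])["probs"]
            for i in range(0, len(X), chunk)]
    return np.vstack(outs)


# ---------------------------------------------------------------------------
# Splitting and evaluation

def split_dataset(dataset: GafDataset, strategy: str = "subject_wise",
                  test_fraction: float = 0.3,
                  seed: int = 0) -> Tuple[GafDataset, GafDataset]:
    """Partition a dataset for training/testing.

    ``subject_wise``: no subject id appears in both partitions (test
    subjects are drawn per class so both classes stay represented).
    ``record_wise``: per-class stratified record split.  Deterministic per
    seed; raises if a class ends up absent from either partition.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    if strategy not in ("subject_wise", "record_wise"):
        raise ValueError(f"unknown split strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(len(dataset), dtype=bool)
    if strategy == "subject_wise":
        for cls in np.unique(dataset.y):
            subs = np.unique(dataset.subjects[dataset.y == cls])
            subs = subs[rng.permutation(len(subs))]
            n_test = int(round(test_fraction * len(subs)))
            n_test = min(max(n_test, 1), len(subs) - 1) if len(subs) > 1 \
                else len(subs)
            test_subs = set(subs[:n_test])
            test_mask |= np.isin(dataset.subjects, list(test_subs))
    else:
        for cls in np.unique(dataset.y):
            idx = np.flatnonzero(dataset.y == cls)
            idx = idx[rng.permutation(len(idx))]
            n_test = min(max(int(round(test_fraction * len(idx))), 1),
                         len(idx) - 1)
            test_mask[idx[:n_test]] = True
    train_set = dataset.subset(~test_mask)
    test_set = dataset.subset(test_mask)
    for name, part in (("train", train_set), ("test", test_set)):
        present = set(np.unique(part.y))
        if present != {0, 1}:
            raise ValueError(
                f"class absent from {name} partition (have {sorted(present)})")
    if strategy == "subject_wise":
        overlap = set(train_set.subjects) & set(test_set.subjects)
        assert not overlap, f"subject leakage: {overlap}"
    return train_set, test_set


@dataclass
class EvalReport:
    """Test-set metrics; positive class for the binary F1 is marijuana."""

    accuracy: float
    f1: float
    f1_macro: float
    roc_auc: Optional[float]
    confusion: np.ndarray
    n_test: int

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "f1": self.f1,
                "f1_macro": self.f1_macro, "roc_auc": self.roc_auc,
                "confusion": np.asarray(self.confusion).tolist(),
                "n_test": self.n_test}


def evaluate(model: ModelSpec, test_set: GafDataset) -> EvalReport:
    """Accuracy, binary F1 (marijuana positive), macro F1, rank-based ROC
    AUC from the marijuana-class probability, and the confusion table."""
    if len(test_set) == 0:
        raise ValueError("test set is empty")
    probs = predict_proba(model, test_set.X)
    return score_predictions(test_set.y, probs)


def score_predictions(y_true: np.ndarray, probs: np.ndarray) -> EvalReport:
    y_true = np.asarray(y_true, dtype=int)
    pred = probs.argmax(axis=1)
    cm = confusion_matrix(y_true, pred, labels=[0, 1])
    acc = float(np.trace(cm) / len(y_true))
    f1 = float(f1_score(y_true, pred, pos_label=1, zero_division=0))
    f1m = float(f1_score(y_true, pred, average="macro", zero_division=0))
    if len(np.unique(y_true)) < 2:
        warnings.warn("test set contains a single class; ROC AUC undefined")
        auc = None
    else:
        auc = float(roc_auc_score(y_true, probs[:, 1]))
    return EvalReport(accuracy=acc, f1=f1, f1_macro=f1m, roc_auc=auc,
                      confusion=cm, n_test=len(y_true))


# ---------------------------------------------------------------------------
# Model I/O

def save_model(path, model: ModelSpec) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("head_w", data=model.head_w)
        f.create_dataset("head_b", data=model.head_b)
        f.attrs["epsilon"] = model.epsilon
        f.attrs["freeze_features"] = model.freeze_features
        f.attrs["input_shape"] = json.dumps(list(model.input_shape))
        f.attrs["classes"] = json.dumps(list(model.classes))
        if model.weights is not None:
            f.create_dataset("banks", data=model.weights.banks)
            f.attrs["tile_k"] = model.weights.tile_k
            f.attrs["rf_s"] = model.weights.rf_s
            f.attrs["n_maps"] = model.weights.n_maps
            f.attrs["pool_grid"] = list(model.pooling.grid)
            f.attrs["pool_radius"] = model.pooling.radius


def load_model(path) -> ModelSpec:
    import h5py

    with h5py.File(path, "r") as f:
        weights = pooling = None
        if "banks" in f:
            weights = TiledWeights(banks=f["banks"][...],
                                   tile_k=int(f.attrs["tile_k"]),
                                   rf_s=int(f.attrs["rf_s"]),
                                   n_maps=int(f.attrs["n_maps"]))
            pooling = PoolingTopology(
                grid=tuple(int(g) for g in f.attrs["pool_grid"]),
                n_maps=weights.n_maps, radius=int(f.attrs["pool_radius"]))
        return ModelSpec(weights=weights, pooling=pooling,
                         head_w=f["head_w"][...], head_b=f["head_b"][...],
                         freeze_features=bool(f.attrs["freeze_features"]),
                         epsilon=float(f.attrs["epsilon"]),
                         input_shape=tuple(json.loads(f.attrs["input_shape"])),
                         classes=tuple(json.loads(f.attrs["classes"])))
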