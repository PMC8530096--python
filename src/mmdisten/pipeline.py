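"""Entropy feature extraction and the three-state seizure classifier.

Each epoch's channels are treated as one multivariate series and reduced to
an entropy-versus-scale curve; the curves form the feature matrix for a
small feed-forward network (two hidden layers of 12 rectified-linear units,
3-way softmax output) trained with RMSprop on the categorical cross-entropy.
The network is implemented directly on numpy so that training is exactly
reproducible from a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .core import EmbeddingError, EntropyParams, InvalidScaleError, mm_mdisten_curve
from .eeg import EpochSet
from .signals import STATES

__all__ = [
    "EpochFeatureTable",
    "ClassifierConfig",
    "MLPModel",
    "extract_features",
    "train_classifier",
    "predict_states",
    "split_epochs",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class EpochFeatureTable:
    """Per-epoch entropy features (epochs x scales) with state labels."""

    features: np.ndarray
    labels: tuple[str, ...]
    scale_values: tuple[int, ...]
    start_times_s: tuple[float, ...] = ()
    n_dropped: int = 0

    def __post_init__(self) -> None:
        feats = np.atleast_2d(np.asarray(self.features, dtype=float))
        if feats.size and feats.shape[1] != len(self.scale_values):
            raise ValueError(
                f"feature width {feats.shape[1]} != number of scales {len(self.scale_values)}"
            )
        if feats.shape[0] != len(self.labels) and feats.size:
            raise ValueError("one label per feature row required")
        if feats.size and (np.any(feats < 0) or np.any(feats > 1) or not np.all(np.isfinite(feats))):
            raise ValueError("entropy features must be finite and within [0, 1]")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return 0 if self.features.size == 0 else self.features.shape[0]

    @property
    def label_indices(self) -> np.ndarray:
        return np.array([STATES.index(lab) for lab in self.labels], dtype=int)

    def subset(self, idx: Sequence[int]) -> "EpochFeatureTable":
        idx = np.asarray(idx, dtype=int)
        starts = tuple(self.start_times_s[i] for i in idx) if self.start_times_s else ()
        return EpochFeatureTable(
            features=self.features[idx],
            labels=tuple(self.labels[i] for i in idx),
            scale_values=self.scale_values,
            start_times_s=starts,
        )

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            self.features, columns=[f"scale_{s}" for s in self.scale_values]
        )
        df["label"] = list(self.labels)
        if self.start_times_s:
            df["start_s"] = list(self.start_times_s)
        return df

    @classmethod
    def from_frame(cls, df) -> "EpochFeatureTable":
        scale_cols = [c for c in df.columns if c.startswith("scale_")]
        scales = tuple(int(c.split("_", 1)[1]) for c in scale_cols)
        starts = tuple(float(v) for v in df["start_s"]) if "start_s" in df.columns else ()
        return cls(
            features=df[scale_cols].to_numpy(dtype=float),
            labels=tuple(df["label"]),
            scale_values=scales,
            start_times_s=starts,
        )


def extract_features(es: EpochSet, params: EntropyParams) -> EpochFeatureTable:
    """One entropy curve per epoch, channels pooled into a single
    multivariate computation.

    Epochs too short for the largest requested scale are dropped and counted
    in ``n_dropped`` rather than aborting the extraction.
    """
    rows, labels, starts = [], [], []
    dropped = 0
    for ep, lab, t0 in zip(es.epochs, es.labels, es.start_times_s):
        try:
            curve = mm_mdisten_curve(ep, params)
        except (EmbeddingError, InvalidScaleError):
            dropped += 1
            continue
        rows.append(curve.entropy_values)
        labels.append(lab)
        starts.append(t0)
    feats = np.vstack(rows) if rows else np.empty((0, len(params.scales)))
    return EpochFeatureTable(
        features=feats,
        labels=tuple(labels),
        scale_values=params.scales,
        start_times_s=tuple(starts),
        n_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierConfig:
    """Feed-forward network and RMSprop training hyperparameters."""

    hidden_units: tuple[int, ...] = (12, 12)
    learning_rate: float = 1e-3
    rho: float = 0.9  # RMSprop moving-average decay
    epsilon: float = 1e-8
    epochs: int = 1000
    batch_size: int = 32
    seed: int = 0


@dataclass
class MLPModel:
    """Weights of the trained network plus its training configuration."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: ClassifierConfig
    n_features: int
    final_loss: float = float("nan")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.size == 0:
            return np.empty((0, 3))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature width {X.shape[1]} does not match training width {self.n_features}"
            )
        a = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        logits = a @ self.weights[-1] + self.biases[-1]
        return _softmax(logits)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(X, Ws, bs):
    acts = [X]
    a = X
    for W, b in zip(Ws[:-1], bs[:-1]):
        a = np.maximum(a @ W + b, 0.0)
        acts.append(a)
    probs = _softmax(a @ Ws[-1] + bs[-1])
    return acts, probs


def train_classifier(ft: EpochFeatureTable, cfg: ClassifierConfig | None = None) -> MLPModel:
    """Train the softmax MLP on entropy features by backpropagation.

    Minimises the categorical cross-entropy with mini-batch RMSprop; a fixed
    seed fixes the weight initialisation and the shuffling order, so two
    runs on the same data give bit-identical models on one platform.
    """
    cfg = cfg or ClassifierConfig()
    if len(ft) == 0:
        raise ValueError("cannot train on an empty feature table")
    y = ft.label_indices
    if np.unique(y).size < 2:
        raise ValueError(
            f"training requires >= 2 classes; got only {STATES[y[0]]!r} epochs"
        )
    X = ft.features
    n, f = X.shape
    rng = np.random.default_rng(cfg.seed)

    sizes = [f, *cfg.hidden_units, len(STATES)]
    Ws = [
        rng.standard_normal((a, b)) * np.sqrt(2.0 / a)
        for a, b in zip(sizes[:-1], sizes[1:])
    ]
    bs = [np.zeros(b) for b in sizes[1:]]
    cache_W = [np.zeros_like(W) for W in Ws]
    cache_b = [np.zeros_like(b) for b in bs]

    onehot = np.eye(len(STATES))[y]
    loss = float("nan")
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            Xb, Yb = X[idx], onehot[idx]
            acts, probs = _forward(Xb, Ws, bs)
            delta = (probs - Yb) / len(idx)
            grads_W, grads_b = [], []
            for layer in range(len(Ws) - 1, -1, -1):
                grads_W.append(acts[layer].T @ delta)
                grads_b.append(delta.sum(axis=0))
                if layer > 0:
                    delta = (delta @ Ws[layer].T) * (acts[layer] > 0)
            grads_W.reverse()
            grads_b.reverse()
            for i in range(len(Ws)):
                cache_W[i] = cfg.rho * cache_W[i] + (1 - cfg.rho) * grads_W[i] ** 2
                cache_b[i] = cfg.rho * cache_b[i] + (1 - cfg.rho) * grads_b[i] ** 2
                Ws[i] -= cfg.learning_rate * grads_W[i] / (np.sqrt(cache_W[i]) + cfg.epsilon)
                bs[i] -= cfg.learning_rate * grads_b[i] / (np.sqrt(cache_b[i]) + cfg.epsilon)
        _, probs = _forward(X, Ws, bs)
        loss = float(-np.mean(np.log(np.clip(probs[np.arange(n), y], 1e-300, None))))
    return MLPModel(weights=Ws, biases=bs, config=cfg, n_features=f, final_loss=loss)


def predict_states(model: MLPModel, ft: EpochFeatureTable) -> tuple[np.ndarray, tuple[str, ...]]:
    """Class probabilities and argmax state labels for each epoch.

    Ties in the probability triple resolve to the lower class index
    (interictal < preictal < ictal).
    """
    probs = model.predict_proba(ft.features)
    labels = tuple(STATES[i] for i in probs.argmax(axis=1)) if len(probs) else ()
    return probs, labels


def split_epochs(
    ft: EpochFeatureTable,
    mode: str = "stratified",
    test_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[EpochFeatureTable, EpochFeatureTable]:
    """Split a feature table for training and evaluation.

    ``"stratified"`` (default) draws a per-state stratified test fraction.
    ``"paper-literal"`` trains on interictal epochs and tests on preictal
    epochs only — reproduced for completeness even though a 3-class model
    cannot be fit from a single training class (training will refuse it).
    """
    idx = np.arange(len(ft))
    if mode == "stratified":
        train_idx, test_idx = train_test_split(
            idx,
            test_size=test_fraction,
            random_state=seed,
            stratify=ft.label_indices,
        )
    elif mode == "paper-literal":
        labs = np.asarray(ft.labels)
        train_idx = idx[labs == "interictal"]
        test_idx = idx[labs == "preictal"]
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    return ft.subset(np.sort(train_idx)), ft.subset(np.sort(test_idx))


def save_model(model: MLPModel, path: str | Path) -> None:
    """Persist a trained model to one ``.npz`` file."""
    arrays = {f"W{i}": W for i, W in enumerate(model.weights)}
    arrays.update({f"b{i}": b for i, b in enumerate(model.biases)})
    meta = {
        "config": model.config.__dict__ | {"hidden_units": list(model.config.hidden_units)},
        "n_features": model.n_features,
        "final_loss": model.final_loss,
        "n_layers": len(model.weights),
    }
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> MLPModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        n_layers = meta["n_layers"]
        Ws = [data[f"W{i}"] for i in range(n_layers)]
        bs = [data[f"b{i}"] for i in range(n_layers)]
    cfg_dict = meta["config"]
    cfg_dict["hidden_units"] = tuple(cfg_dict["hidden_units"])
    return MLPModel(
        weights=Ws,
        biases=bs,
        config=ClassifierConfig(**cfg_dict),
        n_features=meta["n_features"],
        final_loss=meta["final_loss"],
    )
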