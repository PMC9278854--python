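"""Desk-scale VGG-style convolutional classifier with injectable layers.

The network computes class probabilities P = f(X) for image stacks X.  For
any named layer q the forward pass decomposes as f = g'_q ∘ g_q:``activations_at``
returns g_q(X) and ``forward_from`` resumes the pass from injected
activations, which is the substitution primitive the brain-interfacing
analysis is built on.  Injection points sit at the output of a full block
(convolution → batch-norm → ReLU), i.e. post-nonlinearity, so the
decomposition identity f(X) = g'_q(g_q(X)) is exact in evaluation mode.

Flattened activations are row-major over (h, w, c); translation maps use the
same order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import _nn
from ._nn import F32
from ._rng import substream
from .datasets import ImageSet


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite; carries the log."""

    def __init__(self, message: str, log: list[dict]):
        super().__init__(message)
        self.log = log


@dataclass
class NetSpec:
    """Architecture settings for the miniature VGG-style classifier.

    The default is a 4-block miniature (widths 16-32-64-64, one 3x3
    convolution per block, 2x2 pooling) with batch normalization between
    convolution and nonlinearity, one hidden dense layer and a softmax
    output — small enough to train on one CPU in minutes while preserving
    the early/late layer contrast of the full-size architecture.
    """

    blocks: tuple[tuple[int, ...], ...] = ((16,), (32,), (64,), (64,))
    use_batch_norm: bool = True
    dense: tuple[int, ...] = (64,)
    n_classes: int = 10
    input_size: tuple[int, int, int] = (32, 32, 3)
    dropout: float = 0.4
    weight_decay: float = 5e-4

    def __post_init__(self) -> None:
        if len(self.blocks) < 2 or len(self.dense) < 1:
            raise ValueError("need >= 2 conv blocks and >= 1 dense layer")
        if self.n_classes < 2:
            raise ValueError("need >= 2 classes")
        h, w, _ = self.input_size
        if h % (2 ** len(self.blocks)) or w % (2 ** len(self.blocks)):
            raise ValueError("input size must be divisible by 2**n_blocks")

    @classmethod
    def vgg_miniature(cls, n_classes: int = 10, **kwargs) -> "NetSpec":
        """A closer miniature of the full-size architecture.

        Five blocks with wide (64-channel) early layers and a multi-conv
        final block, preserving two structural features of the full-size
        architecture that the noise-perturbation analysis is sensitive to: channel redundancy
        in the early layers and a final pair of convolutions with no pooling
        in between.
        """
        return cls(blocks=((64,), (64,), (64,), (64, 64), (64, 64)),
                   n_classes=n_classes, **kwargs)


@dataclass
class Hyper:
    """Training settings (mini-batch SGD with Nesterov momentum)."""

    batch_size: int = 64
    learning_rate: float = 1e-3
    momentum: float = 0.90561
    max_epochs: int = 60
    lr_patience: int = 4
    lr_factor: float = 0.5
    stop_patience: int = 10
    val_fraction: float = 0.1
    augment: bool = True
    augment_ops: tuple[str, ...] = ("flip", "translate")
    max_translate: int = 2


@dataclass
class LayerActivation:
    """Activations g_q(X): (n, u) flattened values plus the spatial shape."""

    layer: str
    values: np.ndarray
    spatial_shape: tuple[int, ...]
    flatten_order: str = "row-major (h, w, c)"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        u = int(np.prod(self.spatial_shape))
        if self.values.ndim != 2 or self.values.shape[1] != u:
            raise ValueError(
                f"values must be (n, {u}) for spatial shape {self.spatial_shape}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class PredictionMatrix:
    """(n, m) class-probability rows."""

    probs: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(self.class_names):
            raise ValueError("probs must be (n, m) matching class_names")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be nonnegative")
        if np.max(np.abs(self.probs.sum(axis=1) - 1.0)) > 1e-6:
            raise ValueError("every row must sum to 1 (within 1e-6)")

    @property
    def n(self) -> int:
        return self.probs.shape[0]


class TrainedNet:
    """An assembled (possibly trained) network.

    ``layer_names`` enumerates the injectable points from input-adjacent to
    output-adjacent.  Evaluation-mode forward passes are deterministic:
    dropout is off and batch-norm uses frozen running statistics.
    """

    def __init__(self, spec: NetSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = substream(seed, "init")
        stages: list[_nn.Layer] = []
        checkpoints: dict[str, int] = {}
        shapes: dict[str, tuple[int, ...]] = {}
        h, w, c = spec.input_size
        for b, widths in enumerate(spec.blocks):
            for j, width in enumerate(widths):
                stages.append(_nn.Conv3x3(c, width, rng))
                if spec.use_batch_norm:
                    stages.append(_nn.BatchNorm(width))
                stages.append(_nn.ReLU())
                c = width
                name = f"conv{b + 1}" + (chr(ord("a") + j) if len(widths) > 1 else "")
                checkpoints[name] = len(stages) - 1
                shapes[name] = (h, w, c)
            stages.append(_nn.MaxPool2())
            h, w = h // 2, w // 2
        stages.append(_nn.Flatten())
        width = h * w * c
        for i, dw in enumerate(spec.dense):
            stages.append(_nn.Dense(width, dw, rng))
            stages.append(_nn.ReLU())
            checkpoints[f"fc{i + 1}"] = len(stages) - 1
            shapes[f"fc{i + 1}"] = (dw,)
            stages.append(_nn.Dropout(spec.dropout))
            width = dw
        stages.append(_nn.Dense(width, spec.n_classes, rng))
        self.stages = stages
        self.checkpoints = checkpoints
        self.shapes = shapes
        self.layer_names: list[str] = sorted(checkpoints, key=checkpoints.get)
        self.history: list[dict] = []
        self.final_val_accuracy: float | None = None

    # -- raw stage execution -------------------------------------------------
    def _run(self, x: np.ndarray, start: int = 0, stop: int | None = None,
             training: bool = False, capture: dict[str, int] | None = None):
        captured: dict[str, np.ndarray] = {}
        stop = len(self.stages) if stop is None else stop
        inv = {v: k for k, v in (capture or {}).items()}
        for i in range(start, stop):
            x = self.stages[i].forward(x, training)
            if i in inv:
                captured[inv[i]] = x
        return (x, captured) if capture is not None else x

    def layer_width(self, name: str) -> int:
        return int(np.prod(self.shapes[name]))

    def _check_layer(self, name: str) -> None:
        if name not in self.checkpoints:
            raise KeyError(
                f"unknown layer {name!r}; injectable layers are {self.layer_names}"
            )

    def parameter_arrays(self) -> list[np.ndarray]:
        out = []
        for lyr in self.stages:
            out.extend(lyr.params.values())
            if isinstance(lyr, _nn.BatchNorm):
                out.extend([lyr.running_mean, lyr.running_var])
        return out

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["spec"] = json.dumps(
                {
                    "blocks": [list(b) for b in self.spec.blocks],
                    "use_batch_norm": self.spec.use_batch_norm,
                    "dense": list(self.spec.dense),
                    "n_classes": self.spec.n_classes,
                    "input_size": list(self.spec.input_size),
                    "dropout": self.spec.dropout,
                    "weight_decay": self.spec.weight_decay,
                }
            )
            f.attrs["seed"] = self.seed
            f.attrs["history"] = json.dumps(self.history)
            for i, lyr in enumerate(self.stages):
                grp = f.create_group(f"stage_{i:03d}")
                for k, v in lyr.params.items():
                    grp.create_dataset(k, data=v)
                if isinstance(lyr, _nn.BatchNorm):
                    grp.create_dataset("running_mean", data=lyr.running_mean)
                    grp.create_dataset("running_var", data=lyr.running_var)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedNet":
        with h5py.File(path, "r") as f:
            raw = json.loads(f.attrs["spec"])
            spec = NetSpec(
                blocks=tuple(tuple(b) for b in raw["blocks"]),
                use_batch_norm=raw["use_batch_norm"],
                dense=tuple(raw["dense"]),
                n_classes=raw["n_classes"],
                input_size=tuple(raw["input_size"]),
                dropout=raw["dropout"],
                weight_decay=raw["weight_decay"],
            )
            net = cls(spec, seed=int(f.attrs["seed"]))
            net.history = json.loads(f.attrs["history"])
            for i, lyr in enumerate(net.stages):
                grp = f[f"stage_{i:03d}"]
                for k in lyr.params:
                    lyr.params[k] = grp[k][()]
                if isinstance(lyr, _nn.BatchNorm):
                    lyr.running_mean = grp["running_mean"][()]
                    lyr.running_var = grp["running_var"][()]
        return net


# ---------------------------------------------------------------------------
# forward passes


def forward_full(net: TrainedNet, images: ImageSet | np.ndarray,
                 batch_size: int = 256) -> PredictionMatrix:
    """Full evaluation-mode pass: images → softmax class probabilities."""
    x = images.images if isinstance(images, ImageSet) else np.asarray(images, F32)
    if x.shape[1:] != tuple(net.spec.input_size):
        raise ValueError(
            f"image shape {x.shape[1:]} does not match spec {net.spec.input_size}"
        )
    probs = []
    for i in range(0, x.shape[0], batch_size):
        logits = net._run(x[i : i + batch_size].astype(F32))
        probs.append(_nn.softmax(logits))
    names = (
        images.class_names
        if isinstance(images, ImageSet) and len(images.class_names) == net.spec.n_classes
        else [str(i) for i in range(net.spec.n_classes)]
    )
    return PredictionMatrix(np.vstack(probs), names)


def activations_at(net: TrainedNet, images: ImageSet | np.ndarray, q: str,
                   batch_size: int = 256) -> LayerActivation:
    """Evaluation-mode activations g_q(X), flattened row-major over (h, w, c)."""
    return activations_many(net, images, [q], batch_size)[q]


def activations_many(net: TrainedNet, images: ImageSet | np.ndarray,
                     layers: list[str], batch_size: int = 256) -> dict[str, LayerActivation]:
    """Capture several layers in one pass (cheaper than repeated passes)."""
    for q in layers:
        net._check_layer(q)
    x = images.images if isinstance(images, ImageSet) else np.asarray(images, F32)
    capture = {q: net.checkpoints[q] for q in layers}
    last = max(capture.values())
    parts: dict[str, list[np.ndarray]] = {q: [] for q in layers}
    for i in range(0, x.shape[0], batch_size):
        _, got = net._run(x[i : i + batch_size].astype(F32), stop=last + 1,
                          capture=capture)
        for q in layers:
            parts[q].append(got[q].reshape(got[q].shape[0], -1))
    return {
        q: LayerActivation(q, np.vstack(parts[q]), net.shapes[q]) for q in layers
    }


def forward_from(net: TrainedNet, q: str, acts: LayerActivation,
                 batch_size: int = 256) -> PredictionMatrix:
    """Resume the forward pass strictly after injection point q.

    The injected values replace g_q(X) as-is: q's own nonlinearity and
    normalization are not re-applied.
    """
    net._check_layer(q)
    if acts.layer != q:
        raise ValueError(f"activation is tagged {acts.layer!r}, expected {q!r}")
    u = net.layer_width(q)
    if acts.width != u:
        raise ValueError(f"layer {q} has width {u}, got {acts.width}")
    start = net.checkpoints[q] + 1
    vals = acts.values.astype(F32)
    probs = []
    for i in range(0, vals.shape[0], batch_size):
        chunk = vals[i : i + batch_size].reshape(-1, *net.shapes[q])
        logits = net._run(chunk, start=start)
        probs.append(_nn.softmax(logits))
    return PredictionMatrix(np.vstack(probs), [str(i) for i in range(net.spec.n_classes)])


def forward_between(net: TrainedNet, q: str, acts: LayerActivation, ref: str,
                    batch_size: int = 256) -> LayerActivation:
    """Propagate injected activations from q up to (and including) layer ref."""
    net._check_layer(q)
    net._check_layer(ref)
    if net.checkpoints[ref] <= net.checkpoints[q]:
        raise ValueError(f"reference layer {ref!r} must come after {q!r}")
    start, stop = net.checkpoints[q] + 1, net.checkpoints[ref] + 1
    vals = acts.values.astype(F32)
    out = []
    for i in range(0, vals.shape[0], batch_size):
        chunk = vals[i : i + batch_size].reshape(-1, *net.shapes[q])
        y = net._run(chunk, start=start, stop=stop)
        out.append(y.reshape(y.shape[0], -1))
    return LayerActivation(ref, np.vstack(out), net.shapes[ref])


# ---------------------------------------------------------------------------
# training


def _augment_batch(x: np.ndarray, rng: np.random.Generator, hyper: Hyper) -> np.ndarray:
    x = x.copy()
    n, h, w, _ = x.shape
    if "flip" in hyper.augment_ops:
        flips = rng.random(n) < 0.5
        x[flips] = x[flips, :, ::-1, :]
    if "translate" in hyper.augment_ops and hyper.max_translate > 0:
        t = hyper.max_translate
        shifts = rng.integers(-t, t + 1, size=(n, 2))
        for i in range(n):
            x[i] = np.roll(x[i], tuple(shifts[i]), axis=(0, 1))
    if "rescale" in hyper.augment_ops:
        scales = rng.choice([0.9, 1.0, 1.1], size=n)
        base = np.arange(h)
        for i in range(n):
            if scales[i] == 1.0:
                continue
            idx = np.clip(((base - h / 2) / scales[i] + h / 2).astype(int), 0, h - 1)
            x[i] = x[i][np.ix_(idx, idx)]
    return x


def train_net(spec: NetSpec, images: ImageSet, hyper: Hyper | None = None,
              seed: int = 0) -> TrainedNet:
    """Train the classifier with mini-batch SGD and Nesterov momentum.

    The learning rate halves when validation loss fails to improve for
    ``lr_patience`` epochs; training stops after ``stop_patience`` epochs
    without improvement or at ``max_epochs``.  A stratified ``val_fraction``
    of the data is held out internally for the schedule.
    """
    hyper = hyper or Hyper()
    net = TrainedNet(spec, seed=seed)
    rng = substream(seed, "train")
    split_rng = substream(seed, "valsplit")

    # stratified internal validation split
    labels = images.labels
    val_idx: list[int] = []
    for cls in np.unique(labels):
        rows = np.flatnonzero(labels == cls)
        split_rng.shuffle(rows)
        k = max(1, int(round(hyper.val_fraction * len(rows))))
        val_idx.extend(rows[:k])
    val_mask = np.zeros(images.n, dtype=bool)
    val_mask[val_idx] = True
    tr_idx = np.flatnonzero(~val_mask)
    va_idx = np.flatnonzero(val_mask)
    x_tr, y_tr = images.images[tr_idx], labels[tr_idx]
    x_va, y_va = images.images[va_idx], labels[va_idx]

    for st in net.stages:
        if isinstance(st, _nn.Dropout):
            st.rng = substream(seed, "dropout")

    opt = _nn.NesterovSGD(net.stages, hyper.learning_rate, hyper.momentum,
                          spec.weight_decay)
    best_val = np.inf
    wait = 0
    for epoch in range(hyper.max_epochs):
        order = rng.permutation(len(tr_idx))
        ep_loss = 0.0
        nb = 0
        for i in range(0, len(order), hyper.batch_size):
            idx = order[i : i + hyper.batch_size]
            xb = x_tr[idx]
            if hyper.augment:
                xb = _augment_batch(xb, rng, hyper)
            logits = net._run(xb.astype(F32), training=True)
            loss, g = _nn.softmax_xent(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}", net.history
                )
            ep_loss += loss
            nb += 1
            for stage in reversed(net.stages):
                g = stage.backward(g)
            opt.step()
        val_pred = forward_full(net, x_va)
        val_loss = -np.log(
            np.clip(val_pred.probs[np.arange(len(y_va)), y_va], 1e-12, None)
        ).mean()
        val_acc = float((val_pred.probs.argmax(axis=1) == y_va).mean())
        improved = val_loss < best_val - 1e-6
        if improved:
            best_val = val_loss
            wait = 0
        else:
            wait += 1
            if wait % hyper.lr_patience == 0:
                opt.lr *= hyper.lr_factor
        net.history.append(
            {
                "epoch": epoch,
                "train_loss": ep_loss / max(nb, 1),
                "val_loss": float(val_loss),
                "val_accuracy": val_acc,
                "learning_rate": opt.lr,
            }
        )
        if wait >= hyper.stop_patience:
            break
    net.final_val_accuracy = net.history[-1]["val_accuracy"] if net.history else None
    return net
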