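"""The linear brain-to-layer translation W.

Neural feature rows are centered and column-normalized with statistics from
the training partition only, then mapped by a bias-free linear transform W
into the activation space of a chosen network layer: acts ≈ W'(x - mu)/s.
Three training modes are provided:

* ``mse`` — minimize mean squared error to the layer activations.  The
  reference optimizer is mini-batch SGD with momentum, an l2 penalty and a
  plateau-halving schedule; a closed-form ridge solver is offered as a fast
  path and converges to the same solution (tested).  An Adadelta variant is
  the trial-level option.
* ``end_to_end`` — W is the only free parameter of the composed network
  g'_q(W x) and is trained by backpropagating categorical cross-entropy
  from the softmax output; all downstream weights stay frozen.
* ``pca_target`` — targets are first reduced to the leading r principal
  components of layer activations (axes fitted on an independent activation
  sample); W maps into the latent space and application reconstructs
  full-width activations through the stored axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.decomposition import PCA

from . import _nn
from ._rng import substream
from .datasets import RecordingSet
from .dcnn import LayerActivation, TrainedNet
from ._nn import softmax_xent

F64 = np.float64


@dataclass
class PreprocessParams:
    """Per-column centering and scaling statistics of the training rows."""

    mean: np.ndarray
    scale: np.ndarray
    convention: str = "zscore"  # or "unitnorm"

    def apply(self, rows: np.ndarray) -> np.ndarray:
        return (np.asarray(rows, F64) - self.mean) / self.scale


def preprocess_neural(train_rows: np.ndarray | RecordingSet,
                      convention: str = "zscore") -> tuple[PreprocessParams, np.ndarray]:
    """Fit centering/normalization on training rows and return both.

    ``zscore`` scales columns to unit SD; ``unitnorm`` scales centered
    columns to unit Euclidean norm.  Zero-variance columns get scale 1 and
    are thereby mapped to all-zeros after centering (dead channels are data,
    not errors).
    """
    x = train_rows.data if isinstance(train_rows, RecordingSet) else train_rows
    x = np.asarray(x, F64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D slice with at least 2 training rows")
    mean = x.mean(axis=0)
    centered = x - mean
    if convention == "zscore":
        scale = centered.std(axis=0)
    elif convention == "unitnorm":
        scale = np.linalg.norm(centered, axis=0)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    scale = np.where(scale < 1e-12, 1.0, scale)
    params = PreprocessParams(mean, scale, convention)
    return params, centered / scale


@dataclass
class TransHyper:
    """Optimizer settings for translation fitting."""

    solver: str = "ridge"          # "ridge" | "sgd" | "adadelta"
    batch_size: int = 64
    learning_rate: float = 0.1
    momentum: float = 0.9
    l2: float = 3e-4
    lr_patience: int = 4
    lr_factor: float = 0.5
    max_epochs: int = 400
    stop_patience: int = 20
    val_fraction: float = 0.1
    adadelta_lr: float = 0.04
    adadelta_batch: int = 128
    convention: str = "zscore"


@dataclass
class TranslationMap:
    """A fitted brain-to-layer transform.

    ``W`` is (d, u) — or (d, r) in latent mode, with the stored principal
    axes reconstructing the full u-wide activation vector.  W itself has no
    bias term and no nonlinearity.
    """

    W: np.ndarray
    preprocess: PreprocessParams
    source_region: str
    target_layer: str
    mode: str
    spatial_shape: tuple[int, ...]
    residual_mse: float | None = None
    latent_components: np.ndarray | None = None  # (r, u)
    latent_mean: np.ndarray | None = None        # (u,)
    target_mean: np.ndarray | None = None        # (u,) or (r,)
    training_meta: dict = field(default_factory=dict)

    @property
    def rank(self) -> int | None:
        return None if self.latent_components is None else self.latent_components.shape[0]


def apply_translation(tmap: TranslationMap, rows: np.ndarray | RecordingSet) -> LayerActivation:
    """Preprocess rows with the stored training statistics and apply W."""
    x = rows.data if isinstance(rows, RecordingSet) else np.asarray(rows, F64)
    if x.ndim != 2 or x.shape[1] != tmap.W.shape[0]:
        raise ValueError(f"rows must be (n, {tmap.W.shape[0]})")
    z = tmap.preprocess.apply(x) @ tmap.W
    if tmap.target_mean is not None:
        z = z + tmap.target_mean
    if tmap.latent_components is not None:
        z = z @ tmap.latent_components + tmap.latent_mean
    return LayerActivation(tmap.target_layer, z, tmap.spatial_shape)


# ---------------------------------------------------------------------------
# solvers


def _ridge_solve(x: np.ndarray, y: np.ndarray, l2: float) -> np.ndarray:
    """Minimizer of (1/(n*u))||XW - Y||^2 + (l2/u)||W||^2 in closed form."""
    n, d = x.shape
    gram = x.T @ x / n + l2 * np.eye(d)
    return np.linalg.solve(gram, x.T @ y / n)


def _sgd_linear(x: np.ndarray, y: np.ndarray, hyper: TransHyper, seed: int,
                adadelta: bool = False) -> tuple[np.ndarray, dict]:
    """Mini-batch fit of the bias-free linear map; plateau-halving schedule."""
    rng = substream(seed, "translation-sgd")
    n, d = x.shape
    u = y.shape[1]
    layer = _nn.Dense(d, u, rng)
    layer.params["W"] = (rng.standard_normal((d, u)) * 0.01).astype(np.float64)
    layer.params["b"] = np.zeros(u)  # frozen at zero: W has no bias term
    n_val = max(1, int(round(hyper.val_fraction * n)))
    perm = rng.permutation(n)
    va, tr = perm[:n_val], perm[n_val:]
    xtr, ytr, xva, yva = x[tr], y[tr], x[va], y[va]
    if adadelta:
        opt = _nn.Adadelta([layer], lr=hyper.adadelta_lr, weight_decay=2 * hyper.l2 / u)
        batch = hyper.adadelta_batch
    else:
        opt = _nn.NesterovSGD([layer], hyper.learning_rate, hyper.momentum,
                              weight_decay=2 * hyper.l2 / u)
        batch = hyper.batch_size
    best = np.inf
    wait = 0
    log = []
    for epoch in range(hyper.max_epochs):
        order = rng.permutation(len(tr))
        for i in range(0, len(order), batch):
            idx = order[i : i + batch]
            xb, yb = xtr[idx], ytr[idx]
            pred = layer.forward(xb, training=True)
            resid = pred - yb
            if not np.isfinite(resid).all():
                raise FloatingPointError("non-finite translation loss")
            # d/dpred of (1/(b*u))||resid||^2
            layer.backward(2.0 * resid / (resid.shape[0] * u))
            layer.grads["b"][:] = 0.0
            opt.step()
        val = float(np.mean((layer.forward(xva, training=False) - yva) ** 2))
        improved = val < best - 1e-9
        if improved:
            best = val
            wait = 0
        else:
            wait += 1
            if not adadelta and wait % hyper.lr_patience == 0:
                opt.lr *= hyper.lr_factor
        log.append({"epoch": epoch, "val_mse": val})
        if wait >= hyper.stop_patience:
            break
    return layer.params["W"], {"epochs": len(log), "final_val_mse": best}


def fit_translation_mse(rows: np.ndarray | RecordingSet, targets: LayerActivation,
                        hyper: TransHyper | None = None, seed: int = 0) -> TranslationMap:
    """Learn W by minimizing MSE between W-mapped rows and layer activations."""
    hyper = hyper or TransHyper()
    x_raw = rows.data if isinstance(rows, RecordingSet) else np.asarray(rows, F64)
    region = rows.region_name if isinstance(rows, RecordingSet) else "rows"
    y = np.asarray(targets.values, F64)
    if x_raw.shape[0] != y.shape[0]:
        raise ValueError("row counts of recordings and targets must match")
    params, x = preprocess_neural(x_raw, hyper.convention)
    # W is bias-free, so it is fitted against mean-centered targets; the
    # training-target mean travels with the map and is restored on application
    y_mean = y.mean(axis=0)
    yc = y - y_mean
    if hyper.solver == "ridge":
        W = _ridge_solve(x, yc, hyper.l2)
        meta = {"solver": "ridge"}
    elif hyper.solver in ("sgd", "adadelta"):
        W, meta = _sgd_linear(x, yc, hyper, seed, adadelta=hyper.solver == "adadelta")
        meta["solver"] = hyper.solver
    else:
        raise ValueError(f"unknown solver {hyper.solver!r}")
    resid = float(np.mean((x @ W - yc) ** 2))
    return TranslationMap(W, params, region, targets.layer, "mse",
                          tuple(targets.spatial_shape), residual_mse=resid,
                          target_mean=y_mean, training_meta=meta)


def fit_translation_end_to_end(rows: np.ndarray | RecordingSet, labels: np.ndarray,
                               net: TrainedNet, q: str,
                               hyper: TransHyper | None = None,
                               seed: int = 0) -> TranslationMap:
    """Learn W by backpropagating cross-entropy through the frozen net tail.

    Only W's entries change; the network itself is run in evaluation mode
    (deterministic) and its parameters are never updated.
    """
    hyper = hyper or TransHyper(learning_rate=0.05)
    net._check_layer(q)
    x_raw = rows.data if isinstance(rows, RecordingSet) else np.asarray(rows, F64)
    region = rows.region_name if isinstance(rows, RecordingSet) else "rows"
    labels = np.asarray(labels)
    params, x = preprocess_neural(x_raw, hyper.convention)
    rng = substream(seed, "translation-e2e")
    d, u = x.shape[1], net.layer_width(q)
    W = rng.standard_normal((d, u)) * 0.01
    vel = np.zeros_like(W)
    start = net.checkpoints[q] + 1
    n_val = max(1, int(round(hyper.val_fraction * x.shape[0])))
    perm = rng.permutation(x.shape[0])
    va, tr = perm[:n_val], perm[n_val:]
    best = np.inf
    wait = 0
    lr = hyper.learning_rate
    epochs_run = 0
    for epoch in range(hyper.max_epochs):
        order = rng.permutation(len(tr))
        for i in range(0, len(order), hyper.batch_size):
            idx = tr[order[i : i + hyper.batch_size]]
            xb = x[idx]
            acts = (xb @ W).astype(_nn.F32).reshape(-1, *net.shapes[q])
            logits = net._run(acts, start=start)
            loss, g = softmax_xent(logits, labels[idx])
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite end-to-end loss")
            for stage in reversed(net.stages[start:]):
                g = stage.backward(g)
            gW = xb.T @ g.reshape(len(idx), u) + 2 * hyper.l2 / u * W
            vel = hyper.momentum * vel - lr * gW
            W += hyper.momentum * vel - lr * gW
        acts = (x[va] @ W).astype(_nn.F32).reshape(-1, *net.shapes[q])
        logits = net._run(acts, start=start)
        val_loss, _ = softmax_xent(logits, labels[va])
        epochs_run = epoch + 1
        if val_loss < best - 1e-9:
            best = val_loss
            wait = 0
        else:
            wait += 1
            if wait % hyper.lr_patience == 0:
                lr *= hyper.lr_factor
        if wait >= hyper.stop_patience:
            break
    return TranslationMap(W, params, region, q, "end_to_end", tuple(net.shapes[q]),
                          training_meta={"solver": "sgd-e2e", "epochs": epochs_run,
                                         "final_val_xent": float(best)})


def fit_translation_pca_target(rows: np.ndarray | RecordingSet,
                               targets: LayerActivation, r: int,
                               pca_fit_set: LayerActivation,
                               hyper: TransHyper | None = None,
                               seed: int = 0) -> TranslationMap:
    """Learn W into the leading-r principal subspace of layer activations.

    The principal axes are fitted on ``pca_fit_set`` (an activation sample
    independent of the rows being fitted); application reconstructs
    full-width activations through the stored axes.
    """
    hyper = hyper or TransHyper()
    if pca_fit_set.layer != targets.layer:
        raise ValueError("pca_fit_set must come from the target layer")
    r_max = min(pca_fit_set.n, pca_fit_set.width)
    if not 1 <= r <= r_max:
        raise ValueError(f"latent rank r={r} must be in [1, {r_max}]")
    pca = PCA(n_components=r, svd_solver="randomized" if r < r_max else "auto",
              random_state=seed % (2**31))
    pca.fit(np.asarray(pca_fit_set.values, F64))
    comps, mean = pca.components_, pca.mean_
    z = (np.asarray(targets.values, F64) - mean) @ comps.T
    latent_target = LayerActivation(targets.layer, z, (r,))
    base = fit_translation_mse(rows, latent_target, hyper, seed)
    return replace(base, mode="pca_target", spatial_shape=tuple(targets.spatial_shape),
                   latent_components=comps, latent_mean=mean)


# ---------------------------------------------------------------------------
# persistence

def save_translation(tmap: TranslationMap, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=tmap.W)
        f.create_dataset("pre_mean", data=tmap.preprocess.mean)
        f.create_dataset("pre_scale", data=tmap.preprocess.scale)
        f.attrs.update(
            convention=tmap.preprocess.convention, source_region=tmap.source_region,
            target_layer=tmap.target_layer, mode=tmap.mode,
            spatial_shape=list(tmap.spatial_shape),
            residual_mse=-1.0 if tmap.residual_mse is None else tmap.residual_mse,
        )
        if tmap.target_mean is not None:
            f.create_dataset("target_mean", data=tmap.target_mean)
        if tmap.latent_components is not None:
            f.create_dataset("latent_components", data=tmap.latent_components)
            f.create_dataset("latent_mean", data=tmap.latent_mean)


def load_translation(path) -> TranslationMap:
    import h5py

    with h5py.File(path, "r") as f:
        pre = PreprocessParams(f["pre_mean"][()], f["pre_scale"][()],
                               str(f.attrs["convention"]))
        resid = float(f.attrs["residual_mse"])
        return TranslationMap(
            f["W"][()], pre, str(f.attrs["source_region"]),
            str(f.attrs["target_layer"]), str(f.attrs["mode"]),
            tuple(int(v) for v in f.attrs["spatial_shape"]),
            residual_mse=None if resid < 0 else resid,
            latent_components=f["latent_components"][()] if "latent_components" in f else None,
            latent_mean=f["latent_mean"][()] if "latent_mean" in f else None,
            target_mean=f["target_mean"][()] if "target_mean" in f else None,
        )
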