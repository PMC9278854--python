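"""Comparison analyses: MVPA classifiers, shared-variance predictivity, and
pixel-level interfacing.

These are the conventional analyses the direct-interface method is
contrasted against: decoding class labels straight from the recordings
(multivariate pattern analysis), predicting neural responses from model
activations (PCA + partial-least-squares "neural predictivity"), and
running the interfacing pipeline on PCA-reduced pixel data instead of
neural data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC

from ._rng import child_seed
from .crossval import FoldPlan
from .datasets import ImageSet, RecordingSet, check_alignment
from .dcnn import TrainedNet, activations_many
from .interface import CorrespondenceResult, run_interface_grid
from .metrics import multiclass_auc
from .translation import TransHyper, preprocess_neural


@dataclass
class BaselineResult:
    method: str
    auc: float | None = None
    per_fold_auc: list[float] = field(default_factory=list)
    median_r: float | None = None
    per_feature_r: np.ndarray | None = None
    config: dict = field(default_factory=dict)


def _classifiers(seed: int) -> dict[str, object]:
    return {
        "logistic": LogisticRegression(solver="lbfgs", max_iter=1000,
                                       random_state=seed % (2**31)),
        "nearest_neighbor": KNeighborsClassifier(n_neighbors=1, metric="euclidean"),
        "linear_svm": LinearSVC(C=1e-3, max_iter=10_000, random_state=seed % (2**31)),
    }


def mvpa_suite(recordings: RecordingSet, labels: np.ndarray, fold_plan: FoldPlan,
               seed: int = 0) -> dict[str, BaselineResult]:
    """Decode class labels directly from the recordings, per classifier.

    Multinomial logistic regression, single nearest neighbor (Euclidean),
    and a one-vs-rest linear SVM (C = 1e-3; AUC from the uncalibrated
    decision function).  Scores are pooled over held-out folds and scored
    with the same Hand-Till multiclass AUC as the interfacing analysis.
    """
    if recordings.temporal:
        raise ValueError("MVPA baselines expect static recordings")
    labels = np.asarray(labels)
    m = int(labels.max()) + 1
    out: dict[str, BaselineResult] = {}
    for name in _classifiers(seed):
        pooled = np.full((recordings.n, m), np.nan)
        for f, held in enumerate(fold_plan.folds):
            train = fold_plan.train_rows(f)
            if np.unique(labels[train]).size < 2:
                raise ValueError(f"training fold {f} has fewer than 2 classes")
            params, x_tr = preprocess_neural(recordings.data[train])
            x_te = params.apply(recordings.data[held])
            clf = _classifiers(child_seed(seed, f"fold{f}"))[name]
            clf.fit(x_tr, labels[train])
            classes = np.asarray(clf.classes_, dtype=int)
            if hasattr(clf, "predict_proba"):
                scores = clf.predict_proba(x_te)
            else:
                scores = clf.decision_function(x_te)
                if scores.ndim == 1:  # binary decision function
                    scores = np.stack([-scores, scores], axis=1)
            full = np.full((len(held), m), -np.inf)
            full[:, classes] = scores
            pooled[held] = full
        per_fold = [
            multiclass_auc(pooled[h], labels[h])
            for h in fold_plan.folds
            if np.unique(labels[h]).size >= 2
        ]
        out[name] = BaselineResult(
            method=name, auc=multiclass_auc(pooled, labels), per_fold_auc=per_fold,
            config={"k": fold_plan.k, "seed": seed})
    return out


def neural_predictivity(net: TrainedNet, images: ImageSet, recordings: RecordingSet,
                        layer: str, fold_plan: FoldPlan, n_pcs: int = 200,
                        n_pls: int = 10, seed: int = 0) -> BaselineResult:
    """Shared-variance predictivity of a layer for the recorded features.

    Per fold: the leading principal components of the layer activations are
    fitted on the training images, a partial-least-squares regression maps
    the reduced activations to every recording feature, and held-out
    predictions are accumulated.  The summary is the Pearson correlation of
    the median feature (model → brain mapping direction, the reverse of
    interfacing).  Zero-variance features are excluded.
    """
    check_alignment(images, recordings)
    acts = activations_many(net, images, [layer])[layer].values.astype(np.float64)
    n, d = recordings.n, recordings.d
    pred = np.full((n, d), np.nan)
    for f, held in enumerate(fold_plan.folds):
        train = fold_plan.train_rows(f)
        r = min(n_pcs, len(train) - 1, acts.shape[1])
        pca = PCA(n_components=r, random_state=seed % (2**31))
        z_tr = pca.fit_transform(acts[train])
        z_te = pca.transform(acts[held])
        pls = PLSRegression(n_components=min(n_pls, r), scale=False)
        pls.fit(z_tr, recordings.data[train])
        pred[held] = pls.predict(z_te)
    rs = np.full(d, np.nan)
    for j in range(d):
        if recordings.data[:, j].std() > 1e-12 and pred[:, j].std() > 1e-12:
            rs[j] = pearsonr(pred[:, j], recordings.data[:, j]).statistic
    valid = rs[np.isfinite(rs)]
    return BaselineResult(
        method="neural_predictivity", median_r=float(np.median(valid)),
        per_feature_r=rs,
        config={"layer": layer, "n_pcs": n_pcs, "n_pls": n_pls, "k": fold_plan.k,
                "n_excluded": int(d - valid.size)})


def pixel_interface(images: ImageSet, n_components: int, net: TrainedNet,
                    layers: list[str] | None, fold_plan: FoldPlan,
                    pca_pool: ImageSet | None = None, seed: int = 0,
                    hyper: TransHyper | None = None) -> CorrespondenceResult:
    """Interface PCA-reduced pixel data in place of neural recordings.

    The principal axes are fitted on ``pca_pool`` (a held-aside image
    sample; the analyzed images themselves are used only if no pool is
    given) and the reduced codes substitute for recordings in the
    interfacing grid.
    """
    flat = images.images.reshape(images.n, -1).astype(np.float64)
    if n_components > flat.shape[1]:
        raise ValueError(f"n_components must be <= pixel count ({flat.shape[1]})")
    pool = (pca_pool.images.reshape(pca_pool.n, -1).astype(np.float64)
            if pca_pool is not None else flat)
    n_components = min(n_components, pool.shape[0])
    pca = PCA(n_components=n_components, random_state=seed % (2**31))
    pca.fit(pool)
    codes = pca.transform(flat)
    rec = RecordingSet(codes, region_name="pixels")
    return run_interface_grid(net, images, rec, layers, fold_plan, mode="mse",
                              hyper=hyper, seed=seed)
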