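"""Region-by-layer correspondence scoring under cross-validation.

For every (region, layer) cell: per fold, a translation map is fitted on
the training rows only, applied to the held-out rows, and the network's
forward pass is resumed from the injected activations.  Held-out
predictions are pooled over folds; the multiclass AUC is computed once over
the pooled predictions (per-fold values are retained for dispersion only)
and the per-row KL divergence is taken against the image-driven predictions
for the same held-out images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import child_seed
from .crossval import FoldPlan
from .datasets import ImageSet, RecordingSet, check_alignment
from .dcnn import (LayerActivation, PredictionMatrix, TrainedNet,
                   activations_many, forward_from, forward_full)
from .metrics import kl_rows, multiclass_auc
from .translation import (TransHyper, apply_translation, fit_translation_end_to_end,
                          fit_translation_mse, fit_translation_pca_target)


@dataclass
class CellResult:
    """Scores for one (region, layer) cell."""

    region: str
    layer: str
    auc: float
    mean_kl: float
    per_fold_auc: list[float]
    kl: np.ndarray
    predictions: PredictionMatrix | None = None


@dataclass
class CorrespondenceResult:
    """The full grid plus provenance."""

    grid: dict[tuple[str, str], CellResult]
    image_driven_auc: float
    layers: list[str]
    regions: list[str]
    provenance: dict = field(default_factory=dict)

    def auc_of(self, region: str, layer: str) -> float:
        return self.grid[(region, layer)].auc

    def best_layer(self, region: str, metric: str = "auc") -> str:
        cells = [self.grid[(region, q)] for q in self.layers]
        if metric == "auc":
            best = max(cells, key=lambda c: c.auc)
        elif metric == "kl":
            best = min(cells, key=lambda c: c.mean_kl)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        return best.layer

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: region, layer, fold, metric, value."""
        rows = []
        for (region, layer), cell in self.grid.items():
            rows.append((region, layer, "pooled", "auc", cell.auc))
            rows.append((region, layer, "pooled", "mean_kl", cell.mean_kl))
            for f, v in enumerate(cell.per_fold_auc):
                rows.append((region, layer, str(f), "auc", v))
        return pd.DataFrame(rows, columns=["region", "layer", "fold", "metric", "value"])

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "grid_long.csv", index=False)
        summary = {
            "image_driven_auc": self.image_driven_auc,
            "layers": self.layers,
            "regions": self.regions,
            "cells": {
                f"{r}|{q}": {"auc": c.auc, "mean_kl": c.mean_kl}
                for (r, q), c in self.grid.items()
            },
            "provenance": self.provenance,
        }
        (out / "grid_summary.json").write_text(json.dumps(summary, indent=2))


def _fit_cell(mode: str, train_rec: np.ndarray, region: str, acts_train: LayerActivation,
              labels_train: np.ndarray, net: TrainedNet, layer: str,
              hyper: TransHyper, seed: int, pca_rank: int | None,
              pca_fit: LayerActivation | None):
    rec = RecordingSet(train_rec, region_name=region)
    if mode == "mse":
        return fit_translation_mse(rec, acts_train, hyper, seed)
    if mode == "end_to_end":
        return fit_translation_end_to_end(rec, labels_train, net, layer, hyper, seed)
    if mode == "pca_target":
        fit_set = pca_fit if pca_fit is not None else acts_train
        r = pca_rank or min(fit_set.n, fit_set.width)
        return fit_translation_pca_target(rec, acts_train, r, fit_set, hyper, seed)
    raise ValueError(f"unknown translation mode {mode!r}")


def interfaced_predictions(net: TrainedNet, images: ImageSet, recordings: RecordingSet,
                           layer: str, fold_plan: FoldPlan, mode: str = "mse",
                           hyper: TransHyper | None = None, seed: int = 0,
                           pca_rank: int | None = None,
                           pca_fit: LayerActivation | None = None,
                           acts: LayerActivation | None = None,
                           ) -> tuple[PredictionMatrix, list[np.ndarray]]:
    """Pooled held-out brain-driven predictions for one (region, layer) cell.

    Returns the (n, m) pooled prediction matrix (every row predicted by the
    fold that held it out) and the list of held-out index arrays.
    """
    hyper = hyper or TransHyper()
    check_alignment(images, recordings)
    if acts is None:
        acts = activations_many(net, images, [layer])[layer]
    n, m = images.n, net.spec.n_classes
    pooled = np.full((n, m), np.nan)
    for f, held in enumerate(fold_plan.folds):
        train = fold_plan.train_rows(f)
        acts_train = LayerActivation(layer, acts.values[train], acts.spatial_shape)
        tmap = _fit_cell(mode, recordings.data[train], recordings.region_name,
                         acts_train, images.labels[train], net, layer, hyper,
                         child_seed(seed, f"fold{f}"), pca_rank, pca_fit)
        injected = apply_translation(tmap, recordings.data[held])
        pooled[held] = forward_from(net, layer, injected).probs
    return PredictionMatrix(pooled, [str(i) for i in range(m)]), list(fold_plan.folds)


def run_interface_grid(net: TrainedNet, images: ImageSet,
                       recordings: RecordingSet | list[RecordingSet],
                       layers: list[str] | None, fold_plan: FoldPlan,
                       mode: str = "mse", hyper: TransHyper | None = None,
                       seed: int = 0, pca_rank: int | None = None,
                       pca_fit: LayerActivation | None = None,
                       keep_predictions: bool = False) -> CorrespondenceResult:
    """Score every (region, layer) combination; see module docstring."""
    hyper = hyper or TransHyper()
    recs = [recordings] if isinstance(recordings, RecordingSet) else list(recordings)
    layers = layers or net.layer_names
    for rec in recs:
        check_alignment(images, rec)
        if rec.temporal:
            raise ValueError("interface grid expects static recordings; "
                             "use the temporal pipeline for binned data")
    p_img = forward_full(net, images)
    acts_all = activations_many(net, images, layers)
    labels = images.labels
    grid: dict[tuple[str, str], CellResult] = {}
    for rec in recs:
        for q in layers:
            pooled, folds = interfaced_predictions(
                net, images, rec, q, fold_plan, mode, hyper,
                child_seed(seed, f"{rec.region_name}|{q}"), pca_rank, pca_fit,
                acts=acts_all[q])
            per_fold = []
            for held in folds:
                if np.unique(labels[held]).size >= 2:
                    per_fold.append(multiclass_auc(pooled.probs[held], labels[held]))
            kl = kl_rows(pooled, p_img)
            grid[(rec.region_name, q)] = CellResult(
                rec.region_name, q, multiclass_auc(pooled, labels), float(kl.mean()),
                per_fold, kl, pooled if keep_predictions else None)
    return CorrespondenceResult(
        grid=grid,
        image_driven_auc=multiclass_auc(p_img, labels),
        layers=layers,
        regions=[r.region_name for r in recs],
        provenance={"seed": seed, "mode": mode, "k": fold_plan.k,
                    "scheme": fold_plan.scheme},
    )
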