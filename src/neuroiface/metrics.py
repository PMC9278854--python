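"""Evaluation metrics: Hand-Till multiclass AUC and row-wise KL divergence.

The AUC follows the Hand-Till construction: for every unordered pair of
classes, two directed two-class AUCs are computed via the Mann-Whitney U
statistic (ties scored 1/2) and averaged; the multiclass score is the mean
over all pairs.  Chance is 0.5 regardless of the number of classes.

KL divergence compares the brain-driven prediction rows P_r against the
image-driven rows P_i; the default direction is D(P_i || P_r) — the
divergence of the approximation from the reference — with probability
clipping so one-hot rows cannot produce infinities.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import rankdata

from .dcnn import PredictionMatrix

__all__ = ["pairwise_auc", "multiclass_auc", "kl_rows"]


def pairwise_auc(scores_x: np.ndarray, scores_y: np.ndarray) -> float:
    """Two-class AUC via the Mann-Whitney U statistic.

    The proportion of (x, y) pairs with x scored above y, counting ties as
    1/2.  Both groups must be nonempty.
    """
    sx = np.asarray(scores_x, dtype=np.float64)
    sy = np.asarray(scores_y, dtype=np.float64)
    if sx.size == 0 or sy.size == 0:
        raise ValueError("both score groups must be nonempty")
    ranks = rankdata(np.concatenate([sx, sy]))  # average ranks handle ties as 1/2
    u = ranks[: sx.size].sum() - sx.size * (sx.size + 1) / 2.0
    return float(u / (sx.size * sy.size))


def multiclass_auc(pred: PredictionMatrix | np.ndarray, labels: np.ndarray) -> float:
    """Hand-Till multiclass AUC of per-class scores against labels.

    For each unordered class pair (a, b) present in ``labels``, the directed
    AUC of a-rows vs b-rows under the class-a score and of b-rows vs a-rows
    under the class-b score are averaged; the result is the mean over pairs.
    Classes absent from ``labels`` are skipped.
    """
    scores = pred.probs if isinstance(pred, PredictionMatrix) else np.asarray(pred)
    labels = np.asarray(labels)
    present = np.unique(labels)
    if present.size < 2:
        raise ValueError("multiclass AUC needs at least two classes present")
    rows = {int(c): np.flatnonzero(labels == c) for c in present}
    total = 0.0
    npairs = 0
    for a, b in combinations(sorted(rows), 2):
        a_vs_b = pairwise_auc(scores[rows[a], a], scores[rows[b], a])
        b_vs_a = pairwise_auc(scores[rows[b], b], scores[rows[a], b])
        total += 0.5 * (a_vs_b + b_vs_a)
        npairs += 1
    return total / npairs


def kl_rows(p_r: PredictionMatrix | np.ndarray, p_i: PredictionMatrix | np.ndarray,
            reverse: bool = False, clip: float = 1e-9) -> np.ndarray:
    """Row-wise KL divergence of the approximation P_r from the reference P_i.

    Computes D(P_i || P_r) per row (in nats); ``reverse=True`` gives
    D(P_r || P_i).  Rows are clipped at ``clip`` and renormalized before
    taking logs.
    """
    a = p_r.probs if isinstance(p_r, PredictionMatrix) else np.asarray(p_r, float)
    b = p_i.probs if isinstance(p_i, PredictionMatrix) else np.asarray(p_i, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ref, approx = (a, b) if reverse else (b, a)
    ref = np.clip(ref, clip, None)
    ref = ref / ref.sum(axis=1, keepdims=True)
    approx = np.clip(approx, clip, None)
    approx = approx / approx.sum(axis=1, keepdims=True)
    return np.sum(ref * (np.log(ref) - np.log(approx)), axis=1)
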