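"""Temporal interfacing and directional Granger-causal analysis.

Bin-wise interfacing turns a temporal recording into a trials-by-bins KL
time series: for each time bin independently, a translation into the chosen
layer is fitted on the training trials, applied to held-out trials, and the
per-trial KL divergence against the image-driven predictions is recorded.
The same machinery applies to raw rate series (mean spike rate per bin).

Both kinds of series are stationarized (per-trial temporal standardization,
then per-bin standardization across trials) and compared directionally:
does the past of series X improve prediction of series Y beyond Y's own
past?  Each direction is an OLS lag regression pooled across trials without
crossing trial boundaries; the lag order is selected by an information
criterion and the decision is a likelihood-ratio test (chi-squared with p
degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import chi2

from ._rng import child_seed
from .crossval import FoldPlan
from .datasets import ImageSet, RecordingSet, check_alignment
from .dcnn import TrainedNet, activations_many, forward_full
from .interface import interfaced_predictions
from .metrics import kl_rows
from .translation import TransHyper


@dataclass
class KLSeries:
    """A trials-by-bins scalar series (per-trial KL divergence, or a rate).

    After :func:`stationarize`, every bin has mean 0 and SD 1 across trials
    (within 1e-6) and the ``stationarized`` flag is set.
    """

    values: np.ndarray
    bin_onsets: np.ndarray
    region: str
    layer: str
    stationarized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be (trials, bins)")
        self.bin_onsets = np.asarray(self.bin_onsets, dtype=np.float64)
        if self.bin_onsets.shape != (self.values.shape[1],):
            raise ValueError("bin_onsets must have one entry per bin")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        """Trials x bins table; columns named by bin onset."""
        import pandas as pd

        df = pd.DataFrame(self.values,
                          columns=[f"t{onset:+.0f}" for onset in self.bin_onsets])
        df.insert(0, "region", self.region)
        df.insert(1, "layer", self.layer)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "KLSeries":
        import pandas as pd

        df = pd.read_csv(path)
        region = str(df.pop("region").iloc[0])
        layer = str(df.pop("layer").iloc[0])
        onsets = np.array([float(c[1:]) for c in df.columns])
        return cls(df.to_numpy(float), onsets, region, layer)


@dataclass
class GrangerResult:
    """One direction of a pairwise Granger comparison."""

    direction: tuple[str, str]  # (source, target)
    p: int
    loglik_null: float
    loglik_causal: float
    lr_statistic: float
    p_value: float
    significant: bool
    criterion: str
    window: tuple[int, int] | None = None


@dataclass
class GrangerTimeline:
    """Per-window directional decisions for one series pair."""

    windows: list[tuple[int, int]]
    decisions: list[str]           # "none" | "x->y" | "y->x" | "both"
    results: list[tuple[GrangerResult, GrangerResult]]
    names: tuple[str, str]

    def onset(self, direction: str) -> int | None:
        """Index of the first window where ``direction`` is significant."""
        want = {"x->y": ("x->y", "both"), "y->x": ("y->x", "both")}[direction]
        for i, d in enumerate(self.decisions):
            if d in want:
                return i
        return None


# ---------------------------------------------------------------------------
# series construction


def rate_series(rec: RecordingSet) -> KLSeries:
    """Mean rate across features, per trial and bin."""
    if not rec.temporal:
        raise ValueError("rate series requires a temporal recording")
    return KLSeries(rec.data.mean(axis=2), rec.bin_onsets, rec.region_name, "rate")


def binwise_interface_kl(net: TrainedNet, layer: str, recordings: RecordingSet,
                         images: ImageSet, fold_plan: FoldPlan,
                         mode: str = "mse", hyper: TransHyper | None = None,
                         seed: int = 0,
                         shuffle_labels: bool = False) -> KLSeries:
    """Trial-level KL time series from bin-wise interfacing into ``layer``.

    Each 1-bin slice of the temporal recording is treated as an independent
    static decoding problem under the shared fold plan.  ``shuffle_labels``
    permutes the image rows the translation is trained against (per bin),
    giving the chance-level control series.
    """
    if not recordings.temporal:
        raise ValueError("binwise interfacing requires a temporal recording")
    check_alignment(images, recordings)
    hyper = hyper or TransHyper()
    p_img = forward_full(net, images)
    acts = activations_many(net, images, [layer])[layer]
    out = np.empty((recordings.n, recordings.n_bins))
    for t in range(recordings.n_bins):
        acts_t = acts
        if shuffle_labels:
            rng = np.random.default_rng(child_seed(seed, f"shuffle{t}"))
            perm = rng.permutation(recordings.n)
            acts_t = replace(acts, values=acts.values[perm])
        pooled, _ = interfaced_predictions(
            net, images, recordings.at_bin(t), layer, fold_plan, mode, hyper,
            child_seed(seed, f"bin{t}"), acts=acts_t)
        out[:, t] = kl_rows(pooled, p_img)
    return KLSeries(out, recordings.bin_onsets, recordings.region_name, layer)


# ---------------------------------------------------------------------------
# stationarization


def stationarize(series: KLSeries, per_trial: bool = True) -> KLSeries:
    """Two-step stationarization; re-application is the identity.

    Step 1 (``per_trial=True``): per-trial temporal standardization
    (subtract the trial's temporal mean, divide by its temporal SD).
    Step 2: per-bin standardization across trials, which leaves every bin
    with mean 0 and SD 1.  Zero-SD trials or bins fall back to scale 1 (a
    constant trial maps to zeros).

    The two-step form is used for KL series.  For raw rate series
    ``per_trial=False`` applies only the per-bin step: with short trials
    the subtracted trial mean couples late-bin activity into every bin,
    which can smear genuinely late cross-region dependence backward in
    time; rates have no trial-level gain drift in the simulator, so the
    per-bin step alone already delivers stationary series.
    """
    if series.stationarized:
        return series
    v = series.values
    if v.shape[1] < 2:
        raise ValueError("stationarization needs at least 2 bins")
    if per_trial:
        mu_t = v.mean(axis=1, keepdims=True)
        sd_t = v.std(axis=1, keepdims=True)
        sd_t = np.where(sd_t < 1e-12, 1.0, sd_t)
        v = (v - mu_t) / sd_t
    mu_b = v.mean(axis=0, keepdims=True)
    sd_b = v.std(axis=0, keepdims=True)
    sd_b = np.where(sd_b < 1e-12, 1.0, sd_b)
    v = (v - mu_b) / sd_b
    return replace(series, values=v, stationarized=True)


# ---------------------------------------------------------------------------
# Granger fits


def _lag_design(x: np.ndarray, y: np.ndarray, p: int, start: int):
    """Pooled lagged design; lags never cross trial boundaries.

    Target is y[:, t] for t in [start, T); own lags come from y, cross lags
    from x.  Returns (target vector, own-lag matrix, cross-lag matrix).
    """
    n, T = y.shape
    ts = np.arange(start, T)
    tgt = y[:, ts].ravel()
    own = np.stack([y[:, ts - j].ravel() for j in range(1, p + 1)], axis=1)
    cross = np.stack([x[:, ts - j].ravel() for j in range(1, p + 1)], axis=1)
    return tgt, own, cross


def _gauss_loglik(resid: np.ndarray) -> float:
    n = resid.size
    s2 = max(float(resid @ resid) / n, 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)


def _ols_loglik(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return _gauss_loglik(y - X @ beta)


def _fit_direction(x: np.ndarray, y: np.ndarray, names: tuple[str, str],
                   p_max: int, criterion: str, alpha: float) -> GrangerResult:
    """Granger test of direction x -> y on pooled trials-by-bins arrays."""
    T = y.shape[1]
    if T <= p_max + 1:
        raise ValueError(f"series too short ({T} bins) for p_max={p_max}")
    if criterion not in ("bic", "aic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    # Lag order: information criterion on the causal model over a common sample.
    # Selection uses every other trial so that the subsequent likelihood-ratio
    # test is not biased by picking the best-fitting order on the same data.
    sel = slice(None) if x.shape[0] < 2 else slice(0, None, 2)
    best_p, best_ic = 1, np.inf
    tgt0, own0, cross0 = _lag_design(x[sel], y[sel], p_max, p_max)
    nobs = tgt0.size
    log_n = np.log(nobs)
    for p in range(1, p_max + 1):
        X = np.hstack([own0[:, :p], cross0[:, :p]])
        beta, *_ = np.linalg.lstsq(X, tgt0, rcond=None)
        ll = _gauss_loglik(tgt0 - X @ beta)
        k = 2 * p
        ic = -2.0 * ll + (log_n if criterion == "bic" else 2.0) * k
        if ic < best_ic:
            best_ic, best_p = ic, p
    # final nested fit at the selected order, using all usable observations
    tgt, own, cross = _lag_design(x, y, best_p, best_p)
    ll_null = _ols_loglik(own, tgt)
    ll_causal = _ols_loglik(np.hstack([own, cross]), tgt)
    ll_causal = max(ll_causal, ll_null)  # guard against lstsq round-off
    lr = 2.0 * (ll_causal - ll_null)
    pval = float(chi2.sf(lr, df=best_p))
    return GrangerResult(names, best_p, ll_null, ll_causal, lr, pval,
                         pval < alpha, criterion)


def fit_granger_pair(series_x: KLSeries, series_y: KLSeries, p_max: int = 4,
                     criterion: str = "bic", alpha: float = 0.05,
                     per_trial: bool = False) -> tuple[GrangerResult, GrangerResult]:
    """Directional Granger comparison of two stationarized series.

    Returns (x→y result, y→x result).  Estimation pools observations across
    trials without letting lags cross trial boundaries; ``per_trial=True``
    instead fits each trial separately and sums the log-likelihoods.
    """
    for s in (series_x, series_y):
        if not s.stationarized:
            raise ValueError(f"series {s.region!r} must be stationarized first")
    if series_x.values.shape != series_y.values.shape:
        raise ValueError("series must share trials x bins shape")
    x, y = series_x.values, series_y.values
    names_xy = (series_x.region, series_y.region)
    names_yx = (series_y.region, series_x.region)
    if not per_trial:
        return (_fit_direction(x, y, names_xy, p_max, criterion, alpha),
                _fit_direction(y, x, names_yx, p_max, criterion, alpha))

    def per_trial_dir(a, b, names):
        results = [
            _fit_direction(a[i : i + 1], b[i : i + 1], names, p_max, criterion, alpha)
            for i in range(a.shape[0])
        ]
        p = int(np.median([r.p for r in results]))
        lln = sum(r.loglik_null for r in results)
        llc = sum(r.loglik_causal for r in results)
        lr = 2.0 * (llc - lln)
        df = p * len(results)
        pval = float(chi2.sf(lr, df=df))
        return GrangerResult(names, p, lln, llc, lr, pval, pval < alpha, criterion)

    return per_trial_dir(x, y, names_xy), per_trial_dir(y, x, names_yx)


def run_granger_timeline(series_x: KLSeries, series_y: KLSeries,
                         window_start: int = 0, min_window: int | None = None,
                         step: int = 1, p_max: int = 4, criterion: str = "bic",
                         alpha: float = 0.05) -> GrangerTimeline:
    """Expanding-window directional decisions for one series pair.

    Windows start at ``window_start`` (typically the stimulus-onset bin) and
    grow by ``step`` bins; each window yields one of {none, x->y, y->x,
    both}.  The onset of a direction is the first window where it tests
    significant.
    """
    T = series_x.n_bins
    lo = max(p_max + 2, min_window or 0)
    windows, decisions, results = [], [], []
    for end in range(window_start + lo, T + 1, step):
        sx = replace(series_x, values=series_x.values[:, window_start:end],
                     bin_onsets=series_x.bin_onsets[window_start:end])
        sy = replace(series_y, values=series_y.values[:, window_start:end],
                     bin_onsets=series_y.bin_onsets[window_start:end])
        rx, ry = fit_granger_pair(sx, sy, p_max, criterion, alpha)
        rx = replace(rx, window=(window_start, end))
        ry = replace(ry, window=(window_start, end))
        if rx.significant and ry.significant:
            dec = "both"
        elif rx.significant:
            dec = "x->y"
        elif ry.significant:
            dec = "y->x"
        else:
            dec = "none"
        windows.append((window_start, end))
        decisions.append(dec)
        results.append((rx, ry))
    return GrangerTimeline(windows, decisions, results,
                           (series_x.region, series_y.region))
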