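"""Stationarization and directional Granger machinery."""

import numpy as np
import pytest
from dataclasses import replace

from neuroiface.granger import (GrangerTimeline, KLSeries, fit_granger_pair,
                                rate_series, run_granger_timeline, stationarize)
from neuroiface.datasets import RecordingSet


def series(vals, name="x"):
    return KLSeries(np.asarray(vals, float), np.arange(np.shape(vals)[1]), name, "s")


def white(rng, trials=20, bins=30, name="x"):
    return stationarize(series(rng.standard_normal((trials, bins)), name))


class TestStationarize:
    def test_bin_means_zero_sds_one(self):
        rng = np.random.default_rng(0)
        s = stationarize(series(rng.normal(3.0, 2.0, size=(40, 25))))
        assert np.abs(s.values.mean(axis=0)).max() < 1e-6
        assert np.abs(s.values.std(axis=0) - 1.0).max() < 1e-6
        assert s.stationarized

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        once = stationarize(series(rng.random((15, 12))))
        twice = stationarize(once)
        assert np.abs(once.values - twice.values).max() < 1e-6

    def test_constant_trial_maps_to_zeros(self):
        vals = np.vstack([np.full(10, 7.0), np.arange(10.0), np.arange(10.0) ** 2])
        out = stationarize(series(vals))
        assert np.all(np.isfinite(out.values))

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            stationarize(series(np.ones((5, 1))))


class TestGrangerPair:
    def test_requires_stationarized(self):
        with pytest.raises(ValueError):
            fit_granger_pair(series(np.random.rand(5, 20)),
                             series(np.random.rand(5, 20)))

    def test_nestedness_loglik(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            rx, ry = fit_granger_pair(white(rng), white(rng, name="y"), p_max=4)
            assert rx.loglik_causal >= rx.loglik_null
            assert ry.loglik_causal >= ry.loglik_null
            assert rx.p >= 1 and ry.p >= 1

    def test_role_reversal_swaps_results(self):
        rng = np.random.default_rng(3)
        sx, sy = white(rng, name="x"), white(rng, name="y")
        rx, ry = fit_granger_pair(sx, sy, p_max=3)
        ry2, rx2 = fit_granger_pair(sy, sx, p_max=3)
        assert rx.lr_statistic == rx2.lr_statistic
        assert ry.lr_statistic == ry2.lr_statistic
        assert rx.direction == rx2.direction

    def test_affine_rescaling_invariance(self):
        # stationarization makes this moot, but the fits themselves must be
        # scale-free: compare LR statistics on a manually scaled clone
        rng = np.random.default_rng(4)
        x = rng.standard_normal((10, 25))
        y = rng.standard_normal((10, 25))
        sx, sy = stationarize(series(x, "x")), stationarize(series(y, "y"))
        r1 = fit_granger_pair(sx, sy, p_max=2)[0]
        scaled = replace(sx, values=sx.values * 3.7)  # bypass re-standardization
        r2 = fit_granger_pair(scaled, sy, p_max=2)[0]
        assert r1.lr_statistic == pytest.approx(r2.lr_statistic, rel=1e-8)

    def test_lagged_dependence_detected_directionally(self):
        rng = np.random.default_rng(5)
        hits = miss = 0
        for _ in range(20):
            x = rng.standard_normal((20, 60))
            y = 0.8 * np.roll(x, 2, axis=1) + rng.standard_normal((20, 60))
            y[:, :2] = rng.standard_normal((20, 2))
            rx, ry = fit_granger_pair(stationarize(series(x, "x")),
                                      stationarize(series(y, "y")), p_max=4)
            hits += rx.significant
            miss += ry.significant
        assert hits >= 18
        assert miss <= 4

    def test_white_noise_prefers_small_lag(self):
        rng = np.random.default_rng(6)
        orders = [fit_granger_pair(white(rng), white(rng, name="y"), p_max=4)[0].p
                  for _ in range(20)]
        assert np.mean(np.array(orders) == 1) > 0.5

    def test_short_series_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError):
            fit_granger_pair(white(rng, bins=5), white(rng, bins=5, name="y"), p_max=4)

    def test_per_trial_mode_runs(self):
        rng = np.random.default_rng(8)
        rx, ry = fit_granger_pair(white(rng, trials=6, bins=40),
                                  white(rng, trials=6, bins=40, name="y"),
                                  p_max=2, per_trial=True)
        assert rx.loglik_causal >= rx.loglik_null


class TestTimeline:
    def test_injected_lag_structure_detected(self):
        # y inherits x's fluctuations with lag 2 starting at bin 10: the
        # forward direction must be detected and win on the full window
        rng = np.random.default_rng(9)
        x = rng.standard_normal((40, 40))
        y = rng.standard_normal((40, 40))
        y[:, 12:] += 0.6 * x[:, 10:-2]
        sx = stationarize(series(x, "x"))
        sy = stationarize(series(y, "y"))
        tl = run_granger_timeline(sx, sy, window_start=0, p_max=3)
        assert tl.onset("x->y") is not None
        assert tl.decisions[-1] in ("x->y", "both")
        final_xy, final_yx = tl.results[-1]
        assert final_xy.lr_statistic > final_yx.lr_statistic

    def test_window_metadata(self):
        rng = np.random.default_rng(10)
        tl = run_granger_timeline(white(rng), white(rng, name="y"),
                                  window_start=3, p_max=2)
        assert all(w[0] == 3 for w in tl.windows)
        assert len(tl.windows) == len(tl.decisions) == len(tl.results)


def test_kl_series_csv_roundtrip(tmp_path):
    rng = np.random.default_rng(12)
    s = KLSeries(rng.random((5, 8)), -20.0 + 10.0 * np.arange(8), "V4-like", "fc1")
    s.to_csv(tmp_path / "s.csv")
    back = KLSeries.from_csv(tmp_path / "s.csv")
    assert np.allclose(back.values, s.values, atol=1e-12)
    assert np.array_equal(back.bin_onsets, s.bin_onsets)
    assert back.region == "V4-like" and back.layer == "fc1"


def test_rate_series_means_features():
    rng = np.random.default_rng(11)
    data = rng.random((6, 9, 4))
    rec = RecordingSet(data, region_name="r", bin_width=10.0,
                       bin_onsets=np.arange(9) * 10.0)
    rs = rate_series(rec)
    assert np.allclose(rs.values, data.mean(axis=2))
    assert rs.region == "r"
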