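"""MVPA classifiers, shared-variance predictivity, pixel-level interfacing."""

import numpy as np
import pytest

import neuroiface as ni
from neuroiface.baselines import mvpa_suite, neural_predictivity, pixel_interface
from neuroiface.crossval import make_fold_plan
from neuroiface.datasets import RecordingSet


class TestMVPA:
    def test_separable_blobs_all_classifiers_high(self):
        rng = np.random.default_rng(0)
        centers = rng.normal(0, 5, size=(3, 10))
        labels = np.repeat(np.arange(3), 30)
        data = centers[labels] + rng.standard_normal((90, 10)) * 0.5
        rec = RecordingSet(data, region_name="blobs")
        plan = make_fold_plan(labels, k=5, seed=1)
        res = mvpa_suite(rec, labels, plan, seed=2)
        assert set(res) == {"logistic", "nearest_neighbor", "linear_svm"}
        for r in res.values():
            assert r.auc >= 0.95

    def test_pure_noise_at_chance(self):
        rng = np.random.default_rng(3)
        labels = np.repeat(np.arange(10), 12)
        rec = RecordingSet(rng.standard_normal((120, 20)), region_name="noise")
        plan = make_fold_plan(labels, k=4, seed=4)
        res = mvpa_suite(rec, labels, plan, seed=5)
        for r in res.values():
            assert abs(r.auc - 0.5) <= 0.08

    def test_single_class_training_fold_rejected(self):
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        rec = RecordingSet(np.random.rand(8, 3))
        bad_plan = ni.FoldPlan([np.array([0, 1, 2, 3]), np.array([4, 5, 6, 7])],
                               scheme="stratified_kfold")
        with pytest.raises(ValueError, match="classes"):
            mvpa_suite(rec, labels, bad_plan, seed=6)


class TestNeuralPredictivity:
    def test_exact_linear_readout_is_predictable(self, tiny_net, tiny_images):
        q = tiny_net.layer_names[-1]
        rec = ni.simulate_region(tiny_net, tiny_images, q, d=12, noise_sd=0.0,
                                 seed=7)
        plan = make_fold_plan(tiny_images.labels, k=4, seed=8)
        res = neural_predictivity(tiny_net, tiny_images, rec, q, plan,
                                  n_pcs=20, n_pls=10, seed=9)
        assert res.median_r >= 0.95

    def test_source_layer_scores_higher_than_distant_layer(self, tiny_net,
                                                           tiny_images):
        early, late = tiny_net.layer_names[0], tiny_net.layer_names[-1]
        rec = ni.simulate_region(tiny_net, tiny_images, early, d=12,
                                 noise_sd=0.2, seed=10)
        plan = make_fold_plan(tiny_images.labels, k=4, seed=11)
        r_early = neural_predictivity(tiny_net, tiny_images, rec, early, plan,
                                      n_pcs=20, n_pls=10, seed=12).median_r
        r_late = neural_predictivity(tiny_net, tiny_images, rec, late, plan,
                                     n_pcs=20, n_pls=10, seed=12).median_r
        assert r_early >= r_late

    def test_shuffled_rows_near_zero(self, tiny_net, tiny_images):
        q = tiny_net.layer_names[-1]
        rec = ni.simulate_region(tiny_net, tiny_images, q, d=12, noise_sd=0.0,
                                 seed=13)
        rng = np.random.default_rng(14)
        shuffled = RecordingSet(rec.data[rng.permutation(rec.n)],
                                region_name="shuffled")
        plan = make_fold_plan(tiny_images.labels, k=4, seed=15)
        res = neural_predictivity(tiny_net, tiny_images, shuffled, q, plan,
                                  n_pcs=20, n_pls=10, seed=16)
        assert abs(res.median_r) <= 0.1

    def test_feature_permutation_leaves_median_unchanged(self, tiny_net,
                                                         tiny_images):
        q = tiny_net.layer_names[-1]
        rec = ni.simulate_region(tiny_net, tiny_images, q, d=12, noise_sd=0.3,
                                 seed=17)
        perm = np.random.default_rng(18).permutation(12)
        rec_p = RecordingSet(rec.data[:, perm], region_name="perm")
        plan = make_fold_plan(tiny_images.labels, k=4, seed=19)
        a = neural_predictivity(tiny_net, tiny_images, rec, q, plan,
                                n_pcs=20, n_pls=10, seed=20)
        b = neural_predictivity(tiny_net, tiny_images, rec_p, q, plan,
                                n_pcs=20, n_pls=10, seed=20)
        # identical up to PLS deflation round-off
        assert a.median_r == pytest.approx(b.median_r, abs=1e-4)
        assert np.allclose(np.sort(a.per_feature_r), np.sort(b.per_feature_r),
                           atol=1e-4)


class TestPixelInterface:
    def test_one_component_bottleneck_degrades_all_layers(self, tiny_net,
                                                          tiny_images):
        plan = make_fold_plan(tiny_images.labels, k=4, seed=21)
        narrow = pixel_interface(tiny_images, 1, tiny_net, None, plan, seed=22)
        ample = pixel_interface(tiny_images, 48, tiny_net, None, plan, seed=22)
        for q in narrow.layers:
            assert narrow.auc_of("pixels", q) <= ample.auc_of("pixels", q) - 0.15

    def test_component_count_validated(self, tiny_net, tiny_images):
        plan = make_fold_plan(tiny_images.labels, k=4, seed=23)
        with pytest.raises(ValueError):
            pixel_interface(tiny_images, 10**6, tiny_net, None, plan)
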