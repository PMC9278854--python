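"""Synthetic generators: determinism, construction guarantees, signal content."""

import numpy as np
import pytest

import neuroiface as ni
from neuroiface.datasets import DynamicsSpec
from neuroiface.synthetic import (generate_images, simulate_region,
                                  simulate_two_region_dynamics)


class TestGenerateImages:
    def test_deterministic_for_fixed_seed(self):
        a = generate_images(2, 1, seed=0)
        b = generate_images(2, 1, seed=0)
        assert np.array_equal(a.images, b.images)
        assert np.array_equal(a.labels, b.labels)

    def test_seed_changes_output(self):
        a = generate_images(2, 3, seed=0)
        b = generate_images(2, 3, seed=1)
        assert not np.array_equal(a.images, b.images)

    def test_label_counts(self):
        s = generate_images(10, 200, size=(32, 32), seed=3)
        assert np.array_equal(np.bincount(s.labels), np.full(10, 200))
        assert s.images.shape == (2000, 32, 32, 3)
        assert s.images.min() >= 0.0 and s.images.max() <= 1.0

    def test_too_small_canvas_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_images(3, 1, size=(8, 8))

    def test_classes_linearly_separable_in_pixels(self):
        # class archetypes are procedurally separable: even a linear readout
        # of raw pixels should do well above chance
        from sklearn.linear_model import LogisticRegression

        s = generate_images(5, 40, size=(16, 16), seed=7)
        x = s.images.reshape(s.n, -1)
        rng = np.random.default_rng(0)
        idx = rng.permutation(s.n)
        tr, te = idx[:150], idx[150:]
        clf = LogisticRegression(max_iter=500).fit(x[tr], s.labels[tr])
        assert clf.score(x[te], s.labels[te]) >= 0.9


class TestSimulateRegion:
    def test_identity_projection_reproduces_activations(self, tiny_net, tiny_images):
        q = tiny_net.layer_names[-1]
        acts = ni.activations_at(tiny_net, tiny_images, q)
        rec = simulate_region(tiny_net, tiny_images, q, d=acts.width,
                              noise_sd=0.0, identity=True, seed=0)
        assert np.allclose(rec.data, acts.values, atol=1e-6)

    def test_identity_requires_matching_width(self, tiny_net, tiny_images):
        with pytest.raises(ValueError):
            simulate_region(tiny_net, tiny_images, tiny_net.layer_names[-1],
                            d=3, identity=True)

    def test_deterministic_and_noise_scaling(self, tiny_net, tiny_images):
        q = tiny_net.layer_names[-1]
        a = simulate_region(tiny_net, tiny_images, q, d=8, noise_sd=0.5, seed=3)
        b = simulate_region(tiny_net, tiny_images, q, d=8, noise_sd=0.5, seed=3)
        clean = simulate_region(tiny_net, tiny_images, q, d=8, noise_sd=0.0, seed=3)
        assert np.array_equal(a.data, b.data)
        resid_sd = (a.data - clean.data).std(axis=0)
        assert np.allclose(resid_sd, 0.5 * clean.data.std(axis=0), rtol=0.2)

    def test_noise_free_projection_preserves_task_information(self, tiny_net,
                                                              tiny_images):
        # a linear decoder on the projected data matches one on the source
        # activations (invertible A preserves all information)
        from sklearn.linear_model import LogisticRegression

        q = tiny_net.layer_names[-1]
        acts = ni.activations_at(tiny_net, tiny_images, q).values
        rec = simulate_region(tiny_net, tiny_images, q, d=acts.shape[1],
                              noise_sd=0.0, seed=1)
        rng = np.random.default_rng(2)
        idx = rng.permutation(tiny_images.n)
        tr, te = idx[:90], idx[90:]
        y = tiny_images.labels
        acc_src = LogisticRegression(max_iter=500).fit(acts[tr], y[tr]).score(acts[te], y[te])
        acc_rec = LogisticRegression(max_iter=500).fit(rec.data[tr], y[tr]).score(rec.data[te], y[te])
        assert abs(acc_src - acc_rec) <= 0.05

    def test_mixing_blends_layers(self, tiny_net, tiny_images):
        rec = simulate_region(tiny_net, tiny_images, None, d=6,
                              mixing={q: 1.0 for q in tiny_net.layer_names[-2:]},
                              seed=4)
        assert rec.data.shape == (tiny_images.n, 6)

    def test_bad_feature_count_rejected(self, tiny_net, tiny_images):
        with pytest.raises(ValueError):
            simulate_region(tiny_net, tiny_images, tiny_net.layer_names[0], d=0)

    def test_unknown_layer_rejected(self, tiny_net, tiny_images):
        with pytest.raises(KeyError):
            simulate_region(tiny_net, tiny_images, "convX", d=4)


class TestTwoRegionDynamics:
    def test_shapes_and_determinism(self, tiny_net, tiny_images):
        spec = DynamicsSpec(t_bins=20, stimulus_on=2, stimulus_off=10)
        a_v4, a_it = simulate_two_region_dynamics(tiny_net, tiny_images, spec,
                                                  d_v4=10, d_it=12, seed=5)
        b_v4, _ = simulate_two_region_dynamics(tiny_net, tiny_images, spec,
                                               d_v4=10, d_it=12, seed=5)
        assert a_v4.data.shape == (tiny_images.n, 20, 10)
        assert a_it.data.shape == (tiny_images.n, 20, 12)
        assert np.array_equal(a_v4.data, b_v4.data)
        assert np.all(a_v4.data >= 0.0)  # rates are rectified

    def test_v4_rate_rise_precedes_it_rise_by_feedforward_lag(self, tiny_net,
                                                              tiny_images):
        spec = DynamicsSpec()
        v4, it = simulate_two_region_dynamics(tiny_net, tiny_images, spec, seed=6)

        def onset(rec):
            m = rec.data.mean(axis=(0, 2))
            m = m - m[: spec.stimulus_on + 1].mean()  # baseline-correct
            return int(np.argmax(m > 0.5 * m.max()))

        assert onset(it) - onset(v4) == spec.feedforward_lag

    def test_no_feedback_means_no_class_information_in_v4(self, tiny_net,
                                                          tiny_images):
        # with class_gain_feedback = 0 the V4-like features carry only the
        # class-independent drive: a decoder stays at chance at every bin
        from sklearn.linear_model import LogisticRegression

        spec = DynamicsSpec(class_gain_feedback=0.0)
        v4, _ = simulate_two_region_dynamics(tiny_net, tiny_images, spec, seed=7)
        y = tiny_images.labels
        rng = np.random.default_rng(8)
        idx = rng.permutation(tiny_images.n)
        tr, te = idx[:90], idx[90:]
        accs = []
        for t in range(8, 16):  # bins inside the class-signal window
            x = v4.data[:, t, :]
            clf = LogisticRegression(max_iter=300).fit(x[tr], y[tr])
            accs.append(clf.score(x[te], y[te]))
        assert np.mean(accs) <= 0.5  # chance for 4 classes is 0.25

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DynamicsSpec(feedforward_lag=0)
        with pytest.raises(ValueError):
            DynamicsSpec(stimulus_on=10, stimulus_off=5)
        with pytest.raises(ValueError):
            DynamicsSpec(t_bins=10, feedback_lag=12, stimulus_off=9)
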