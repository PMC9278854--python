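"""Translation-map fitting: preprocessing, parameter recovery, mode contracts."""

import numpy as np
import pytest

import neuroiface as ni
from neuroiface.dcnn import LayerActivation
from neuroiface.translation import (TransHyper, apply_translation,
                                    fit_translation_end_to_end, fit_translation_mse,
                                    fit_translation_pca_target, load_translation,
                                    preprocess_neural, save_translation)


def linear_fixture(n=300, d=24, u=16, noise=0.0, seed=0):
    """Recordings whose targets are an exact (or noisy) linear function."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, d)) * rng.uniform(0.5, 2.0, size=d) + rng.normal(0, 1, d)
    M = rng.standard_normal((d, u))
    y = x @ M + noise * rng.standard_normal((n, u))
    return x, y


class TestPreprocess:
    def test_centered_unit_scale_data_maps_to_itself(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2000, 5))
        x = (x - x.mean(0)) / x.std(0)
        params, z = preprocess_neural(x)
        assert np.allclose(z, x, atol=1e-10)

    def test_constant_column_zeroed_without_error(self):
        x = np.column_stack([np.full(10, 3.0), np.arange(10.0)])
        params, z = preprocess_neural(x)
        assert np.all(z[:, 0] == 0.0)
        assert params.scale[0] == 1.0

    def test_no_leakage_heldout_means_nonzero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(5.0, 2.0, size=(50, 4))
        params, _ = preprocess_neural(x[:30])
        held = params.apply(x[30:])
        assert np.all(np.abs(held.mean(0)) > 1e-8)

    def test_unitnorm_convention(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((40, 3)) * 7
        _, z = preprocess_neural(x, convention="unitnorm")
        assert np.allclose(np.linalg.norm(z, axis=0), 1.0)


class TestMSEFit:
    def test_ridge_recovers_exact_linear_map(self):
        x, y = linear_fixture()
        tmap = fit_translation_mse(x[:200], LayerActivation("fc1", y[:200], (16,)),
                                   TransHyper(solver="ridge", l2=1e-10))
        pred = apply_translation(tmap, x[200:]).values
        resid = pred - y[200:]
        r2 = 1 - resid.var() / y[200:].var()
        assert r2 >= 0.99

    def test_sgd_matches_ridge(self):
        x, y = linear_fixture(n=200, d=8, u=4)
        ya = LayerActivation("fc1", y, (4,))
        ridge = fit_translation_mse(x, ya, TransHyper(solver="ridge", l2=3e-4))
        sgd = fit_translation_mse(x, ya, TransHyper(solver="sgd", l2=3e-4,
                                                    max_epochs=400), seed=0)
        pr = apply_translation(ridge, x).values
        ps = apply_translation(sgd, x).values
        # same solution up to optimizer tolerance, measured on predictions
        rel = np.abs(pr - ps).max() / np.abs(pr).max()
        assert rel < 0.05

    def test_adadelta_solver_optimizes(self):
        # Adadelta is the slow-and-steady trial-level option; check that it
        # makes consistent progress toward the exact solution
        x, y = linear_fixture(n=200, d=8, u=4)
        ya = LayerActivation("fc1", y, (4,))
        short = fit_translation_mse(x, ya, TransHyper(solver="adadelta",
                                                      adadelta_lr=1.0,
                                                      max_epochs=20), seed=0)
        tmap = fit_translation_mse(x, ya, TransHyper(solver="adadelta",
                                                     adadelta_lr=1.0,
                                                     max_epochs=150), seed=0)
        pred = apply_translation(tmap, x).values
        r2 = 1 - (pred - y).var() / y.var()
        assert tmap.residual_mse < short.residual_mse
        assert r2 >= 0.5

    def test_zero_targets_shrink_w(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((100, 6))
        ya = LayerActivation("fc1", np.zeros((100, 3)), (3,))
        tmap = fit_translation_mse(x, ya, TransHyper(solver="sgd", l2=1e-2,
                                                     max_epochs=50), seed=0)
        assert np.abs(tmap.W).max() < 1e-2
        assert np.abs(apply_translation(tmap, x).values).max() < 0.1

    def test_joint_permutation_invariance_at_convergence(self):
        x, y = linear_fixture(n=150, d=6, u=3)
        perm = np.random.default_rng(4).permutation(150)
        a = fit_translation_mse(x, LayerActivation("fc1", y, (3,)),
                                TransHyper(solver="ridge", l2=1e-6))
        b = fit_translation_mse(x[perm], LayerActivation("fc1", y[perm], (3,)),
                                TransHyper(solver="ridge", l2=1e-6))
        assert a.residual_mse == pytest.approx(b.residual_mse, rel=1e-8)
        assert np.allclose(a.W, b.W, atol=1e-8)

    def test_linearity_after_preprocessing(self):
        x, y = linear_fixture(n=100, d=5, u=2)
        tmap = fit_translation_mse(x, LayerActivation("fc1", y, (2,)))
        z = tmap.preprocess.apply(x[:10])
        lhs = (0.3 * z[0] + 0.7 * z[1]) @ tmap.W
        rhs = 0.3 * z[0] @ tmap.W + 0.7 * z[1] @ tmap.W
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_row_count_mismatch_rejected(self):
        x, y = linear_fixture(n=50)
        with pytest.raises(ValueError):
            fit_translation_mse(x[:40], LayerActivation("fc1", y, (16,)))


class TestEndToEnd:
    def test_downstream_weights_frozen(self, tiny_net, tiny_images):
        rng = np.random.default_rng(0)
        rows = rng.standard_normal((tiny_images.n, 12))
        before = [p.copy() for p in tiny_net.parameter_arrays()]
        fit_translation_end_to_end(rows, tiny_images.labels, tiny_net,
                                   tiny_net.layer_names[-1],
                                   TransHyper(max_epochs=3), seed=0)
        after = tiny_net.parameter_arrays()
        for b, a in zip(before, after):
            assert np.array_equal(b, a)

    def test_shuffled_labels_stay_at_chance(self, tiny_net, tiny_images):
        q = tiny_net.layer_names[-1]
        acts = ni.activations_at(tiny_net, tiny_images, q)
        rng = np.random.default_rng(1)
        rows = acts.values @ rng.standard_normal((acts.width, 16)) / 4.0
        labels = rng.permutation(tiny_images.labels)
        split = rng.permutation(tiny_images.n)
        tr, te = split[:90], split[90:]
        tmap = fit_translation_end_to_end(rows[tr], labels[tr], tiny_net, q,
                                          TransHyper(max_epochs=30), seed=0)
        pred = ni.forward_from(tiny_net, q, apply_translation(tmap, rows[te]))
        auc = ni.multiclass_auc(pred.probs, tiny_images.labels[te])
        assert abs(auc - 0.5) < 0.15


class TestPCATarget:
    def test_full_rank_matches_mse_mode(self):
        x, y = linear_fixture(n=240, d=10, u=6)
        ya = LayerActivation("fc1", y, (6,))
        full = fit_translation_pca_target(x, ya, r=6, pca_fit_set=ya,
                                          hyper=TransHyper(l2=1e-8))
        mse = fit_translation_mse(x, ya, TransHyper(l2=1e-8))
        pf = apply_translation(full, x).values
        pm = apply_translation(mse, x).values
        assert np.abs(pf - pm).max() < 1e-6 * max(1.0, np.abs(pm).max())

    def test_rank_one_degrades(self):
        x, y = linear_fixture(n=240, d=10, u=6)
        ya = LayerActivation("fc1", y, (6,))
        full = fit_translation_pca_target(x, ya, r=6, pca_fit_set=ya)
        one = fit_translation_pca_target(x, ya, r=1, pca_fit_set=ya)
        ef = ((apply_translation(full, x).values - y) ** 2).mean()
        e1 = ((apply_translation(one, x).values - y) ** 2).mean()
        assert e1 > ef

    def test_rank_too_large_rejected(self):
        x, y = linear_fixture(n=50, d=5, u=4)
        ya = LayerActivation("fc1", y, (4,))
        with pytest.raises(ValueError):
            fit_translation_pca_target(x, ya, r=5, pca_fit_set=ya)


class TestApplyAndIO:
    def test_width_mismatch_rejected(self):
        x, y = linear_fixture(n=50, d=5, u=4)
        tmap = fit_translation_mse(x, LayerActivation("fc1", y, (4,)))
        with pytest.raises(ValueError):
            apply_translation(tmap, np.zeros((3, 6)))

    def test_hdf5_roundtrip(self, tmp_path):
        x, y = linear_fixture(n=60, d=5, u=4)
        ya = LayerActivation("fc1", y, (4,))
        tmap = fit_translation_pca_target(x, ya, r=3, pca_fit_set=ya)
        path = tmp_path / "map.h5"
        save_translation(tmap, path)
        clone = load_translation(path)
        a = apply_translation(tmap, x).values
        b = apply_translation(clone, x).values
        assert np.allclose(a, b, atol=1e-12)
        assert clone.mode == "pca_target" and clone.target_layer == "fc1"
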