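# neuroiface

Score correspondence between neural recordings and layers of a deep
convolutional classifier by **direct interface**: learn a linear
translation from brain activity into a layer's activation space,
substitute the translated activity for that layer, and judge the
correspondence by how well the substituted network performs its
object-recognition task.

## Why

The standard way to relate brain regions to network layers measures
*shared variance* — how well model activations predict neural responses.
But shared variance need not be task-relevant: a region can correlate with
a layer without being able to play that layer's functional role.  The
direct-interface test is stricter.  If region *r* corresponds to layer
*q*, then brain activity recorded from *r*, mapped by a linear translation
`W` into *q*'s activation space, should drive the rest of the network to
the correct decision with no image input at all:

    f(X) = g'_q(g_q(X)),     g_q(X) ≈ W · preprocess(R),
    P_r  = g'_q(W · preprocess(R))

Correspondence is scored on held-out rows by the Hand–Till multiclass AUC
of `P_r` against the class labels (each pairwise AUC computed through the
Mann–Whitney U statistic, ties ½) and by the per-row KL divergence
D(P_i ‖ P_r) between image-driven and brain-driven outputs.  On top of the
static analysis, the package provides bin-wise temporal interfacing with
directional Granger-causal comparison of two regions (do raw rates flow
feedforward while class information flows back?), a noise-perturbation
analysis of error attenuation across layers, and the conventional
baselines (MVPA classifiers, PCA+PLS neural predictivity, pixel-level
interfacing).

Everything runs on synthetic study conditions: a generator produces
separable image classes, simulated recordings as noisy linear readouts of
chosen layers, and two-region temporal dynamics with configurable
feedforward/feedback lags, so every claim is testable against planted
ground truth on one CPU.  See `docs/methods.md` for the full model
description and design rationale.

## Worked example

```python
import neuroiface as ni

# 10 procedurally separable classes, 200 images each, and a small
# VGG-style classifier trained on them
images = ni.generate_images(10, 200, seed=11)
net = ni.train_net(ni.NetSpec(), images, ni.Hyper(max_epochs=10), seed=7)
print("validation accuracy:", net.final_val_accuracy)

# a simulated 64-feature region reading out the late dense layer
rec = ni.simulate_region(net, images, "fc1", d=64, noise_sd=0.0, seed=21)

# interface it into every layer under stratified 8-fold cross-validation
plan = ni.make_fold_plan(images.labels, k=8, seed=22)
grid = ni.run_interface_grid(net, images, rec, None, plan, seed=23)
print("image-driven AUC:", round(grid.image_driven_auc, 3))
for q in grid.layers:
    cell = grid.grid[(rec.region_name, q)]
    print(f"{q:6s}  AUC={cell.auc:.3f}  mean KL={cell.mean_kl:.4f}")
```

Output:

```
validation accuracy: 1.0
image-driven AUC: 1.0
conv1   AUC=0.979  mean KL=1.1090
conv2   AUC=1.000  mean KL=0.3571
conv3   AUC=1.000  mean KL=0.0186
conv4   AUC=1.000  mean KL=0.0008
fc1     AUC=1.000  mean KL=0.0000
```

The recordings were constructed as an invertible readout of `fc1`, and the
grid recovers exactly that: interfacing into `fc1` reproduces the
image-driven behavior almost perfectly (AUC equal to image-driven, KL near
zero), while forcing the same data into the earliest convolutional layer
loses most of the correspondence.  On real recordings the row of AUCs per
region is the correspondence profile the method is after.

A command-line umbrella mirrors the library:

```bash
neuroiface simulate images --seed 1 --out imgs.h5
neuroiface train-net --images imgs.h5 --seed 1 --out net.h5
neuroiface layers --net net.h5
neuroiface interface --net net.h5 --images imgs.h5 --recordings rec.csv \
    --layers all --cv stratified:8 --seed 1 --out results/
neuroiface scenario granger-dissociation --seed 1 --out artifacts/
```

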