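"""Synthetic stimuli and simulated neural recordings.

Three generators make every downstream analysis testable without external
data:

* :func:`generate_images` renders procedurally separable object classes
  (geometric shape x hue x texture archetypes with position/scale jitter),
  a stand-in for natural-image stimuli.
* :func:`simulate_region` produces a static recording as a noisy linear
  readout of a chosen network layer — exactly the generative structure the
  linear brain-to-layer translation assumes, so translation quality is
  measurable against ground truth.
* :func:`simulate_two_region_dynamics` produces paired temporal recordings
  for a V4-like and an IT-like region in which the stimulus-driven rate
  leads in V4 and the object-class signal arises in IT first and feeds back
  to V4 with a configurable lag — the recurrence hypothesis in generative
  form.

All generators are pure functions of (arguments, seed).
"""

from __future__ import annotations

import colorsys

import numpy as np

from ._rng import substream
from .datasets import DynamicsSpec, ImageSet, RecordingSet
from .dcnn import TrainedNet, activations_many

# --------------------------------------------------------------------------
# images

_SHAPES = (
    "disc", "square", "cross", "hbars", "vgrating",
    "ring", "triangle", "checker", "xcross", "dgrating",
)


def _shape_mask(shape: str, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Boolean mask of a unit-scale archetype on normalized coords u, v."""
    d = np.sqrt(u * u + v * v)
    box = np.maximum(np.abs(u), np.abs(v)) <= 1.0
    if shape == "disc":
        return d <= 1.0
    if shape == "square":
        return box
    if shape == "cross":
        return box & ((np.abs(u) <= 0.34) | (np.abs(v) <= 0.34))
    if shape == "hbars":
        return box & (np.sin(3.0 * np.pi * v) > 0)
    if shape == "vgrating":
        return box & (np.sin(3.0 * np.pi * u) > 0)
    if shape == "ring":
        return (d <= 1.0) & (d >= 0.55)
    if shape == "triangle":
        return (v >= -0.9) & (v <= 1.0) & (np.abs(u) <= (1.0 - v) / 2.0)
    if shape == "checker":
        return box & (((np.floor(u * 2) + np.floor(v * 2)) % 2) == 0)
    if shape == "xcross":
        return box & ((np.abs(u - v) <= 0.45) | (np.abs(u + v) <= 0.45))
    if shape == "dgrating":
        return (d <= 1.0) & (np.sin(2.0 * np.pi * (u + v)) > 0)
    raise ValueError(f"unknown shape {shape!r}")


def generate_images(m: int, n_per_class: int, size: tuple[int, int] = (32, 32),
                    seed: int = 0) -> ImageSet:
    """Render ``m`` procedurally separable classes, ``n_per_class`` images each.

    Class k is a (shape, hue, texture) archetype: shape cycles through ten
    geometric figures, hue advances around the color circle, and classes
    beyond the first ten additionally get a textured fill.  Position and
    scale are jittered per image; light pixel noise is added.  Deterministic
    for a fixed seed.
    """
    if m < 2 or n_per_class < 1:
        raise ValueError("need m >= 2 classes and n_per_class >= 1")
    h, w = size
    if min(h, w) < 12:
        raise ValueError(f"size {size} too small to render class archetypes")
    rng = substream(seed, "images")
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    images = np.empty((m * n_per_class, h, w, 3), dtype=np.float32)
    labels = np.empty(m * n_per_class, dtype=np.int64)
    row = 0
    for k in range(m):
        shape = _SHAPES[k % len(_SHAPES)]
        hue = (k * 0.3779) % 1.0
        textured = (k // len(_SHAPES)) % 2 == 1
        fg = np.array(colorsys.hsv_to_rgb(hue, 0.85, 0.95))
        for _ in range(n_per_class):
            cy = h / 2 + rng.uniform(-0.15, 0.15) * h
            cx = w / 2 + rng.uniform(-0.15, 0.15) * w
            r = rng.uniform(0.55, 0.8) * min(h, w) / 2
            u, v = (xx - cx) / r, (yy - cy) / r
            mask = _shape_mask(shape, u, v)
            img = np.full((h, w, 3), 0.15, dtype=np.float64)
            img[mask] = fg
            if textured:
                stripes = (np.sin(2.0 * np.pi * yy / 3.0) > 0) & mask
                img[stripes] *= 0.45
            img += rng.normal(0.0, 0.02, size=img.shape)
            images[row] = np.clip(img, 0.0, 1.0)
            labels[row] = k
            row += 1
    names = [f"class_{k:02d}" for k in range(m)]
    return ImageSet(images, labels, names)


# --------------------------------------------------------------------------
# static region simulation


def simulate_region(net: TrainedNet, images: ImageSet, source_layer: str | list[str],
                    d: int, noise_sd: float = 0.0,
                    mixing: dict[str, float] | None = None,
                    identity: bool = False, seed: int = 0) -> RecordingSet:
    """Simulate d neural features as a noisy linear readout of a layer.

    data = activations(source_layer) @ A + eta, where A has standard-normal
    entries scaled by 1/sqrt(source width) (full rank almost surely) and eta
    is i.i.d. Gaussian with SD ``noise_sd`` times each feature's signal SD
    (measurement noise, applied after the projection).  ``mixing`` blends
    several source layers (concatenated with the given weights) before the
    projection; ``identity`` uses A = I and requires d == source width.
    """
    if d < 1:
        raise ValueError("need at least one simulated feature")
    if mixing:
        layers = list(mixing)
        weights = np.array([mixing[q] for q in layers])
    else:
        layers = [source_layer] if isinstance(source_layer, str) else list(source_layer)
        weights = np.ones(len(layers))
    acts = activations_many(net, images, layers)
    source = np.hstack(
        [w * acts[q].values.astype(np.float64) for q, w in zip(layers, weights)]
    )
    u = source.shape[1]
    rng = substream(seed, "region")
    if identity:
        if d != u:
            raise ValueError(f"identity projection requires d == source width ({u})")
        signal = source
    else:
        A = rng.standard_normal((u, d)) / np.sqrt(u)
        signal = source @ A
    if noise_sd > 0:
        sd = signal.std(axis=0)
        signal = signal + rng.standard_normal(signal.shape) * (noise_sd * sd)
    name = "+".join(layers)
    return RecordingSet(signal, region_name=f"sim[{name}]")


# --------------------------------------------------------------------------
# two-region temporal dynamics


def _shift(x: np.ndarray, lag: int, axis: int = -1) -> np.ndarray:
    """Shift forward in time by ``lag`` bins, zero-filling the start."""
    if lag == 0:
        return x
    out = np.zeros_like(x)
    sl_src = [slice(None)] * x.ndim
    sl_dst = [slice(None)] * x.ndim
    sl_src[axis] = slice(0, x.shape[axis] - lag)
    sl_dst[axis] = slice(lag, None)
    out[tuple(sl_dst)] = x[tuple(sl_src)]
    return out


def simulate_two_region_dynamics(net: TrainedNet, images: ImageSet,
                                 spec: DynamicsSpec | None = None,
                                 d_v4: int = 48, d_it: int = 48,
                                 code_layer: str | None = None,
                                 seed: int = 0) -> tuple[RecordingSet, RecordingSet]:
    """Paired V4-like / IT-like temporal recordings with recurrent structure.

    Generative story per trial i, bin t, feature j (rates are rectified and
    carry additive Gaussian noise everywhere):

    * a stimulus drive s(t) turns on one bin after stimulus onset; the
      V4-like drive carries trial-level fluctuations eps[i, t], and the
      IT-like drive receives the *same* fluctuations ``feedforward_lag``
      bins later — raw rates are therefore Granger-causal V4 → IT;
    * an object-class code c_i (a random projection of a late layer's
      activations for image i) enters the IT-like region under an envelope
      following the drive's arrival there, with amplitude fluctuations
      zeta[i, t]; the V4-like region receives the class signal — including
      its fluctuations — ``feedback_lag`` bins later, scaled by
      ``class_gain_feedback``: class information is Granger-causal IT → V4;
    * the class amplitude also has a small mean-rate component, so late
      feedback raises V4's overall rate, and a weak third-order loop feeds
      the V4 class signal back into IT.
    """
    spec = spec or DynamicsSpec()
    layer = code_layer or net.layer_names[-1]
    rng = substream(seed, "dynamics")
    n, T = images.n, spec.t_bins

    acts = activations_many(net, images, [layer])[layer].values.astype(np.float64)
    u = acts.shape[1]

    def class_codes(d: int) -> np.ndarray:
        P = rng.standard_normal((u, d)) / np.sqrt(u)
        c = acts @ P
        c = (c - c.mean(axis=0)) / np.maximum(c.std(axis=0), 1e-12)
        return c

    c_v4 = class_codes(d_v4)
    c_it = class_codes(d_it)

    # stimulus drive: smoothed boxcar, one-bin onset latency in V4
    s = np.zeros(T)
    s[spec.stimulus_on + 1 : spec.stimulus_off + 1] = 1.0
    s = np.convolve(s, [0.25, 0.5, 0.25], mode="same")
    s_it = _shift(s, spec.feedforward_lag)

    eps = rng.standard_normal((n, T)) * spec.drive_jitter
    zeta = rng.standard_normal((n, T)) * spec.class_jitter

    drive_v4 = s[None, :] * (1.0 + eps)
    drive_it = s_it[None, :] * (1.0 + _shift(eps, spec.feedforward_lag, axis=1))

    env_it = s_it                       # class envelope arrives in IT with the drive
    env_v4 = _shift(env_it, spec.feedback_lag)
    amp_it = env_it[None, :] * (1.0 + zeta)
    amp_v4 = env_v4[None, :] * (1.0 + _shift(zeta, spec.feedback_lag, axis=1))
    # weak loop closure: the fed-back V4 class signal re-enters IT
    # (scaled by the feedback gain: no feedback, no loop)
    amp_it = amp_it + 0.3 * spec.class_gain_feedback * _shift(
        amp_v4, spec.feedforward_lag, axis=1
    )

    b_v4 = 0.5 + np.abs(rng.standard_normal(d_v4))
    b_it = 0.5 + np.abs(rng.standard_normal(d_it))
    mean_rate_frac = 0.3  # class amplitude's contribution to overall rate

    def assemble(drive, amp, gain_cls, b, codes, d):
        rate = (
            spec.stimulus_gain * drive[:, :, None] * b[None, None, :]
            + gain_cls * amp[:, :, None] * (codes[:, None, :] + mean_rate_frac)
        )
        rate = rate + rng.standard_normal((n, T, d)) * spec.noise_sd
        return np.maximum(rate + 0.2, 0.0)

    data_v4 = assemble(drive_v4, amp_v4, spec.class_gain_feedback, b_v4, c_v4, d_v4)
    data_it = assemble(drive_it, amp_it, spec.class_gain_it, b_it, c_it, d_it)

    onsets = spec.bin_onsets
    rec_v4 = RecordingSet(data_v4, region_name="V4-like", bin_width=spec.bin_width,
                          bin_onsets=onsets)
    rec_it = RecordingSet(data_it, region_name="IT-like", bin_width=spec.bin_width,
                          bin_onsets=onsets)
    return rec_v4, rec_it
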