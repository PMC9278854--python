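"""Named end-to-end scenarios over synthetic data.

Each scenario materializes its inputs from the configuration (or reuses a
supplied trained net), runs the corresponding analysis pipeline, and writes
a self-describing artifact directory: results, the config echo and hash,
all seeds, and a machine-readable pass/fail report against the scenario's
property thresholds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ._rng import child_seed
from .baselines import mvpa_suite
from .config import ExperimentConfig, make_config
from .crossval import LOCO, make_fold_plan
from .datasets import DynamicsSpec, ImageSet
from .dcnn import (Hyper, NetSpec, TrainedNet, activations_at, forward_from,
                   forward_full, train_net)
from .granger import (binwise_interface_kl, rate_series, run_granger_timeline,
                      stationarize)
from .interface import run_interface_grid
from .perturbation import perturb_and_propagate
from .synthetic import generate_images, simulate_region, simulate_two_region_dynamics
from .translation import TransHyper

SCENARIOS = (
    "substitution-identity",
    "layer-recovery",
    "zero-shot",
    "granger-dissociation",
    "perturbation",
    "baselines-comparison",
)


def build_images(config: ExperimentConfig, seed: int | None = None) -> ImageSet:
    d = config.section("data")
    seed = config["seed"] if seed is None else seed
    if d["source"] == "synthetic":
        return generate_images(d["n_classes"], d["n_per_class"],
                               tuple(d["image_size"]), seed=child_seed(seed, "images"))
    from .datasets import read_imageset_dir, read_imageset_h5

    path = Path(d["images_path"])
    return read_imageset_h5(path) if path.suffix in (".h5", ".hdf5") else read_imageset_dir(path)


def build_net_spec(config: ExperimentConfig) -> NetSpec:
    n = config.section("network")
    if n["preset"] == "vgg-miniature":
        return NetSpec.vgg_miniature(
            n_classes=config.section("data")["n_classes"],
            use_batch_norm=n["use_batch_norm"], dense=tuple(n["dense"]),
            input_size=tuple(n["input_size"]), dropout=n["dropout"],
            weight_decay=n["weight_decay"])
    if n["preset"] is not None:
        raise ValueError(f"unknown network preset {n['preset']!r}")
    return NetSpec(
        blocks=tuple(tuple(b) for b in n["blocks"]),
        use_batch_norm=n["use_batch_norm"], dense=tuple(n["dense"]),
        n_classes=config.section("data")["n_classes"],
        input_size=tuple(n["input_size"]), dropout=n["dropout"],
        weight_decay=n["weight_decay"])


def build_hyper(config: ExperimentConfig) -> Hyper:
    t = config.section("network")["training"]
    return Hyper(batch_size=t["batch_size"], learning_rate=t["learning_rate"],
                 momentum=t["momentum"], max_epochs=t["max_epochs"],
                 lr_patience=t["lr_patience"], lr_factor=t["lr_factor"],
                 stop_patience=t["stop_patience"], val_fraction=t["val_fraction"],
                 augment=t["augment"])


def build_trans_hyper(config: ExperimentConfig) -> TransHyper:
    t = config.section("translation")
    return TransHyper(solver=t["solver"], l2=t["l2"], learning_rate=t["learning_rate"],
                      batch_size=t["batch_size"], momentum=t["momentum"],
                      convention=t["convention"])


def prepare_net(config: ExperimentConfig, images: ImageSet | None = None,
                net: TrainedNet | None = None) -> tuple[TrainedNet, ImageSet]:
    """Train (or load) the classifier the scenarios interface with."""
    images = images if images is not None else build_images(config)
    if net is not None:
        return net, images
    ckpt = config.section("network")["checkpoint"]
    if ckpt:
        return TrainedNet.load(ckpt), images
    net = train_net(build_net_spec(config), images, build_hyper(config),
                    seed=child_seed(config["seed"], "net"))
    return net, images


def _write_report(out_dir: str | Path, name: str, config: ExperimentConfig,
                  report: dict) -> Path:
    out = Path(out_dir) / name
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "scenario": name,
        "passed": bool(report.get("passed", False)),
        "report": report,
        "config": config.values,
        "config_hash": config.content_hash,
    }
    path = out / "report.json"
    path.write_text(json.dumps(payload, indent=2, default=_jsonable))
    return path


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    raise TypeError(type(v))


def run_scenario(name: str, config: ExperimentConfig | dict | None = None,
                 out_dir: str | Path | None = None,
                 net: TrainedNet | None = None,
                 images: ImageSet | None = None) -> dict:
    """Execute a named scenario; returns the report dict and writes it."""
    if not isinstance(config, ExperimentConfig):
        config = make_config(config)
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    out_dir = Path(out_dir or config["out_dir"])
    seed = config["seed"]
    try:
        if name == "substitution-identity":
            report = _scenario_substitution(config, net, images)
        elif name == "layer-recovery":
            report = _scenario_layer_recovery(config, net, images)
        elif name == "zero-shot":
            report = _scenario_zero_shot(config, net, images)
        elif name == "granger-dissociation":
            report = _scenario_granger(config, net, images)
        elif name == "perturbation":
            report = _scenario_perturbation(config, net, images)
        else:
            report = _scenario_baselines(config, net, images)
    except Exception as exc:
        raise RuntimeError(f"scenario {name!r} failed: {exc}") from exc
    report["seed"] = seed
    _write_report(out_dir, name, config, report)
    return json.loads(json.dumps(report, default=_jsonable))


# ---------------------------------------------------------------------------
# individual scenarios


def _scenario_substitution(config, net, images):
    images = images if images is not None else build_images(config)
    net = net or TrainedNet(build_net_spec(config), seed=child_seed(config["seed"], "net"))
    sub = images.subset(np.arange(min(images.n, 128)))
    p_full = forward_full(net, sub)
    errs = {}
    for q in net.layer_names:
        p_sub = forward_from(net, q, activations_at(net, sub, q))
        errs[q] = float(np.abs(p_sub.probs - p_full.probs).max())
    worst = max(errs.values())
    return {"max_abs_error_per_layer": errs, "max_abs_error": worst,
            "passed": worst <= 1e-5}


def _grid_for_region(config, net, images, noise_sd, scheme="stratified_kfold"):
    d = config.section("data")
    layer = d["source_layer"] or net.layer_names[-1]
    rec = simulate_region(net, images, layer, d=d["n_features"], noise_sd=noise_sd,
                          seed=child_seed(config["seed"], "region"))
    plan = make_fold_plan(images.labels, k=config.section("evaluation")["k"],
                          scheme=scheme, seed=child_seed(config["seed"], "folds"))
    grid = run_interface_grid(net, images, rec, config.section("evaluation")["layers"],
                              plan, mode=config.section("translation")["mode"],
                              hyper=build_trans_hyper(config),
                              seed=child_seed(config["seed"], "grid"))
    return layer, rec, grid


def _scenario_layer_recovery(config, net, images):
    net, images = prepare_net(config, images, net)
    source_layer, rec, grid = _grid_for_region(config, net, images,
                                               config.section("data")["noise_sd"])
    best = grid.best_layer(rec.region_name)
    cell = grid.grid[(rec.region_name, best)]
    auc_gap = grid.image_driven_auc - cell.auc
    return {
        "source_layer": source_layer, "best_layer": best,
        "image_driven_auc": grid.image_driven_auc, "interfaced_auc": cell.auc,
        "auc_gap": auc_gap, "mean_kl": cell.mean_kl,
        "auc_by_layer": {q: grid.auc_of(rec.region_name, q) for q in grid.layers},
        "passed": (auc_gap <= 0.02) and (cell.mean_kl <= 0.05),
    }


def _scenario_zero_shot(config, net, images):
    net, images = prepare_net(config, images, net)
    d = config.section("data")
    layer = d["source_layer"] or net.layer_names[-1]
    rec = simulate_region(net, images, layer, d=d["n_features"],
                          noise_sd=d["noise_sd"], seed=child_seed(config["seed"], "region"))
    plan = make_fold_plan(images.labels, scheme=LOCO)
    grid = run_interface_grid(net, images, rec, [layer], plan,
                              hyper=build_trans_hyper(config),
                              seed=child_seed(config["seed"], "grid"))
    auc = grid.auc_of(rec.region_name, layer)
    return {"layer": layer, "zero_shot_auc": auc,
            "image_driven_auc": grid.image_driven_auc, "passed": auc >= 0.7}


def _scenario_granger(config, net, images):
    g = config.section("granger")
    cfg_imgs = config.section("data")
    # the temporal fixture uses a fresh, smaller trial set
    n_trials = g["n_trials_per_class"]
    trial_images = generate_images(cfg_imgs["n_classes"], n_trials,
                                   tuple(cfg_imgs["image_size"]),
                                   seed=child_seed(config["seed"], "trial-images"))
    net, _ = prepare_net(config, None, net)
    spec = DynamicsSpec(**g["dynamics"])
    rec_v4, rec_it = simulate_two_region_dynamics(
        net, trial_images, spec, g["d_v4"], g["d_it"],
        seed=child_seed(config["seed"], "dynamics"))
    layer = g["layer"] or net.layer_names[-1]
    plan = make_fold_plan(trial_images.labels, k=config.section("evaluation")["k"],
                          seed=child_seed(config["seed"], "folds"))
    kw = dict(mode=config.section("translation")["mode"],
              hyper=build_trans_hyper(config))
    kl_v4 = stationarize(binwise_interface_kl(net, layer, rec_v4, trial_images, plan,
                                              seed=child_seed(config["seed"], "klv4"), **kw))
    kl_it = stationarize(binwise_interface_kl(net, layer, rec_it, trial_images, plan,
                                              seed=child_seed(config["seed"], "klit"), **kw))
    r_v4 = stationarize(rate_series(rec_v4), per_trial=False)
    r_it = stationarize(rate_series(rec_it), per_trial=False)
    gkw = dict(window_start=spec.stimulus_on, p_max=g["p_max"],
               criterion=g["criterion"], alpha=g["alpha"])
    tl_rate = run_granger_timeline(r_v4, r_it, **gkw)   # x = V4, y = IT
    tl_kl = run_granger_timeline(kl_v4, kl_it, **gkw)
    onsets = {
        "rate_v4_to_it": tl_rate.onset("x->y"), "rate_it_to_v4": tl_rate.onset("y->x"),
        "kl_it_to_v4": tl_kl.onset("y->x"), "kl_v4_to_it": tl_kl.onset("x->y"),
    }
    inf = float("inf")

    def first(v):
        return inf if v is None else v

    passed = (first(onsets["rate_v4_to_it"]) < first(onsets["rate_it_to_v4"])
              and first(onsets["kl_it_to_v4"]) < first(onsets["kl_v4_to_it"]))
    return {"layer": layer, "onset_windows": onsets,
            "rate_decisions": tl_rate.decisions, "kl_decisions": tl_kl.decisions,
            "passed": passed}


def _scenario_perturbation(config, net, images):
    # the attenuation analysis is architecture-sensitive: default to the
    # VGG-like miniature unless a net or an explicit preset is given
    if net is None and config.section("network")["preset"] is None:
        images = images if images is not None else build_images(config)
        spec = NetSpec.vgg_miniature(
            n_classes=config.section("data")["n_classes"],
            input_size=tuple(config.section("network")["input_size"]))
        net = train_net(spec, images, build_hyper(config),
                        seed=child_seed(config["seed"], "net"))
    net, images = prepare_net(config, images, net)
    p = config.section("perturbation")
    conv_layers = [q for q in net.layer_names if q.startswith("conv")]
    ref = p["reference_layer"] or conv_layers[-1]
    earliest = conv_layers[0]
    preceding = conv_layers[[i for i, q in enumerate(conv_layers) if q == ref][0] - 1]
    kw = dict(metric=p["metric"], seed=child_seed(config["seed"], "perturb"),
              n_repeats=p["n_repeats"])
    dev_pre = perturb_and_propagate(net, images, preceding, p["gamma"], ref, **kw)
    dev_early = perturb_and_propagate(net, images, earliest, p["gamma"], ref, **kw)
    dev_zero = perturb_and_propagate(net, images, earliest, 0.0, ref, **kw)
    return {
        "reference_layer": ref, "preceding_layer": preceding, "earliest_layer": earliest,
        "deviation_preceding": dev_pre.deviation, "deviation_earliest": dev_early.deviation,
        "deviation_gamma0": dev_zero.deviation,
        "passed": dev_pre.deviation > dev_early.deviation and dev_zero.deviation == 0.0,
    }


def _scenario_baselines(config, net, images):
    b = config.section("baselines")
    d = config.section("data")
    seed = config["seed"]
    # the sparse regime needs a many-class net of its own
    train_images = generate_images(b["mvpa_n_classes"], b["mvpa_train_per_class"],
                                   tuple(d["image_size"]),
                                   seed=child_seed(seed, "many-images"))
    if net is None or net.spec.n_classes != b["mvpa_n_classes"]:
        spec = build_net_spec(config)
        from dataclasses import replace as dc_replace

        spec = dc_replace(spec, n_classes=b["mvpa_n_classes"])
        net = train_net(spec, train_images, build_hyper(config),
                        seed=child_seed(seed, "many-net"))
    sparse = generate_images(b["mvpa_n_classes"], b["mvpa_n_per_class"],
                             tuple(d["image_size"]),
                             seed=child_seed(seed, "sparse-images"))
    layer = d["source_layer"] or net.layer_names[-1]
    rec = simulate_region(net, sparse, layer, d=d["n_features"],
                          noise_sd=b["mvpa_noise_sd"],
                          seed=child_seed(seed, "sparse-region"))
    plan = make_fold_plan(sparse.labels, k=config.section("evaluation")["k"],
                          seed=child_seed(seed, "folds"))
    mvpa = mvpa_suite(rec, sparse.labels, plan, seed=child_seed(seed, "mvpa"))
    hyper = build_trans_hyper(config)
    hyper.solver = "sgd"  # early stopping regularizes the ill-posed sparse fit
    grid = run_interface_grid(net, sparse, rec, [layer], plan, hyper=hyper,
                              seed=child_seed(seed, "grid"))
    iface_auc = grid.auc_of(rec.region_name, layer)
    mvpa_aucs = {k: v.auc for k, v in mvpa.items()}
    return {
        "mvpa_auc": mvpa_aucs, "interfaced_auc": iface_auc, "layer": layer,
        "passed": max(mvpa_aucs.values()) <= 0.55 and iface_auc >= 0.65,
    }
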