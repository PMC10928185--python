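"""End-to-end orchestration: simulate -> train -> extract -> fuse ->
select -> classify -> explain -> compare.

Every stage draws its randomness from a named substream spawned from the
single root seed, so a config + seed pair reproduces the whole run,
including byte-identical mask JSON. Stage artifacts (feature tables,
mask, metrics, heatmaps, consolidated report) are written under
``out_dir``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classification import evaluate_classifier, make_classifier_preset
from .datasets import (load_features, make_modality_images, save_features,
                       FeatureMatrix, LabelVector)
from .explain import (deepest_spatial_conv, explain_image,
                      save_heatmap_overlay)
from .features import ResNetFeatureExtractor, SAEFeatureExtractor
from .fusion import FusionConfig, fuse_features
from .selection import SelectionConfig, select_features
from .stats import paired_difference_test

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("brainfuse")

_ALL_STAGES = ("simulate", "train", "extract", "fuse", "select",
               "classify", "explain", "ttest")


@dataclass
class PipelineConfig:
    """Configuration of the full pipeline (schema version 1)."""

    seed: int = 1
    out_dir: str = "brainfuse_run"
    stages: tuple = _ALL_STAGES
    # synthetic image simulation
    n_per_class: int = 50
    image_size: int = 32
    # modified ResNet-50 extractor
    width_scale: float = 0.25
    resnet_epochs: int = 5
    resnet_lr: float = 1e-2
    minibatch: int = 32
    # stacked autoencoder extractor
    sae_epochs: int = 3
    sae_lr: float = 1e-3
    feature_dim: int = 1236
    # parallel-pooling fusion
    window: int = 2
    stride: int = 2
    mode: str = "max"
    # GWO -> Jaya selection (desk-scale demo budget)
    population: int = 10
    gwo_iterations: int = 20
    jaya_iterations: int = 10
    # classification
    presets: tuple = ("narrow", "medium", "wide", "bilayered", "trilayered")
    compare_presets: tuple = ("wide", "narrow")
    protocol: str = "holdout:0.5"
    classifier_max_iter: int = 400
    alpha: float = 0.05
    # optional precomputed feature tables (skip simulate/train/extract)
    features_fv1: str | None = None
    features_fv2: str | None = None
    schema_version: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "presets", "compare_presets"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("stages", "presets", "compare_presets"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(len(_ALL_STAGES))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(_ALL_STAGES, children)}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages and return the consolidated report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    report: dict = {"seed": cfg.seed, "stages": list(cfg.stages),
                    "stage_seconds": {}, "dims": {}}
    t_start = time.perf_counter()

    def tick(stage, t0):
        dt = time.perf_counter() - t0
        report["stage_seconds"][stage] = round(dt, 2)
        logger.info("stage %-9s done in %.1fs", stage, dt)

    dataset = None
    labels = None
    fv1 = fv2 = None

    if "simulate" in cfg.stages:
        t0 = time.perf_counter()
        dataset = make_modality_images(cfg.n_per_class, cfg.image_size,
                                       cfg.image_size, seed=seeds["simulate"])
        labels = dataset.labels
        report["dims"]["n_images"] = int(len(dataset.images))
        tick("simulate", t0)

    resnet = sae = None
    if "train" in cfg.stages:
        if dataset is None:
            raise ValueError("the train stage needs the simulate stage "
                             "(or supply precomputed feature tables)")
        t0 = time.perf_counter()
        resnet = ResNetFeatureExtractor(
            width_scale=cfg.width_scale, max_epochs=cfg.resnet_epochs,
            minibatch=cfg.minibatch, learning_rate=cfg.resnet_lr,
            random_state=seeds["train"])
        resnet.fit(dataset, labels.labels)
        sae = SAEFeatureExtractor(
            feature_dim=cfg.feature_dim, max_epochs=cfg.sae_epochs,
            minibatch=cfg.minibatch, learning_rate=cfg.sae_lr,
            random_state=seeds["train"])
        sae.fit(dataset)
        resnet.model_.save(out / "resnet_model")
        sae.model_.save(out / "sae_model")
        report["train"] = {
            "resnet_final_accuracy": resnet.history_[-1]["accuracy"],
            "sae_final_loss": sae.history_[-1]["loss"],
        }
        tick("train", t0)

    if "extract" in cfg.stages:
        t0 = time.perf_counter()
        if resnet is not None:
            from .features import extract_features

            fv1 = extract_features(resnet.model_, dataset, tap="gap")
            fv2 = extract_features(sae.model_, dataset, tap="decoder_conv_last")
        elif cfg.features_fv1 and cfg.features_fv2:
            fv1, labels = load_features(cfg.features_fv1)
            fv2, _ = load_features(cfg.features_fv2)
        else:
            raise ValueError("extract stage needs trained models or "
                             "precomputed feature tables")
        save_features(fv1, labels, out / "fv1.csv")
        save_features(fv2, labels, out / "fv2.csv")
        report["dims"]["fv1_width"] = fv1.n_features
        report["dims"]["fv2_width"] = fv2.n_features
        tick("extract", t0)
    elif cfg.features_fv1 and cfg.features_fv2:
        fv1, labels = load_features(cfg.features_fv1)
        fv2, _ = load_features(cfg.features_fv2)
        report["dims"]["fv1_width"] = fv1.n_features
        report["dims"]["fv2_width"] = fv2.n_features

    fused = None
    if "fuse" in cfg.stages:
        if fv1 is None:
            raise ValueError("fuse stage needs extracted features")
        t0 = time.perf_counter()
        fused = fuse_features(fv1, fv2, FusionConfig(
            window=cfg.window, stride=cfg.stride, mode=cfg.mode))
        save_features(fused, labels, out / "fused.csv")
        report["dims"]["fused_width"] = fused.n_features
        tick("fuse", t0)

    selection = None
    selected = None
    if "select" in cfg.stages:
        if fused is None:
            raise ValueError("select stage needs fused features")
        t0 = time.perf_counter()
        selection = select_features(
            fused, labels,
            SelectionConfig(population=cfg.population,
                            gwo_iterations=cfg.gwo_iterations,
                            jaya_iterations=cfg.jaya_iterations),
            seed=seeds["select"])
        mask_doc = {
            "n_selected": int(selection.n_selected),
            "n_features": int(len(selection.mask)),
            "best_fitness": float(selection.best_fitness),
            "selected_columns": [fused.feature_names[i]
                                 for i in np.flatnonzero(selection.mask)],
            "mask": selection.mask.astype(int).tolist(),
            "seed": int(selection.seed),
        }
        (out / "mask.json").write_text(json.dumps(mask_doc, indent=1,
                                                  sort_keys=True))
        np.savetxt(out / "fitness_trace.csv",
                   np.asarray(selection.fitness_trace), header="best_fitness",
                   comments="")
        selected = FeatureMatrix(
            values=fused.values[:, selection.mask],
            feature_names=[fused.feature_names[i]
                           for i in np.flatnonzero(selection.mask)])
        save_features(selected, labels, out / "selected.csv")
        report["selection"] = {"n_selected": int(selection.n_selected),
                               "best_fitness": float(selection.best_fitness)}
        tick("select", t0)

    if "classify" in cfg.stages:
        if selected is None:
            raise ValueError("classify stage needs selected features")
        t0 = time.perf_counter()
        metrics = {}
        for name in cfg.presets:
            spec = make_classifier_preset(name,
                                          max_iterations=cfg.classifier_max_iter)
            rep = evaluate_classifier(selected, labels, spec,
                                      protocol=cfg.protocol,
                                      seed=seeds["classify"])
            metrics[name] = rep.to_dict()
        (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
        report["classification"] = {
            name: {"accuracy": m["accuracy"], "auc": m["auc"]}
            for name, m in metrics.items()}
        tick("classify", t0)

    if "explain" in cfg.stages:
        if resnet is None or dataset is None:
            logger.info("explain stage skipped: no trained CNN in this run")
        else:
            t0 = time.perf_counter()
            hm_dir = out / "heatmaps"
            hm_dir.mkdir(exist_ok=True)
            from .datasets import brain_mask

            mask = brain_mask(cfg.image_size, cfg.image_size)
            cam_layer = deepest_spatial_conv(resnet.model_.spec)
            inside = []
            for cls in range(labels.n_classes):
                idx = int(np.flatnonzero(labels.labels == cls)[0])
                hm = explain_image(resnet.model_, dataset.images[idx],
                                   layer=cam_layer)
                save_heatmap_overlay(dataset.images[idx], hm,
                                     hm_dir / f"class{cls}_img{idx}.png")
                up = hm.upsampled
                if up is not None and up.sum() > 0:
                    inside.append(float(up[mask].sum() / up.sum()))
            report["explain"] = {
                "n_heatmaps": labels.n_classes,
                "mean_mass_inside_brain": (float(np.mean(inside))
                                           if inside else None)}
            tick("explain", t0)

    if "ttest" in cfg.stages:
        stage_sets = [("resnet", fv1), ("sae", fv2), ("fused", fused),
                      ("selected", selected)]
        stage_sets = [(n, f) for n, f in stage_sets if f is not None]
        if len(stage_sets) >= 2 and len(cfg.compare_presets) == 2:
            t0 = time.perf_counter()
            acc = {p: [] for p in cfg.compare_presets}
            for _, feats in stage_sets:
                for p in cfg.compare_presets:
                    spec = make_classifier_preset(
                        p, max_iterations=cfg.classifier_max_iter)
                    rep = evaluate_classifier(feats, labels, spec,
                                              protocol=cfg.protocol,
                                              seed=seeds["ttest"])
                    acc[p].append(rep.accuracy)
            a, b = (acc[p] for p in cfg.compare_presets)
            try:
                tres = paired_difference_test(a, b, alpha=cfg.alpha)
                report["ttest"] = {"stages": [n for n, _ in stage_sets],
                                   "accuracies": acc, **tres.to_dict()}
            except ValueError as exc:      # identical accuracy differences
                report["ttest"] = {"stages": [n for n, _ in stage_sets],
                                   "accuracies": acc, "error": str(exc)}
            (out / "ttest.json").write_text(json.dumps(report["ttest"],
                                                       indent=1))
            tick("ttest", t0)

    report["total_seconds"] = round(time.perf_counter() - t_start, 2)
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
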