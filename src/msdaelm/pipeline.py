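"""End-to-end pipeline: simulate → train/extract → select → ELM → evaluate.

A :class:`PipelineConfig` captures every stage's knobs plus the ablation
switches that reproduce the method's structural variants:

* ``disable_mmd`` — train with α ≡ 0 (no distribution alignment);
* ``disable_ensemble`` — use a single sub-predictor instead of the average;
* ``solver`` — ELM output-weight solver (``pinv`` = no regularization,
  ``ridge_closed_form`` = regularized closed form, ``l1_coordinate_descent`` =
  sparse L1 weights);
* ``source_subset`` — train on a subset of the three sources (single- and
  double-source transfer variants).

One global seed fans out to per-stage seeds by fixed offsets so that each
stage is individually reproducible.  Every run writes its resolved config
next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import LabeledImageSet, write_feature_table
from .divergence import KernelSpec
from .elm import elm_fit_predict
from .errors import ConfigurationError
from .evaluation import confusion_metrics, roc_auc
from .network import (
    BackboneSpec,
    SpecificExtractorSpec,
    TrainingConfig,
    build_model,
    extract_deep_features,
    train,
)
from .selection import mrmr_select
from .synthetic import gen_image_domains, image_preset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "transfer_trial"]

_SEED_STRIDE = 1_000_003


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (int(global_seed) + _SEED_STRIDE * stage_index) % (2**31)


@dataclass
class PipelineConfig:
    # simulate
    preset: str = "shifted"
    image_size: int = 32
    n_source_per_class: int = 30
    n_target_train_per_class: int = 10
    n_target_test_per_class: int = 40
    # network
    stage_channels: tuple = (8, 16)
    specific_channels: tuple = (8, 8, 8)
    iterations: int = 150
    batch_size: int = 8
    alpha_mode: str = "progressive"
    theta: float = 10.0
    lr_common: float = 0.001
    lr_specific: float = 0.01
    bandwidth: float | str = "median"
    # ablations
    disable_mmd: bool = False
    disable_ensemble: bool = False
    source_subset: tuple | None = None  # 1-based source indices, e.g. (3,)
    # selection
    fraction: float = 0.10
    # elm
    hidden_size: int = 200
    activation: str = "sigmoid"
    beta: float = 0.05
    solver: str = "ridge_closed_form"
    # global
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        if d["source_subset"] is not None:
            d["source_subset"] = [int(i) for i in d["source_subset"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for k in ("stage_channels", "specific_channels"):
            if k in kwargs and kwargs[k] is not None:
                kwargs[k] = tuple(kwargs[k])
        if kwargs.get("source_subset") is not None:
            kwargs["source_subset"] = tuple(int(i) for i in kwargs["source_subset"])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def transfer_trial(
    seed: int,
    alpha_override: float | None = None,
    source_subset: tuple | None = None,
    iterations: int = 200,
    n_target_train_per_class: int = 3,
    n_target_test_per_class: int = 40,
    n_source_per_class: int = 30,
) -> float:
    """One trial of the transfer-benefit experiment; returns target test
    accuracy of the ensemble.

    Conditions: the ``transfer_benchmark`` image preset (clean, well-sampled
    sources; scarce, noisy target), 32×32 images, batch 8 per domain, the
    progressive α schedule (an ``alpha_override`` of 0 turns the alignment
    loss off), default learning rates.  Used for the "alignment on vs off"
    and "three sources vs one" directional comparisons.
    """
    template, source_specs = image_preset("transfer_benchmark",
                                          n_source_per_class)
    template = dataclasses.replace(
        template,
        n_per_class=n_target_train_per_class + n_target_test_per_class,
    )
    doms = gen_image_domains(template, source_specs, 32, seed)
    target_all, sources = doms[0], doms[1:]
    if source_subset is not None:
        sources = [sources[i - 1] for i in source_subset]
    target_train, target_test = _split_target(target_all,
                                              n_target_train_per_class)
    model = build_model(BackboneSpec(input_shape=(1, 32, 32)),
                        SpecificExtractorSpec(), n_sources=len(sources),
                        seed=seed + 100)
    cfg = TrainingConfig(batch_size=8, iterations=iterations,
                         alpha_mode="progressive",
                         alpha_override=alpha_override, seed=seed + 100)
    train(model, sources, target_train, cfg)
    pred = model.predict(target_test.images)
    return float((pred.averaged.argmax(axis=1) == target_test.labels).mean())


def _split_target(target: LabeledImageSet, n_train_per_class: int
                  ) -> tuple[LabeledImageSet, LabeledImageSet]:
    tr_idx, te_idx = [], []
    for l in target.classes:
        idx = np.flatnonzero(target.labels == l)
        tr_idx.append(idx[:n_train_per_class])
        te_idx.append(idx[n_train_per_class:])
    tr = np.concatenate(tr_idx)
    te = np.concatenate(te_idx)
    return (
        LabeledImageSet(target.images[tr], target.labels[tr], target.domain_id),
        LabeledImageSet(target.images[te], target.labels[te],
                        target.domain_id + "_test"),
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run all stages; returns a result dict and (optionally) writes artifacts.

    Result keys: ``report`` (evaluation dict), ``history`` (training
    history), ``selection`` (selected indices), ``mu_running_mean``.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "resolved_config.yaml")

    # --- simulate -----------------------------------------------------
    sim_seed = stage_seed(config.seed, 0)
    template, source_specs = image_preset(config.preset, config.n_source_per_class)
    n_target = config.n_target_train_per_class + config.n_target_test_per_class
    template = dataclasses.replace(template, n_per_class=n_target)
    domains = gen_image_domains(template, source_specs, config.image_size, sim_seed)
    target_all, sources = domains[0], domains[1:]
    if config.source_subset is not None:
        sources = [sources[i - 1] for i in config.source_subset]
    target_train, target_test = _split_target(
        target_all, config.n_target_train_per_class
    )
    logger.info("simulate: preset=%s sources=%s target train/test=%d/%d",
                config.preset, [s.domain_id for s in sources],
                target_train.n_samples, target_test.n_samples)

    # --- train + extract ----------------------------------------------
    net_seed = stage_seed(config.seed, 1)
    backbone = BackboneSpec(input_shape=(1, config.image_size, config.image_size),
                            stage_channels=tuple(config.stage_channels))
    model = build_model(backbone,
                        SpecificExtractorSpec(tuple(config.specific_channels)),
                        n_sources=len(sources), seed=net_seed)
    cfg = TrainingConfig(
        lr_common=config.lr_common, lr_specific=config.lr_specific,
        batch_size=config.batch_size, iterations=config.iterations,
        theta=config.theta, alpha_mode=config.alpha_mode,
        alpha_override=0.0 if config.disable_mmd else None,
        ensemble=not config.disable_ensemble, seed=net_seed,
    )
    spec = KernelSpec(bandwidth=config.bandwidth)
    history = train(model, sources, target_train, cfg, spec)
    for it, lb in enumerate(history.losses):
        if it % max(1, config.iterations // 10) == 0:
            mus = [r.mu for r in history.divergences[it]]
            logger.info("train: iter=%d l_total=%.4f l_task=%.4f l_mmd=%.4f "
                        "alpha=%.3f mu=%s", it, lb.l_total, lb.l_task, lb.l_mmd,
                        lb.alpha, np.round(mus, 3).tolist())

    feats_train = extract_deep_features(model, target_train)
    feats_test = extract_deep_features(model, target_test)

    # --- select ---------------------------------------------------------
    selection = mrmr_select(feats_train, fraction=config.fraction)
    sel_train = selection.apply(feats_train)
    sel_test = selection.apply(feats_test)
    logger.info("select: kept %d/%d features", len(selection.selected_indices),
                feats_train.n_features)

    # --- elm + evaluate -------------------------------------------------
    elm_seed = stage_seed(config.seed, 2)
    scores, predicted, elm_model = elm_fit_predict(
        sel_train, sel_test, L=config.hidden_size,
        activation=config.activation, beta=config.beta,
        solver=config.solver, seed=elm_seed,
    )
    report = confusion_metrics(target_test.labels, predicted)
    report.auc, report.roc_points = roc_auc(target_test.labels, scores[:, 1])
    logger.info("evaluate: acc=%.3f auc=%.3f f1=%.3f",
                report.acc, report.auc, report.f1)

    if out is not None:
        write_feature_table(feats_train, out / "features_target_train.csv")
        write_feature_table(feats_test, out / "features_target_test.csv")
        pd.DataFrame(
            [{"iteration": i, "l_mmd": lb.l_mmd, "l_task": lb.l_task,
              "alpha": lb.alpha, "l_total": lb.l_total,
              **{f"mu_pair{j}": r.mu
                 for j, r in enumerate(history.divergences[i])}}
             for i, lb in enumerate(history.losses)]
        ).to_csv(out / "loss_history.csv", index=False)
        pd.DataFrame({
            "step": range(len(selection.selected_indices)),
            "index": selection.selected_indices,
            "name": [feats_train.feature_names[i]
                     for i in selection.selected_indices],
            "score": selection.scores,
        }).to_csv(out / "selection.csv", index=False)
        pd.DataFrame({
            "id": range(target_test.n_samples),
            "true_label": target_test.labels,
            "score": scores[:, 1],
            "predicted": predicted,
        }).to_csv(out / "scores.csv", index=False)
        (out / "evaluation.json").write_text(
            json.dumps(report.to_dict(), indent=2)
        )

    return {
        "report": report,
        "history": history,
        "selection": selection,
        "mu_running_mean": history.mu_running_mean,
        "model": model,
        "elm_model": elm_model,
    }
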