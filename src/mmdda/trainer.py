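"""Two-phase adversarial training protocol and ablation variants.

Phase 1 trains the source-domain path alone (correlation loss + category
classification loss).  The trained source weights are then shared with the
target-domain branches, and phase 2 trains both domains jointly on the full
objective: both correlation losses, the source/target fused-feature
consistency loss, the classification loss, and the domain-discrimination
loss flowing through the gradient-reversal layer.  Target labels are never
read at any point.

Reference settings: 150 + 50 epochs, Adam (betas 0.9/0.999) at learning
rate 9e-7, batch size 1.  Everything scales down by configuration for
desk-size experiments.

Per-epoch randomness (sample order, dropout masks) is derived from
``(seed, phase, epoch)``, so a run checkpointed and resumed mid-way follows
the same trajectory as an uninterrupted one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autograd import Tensor
from . import objectives

__all__ = ["TrainConfig", "Adam", "train_phase1", "train_phase2",
           "share_weights", "train", "run_variant", "VARIANTS"]

#: ablation variants: MRI-only / plain concat fusion / attention fusion
#: without correlation loss / the full model
VARIANTS = ("SDA", "MSDA", "M3HF", "MMDDA")


@dataclass(frozen=True)
class TrainConfig:
    epochs_phase1: int = 150
    epochs_phase2: int = 50
    learning_rate: float = 9e-7
    betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 1
    seed: int = 0
    freeze_target_bn: bool = False

    @property
    def epochs_total(self) -> int:
        return self.epochs_phase1 + self.epochs_phase2

    def __post_init__(self) -> None:
        if self.epochs_phase1 < 0 or self.epochs_phase2 < 0:
            raise ValueError("epoch counts must be non-negative")
        if self.batch_size != 1:
            raise ValueError("only batch size 1 is supported (the reference setting)")


def desk_train_config(epochs_phase1: int = 3, epochs_phase2: int = 2,
                      learning_rate: float = 1e-3, seed: int = 0) -> TrainConfig:
    """A small-scale configuration for synthetic experiments and tests."""
    return TrainConfig(epochs_phase1=epochs_phase1, epochs_phase2=epochs_phase2,
                       learning_rate=learning_rate, seed=seed)


class Adam(object):
    """Adam optimizer over named parameters; skips parameters without a
    gradient so one optimizer can span both training phases."""

    def __init__(self, named_params: list[tuple[str, Tensor]], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = dict(named_params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.t = {k: 0 for k in self.params}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        for key, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient for parameter {key!r}")
            self.t[key] += 1
            t = self.t[key]
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g ** 2
            m_hat = self.m[key] / (1 - self.beta1 ** t)
            v_hat = self.v[key] / (1 - self.beta2 ** t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def state_dict(self) -> dict:
        return {"m": {k: v.copy() for k, v in self.m.items()},
                "v": {k: v.copy() for k, v in self.v.items()},
                "t": dict(self.t)}

    def load_state_dict(self, state: dict) -> None:
        self.m = {k: np.array(v) for k, v in state["m"].items()}
        self.v = {k: np.array(v) for k, v in state["v"].items()}
        self.t = dict(state["t"])


def _epoch_rng(seed: int, phase: int, epoch: int) -> np.random.Generator:
    return np.random.default_rng([seed % (2 ** 31), phase, epoch])


def share_weights(model) -> None:
    """Copy source-branch encoder parameters (and batch-norm statistics)
    into the target branches; no aliasing, later target updates leave the
    source branches unchanged."""
    for modality in model.modalities:
        src = model.encoders[("source", modality)]
        tgt = model.encoders[("target", modality)]
        tgt.load_state_dict(src.state_dict())


def _phase1_step(model, sample, optimizer) -> objectives.LossBundle:
    optimizer.zero_grad()
    fused, flat_mri, flat_pet = model.forward_features([sample], "source")
    losses = {}
    w = model.loss_weights
    if w.cor_s != 0.0 and flat_pet is not None:
        losses["cor_s"] = objectives.correlation_loss(flat_mri, flat_pet,
                                                      model.kernel_config) * w.cor_s
    probs = model.classifier(fused)
    losses["cls"] = objectives.classification_loss(probs, [sample.label]) * w.cls
    total = sum(losses.values(), Tensor(0.0))
    bundle = objectives.total_loss(**{k: float(v.data) for k, v in losses.items()})
    total.backward()
    optimizer.step()
    return bundle


def _phase2_step(model, s_sample, t_sample, optimizer) -> objectives.LossBundle:
    optimizer.zero_grad()
    fused_s, mri_s, pet_s = model.forward_features([s_sample], "source")
    fused_t, mri_t, pet_t = model.forward_features([t_sample], "target")
    w = model.loss_weights
    losses = {}
    if w.cor_s != 0.0 and pet_s is not None:
        losses["cor_s"] = objectives.correlation_loss(mri_s, pet_s,
                                                      model.kernel_config) * w.cor_s
    if w.cor_t != 0.0 and pet_t is not None:
        losses["cor_t"] = objectives.correlation_loss(mri_t, pet_t,
                                                      model.kernel_config) * w.cor_t
    losses["mse"] = objectives.consistency_loss(fused_s, fused_t) * w.mse
    probs = model.classifier(fused_s)
    losses["cls"] = objectives.classification_loss(probs, [s_sample.label]) * w.cls
    dom_probs, indicators = model.discriminator.discriminate(fused_s, fused_t)
    losses["dom"] = objectives.domain_loss(dom_probs, indicators) * w.dom
    total = sum(losses.values(), Tensor(0.0))
    bundle = objectives.total_loss(**{k: float(v.data) for k, v in losses.items()})
    total.backward()
    optimizer.step()
    return bundle


def _mean_bundle(bundles: list[objectives.LossBundle]) -> dict[str, float]:
    frame = pd.DataFrame([b.as_dict() for b in bundles])
    return frame.mean().to_dict()


def _run_phase1_epoch(model, source, config, epoch, optimizer) -> dict[str, float]:
    rng = _epoch_rng(config.seed, 1, epoch)
    model.set_training(True)
    model.set_dropout_rng(_epoch_rng(config.seed, 7, epoch))
    order = rng.permutation(len(source))
    bundles = []
    for idx in order:
        try:
            bundles.append(_phase1_step(model, source[idx], optimizer))
        except FloatingPointError as exc:
            raise FloatingPointError(f"phase 1, epoch {epoch}: {exc}") from exc
    return _mean_bundle(bundles)


def _run_phase2_epoch(model, source, target, config, epoch, optimizer) -> dict[str, float]:
    rng = _epoch_rng(config.seed, 2, epoch)
    model.set_training(True, freeze_target_bn=config.freeze_target_bn)
    model.set_dropout_rng(_epoch_rng(config.seed, 7, 10_000 + epoch))
    s_order = rng.permutation(len(source))
    t_order = rng.permutation(len(target))
    steps = max(len(source), len(target))
    bundles = []
    for i in range(steps):  # cycle the shorter list
        s = source[s_order[i % len(source)]]
        t = target[t_order[i % len(target)]]
        try:
            bundles.append(_phase2_step(model, s, t, optimizer))
        except FloatingPointError as exc:
            raise FloatingPointError(f"phase 2, epoch {epoch}: {exc}") from exc
    return _mean_bundle(bundles)


def train_phase1(model, source, config: TrainConfig, optimizer: Adam | None = None,
                 epochs: int | None = None) -> pd.DataFrame:
    """Train the source path alone; returns the per-epoch loss history."""
    if not source:
        raise ValueError("phase 1 needs labeled source samples")
    optimizer = optimizer or Adam(list(model.named_parameters()),
                                  config.learning_rate, config.betas)
    rows = []
    for epoch in range(epochs if epochs is not None else config.epochs_phase1):
        row = _run_phase1_epoch(model, source, config, epoch, optimizer)
        rows.append({"phase": 1, "epoch": epoch, **row})
    return pd.DataFrame(rows)


def train_phase2(model, source, target, config: TrainConfig,
                 optimizer: Adam | None = None,
                 epochs: int | None = None) -> pd.DataFrame:
    """Joint source+target training on the full objective (after weight
    sharing); target labels are never read."""
    if not source or not target:
        raise ValueError("phase 2 needs both source and target samples")
    optimizer = optimizer or Adam(list(model.named_parameters()),
                                  config.learning_rate, config.betas)
    rows = []
    for epoch in range(epochs if epochs is not None else config.epochs_phase2):
        row = _run_phase2_epoch(model, source, target, config, epoch, optimizer)
        rows.append({"phase": 2, "epoch": epoch, **row})
    return pd.DataFrame(rows)


def train(model, source, target, config: TrainConfig, state: dict | None = None,
          stop_after_epoch: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Run the full two-phase protocol, resumable from a saved state.

    ``state`` carries the next epoch index, whether weights have been shared,
    and the optimizer moments; stopping at ``stop_after_epoch`` and resuming
    from the returned state reproduces the uninterrupted trajectory exactly.
    """
    optimizer = Adam(list(model.named_parameters()), config.learning_rate, config.betas)
    start_epoch, shared = 0, False
    if state is not None:
        start_epoch = state["epoch"]
        shared = state["shared"]
        optimizer.load_state_dict(state["optimizer"])
    rows = []
    end = config.epochs_total if stop_after_epoch is None else min(
        stop_after_epoch, config.epochs_total)
    for epoch in range(start_epoch, end):
        if epoch >= config.epochs_phase1 and not shared:
            share_weights(model)
            shared = True
        if epoch < config.epochs_phase1:
            row = _run_phase1_epoch(model, source, config, epoch, optimizer)
            rows.append({"phase": 1, "epoch": epoch, **row})
        else:
            row = _run_phase2_epoch(model, source, target, config,
                                    epoch - config.epochs_phase1, optimizer)
            rows.append({"phase": 2, "epoch": epoch - config.epochs_phase1, **row})
    if end >= config.epochs_phase1 and not shared and config.epochs_phase2 == 0:
        share_weights(model)
        shared = True
    new_state = {"epoch": end, "shared": shared, "optimizer": optimizer.state_dict()}
    return pd.DataFrame(rows), new_state


def run_variant(variant: str, samples, heads: int = 4, encoder_config=None,
                train_config: TrainConfig | None = None, head_config=None,
                kernel_config=None, fusion_reduce: str = "mean"):
    """Train one ablation variant on a mixed source/target sample collection
    and return the metric report on the target domain."""
    from .model import MMDDA  # local import: model builds on this module

    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    source = [s for s in samples if s.domain == "source"]
    target = [s for s in samples if s.domain == "target"]
    config = train_config or desk_train_config()
    model = MMDDA(source, target, variant=variant, heads=heads,
                  encoder_config=encoder_config, head_config=head_config,
                  kernel_config=kernel_config, fusion_reduce=fusion_reduce,
                  seed=config.seed)
    results = model.fit(config)
    return results.target_report
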