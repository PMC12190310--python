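"""The multi-modal domain-adaptation model and its fitted results.

:class:`MMDDA` is built from source-domain (labeled) and target-domain
(unlabeled) subject samples plus the architectural configuration;
:meth:`MMDDA.fit` runs the two-phase adversarial protocol and returns an
:class:`AdaptationResults` carrying the loss history, source- and
target-domain metric reports, and a ``summary()`` table.

Ablation variants select how much of the pipeline is active:

========  =========================================================
variant   pipeline
========  =========================================================
SDA       MRI only; flattened encoder features -> heads
MSDA      MRI+PET; plain concatenation of flattened features
M3HF      MRI+PET; multi-head attention fusion, no correlation loss
MMDDA     full model: attention fusion + cross-modal correlation
========  =========================================================

All variants share the adversarial domain-transfer stage.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._autograd import Tensor, concatenate
from . import trainer
from .encoder3d import Encoder3D, EncoderConfig, feature_dim
from .evaluation import MetricReport
from .fusion import MultiHeadAttention, concat_reshape, flatten_fused
from .heads import ClassifierHead, DomainDiscriminator, HeadConfig
from .objectives import KernelConfig, LossWeights
from .synthetic import SubjectSample

__all__ = ["MMDDA", "AdaptationResults"]


class MMDDA:
    """Multi-modal deep domain-adaptation classifier.

    Parameters
    ----------
    source_samples, target_samples
        Labeled source-domain and unlabeled target-domain subjects; all
        volumes must share one spatial shape.
    variant
        One of ``SDA``, ``MSDA``, ``M3HF``, ``MMDDA``.
    heads
        Attention head count (must divide the fused feature width E = 2C).
    seed
        Seeds the parameter initialisation.
    """

    def __init__(self, source_samples: list[SubjectSample],
                 target_samples: list[SubjectSample], variant: str = "MMDDA",
                 heads: int = 4, encoder_config: EncoderConfig | None = None,
                 head_config: HeadConfig | None = None,
                 kernel_config: KernelConfig | None = None,
                 fusion_reduce: str = "mean", seed: int = 0) -> None:
        if variant not in trainer.VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        if not source_samples:
            raise ValueError("at least one labeled source sample is required")
        self.variant = variant
        self.source_samples = list(source_samples)
        self.target_samples = list(target_samples)
        self.encoder_config = encoder_config or EncoderConfig()
        self.head_config = head_config or HeadConfig()
        self.kernel_config = kernel_config or KernelConfig()
        self.fusion_reduce = fusion_reduce
        self.heads = heads
        self.seed = int(seed)
        self.input_shape = tuple(source_samples[0].mri.shape)
        for s in self.source_samples + self.target_samples:
            if tuple(s.mri.shape) != self.input_shape:
                raise ValueError(f"{s.subject_id}: volume shape {s.mri.shape} "
                                 f"differs from {self.input_shape}")

        self.modalities = ("mri",) if variant == "SDA" else ("mri", "pet")
        rng = np.random.default_rng([self.seed % (2 ** 31), 11])
        self.encoders: dict[tuple[str, str], Encoder3D] = {}
        for domain in ("source", "target"):
            for modality in self.modalities:
                self.encoders[(domain, modality)] = Encoder3D(
                    self.encoder_config, self.input_shape, rng)

        flat = feature_dim(self.encoder_config, self.input_shape)
        c_last = self.encoder_config.channels[-1]
        spatial = flat // c_last
        self.attention: MultiHeadAttention | None = None
        if variant == "SDA":
            self.fused_dim = flat
        elif variant == "MSDA":
            self.fused_dim = 2 * flat
        else:
            embed = 2 * c_last
            self.attention = MultiHeadAttention(embed, heads, rng)
            self.fused_dim = embed if fusion_reduce == "mean" else spatial * embed
        self.classifier = ClassifierHead(self.fused_dim, self.head_config, rng)
        self.discriminator = DomainDiscriminator(self.fused_dim, self.head_config, rng)
        # correlation terms only exist in the full model (and need 2 modalities)
        cor = 1.0 if variant == "MMDDA" else 0.0
        self.loss_weights = LossWeights(cor_s=cor, cor_t=cor)

    # ------------------------------------------------------------------ plumbing
    def _modules(self) -> dict[str, object]:
        mods: dict[str, object] = {}
        for (domain, modality), enc in self.encoders.items():
            mods[f"encoder.{domain}.{modality}"] = enc
        if self.attention is not None:
            mods["attention"] = self.attention
        mods["classifier"] = self.classifier
        mods["discriminator"] = self.discriminator
        return mods

    def named_parameters(self):
        for name, module in self._modules().items():
            yield from module.named_parameters(f"{name}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for name, module in self._modules().items():
            for key, arr in module.state_dict().items():
                state[f"{name}.{key}"] = arr
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, module in self._modules().items():
            prefix = f"{name}."
            sub = {k[len(prefix):]: v for k, v in state.items() if k.startswith(prefix)}
            module.load_state_dict(sub)

    def set_training(self, training: bool, freeze_target_bn: bool = False) -> None:
        for name, module in self._modules().items():
            module.train() if training else module.eval()
        if training and freeze_target_bn:
            for modality in self.modalities:
                for norm in self.encoders[("target", modality)].norms:
                    norm.eval()

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        self.classifier.set_dropout_rng(rng)
        self.discriminator.set_dropout_rng(rng)

    # ------------------------------------------------------------------ forward
    def forward_features(self, samples: list[SubjectSample], domain: str
                         ) -> tuple[Tensor, Tensor, Tensor | None]:
        """Fused feature batch plus flattened per-modality encoder features."""
        from .encoder3d import flatten_features

        mri = Tensor(np.stack([s.mri for s in samples]).astype(np.float64))
        fm = self.encoders[(domain, "mri")](mri)
        flat_mri = flatten_features(fm)
        if self.variant == "SDA":
            return flat_mri, flat_mri, None
        pet = Tensor(np.stack([s.pet for s in samples]).astype(np.float64))
        fp = self.encoders[(domain, "pet")](pet)
        flat_pet = flatten_features(fp)
        if self.variant == "MSDA":
            return concatenate([flat_mri, flat_pet], axis=1), flat_mri, flat_pet
        seq = concat_reshape(fm, fp)
        attn = self.attention(seq)
        return flatten_fused(attn, self.fusion_reduce), flat_mri, flat_pet

    def predict_proba(self, samples: list[SubjectSample]) -> np.ndarray:
        """Positive-class probability per sample (eval mode; each sample is
        routed through the encoder branch of its own domain)."""
        self.set_training(False)
        probs = np.empty(len(samples))
        for i, s in enumerate(samples):
            fused, _, _ = self.forward_features([s], s.domain)
            probs[i] = self.classifier(fused).data[0, 1]
        return probs

    def predict(self, samples: list[SubjectSample], threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(samples) >= threshold).astype(int)

    def evaluate(self, samples: list[SubjectSample]) -> MetricReport:
        labels = [s.label for s in samples]
        if any(l is None for l in labels):
            raise ValueError("evaluation needs labeled samples")
        return MetricReport.from_scores(np.asarray(labels, dtype=int),
                                        self.predict_proba(samples))

    # ---------------------------------------------------------------------- fit
    def fit(self, train_config: trainer.TrainConfig | None = None,
            state: dict | None = None,
            stop_after_epoch: int | None = None) -> "AdaptationResults":
        """Run the two-phase protocol and evaluate on both domains."""
        config = train_config or trainer.TrainConfig(seed=self.seed)
        history, state = trainer.train(self, self.source_samples,
                                       self.target_samples, config,
                                       state=state, stop_after_epoch=stop_after_epoch)
        source_report = self.evaluate(self.source_samples)
        target_report = (self.evaluate(self.target_samples)
                         if self.target_samples and
                         all(s.label is not None for s in self.target_samples)
                         else None)
        return AdaptationResults(self, config, history, source_report,
                                 target_report, state)

    # -------------------------------------------------------------- persistence
    def save_checkpoint(self, path: str | Path, state: dict | None = None) -> None:
        """Write all parameters, configuration and optional training state."""
        path = Path(path)
        arrays = {f"param::{k}": v for k, v in self.state_dict().items()}
        if state is not None:
            arrays.update({f"adam_m::{k}": v for k, v in state["optimizer"]["m"].items()})
            arrays.update({f"adam_v::{k}": v for k, v in state["optimizer"]["v"].items()})
        meta = {"variant": self.variant, "heads": self.heads, "seed": self.seed,
                "input_shape": list(self.input_shape),
                "fusion_reduce": self.fusion_reduce,
                "encoder": {"channels": list(self.encoder_config.channels),
                            "kernel": self.encoder_config.kernel,
                            "pool_after": sorted(self.encoder_config.pool_after),
                            "leaky_slope": self.encoder_config.leaky_slope,
                            "batch_norm": self.encoder_config.batch_norm},
                "head": {"layer_units": list(self.head_config.layer_units),
                         "dropout_rate": self.head_config.dropout_rate,
                         "grl_weight": self.head_config.grl_weight},
                "kernel": {"sigma": self.kernel_config.sigma,
                           "epsilon": self.kernel_config.epsilon}}
        if state is not None:
            meta["train_state"] = {"epoch": state["epoch"], "shared": state["shared"],
                                   "adam_t": state["optimizer"]["t"]}
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load_checkpoint(cls, path: str | Path, source_samples, target_samples
                        ) -> tuple["MMDDA", dict | None]:
        """Rebuild a model (and resumable training state) from a checkpoint."""
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            arrays = {k: data[k] for k in data.files if k != "meta"}
        enc = meta["encoder"]
        model = cls(source_samples, target_samples, variant=meta["variant"],
                    heads=meta["heads"],
                    encoder_config=EncoderConfig(
                        channels=tuple(enc["channels"]), kernel=enc["kernel"],
                        pool_after=frozenset(enc["pool_after"]),
                        leaky_slope=enc["leaky_slope"], batch_norm=enc["batch_norm"]),
                    head_config=HeadConfig(
                        layer_units=tuple(meta["head"]["layer_units"]),
                        dropout_rate=meta["head"]["dropout_rate"],
                        grl_weight=meta["head"]["grl_weight"]),
                    kernel_config=KernelConfig(sigma=meta["kernel"]["sigma"],
                                               epsilon=meta["kernel"]["epsilon"]),
                    fusion_reduce=meta["fusion_reduce"], seed=meta["seed"])
        if tuple(meta["input_shape"]) != model.input_shape:
            raise ValueError(f"checkpoint built for volumes {meta['input_shape']}, "
                             f"samples have {model.input_shape}")
        model.load_state_dict({k[len("param::"):]: v for k, v in arrays.items()
                               if k.startswith("param::")})
        state = None
        if "train_state" in meta:
            state = {"epoch": meta["train_state"]["epoch"],
                     "shared": meta["train_state"]["shared"],
                     "optimizer": {
                         "m": {k[len("adam_m::"):]: v for k, v in arrays.items()
                               if k.startswith("adam_m::")},
                         "v": {k[len("adam_v::"):]: v for k, v in arrays.items()
                               if k.startswith("adam_v::")},
                         "t": meta["train_state"]["adam_t"]}}
        return model, state


class AdaptationResults:
    """Fit artifacts: loss history, per-domain metric reports, summary."""

    def __init__(self, model: MMDDA, train_config: trainer.TrainConfig,
                 loss_history: pd.DataFrame, source_report: MetricReport,
                 target_report: MetricReport | None, train_state: dict) -> None:
        self.model = model
        self.train_config = train_config
        self.loss_history = loss_history
        self.source_report = source_report
        self.target_report = target_report
        self.train_state = train_state

    def summary(self) -> str:
        lines = [
            "Multi-modal domain adaptation fit",
            "=" * 48,
            f"variant:          {self.model.variant}",
            f"attention heads:  {self.model.heads if self.model.attention else '-'}",
            f"fused dimension:  {self.model.fused_dim}",
            f"volume shape:     {self.model.input_shape}",
            f"epochs:           {self.train_config.epochs_phase1} (phase 1) + "
            f"{self.train_config.epochs_phase2} (phase 2)",
            f"learning rate:    {self.train_config.learning_rate:g}",
            f"seed:             {self.train_config.seed}",
            "-" * 48,
        ]

        def fmt(value):
            return "undefined" if value is None else f"{value:.4f}"

        for name, report in (("source", self.source_report),
                             ("target", self.target_report)):
            if report is None:
                continue
            lines.append(f"{name} domain (n={report.n}):")
            lines.append(f"  ACC {fmt(report.acc)}  SEN {fmt(report.sen)}  "
                         f"SPE {fmt(report.spe)}  AUC {fmt(report.auc)}  "
                         f"F1 {fmt(report.f1)}")
        if len(self.loss_history):
            last = self.loss_history.iloc[-1]
            lines.append("-" * 48)
            lines.append(f"final epoch losses: total {last['total']:.4f} "
                         f"(cor_s {last['cor_s']:.4f}, cor_t {last['cor_t']:.4f}, "
                         f"mse {last['mse']:.4f}, cls {last['cls']:.4f}, "
                         f"dom {last['dom']:.4f})")
        return "\n".join(lines)

    def plot_losses(self, ax=None):
        """Per-epoch loss components; phases are separated by a vertical line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        hist = self.loss_history.reset_index(drop=True)
        for column in ("cor_s", "cor_t", "mse", "cls", "dom", "total"):
            ax.plot(hist.index, hist[column], label=column)
        boundary = (hist["phase"] == 1).sum()
        if 0 < boundary < len(hist):
            ax.axvline(boundary - 0.5, color="grey", linestyle="--", linewidth=1)
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.legend(loc="best", fontsize=8)
        return ax
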