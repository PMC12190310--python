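"""YAML run configuration covering every tunable of the pipeline.

One file drives `mmdda simulate/train/evaluate/ablate/sweep-heads`; a saved
run's config re-executes identically.  Every section is optional and falls
back to the documented defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .encoder3d import EncoderConfig
from .fusion import FusionConfig
from .heads import HeadConfig
from .objectives import KernelConfig, LossWeights
from .synthetic import SyntheticConfig
from .trainer import TrainConfig

__all__ = ["RunConfig", "load_run_config"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/run"
    variant: str = "MMDDA"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    loss_weights: LossWeights = field(default_factory=LossWeights)
    heads: HeadConfig = field(default_factory=HeadConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "variant": self.variant,
            "synthetic": {
                "volume_shape": list(self.synthetic.volume_shape),
                "n_per_class_source": self.synthetic.n_per_class_source,
                "n_per_class_target": self.synthetic.n_per_class_target,
                "class_effect": self.synthetic.class_effect,
                "modality_balance": self.synthetic.modality_balance,
                "modality_correlation": self.synthetic.modality_correlation,
                "shift_gain": self.synthetic.shift_gain,
                "shift_smooth": self.synthetic.shift_smooth,
                "bias_amplitude": self.synthetic.bias_amplitude,
                "noise_sd": self.synthetic.noise_sd,
                "seed": self.synthetic.seed,
            },
            "encoder": {
                "channels": list(self.encoder.channels),
                "kernel": self.encoder.kernel,
                "pool_after": sorted(self.encoder.pool_after),
                "leaky_slope": self.encoder.leaky_slope,
                "batch_norm": self.encoder.batch_norm,
            },
            "fusion": {"heads": self.fusion.heads, "reduce": self.fusion.reduce},
            "loss": {
                "sigma": self.kernel.sigma,
                "epsilon": self.kernel.epsilon,
                "weights": {
                    "cor_s": self.loss_weights.cor_s,
                    "cor_t": self.loss_weights.cor_t,
                    "mse": self.loss_weights.mse,
                    "cls": self.loss_weights.cls,
                    "dom": self.loss_weights.dom,
                },
            },
            "heads": {
                "units": list(self.heads.layer_units),
                "dropout": self.heads.dropout_rate,
                "grl_weight": self.heads.grl_weight,
            },
            "train": {
                "epochs_phase1": self.train.epochs_phase1,
                "epochs_phase2": self.train.epochs_phase2,
                "learning_rate": self.train.learning_rate,
                "betas": list(self.train.betas),
                "batch_size": self.train.batch_size,
                "seed": self.train.seed,
                "freeze_target_bn": self.train.freeze_target_bn,
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        syn = raw.get("synthetic", {})
        enc = raw.get("encoder", {})
        fus = raw.get("fusion", {})
        loss = raw.get("loss", {})
        weights = loss.get("weights", {})
        hd = raw.get("heads", {})
        tr = raw.get("train", {})
        defaults = cls()
        return cls(
            seed=raw.get("seed", 0),
            out_dir=raw.get("out_dir", "runs/run"),
            variant=raw.get("variant", "MMDDA"),
            synthetic=SyntheticConfig(
                volume_shape=tuple(syn.get("volume_shape",
                                           defaults.synthetic.volume_shape)),
                n_per_class_source=syn.get("n_per_class_source",
                                           defaults.synthetic.n_per_class_source),
                n_per_class_target=syn.get("n_per_class_target",
                                           defaults.synthetic.n_per_class_target),
                class_effect=syn.get("class_effect", defaults.synthetic.class_effect),
                modality_balance=syn.get("modality_balance",
                                         defaults.synthetic.modality_balance),
                modality_correlation=syn.get("modality_correlation",
                                             defaults.synthetic.modality_correlation),
                shift_gain=syn.get("shift_gain", defaults.synthetic.shift_gain),
                shift_smooth=syn.get("shift_smooth", defaults.synthetic.shift_smooth),
                bias_amplitude=syn.get("bias_amplitude",
                                       defaults.synthetic.bias_amplitude),
                noise_sd=syn.get("noise_sd", defaults.synthetic.noise_sd),
                seed=syn.get("seed", raw.get("seed", 0))),
            encoder=EncoderConfig(
                channels=tuple(enc.get("channels", defaults.encoder.channels)),
                kernel=enc.get("kernel", defaults.encoder.kernel),
                pool_after=frozenset(enc.get("pool_after",
                                             defaults.encoder.pool_after)),
                leaky_slope=enc.get("leaky_slope", defaults.encoder.leaky_slope),
                batch_norm=enc.get("batch_norm", defaults.encoder.batch_norm)),
            fusion=FusionConfig(heads=fus.get("heads", defaults.fusion.heads),
                                reduce=fus.get("reduce", defaults.fusion.reduce)),
            kernel=KernelConfig(sigma=loss.get("sigma", defaults.kernel.sigma),
                                epsilon=loss.get("epsilon", defaults.kernel.epsilon)),
            loss_weights=LossWeights(
                cor_s=weights.get("cor_s", 1.0), cor_t=weights.get("cor_t", 1.0),
                mse=weights.get("mse", 1.0), cls=weights.get("cls", 1.0),
                dom=weights.get("dom", 1.0)),
            heads=HeadConfig(
                layer_units=tuple(hd.get("units", defaults.heads.layer_units)),
                dropout_rate=hd.get("dropout", defaults.heads.dropout_rate),
                grl_weight=hd.get("grl_weight", defaults.heads.grl_weight)),
            train=TrainConfig(
                epochs_phase1=tr.get("epochs_phase1", defaults.train.epochs_phase1),
                epochs_phase2=tr.get("epochs_phase2", defaults.train.epochs_phase2),
                learning_rate=tr.get("learning_rate", defaults.train.learning_rate),
                betas=tuple(tr.get("betas", defaults.train.betas)),
                batch_size=tr.get("batch_size", defaults.train.batch_size),
                seed=tr.get("seed", raw.get("seed", 0)),
                freeze_target_bn=tr.get("freeze_target_bn",
                                        defaults.train.freeze_target_bn)))


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(raw)
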