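"""Loss functions of the adaptation objective.

The total objective is the unweighted sum

    L_total = L_cor^S + L_cor^T + L_mse + L_cls + L_dom

where L_cor is a cross-entropy-of-similarity loss on the Gaussian-kernel
Gram matrix between the flattened MRI and PET encoder features of a batch,
L_mse is the mean squared difference between source and target fused
vectors, and L_cls / L_dom are cross-entropy losses of the category
classifier and domain discriminator.

Note a structural property of the correlation term: for a single pair the
summand -K log(K + eps) vanishes both as K -> 1 (identical features) and as
K -> 0 (infinitely distant features), with its maximum near K = 1/e.  The
loss therefore penalises *intermediate* similarity rather than strictly
forcing alignment; it is implemented exactly as defined, and the property
is covered by tests rather than silently "fixed".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, as_tensor

__all__ = ["KernelConfig", "LossBundle", "gaussian_kernel", "kernel_gram",
           "correlation_loss", "consistency_loss", "classification_loss",
           "domain_loss", "total_loss", "LossWeights"]

_PROB_FLOOR = 1e-12  # keeps log finite on saturated softmax outputs


@dataclass(frozen=True)
class KernelConfig:
    """Gaussian kernel width ``sigma`` and log-guard ``epsilon``."""

    sigma: float = 1.0
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")


@dataclass(frozen=True)
class LossWeights:
    """Multipliers for the loss components; the model's objective uses 1.0
    for every term, and ablation variants zero individual terms."""

    cor_s: float = 1.0
    cor_t: float = 1.0
    mse: float = 1.0
    cls: float = 1.0
    dom: float = 1.0


@dataclass
class LossBundle:
    """Named scalar components and their sum for one optimisation step."""

    cor_s: float = 0.0
    cor_t: float = 0.0
    mse: float = 0.0
    cls: float = 0.0
    dom: float = 0.0

    @property
    def total(self) -> float:
        return self.cor_s + self.cor_t + self.mse + self.cls + self.dom

    def validate(self) -> "LossBundle":
        for name in ("cor_s", "cor_t", "mse", "cls", "dom"):
            if not np.isfinite(getattr(self, name)):
                raise FloatingPointError(f"loss component {name!r} is not finite")
        return self

    def as_dict(self) -> dict[str, float]:
        return {"cor_s": self.cor_s, "cor_t": self.cor_t, "mse": self.mse,
                "cls": self.cls, "dom": self.dom, "total": self.total}


def gaussian_kernel(x, y, config: KernelConfig = KernelConfig()) -> Tensor:
    """K(x, y) = exp(-||x - y||^2 / (2 sigma^2)) for two feature vectors."""
    x, y = as_tensor(x), as_tensor(y)
    if x.shape != y.shape:
        raise ValueError(f"feature vectors disagree in shape: {x.shape} vs {y.shape}")
    d2 = ((x - y) ** 2.0).sum()
    return (d2 * (-1.0 / (2.0 * config.sigma ** 2))).exp()


def kernel_gram(mri_feats, pet_feats, config: KernelConfig = KernelConfig()) -> Tensor:
    """(N, N) Gaussian-kernel matrix K[i, j] = K(mri_i, pet_j).

    Squared distances are expanded as ||a||^2 + ||b||^2 - 2 a.b so the whole
    matrix is two matmuls; clipping at zero guards the tiny negative values
    the expansion can produce.
    """
    a, b = as_tensor(mri_feats), as_tensor(pet_feats)
    if a.ndim != 2 or b.ndim != 2 or a.shape != b.shape:
        raise ValueError(f"expected matching (N, d) feature matrices, got {a.shape} and {b.shape}")
    if a.shape[0] == 0:
        raise ValueError("empty feature batch")
    sq_a = (a ** 2.0).sum(axis=1, keepdims=True)        # (N, 1)
    sq_b = (b ** 2.0).sum(axis=1, keepdims=True)        # (N, 1)
    d2 = sq_a + sq_b.transpose(1, 0) - (a @ b.transpose(1, 0)) * 2.0
    d2 = d2.leaky_relu(0.0)                              # max(d2, 0)
    return (d2 * (-1.0 / (2.0 * config.sigma ** 2))).exp()


def correlation_loss(mri_feats, pet_feats, config: KernelConfig = KernelConfig()) -> Tensor:
    """Cross-modal correlation loss -sum_ij K_ij log(K_ij + eps)."""
    k = kernel_gram(mri_feats, pet_feats, config)
    return -(k * (k + config.epsilon).log()).sum()


def consistency_loss(f_s, f_t) -> Tensor:
    """Mean squared difference between source and target fused vectors."""
    f_s, f_t = as_tensor(f_s), as_tensor(f_t)
    if f_s.shape != f_t.shape:
        raise ValueError(f"fused vectors disagree in shape: {f_s.shape} vs {f_t.shape}")
    return ((f_s - f_t) ** 2.0).mean()


def _cross_entropy(probabilities, labels) -> Tensor:
    p = as_tensor(probabilities)
    y = np.asarray(labels)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError(f"expected (N, 2) probability rows, got {p.shape}")
    if y.shape != (p.shape[0],):
        raise ValueError(f"labels shape {y.shape} does not match {p.shape[0]} rows")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if np.any(p.data < -1e-9) or np.any(np.abs(p.data.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must be non-negative and sum to 1")
    n = p.shape[0]
    picked = p[np.arange(n), y.astype(int)]
    return -((picked + _PROB_FLOOR).log()).mean()


def classification_loss(probabilities, labels) -> Tensor:
    """Mean cross-entropy of predicted class probabilities vs true labels."""
    return _cross_entropy(probabilities, labels)


def domain_loss(probabilities, domain_labels) -> Tensor:
    """Mean cross-entropy of domain-membership probabilities; the domain
    indicator is 1 for source and 0 for target samples."""
    return _cross_entropy(probabilities, domain_labels)


def total_loss(cor_s=0.0, cor_t=0.0, mse=0.0, cls=0.0, dom=0.0) -> LossBundle:
    """Assemble the named components into a validated :class:`LossBundle`."""

    def val(x) -> float:
        return float(x.data) if isinstance(x, Tensor) else float(x)

    return LossBundle(cor_s=val(cor_s), cor_t=val(cor_t), mse=val(mse),
                      cls=val(cls), dom=val(dom)).validate()
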