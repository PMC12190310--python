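"""Seeded generator of paired MRI/PET-like volumes with a domain shift.

Real inputs to the model are co-registered, preprocessed 3-D brain volumes
from two cohorts whose scanners/protocols differ (a domain shift).  The
generator emulates the three properties the model exploits, without any
anatomical realism:

* **class signal** — a fixed set of smooth Gaussian blobs whose amplitudes
  differ between classes by ``class_effect``, in alternating directions so
  the classes are separated by a spatial pattern rather than by overall
  brightness (an atrophy/hypometabolism caricature);
* **modality coupling** — blob amplitudes mix a shared per-subject latent
  with modality-private variation, weighted by ``modality_correlation``, so
  cross-modal correlation has something real to align;
* **domain shift** — target-domain volumes are intensity-scaled
  (``shift_gain``), blurred (``shift_smooth``) and modulated by a smooth
  low-order polynomial bias field, the standard caricature of scanner
  differences.

Identical configs produce byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = ["SyntheticConfig", "SubjectSample", "generate_dataset",
           "describe_dataset", "save_dataset"]

#: canonical fractional blob centres (fixed across all datasets)
_BLOB_CENTRES = ((0.30, 0.30, 0.30), (0.70, 0.70, 0.30),
                 (0.30, 0.70, 0.70), (0.70, 0.30, 0.50))
#: per-blob direction of the class effect (alternating so the class signal
#: is a pattern, not a global intensity offset)
_BLOB_SIGNS = (1.0, -1.0, 1.0, -1.0)
_BASE_AMPLITUDE = 1.0
_SUBJECT_SD = 0.25       # subject-to-subject amplitude variability
_MIN_EDGE = 8            # smallest volume edge that still fits the blobs


class SyntheticConfigError(ValueError):
    """Invalid synthetic-dataset configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic source/target dataset."""

    volume_shape: tuple[int, int, int] = (32, 32, 32)
    n_per_class_source: int = 8
    n_per_class_target: int = 8
    class_effect: float = 1.0
    modality_balance: float = 0.5
    modality_correlation: float = 0.7
    shift_gain: float = 1.3
    shift_smooth: float = 0.75
    bias_amplitude: float = 0.15
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.volume_shape) != 3 or min(self.volume_shape) < _MIN_EDGE:
            raise SyntheticConfigError(
                f"volume_shape must be 3 ints >= {_MIN_EDGE} (blob placement), "
                f"got {self.volume_shape}")
        if self.n_per_class_source < 1 or self.n_per_class_target < 1:
            raise SyntheticConfigError("per-class sample counts must be positive")
        if self.class_effect < 0:
            raise SyntheticConfigError("class_effect must be non-negative")
        if not 0.0 <= self.modality_correlation <= 1.0:
            raise SyntheticConfigError("modality_correlation must lie in [0, 1]")
        if not 0.0 <= self.modality_balance <= 1.0:
            raise SyntheticConfigError("modality_balance must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise SyntheticConfigError("noise_sd must be positive")
        if self.shift_smooth < 0:
            raise SyntheticConfigError("shift_smooth must be non-negative")


@dataclass
class SubjectSample:
    """One subject: co-registered MRI and PET volumes, label, domain tag.

    Target-domain labels are retained for evaluation only; training never
    reads them.
    """

    subject_id: str
    mri: np.ndarray
    pet: np.ndarray
    label: int | None
    domain: str

    def __post_init__(self) -> None:
        if self.mri.shape != self.pet.shape:
            raise ValueError(
                f"{self.subject_id}: MRI {self.mri.shape} and PET {self.pet.shape} "
                "are not co-registered (shapes differ)")
        if self.domain not in ("source", "target"):
            raise ValueError(f"domain must be 'source' or 'target', got {self.domain!r}")
        if self.domain == "source" and self.label is None:
            raise ValueError(f"{self.subject_id}: source samples must be labeled")


def _blob_basis(shape: tuple[int, int, int]) -> np.ndarray:
    """(K, D, H, W) array of unit-peak Gaussian bumps at the canonical centres."""
    grids = np.indices(shape, dtype=np.float64)
    sigma = 0.12 * min(shape)
    basis = np.empty((len(_BLOB_CENTRES),) + tuple(shape))
    for k, centre in enumerate(_BLOB_CENTRES):
        d2 = sum((grids[a] - centre[a] * (shape[a] - 1)) ** 2 for a in range(3))
        basis[k] = np.exp(-d2 / (2.0 * sigma ** 2))
    return basis


def _bias_field(shape: tuple[int, int, int], amplitude: float,
                rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * (order-2 polynomial)."""
    coords = [np.linspace(-1.0, 1.0, s) for s in shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    terms = [x, y, z, x * y, y * z, x * z, x ** 2, y ** 2, z ** 2]
    coeffs = rng.uniform(-1.0, 1.0, size=len(terms))
    poly = sum(c * t for c, t in zip(coeffs, terms))
    poly /= max(np.abs(poly).max(), 1e-12)
    return 1.0 + amplitude * poly


def _subject_volumes(label: int, basis: np.ndarray, config: SyntheticConfig,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    k = basis.shape[0]
    signs = np.array(_BLOB_SIGNS[:k])
    # modality_balance splits the class effect between modalities: 0.5 is
    # symmetric; larger values make PET the more class-sensitive channel
    # (the FDG-PET-leads-atrophy caricature) at constant total effect.
    effect = {"mri": 2.0 * (1.0 - config.modality_balance) * config.class_effect,
              "pet": 2.0 * config.modality_balance * config.class_effect}
    rho = config.modality_correlation
    shared_noise = _SUBJECT_SD * rng.standard_normal(k)
    amps = {}
    for modality in ("mri", "pet"):
        private_noise = _SUBJECT_SD * rng.standard_normal(k)
        means = _BASE_AMPLITUDE + label * effect[modality] * signs
        amps[modality] = means + rho * shared_noise + (1.0 - rho) * private_noise
    shape = basis.shape[1:]
    volumes = []
    for modality in ("mri", "pet"):
        vol = 1.0 + np.tensordot(amps[modality], basis, axes=1)
        vol += config.noise_sd * rng.standard_normal(shape)
        volumes.append(vol)
    return volumes[0], volumes[1]


def _apply_shift(volume: np.ndarray, bias: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    out = config.shift_gain * volume
    if config.shift_smooth > 0:
        out = gaussian_filter(out, sigma=config.shift_smooth)
    return out * bias


def generate_dataset(config: SyntheticConfig) -> list[SubjectSample]:
    """Generate labeled source samples and shifted target samples.

    Returns ``2 * n_per_class_source`` source samples followed by
    ``2 * n_per_class_target`` target samples, class-balanced within each
    domain.  Target labels are kept on the samples for evaluation, but the
    ``target`` domain tag marks them as held out from training.
    """
    rng = np.random.default_rng(config.seed)
    basis = _blob_basis(tuple(config.volume_shape))
    bias = (_bias_field(tuple(config.volume_shape), config.bias_amplitude, rng)
            if config.bias_amplitude > 0 else np.ones(tuple(config.volume_shape)))
    samples: list[SubjectSample] = []
    for i in range(2 * config.n_per_class_source):
        label = i % 2
        mri, pet = _subject_volumes(label, basis, config, rng)
        samples.append(SubjectSample(f"src-{i:03d}", mri.astype(np.float32),
                                     pet.astype(np.float32), label, "source"))
    for j in range(2 * config.n_per_class_target):
        label = j % 2
        mri, pet = _subject_volumes(label, basis, config, rng)
        mri = _apply_shift(mri, bias, config)
        pet = _apply_shift(pet, bias, config)
        samples.append(SubjectSample(f"tgt-{j:03d}", mri.astype(np.float32),
                                     pet.astype(np.float32), label, "target"))
    return samples


def describe_dataset(samples: list[SubjectSample]) -> pd.DataFrame:
    """Counts and mean intensities per (domain, class)."""
    if not samples:
        raise ValueError("empty sample collection")
    rows = []
    for s in samples:
        rows.append({"domain": s.domain, "label": s.label,
                     "mean_mri": float(s.mri.mean()), "mean_pet": float(s.pet.mean())})
    frame = pd.DataFrame(rows)
    summary = (frame.groupby(["domain", "label"], dropna=False)
               .agg(n=("domain", "size"), mean_mri=("mean_mri", "mean"),
                    mean_pet=("mean_pet", "mean"))
               .reset_index())
    return summary


def save_dataset(samples: list[SubjectSample], out_dir: str | Path) -> Path:
    """Write NIfTI volume pairs plus a manifest CSV; returns the manifest path."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        mri_path = out_dir / f"{s.subject_id}_mri.nii.gz"
        pet_path = out_dir / f"{s.subject_id}_pet.nii.gz"
        nib.save(nib.Nifti1Image(s.mri.astype(np.float32), np.eye(4)), mri_path)
        nib.save(nib.Nifti1Image(s.pet.astype(np.float32), np.eye(4)), pet_path)
        rows.append({"subject_id": s.subject_id, "mri_path": mri_path.name,
                     "pet_path": pet_path.name,
                     "label": "" if s.label is None else int(s.label),
                     "domain": s.domain})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=["subject_id", "mri_path", "pet_path", "label",
                                "domain"]).to_csv(manifest, index=False)
    return manifest
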