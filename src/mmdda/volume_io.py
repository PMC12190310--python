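"""NIfTI volume / manifest I/O and the stratified train/val/test split.

The manifest is a CSV with header exactly
``subject_id,mri_path,pet_path,label,domain``; labels may be empty for
target-domain rows.  The split holds out 30% of subjects as the test set,
then 30% of the remainder as a validation set (so roughly 49/21/30 percent
train/val/test), stratified by label, and is a deterministic function of
(manifest, seed).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .synthetic import SubjectSample

__all__ = ["MANIFEST_COLUMNS", "read_manifest", "load_sample", "load_dataset",
           "make_split", "CoregistrationError", "StratificationError"]

MANIFEST_COLUMNS = ("subject_id", "mri_path", "pet_path", "label", "domain")
TEST_FRACTION = 0.30
VAL_FRACTION = 0.30  # of what remains after the test split


class CoregistrationError(ValueError):
    """MRI and PET volumes of one subject are not on the same voxel grid."""


class StratificationError(ValueError):
    """A class is absent from one of the split partitions."""


def read_manifest(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"subject_id": str, "mri_path": str,
                                     "pet_path": str, "domain": str})
    if tuple(frame.columns) != MANIFEST_COLUMNS:
        raise ValueError(f"manifest columns must be {MANIFEST_COLUMNS}, "
                         f"got {tuple(frame.columns)}")
    for domain, group in frame.groupby("domain"):
        if group["subject_id"].duplicated().any():
            raise ValueError(f"duplicate subject_id within domain {domain!r}")
    source = frame[frame["domain"] == "source"]
    if source["label"].isna().any():
        raise ValueError("all source-domain rows must carry a label")
    return frame


def _read_volume(path: Path) -> np.ndarray:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # unreadable / missing file
        raise IOError(f"cannot read volume {path}: {exc}") from exc
    return np.asarray(img.get_fdata(), dtype=np.float32)


def load_sample(row: pd.Series, base_dir: str | Path = ".") -> SubjectSample:
    """Load one manifest row into a :class:`SubjectSample`."""
    base = Path(base_dir)
    mri = _read_volume(base / str(row["mri_path"]))
    pet = _read_volume(base / str(row["pet_path"]))
    if mri.shape != pet.shape:
        raise CoregistrationError(
            f"{row['subject_id']}: MRI shape {mri.shape} != PET shape {pet.shape}")
    label = row["label"]
    label = None if (label is None or (isinstance(label, float) and np.isnan(label))
                     or label == "") else int(label)
    return SubjectSample(str(row["subject_id"]), mri, pet, label, str(row["domain"]))


def load_dataset(manifest_path: str | Path) -> list[SubjectSample]:
    manifest_path = Path(manifest_path)
    frame = read_manifest(manifest_path)
    return [load_sample(row, manifest_path.parent) for _, row in frame.iterrows()]


def make_split(manifest: pd.DataFrame, seed: int) -> dict[str, str]:
    """Assign each labeled subject to train/val/test.

    test = round(0.30 n); val = round(0.30 (n - test)); remainder train;
    each draw stratified by label.
    """
    labeled = manifest[~manifest["label"].isna() & (manifest["label"] != "")]
    ids = labeled["subject_id"].astype(str).to_numpy()
    labels = labeled["label"].astype(int).to_numpy()
    n = len(ids)
    if n < 10:
        raise ValueError(f"need at least 10 labeled samples to split, got {n}")
    if len(np.unique(labels)) < 2:
        raise StratificationError("stratified split needs both classes present")
    n_test = round(TEST_FRACTION * n)
    n_val = round(VAL_FRACTION * (n - n_test))
    try:
        rest_ids, test_ids, rest_y, _ = train_test_split(
            ids, labels, test_size=n_test, stratify=labels, random_state=seed)
        train_ids, val_ids = train_test_split(
            rest_ids, test_size=n_val, stratify=rest_y, random_state=seed)
    except ValueError as exc:
        raise StratificationError(f"stratified split failed: {exc}") from exc
    assignment = {str(s): "train" for s in train_ids}
    assignment.update({str(s): "val" for s in val_ids})
    assignment.update({str(s): "test" for s in test_ids})
    by_label = dict(zip(ids, labels))
    for part in ("train", "val", "test"):
        present = {by_label[s] for s, p in assignment.items() if p == part}
        if present != set(labels.tolist()):
            raise StratificationError(f"partition {part!r} is missing a class")
    return assignment
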