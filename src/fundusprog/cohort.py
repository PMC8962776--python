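"""Cohort data model, manifest I/O, image preprocessing, and partitioning.

The manifest is a CSV with columns ``subject_id, eye, visit_index,
image_path, severity, age`` (age may be blank); rows are grouped into
per-eye longitudinal series.  Splitting is done at the subject level so
that no participant contributes images to two partitions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .phantom import ADVANCED_THRESHOLD, MAX_SEVERITY, MAX_VISIT_INDEX

MANIFEST_COLUMNS = ["subject_id", "eye", "visit_index", "image_path", "severity", "age"]


class ManifestSchemaError(ValueError):
    """A manifest row or header violates the cohort schema."""


@dataclass(frozen=True)
class VisitRecord:
    """One graded fundus image of one eye at one 6-month visit index."""

    subject_id: str
    eye: str
    visit_index: int
    image_path: str
    severity: int
    age: float | None = None

    def __post_init__(self):
        if self.eye not in ("L", "R"):
            raise ManifestSchemaError(f"eye must be 'L' or 'R', got {self.eye!r}")
        if not 0 <= self.visit_index <= MAX_VISIT_INDEX:
            raise ManifestSchemaError(
                f"visit_index must be in 0..{MAX_VISIT_INDEX}, got {self.visit_index}")
        if not 0 <= self.severity <= MAX_SEVERITY:
            raise ManifestSchemaError(
                f"severity must be in 0..{MAX_SEVERITY}, got {self.severity}")

    @property
    def advanced(self) -> bool:
        return self.severity >= ADVANCED_THRESHOLD


@dataclass
class EyeSeries:
    """All visits of one eye, sorted by visit index."""

    subject_id: str
    eye: str
    records: list = field(default_factory=list)

    def __post_init__(self):
        self.records = sorted(self.records, key=lambda r: r.visit_index)
        idx = [r.visit_index for r in self.records]
        if len(set(idx)) != len(idx):
            raise ManifestSchemaError(
                f"duplicate visit_index for ({self.subject_id}, {self.eye})")

    def visit_indices(self) -> list:
        return [r.visit_index for r in self.records]

    def check_monotone(self, strict: bool = False) -> bool:
        """Severity should never decrease (advanced AMD is irreversible)."""
        sev = [r.severity for r in self.records]
        ok = all(b >= a for a, b in zip(sev, sev[1:]))
        if not ok:
            msg = (f"non-monotone severity for ({self.subject_id}, {self.eye}): {sev}")
            if strict:
                raise ManifestSchemaError(msg)
            warnings.warn(msg, stacklevel=2)
        return ok


@dataclass(frozen=True)
class CohortSplit:
    train_ids: frozenset
    val_ids: frozenset
    test_ids: frozenset
    seed: int

    def __post_init__(self):
        if (self.train_ids & self.val_ids or self.train_ids & self.test_ids
                or self.val_ids & self.test_ids):
            raise ValueError("split partitions must be pairwise disjoint")

    def partition_of(self, subject_id: str) -> str:
        if subject_id in self.train_ids:
            return "train"
        if subject_id in self.val_ids:
            return "val"
        if subject_id in self.test_ids:
            return "test"
        raise KeyError(subject_id)


def series_from_frame(manifest: pd.DataFrame, strict_monotone: bool = False) -> list:
    """Group validated manifest rows into per-(subject, eye) EyeSeries."""
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ManifestSchemaError(f"manifest missing columns: {missing}")
    records = {}
    for i, row in enumerate(manifest.itertuples(index=False)):
        age = getattr(row, "age", None)
        if age is None or (isinstance(age, float) and math.isnan(age)):
            age = None
        else:
            age = float(age)
            if age < 0:
                raise ManifestSchemaError(f"row {i}: negative age {age}")
        try:
            rec = VisitRecord(str(row.subject_id), str(row.eye), int(row.visit_index),
                              str(row.image_path), int(row.severity), age)
        except ManifestSchemaError as exc:
            raise ManifestSchemaError(f"row {i}: {exc}") from exc
        key = (rec.subject_id, rec.eye)
        if any(r.visit_index == rec.visit_index for r in records.get(key, [])):
            raise ManifestSchemaError(
                f"row {i}: duplicate (subject, eye, visit) {key + (rec.visit_index,)}")
        records.setdefault(key, []).append(rec)
    out = []
    for (subject, eye), recs in sorted(records.items()):
        series = EyeSeries(subject, eye, recs)
        series.check_monotone(strict=strict_monotone)
        out.append(series)
    return out


def read_manifest(path, strict_monotone: bool = False) -> list:
    """Read a manifest CSV into a list of EyeSeries."""
    frame = pd.read_csv(path, dtype={"subject_id": str, "eye": str})
    return series_from_frame(frame, strict_monotone=strict_monotone)


def write_manifest(series: Iterable[EyeSeries], path) -> None:
    """Write EyeSeries back to the manifest CSV (inverse of read_manifest)."""
    rows = []
    for s in series:
        for r in s.records:
            rows.append({"subject_id": r.subject_id, "eye": r.eye,
                         "visit_index": r.visit_index, "image_path": r.image_path,
                         "severity": r.severity,
                         "age": "" if r.age is None else r.age})
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


# --------------------------------------------------------------------------
# preprocessing

def preprocess_image(image, target_size: int = 224) -> np.ndarray:
    """Center-crop to a square covering the macula and resize.

    The crop is the centered square of side ``min(height, width)`` —
    fundus photographs (and all phantoms here) are macula-centered, so
    the central square always contains the macula.  No flips, mirrors,
    rotations or other augmentations are ever applied: the downstream
    generator relies on the optic disc and vessel layout being preserved.

    Accepts a PIL image or an array (uint8 or float in [0, 1]) with 3
    channels; returns float32 in [0, 1], shape (target, target, 3).
    """
    if isinstance(image, Image.Image):
        arr = np.asarray(image)
    else:
        arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {arr.shape}")
    h, w = arr.shape[:2]
    if min(h, w) < 32:
        raise ValueError(f"image too small: {arr.shape}")
    side = min(h, w)
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    crop = arr[r0:r0 + side, c0:c0 + side]
    if crop.dtype != np.uint8:
        crop = (np.clip(crop, 0.0, 1.0) * 255).round().astype(np.uint8)
    if side != target_size:
        crop = np.asarray(Image.fromarray(crop).resize(
            (target_size, target_size), Image.BILINEAR))
    return crop.astype(np.float32) / 255.0


def load_image(path, target_size: int = 224) -> np.ndarray:
    """Load an image file and preprocess it."""
    with Image.open(path) as im:
        return preprocess_image(im.convert("RGB"), target_size)


# --------------------------------------------------------------------------
# partitioning

def partition_subjects(ids: Sequence[str], ratios=(0.90, 0.05, 0.05),
                       seed: int = 0) -> CohortSplit:
    """Subject-level train/val/test split.

    Sizes: train takes ``ceil(r_train * N)``, val ``ceil(r_val * N)``, and
    test the remainder — for N=4,628 at 90/5/5 this yields 4,166/232/230.
    Deterministic given ``seed``.
    """
    ids = sorted(set(map(str, ids)))
    n = len(ids)
    if n == 0:
        raise ValueError("cannot partition an empty id set")
    if len(ratios) != 3 or any(r <= 0 for r in ratios) or not math.isclose(sum(ratios), 1.0):
        raise ValueError(f"ratios must be three positive numbers summing to 1, got {ratios}")
    n_train = min(n, math.ceil(ratios[0] * n))
    n_val = min(n - n_train, math.ceil(ratios[1] * n))
    n_test = n - n_train - n_val
    perm = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in perm]
    return CohortSplit(
        train_ids=frozenset(shuffled[:n_train]),
        val_ids=frozenset(shuffled[n_train:n_train + n_val]),
        test_ids=frozenset(shuffled[n_train + n_val:]),
        seed=seed,
    )
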