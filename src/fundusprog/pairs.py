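"""Visit pairing, 3-class labels, class weights, and per-eye down-sampling.

A pair couples a current visit with the visit ``T`` 6-month steps later.
Its label encodes both visits' advanced-AMD status (severity >= 10):

* 0 — neither visit advanced,
* 1 — progresses to advanced by the second visit,
* 2 — both visits advanced.

(Advanced, not advanced) is impossible because advanced AMD is
irreversible; encountering it raises.  The raw pair population is
dominated by label 0, so training sets are rebalanced per eye: all
nonzero-label pairs are kept and at most ``max(1, #nonzero)`` zero-label
pairs are sampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cohort import EyeSeries, VisitRecord
from .phantom import ADVANCED_THRESHOLD, MAX_SEVERITY


class InvalidTrajectoryError(ValueError):
    """An (advanced, not advanced) pair, which irreversibility forbids."""


@dataclass(frozen=True)
class VisitPair:
    """Ordered (current, future) visit pair with gap ``T`` and label ``y``."""

    first: VisitRecord
    second: VisitRecord
    gap_T: int
    label_y: int

    def __post_init__(self):
        if self.second.visit_index - self.first.visit_index != self.gap_T:
            raise ValueError("second.visit_index - first.visit_index must equal gap_T")
        if (self.first.subject_id, self.first.eye) != (self.second.subject_id, self.second.eye):
            raise ValueError("pair must come from a single eye")
        if self.label_y != encode_label(self.first.severity, self.second.severity):
            raise ValueError("label_y inconsistent with the severity pair")


@dataclass(frozen=True)
class ClassWeights:
    """Normalized inverse-frequency weights for the weighted cross-entropy."""

    w: np.ndarray
    source_histogram: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if np.any(w <= 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be positive and sum to 1")
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "source_histogram",
                           np.asarray(self.source_histogram, dtype=float))


def encode_label(s1: int, s2: int) -> int:
    """Map a (current, future) severity pair to the 3-class label."""
    for s in (s1, s2):
        if not 0 <= s <= MAX_SEVERITY:
            raise ValueError(f"severity must be in 0..{MAX_SEVERITY}, got {s}")
    adv1 = s1 >= ADVANCED_THRESHOLD
    adv2 = s2 >= ADVANCED_THRESHOLD
    if adv1 and not adv2:
        raise InvalidTrajectoryError(
            f"(advanced, not advanced) severity pair ({s1}, {s2}) is not possible")
    if adv1:
        return 2
    return 1 if adv2 else 0


def extract_pairs(series: EyeSeries, T: int) -> list:
    """All available visit pairs of one eye whose index gap equals ``T``."""
    if T < 1:
        raise ValueError(f"gap T must be >= 1, got {T}")
    by_index = {r.visit_index: r for r in series.records}
    pairs = []
    for r in series.records:
        partner = by_index.get(r.visit_index + T)
        if partner is not None:
            pairs.append(VisitPair(r, partner, T,
                                   encode_label(r.severity, partner.severity)))
    return pairs


def class_histogram(pairs_or_labels, num_classes: int = 3) -> np.ndarray:
    """Label proportions ``h`` (sums to 1) over the pair classes."""
    labels = [p.label_y if isinstance(p, VisitPair) else int(p)
              for p in pairs_or_labels]
    if len(labels) == 0:
        raise ValueError("cannot compute a histogram of zero pairs")
    counts = np.bincount(labels, minlength=num_classes).astype(float)
    return counts / counts.sum()


def class_weights(h) -> ClassWeights:
    """Normalized inverse-frequency weights ``w_k = (1/h_k) / sum_j (1/h_j)``."""
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError(
            "every class must be present in the histogram (a zero entry makes "
            "the inverse-frequency weight undefined); merge or resample first")
    if not np.isclose(h.sum(), 1.0):
        raise ValueError("histogram must sum to 1")
    inv = 1.0 / h
    return ClassWeights(w=inv / inv.sum(), source_histogram=h)


def downsample_eye(pairs: Sequence[VisitPair], rng: np.random.Generator) -> list:
    """Per-eye rebalancing of the label-0 majority.

    With ``n`` nonzero-label pairs and ``m`` zero-label pairs:
    all nonzero pairs are always kept; zero pairs are kept in full when
    ``n >= m``, subsampled to ``n`` when ``0 < n < m``, and reduced to a
    single random pair when ``n = 0``.  Output preserves visit order.
    """
    pairs = list(pairs)
    if not pairs:
        return []
    zero_idx = [i for i, p in enumerate(pairs) if p.label_y == 0]
    nonzero_idx = [i for i, p in enumerate(pairs) if p.label_y != 0]
    n, m = len(nonzero_idx), len(zero_idx)
    if m == 0:
        keep = nonzero_idx
    elif n == 0:
        keep = [zero_idx[rng.integers(m)]]
    elif n < m:
        chosen = rng.choice(m, size=n, replace=False)
        keep = nonzero_idx + [zero_idx[i] for i in chosen]
    else:
        keep = nonzero_idx + zero_idx
    return [pairs[i] for i in sorted(keep)]


def downsample_cohort(series_collection: Iterable[EyeSeries], T: int,
                      seed: int = 0) -> list:
    """Apply :func:`downsample_eye` independently per eye, deterministically.

    Each eye gets its own random stream derived from ``seed`` and the eye's
    identity, so the selection does not depend on iteration order.
    """
    out = []
    for series in series_collection:
        pairs = extract_pairs(series, T)
        if not pairs:
            continue
        key = [seed, T] + [ord(c) for c in f"{series.subject_id}|{series.eye}"]
        rng = np.random.default_rng(np.random.SeedSequence(key))
        out.extend(downsample_eye(pairs, rng))
    return out


def pairs_to_frame(pairs: Sequence[VisitPair]):
    """Serialize pairs as a DataFrame (subject, eye, t1, t2, label)."""
    import pandas as pd

    return pd.DataFrame(
        [{"subject_id": p.first.subject_id, "eye": p.first.eye,
          "t1": p.first.visit_index, "t2": p.second.visit_index,
          "label": p.label_y} for p in pairs],
        columns=["subject_id", "eye", "t1", "t2", "label"])
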