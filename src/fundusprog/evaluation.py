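"""Metrics, label decoders, sequential GAN-classifier pipelines, bootstrap
confidence intervals, and input-gradient saliency maps.

The 3-class pair label carries both visits' advanced-AMD status, so it
decodes to a binary statement about either visit:

* current visit:  label 2 means advanced, labels {0, 1} not advanced;
* future visit:   labels {1, 2} mean advanced, label 0 not advanced.

All headline numbers (accuracy, multiclass AUC in the Hand-Till sense,
binarized sensitivity/specificity) derive from the 3x3 confusion matrix
or the per-sample scores collected here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from . import nn

# --------------------------------------------------------------------------
# confusion matrices

@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 counts; rows = actual label, columns = predicted label."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (3, 3) or np.any(c < 0):
            raise ValueError(f"expected a non-negative 3x3 count matrix, got {c!r}")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ConfusionMatrix2:
    """2x2 counts; positive class = advanced (3-class label 2)."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (2, 2) or np.any(c < 0):
            raise ValueError(f"expected a non-negative 2x2 count matrix, got {c!r}")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricWithCI:
    point: float
    lo: float
    hi: float
    B: int
    seed: int

    def __post_init__(self):
        if not (self.lo <= self.point <= self.hi):
            warnings.warn(
                f"point estimate {self.point} outside percentile CI "
                f"({self.lo}, {self.hi})", stacklevel=2)


def confusion_matrix(true_labels, predicted_labels) -> ConfusionMatrix3:
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.size == 0:
        raise ValueError("cannot build a confusion matrix from zero pairs")
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    if np.any((t < 0) | (t > 2)) or np.any((p < 0) | (p > 2)):
        raise ValueError("labels must be in {0, 1, 2}")
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix3(counts)


def accuracy(cm) -> float:
    """Trace over total of a confusion matrix (3x3 or 2x2, object or array)."""
    c = np.asarray(getattr(cm, "counts", cm), dtype=float)
    return float(np.trace(c) / c.sum())


# --------------------------------------------------------------------------
# Hand-Till multiclass AUC

def _pairwise_rank_prob(scores_pos, scores_neg) -> float:
    """P(score of a positive > score of a negative), ties counting 1/2."""
    s = np.concatenate([scores_pos, scores_neg])
    r = rankdata(s)
    n_pos, n_neg = len(scores_pos), len(scores_neg)
    u = r[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def hand_till_auc(true_labels, class_probabilities) -> float:
    """Multiclass AUC as the average of pairwise one-vs-one ranking terms.

    For each unordered class pair (i, j), A_hat(i, j) averages
    A(i|j) — computed from the class-i scores — and A(j|i) — from the
    class-j scores; the final measure averages A_hat over all pairs with
    both classes present (absent-class pairs are skipped with a warning
    and the normalization adjusted).
    """
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(class_probabilities, dtype=float)
    if p.ndim != 2 or p.shape[0] != y.shape[0]:
        raise ValueError("probability matrix must be (n_samples, n_classes)")
    n_classes = p.shape[1]
    present = [k for k in range(n_classes) if np.any(y == k)]
    if len(present) < 2:
        raise ValueError("need at least two classes present to compute an AUC")
    terms = []
    for a in range(n_classes):
        for b in range(a + 1, n_classes):
            if a not in present or b not in present:
                warnings.warn(
                    f"class pair ({a}, {b}) skipped: a class is absent", stacklevel=2)
                continue
            ia, ib = y == a, y == b
            a_given_b = _pairwise_rank_prob(p[ia, a], p[ib, a])
            b_given_a = _pairwise_rank_prob(p[ib, b], p[ia, b])
            terms.append(0.5 * (a_given_b + b_given_a))
    return float(np.mean(terms))


# --------------------------------------------------------------------------
# bootstrap

def bootstrap_ci(per_sample_data, metric_fn, B: int = 2000, level: float = 0.95,
                 seed: int = 0) -> MetricWithCI:
    """Percentile bootstrap CI from per-sample data.

    ``per_sample_data`` is an array or a tuple/list of arrays resampled
    jointly along axis 0 (size-N resamples with replacement, B times).
    A resample on which ``metric_fn`` raises is redrawn (counted and
    warned about at the end).
    """
    arrays = per_sample_data if isinstance(per_sample_data, (tuple, list)) \
        else (per_sample_data,)
    arrays = tuple(np.asarray(a) for a in arrays)
    n = arrays[0].shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to bootstrap")
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("all per-sample arrays must share axis-0 length")

    def call(arrs):
        return float(metric_fn(*arrs) if len(arrs) > 1 else metric_fn(arrs[0]))

    point = call(arrays)
    rng = np.random.default_rng(seed)
    stats = np.empty(B)
    failures = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                stats[b] = call(tuple(a[idx] for a in arrays))
                break
            except Exception:
                failures += 1
                if failures > 100 * B:
                    raise
    if failures:
        warnings.warn(f"{failures} bootstrap resamples redrawn after metric "
                      "failures", stacklevel=2)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return MetricWithCI(point=point, lo=float(lo), hi=float(hi), B=B, seed=seed)


# --------------------------------------------------------------------------
# decoders and binarization

def decode_current_binary(y) -> np.ndarray:
    """Advanced status of the *current* visit: only label 2 is advanced."""
    y = np.asarray(y, dtype=int)
    if np.any((y < 0) | (y > 2)):
        raise ValueError("labels must be in {0, 1, 2}")
    return (y == 2).astype(int)


def decode_future_binary(y) -> np.ndarray:
    """Advanced status of the *future* visit: labels 1 and 2 are advanced."""
    y = np.asarray(y, dtype=int)
    if np.any((y < 0) | (y > 2)):
        raise ValueError("labels must be in {0, 1, 2}")
    return (y >= 1).astype(int)


def binarize_current(cm: ConfusionMatrix3):
    """Collapse labels {0, 1} of a 3x3 matrix into 'not advanced'.

    Returns ``(ConfusionMatrix2, sensitivity, specificity, accuracy)``
    for the current-visit advanced/not-advanced grading task.
    """
    c = cm.counts
    tp = int(c[2, 2])
    fn = int(c[2, 0] + c[2, 1])
    tn = int(c[0:2, 0:2].sum())
    fp = int(c[0, 2] + c[1, 2])
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("empty positive or negative stratum")
    cm2 = ConfusionMatrix2(np.array([[tn, fp], [fn, tp]]))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / cm.total
    return cm2, float(sens), float(spec), float(acc)


# --------------------------------------------------------------------------
# sequential GAN -> classifier evaluation

SEQUENTIAL_MODES = ("gan3c", "ganB", "first3c", "second3c")


def _num_classes_of(classifier) -> int:
    cfg = getattr(classifier, "cfg", None)
    if cfg is not None and hasattr(cfg, "num_classes"):
        return cfg.num_classes
    n = getattr(classifier, "n_classes_", None)
    if n is not None:
        return int(n)
    return int(getattr(classifier, "num_classes"))


def _generate(generator, X):
    if hasattr(generator, "transform"):
        return generator.transform(X)
    return generator(X)


def sequential_eval(generator, classifier, X_first, X_second, y_true, mode: str):
    """Predict the future visit's advanced status and score the accuracy.

    Modes: ``gan3c`` classifies the generated future image with the
    3-class model and decodes its current-visit status; ``ganB`` scores
    the generated image with a binary grader; ``first3c``/``second3c``
    are classifier-only baselines on the real first/second image.
    Images are channels-last arrays in [0, 1]; ``y_true`` holds 3-class
    pair labels.  Returns ``(binary predictions, accuracy)``.
    """
    if mode not in SEQUENTIAL_MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {SEQUENTIAL_MODES}")
    y_true = np.asarray(y_true, dtype=int)
    needed = 2 if mode == "ganB" else 3
    if _num_classes_of(classifier) != needed:
        raise ValueError(f"mode {mode!r} needs a {needed}-class classifier")
    if mode in ("gan3c", "ganB") and generator is None:
        raise ValueError(f"mode {mode!r} needs a generator")

    if mode in ("gan3c", "ganB"):
        X_in = _generate(generator, np.asarray(X_first))
    elif mode == "first3c":
        X_in = np.asarray(X_first)
    else:
        X_in = np.asarray(X_second)
    proba = classifier.predict_proba(X_in)
    pred = np.argmax(proba, axis=1)
    if mode == "ganB":
        binary = pred.astype(int)
    elif mode == "first3c":
        binary = decode_future_binary(pred)
    else:
        binary = decode_current_binary(pred)
    truth = decode_future_binary(y_true)
    return binary, float(np.mean(binary == truth))


# --------------------------------------------------------------------------
# saliency

def saliency_map(classifier, image, target_class: int) -> np.ndarray:
    """Input-gradient saliency: channel-max |d score_c / d pixel|, in [0, 1].

    ``classifier`` is a built network (or a fitted estimator exposing
    ``net_``); ``image`` is a single channels-last [0, 1] image.
    """
    net = getattr(classifier, "net_", classifier)
    x = np.asarray(image, dtype=np.float64)
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError(f"expected one (H, W, 3) image, got shape {x.shape}")
    xin = x.transpose(2, 0, 1)[None]
    logits = net.forward(xin, train=False)
    n_classes = logits.shape[1]
    if not 0 <= target_class < n_classes:
        raise ValueError(f"target_class must be in 0..{n_classes - 1}")
    for p in net.params():
        p.grad[...] = 0.0
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    dx = net.backward(dlogits)[0]
    heat = np.abs(dx).max(axis=0)
    peak = heat.max()
    return heat / peak if peak > 0 else heat
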