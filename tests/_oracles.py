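"""Independent brute-force oracles used by the metric and geometry tests."""

import itertools

import numpy as np

from fundusprog import nn
from fundusprog.models import DiscriminatorConfig, receptive_field


def hand_till_brute_force(y, proba):
    """Hand-Till multiclass AUC by exhaustive enumeration of sample pairs."""
    y = np.asarray(y)
    proba = np.asarray(proba, dtype=float)
    classes = [c for c in range(proba.shape[1]) if np.any(y == c)]
    terms = []
    for i, j in itertools.combinations(classes, 2):
        for pos, col in ((i, i), (j, j)):
            neg = j if pos == i else i
            wins = 0.0
            num = 0
            for a in np.where(y == pos)[0]:
                for b in np.where(y == neg)[0]:
                    num += 1
                    if proba[a, col] > proba[b, col]:
                        wins += 1.0
                    elif proba[a, col] == proba[b, col]:
                        wins += 0.5
            terms.append(wins / num)
        terms[-2:] = [0.5 * (terms[-2] + terms[-1])]
    return float(np.mean(terms))


def receptive_field_by_gradient_support(kernel, strides, seed=0):
    """Measure one output unit's input support through an unpadded,
    positive-weight conv stack mirroring the critic's geometry."""
    rng = np.random.default_rng(seed)
    cfg = DiscriminatorConfig(layer_channels=(2,) * len(strides),
                              strides=tuple(strides), kernel=kernel,
                              in_channels=1, pad=0)
    expected = receptive_field(cfg)
    layers = []
    c = 1
    for s in strides:
        conv = nn.Conv2d(c, 2, kernel, s, 0, rng=rng)
        conv.W.data = np.abs(conv.W.data) + 0.1
        conv.b.data[...] = 0.0
        layers.append(conv)
        c = 2
    final = nn.Conv2d(c, 1, kernel, 1, 0, rng=rng)
    final.W.data = np.abs(final.W.data) + 0.1
    net = nn.Sequential(*layers, final)
    size = expected + kernel  # slack so the output grid is non-degenerate
    x = np.full((1, 1, size, size), 0.5)
    y = net.forward(x)
    dout = np.zeros_like(y)
    dout[0, 0, 0, 0] = 1.0
    dx = net.backward(dout)[0, 0]
    rows, cols = np.nonzero(np.abs(dx) > 1e-12)
    measured = max(rows.max() - rows.min() + 1, cols.max() - cols.min() + 1)
    return measured, expected
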