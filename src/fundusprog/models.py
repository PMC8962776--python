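"""Network constructors and loss functions.

Three networks drive the framework:

* a residual CNN classifier that grades the *current* fundus image into
  the 3 pair classes (or 2 classes for plain advanced/not-advanced
  grading), optionally fusing the subject's age into the pooled feature
  vector;
* a U-Net generator that maps the current visit's image to a forecast of
  the future visit's image (dropout provides the stochasticity instead
  of an input noise vector);
* a patch discriminator that scores overlapping patches of the
  (current image, candidate future image) 6-channel concatenation — the
  default configuration has a 70x70-pixel receptive field per score.

The classification loss is a weighted cross-entropy with normalized
inverse-frequency class weights; the GAN objective couples the
conditional adversarial terms with an L1 reconstruction term weighted by
``lambda_r``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

LOG_EPS = 1e-7


# --------------------------------------------------------------------------
# configs

@dataclass(frozen=True)
class ClassifierConfig:
    num_classes: int = 3
    input_size: int = 224
    width_scale: float = 1.0
    pretrained: bool = False
    age_fusion: bool = False

    def __post_init__(self):
        if self.num_classes not in (2, 3):
            raise ValueError("num_classes must be 2 or 3")
        if self.width_scale <= 0:
            raise ValueError("width_scale must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    input_size: int = 256
    depth: int = 8
    base_channels: int = 64
    dropout_rate: float = 0.5

    def __post_init__(self):
        if self.input_size % (2**self.depth) != 0 or self.input_size < 2**self.depth:
            raise ValueError(
                f"input_size {self.input_size} must be a multiple of 2^depth={2**self.depth}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0,1)")


@dataclass(frozen=True)
class DiscriminatorConfig:
    layer_channels: tuple = (64, 128, 256, 512)
    strides: tuple = (2, 2, 2, 1)
    kernel: int = 4
    in_channels: int = 6
    pad: int = 1  # 0 makes a 70x70 input collapse to exactly one score

    def __post_init__(self):
        if len(self.layer_channels) != len(self.strides):
            raise ValueError("layer_channels and strides must have equal length")


@dataclass(frozen=True)
class GanLossTerms:
    """Components of the GAN objective.

    ``d_real``/``d_fake`` are the discriminator's patch-averaged binary
    log-likelihood terms of the minimax objective, ``E[log D(x, y)]`` and
    ``E[log(1 - D(x, G(x)))]`` (to be maximized by D).  ``g_adv`` is the
    generator's non-saturating adversarial loss ``-E[log D(x, G(x))]``
    (to be minimized), and ``g_l1`` the mean absolute reconstruction
    error; the total generator loss is ``g_adv + lambda_r * g_l1``.
    """

    d_real: float
    d_fake: float
    g_adv: float
    g_l1: float
    lambda_r: float

    @property
    def d_objective(self) -> float:
        return self.d_real + self.d_fake

    @property
    def g_total(self) -> float:
        return self.g_adv + self.lambda_r * self.g_l1


# --------------------------------------------------------------------------
# classifier

class Classifier:
    """Width-scalable residual CNN with global average pooling.

    ``forward`` takes images of shape (N, 3, H, W) in [0, 1] and returns
    logits; ``predict_proba`` applies the softmax.  With ``age_fusion``
    the (rescaled) age scalar is concatenated to the pooled feature
    vector right before the final affine map.
    """

    def __init__(self, cfg: ClassifierConfig, rng: np.random.Generator):
        if cfg.pretrained:
            raise ValueError(
                "no pretrained weights ship with this package; "
                "build with pretrained=False and load a checkpoint instead")
        self.cfg = cfg
        base = max(4, int(round(16 * cfg.width_scale)))
        self.feature_dim = 4 * base
        self.trunk = nn.Sequential(
            nn.Conv2d(3, base, 3, 2, rng=rng), nn.ReLU(),
            nn.ResidualBlock(base, rng=rng),
            nn.Conv2d(base, 2 * base, 3, 2, rng=rng), nn.ReLU(),
            nn.ResidualBlock(2 * base, rng=rng),
            nn.Conv2d(2 * base, 4 * base, 3, 2, rng=rng), nn.ReLU(),
            nn.GlobalAvgPool(),
        )
        head_in = self.feature_dim + (1 if cfg.age_fusion else 0)
        self.head = nn.Linear(head_in, cfg.num_classes, rng=rng)

    def params(self):
        return self.trunk.params() + self.head.params()

    def forward(self, x, age=None, train=False):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) images, got {x.shape}")
        if self.cfg.age_fusion:
            if age is None:
                raise ValueError("age_fusion classifier requires an age input")
            age = np.asarray(age, dtype=np.float64).reshape(-1, 1) / 100.0
        feat = self.trunk.forward(x, train=train)
        if self.cfg.age_fusion:
            feat = np.concatenate([feat, age], axis=1)
        self.fused_dim_ = feat.shape[1]
        return self.head.forward(feat, train=train)

    def backward(self, dlogits):
        dfeat = self.head.backward(dlogits)
        if self.cfg.age_fusion:
            dfeat = dfeat[:, :-1]
        return self.trunk.backward(dfeat)

    def predict_proba(self, x, age=None):
        return nn.softmax(self.forward(x, age=age, train=False))


def build_classifier(cfg: ClassifierConfig, seed: int = 0) -> Classifier:
    return Classifier(cfg, np.random.default_rng(seed))


def classifier_forward(classifier: Classifier, image, age=None) -> np.ndarray:
    """Probability vector(s) over the classes for (a batch of) image(s)."""
    x = np.asarray(image, dtype=np.float64)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    p = classifier.predict_proba(x, age=age)
    return p[0] if squeeze else p


# --------------------------------------------------------------------------
# weighted cross-entropy

def weighted_ce(probabilities, one_hot_labels, weights) -> float:
    """Class-weighted cross-entropy, averaged over the batch.

    ``weights`` may be a ClassWeights instance or a plain vector.  True
    class probabilities are clamped at 1e-7 before the log.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(one_hot_labels, dtype=float)
    w = np.asarray(getattr(weights, "w", weights), dtype=float)
    if p.ndim == 1:
        p, y = p[None], y[None]
    if p.shape != y.shape or p.shape[1] != w.shape[0]:
        raise ValueError("probabilities, labels and weights disagree in shape")
    p_true = np.clip((p * y).sum(axis=1), LOG_EPS, 1.0)
    w_true = (w[None, :] * y).sum(axis=1)
    return float(np.mean(-w_true * np.log(p_true)))


def weighted_ce_grad_logits(logits, labels_int, weights) -> tuple:
    """Loss and its gradient w.r.t. the logits (softmax folded in)."""
    w = np.asarray(getattr(weights, "w", weights), dtype=float)
    p = nn.softmax(logits)
    n = logits.shape[0]
    onehot = np.eye(logits.shape[1])[np.asarray(labels_int, dtype=int)]
    loss = weighted_ce(p, onehot, w)
    dlogits = w[np.asarray(labels_int, dtype=int)][:, None] * (p - onehot) / n
    return loss, dlogits


# --------------------------------------------------------------------------
# generator (U-Net)

class UNetGenerator:
    """Symmetric encoder/decoder with skip connections and a tanh head.

    Works on images in [-1, 1] of shape (N, 3, S, S) where S equals
    ``cfg.input_size``.  ``stochastic=True`` (the ``train`` flag of
    ``forward``) keeps dropout active, which is the model's source of
    output diversity.

    Level ``i`` runs from 1 (outermost, full resolution / 2) to
    ``depth`` (bottleneck, 1x1 spatial when input_size == 2**depth).
    """

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        self.cfg = cfg
        d = cfg.depth
        ch = [3] + [min(cfg.base_channels * 2**i, cfg.base_channels * 8) for i in range(d)]
        self.ch = ch
        self.enc = {i: nn.Conv2d(ch[i - 1], ch[i], 4, 2, 1, rng=rng) for i in range(1, d + 1)}
        self.enc_norm = {i: nn.InstanceNorm2d(ch[i]) for i in range(2, d)}
        self.dec = {}
        self.dec_norm = {}
        self.dec_drop = {}
        for i in range(d, 0, -1):
            c_in = ch[i] if i == d else 2 * ch[i]
            c_out = ch[i - 1] if i > 1 else 3
            self.dec[i] = nn.ConvTranspose2d(c_in, c_out, 4, 2, 1, rng=rng)
            if i > 1:
                self.dec_norm[i] = nn.InstanceNorm2d(c_out)
            if cfg.dropout_rate > 0 and i > d - 3:
                self.dec_drop[i] = nn.Dropout(cfg.dropout_rate, rng=rng)
        self.tanh = nn.Tanh()

    def params(self):
        ps = []
        for group in (self.enc, self.enc_norm, self.dec, self.dec_norm):
            for l in group.values():
                ps.extend(l.params())
        return ps

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=np.float64)
        S = self.cfg.input_size
        if x.ndim != 4 or x.shape[1:] != (3, S, S):
            raise ValueError(f"expected (N, 3, {S}, {S}) input, got {x.shape}")
        d = self.cfg.depth

        # encoder: a_i = leaky(e_{i-1}) for i > 1; e_i = [norm](conv_i(a_i))
        e = {0: x}
        self._lrelu_masks = {}
        for i in range(1, d + 1):
            a = e[i - 1]
            if i > 1:
                m = a > 0
                self._lrelu_masks[i] = m
                a = np.where(m, a, 0.2 * a)
            h = self.enc[i].forward(a, train)
            if i in self.enc_norm:
                h = self.enc_norm[i].forward(h, train)
            e[i] = h
        self._e = e

        # decoder: from the bottleneck out, concatenating encoder skips
        self._relu_masks = {}
        h = e[d]
        for i in range(d, 0, -1):
            if i < d:
                h = np.concatenate([h, e[i]], axis=1)
            m = h > 0
            self._relu_masks[i] = m
            u = self.dec[i].forward(h * m, train)
            if i in self.dec_norm:
                u = self.dec_norm[i].forward(u, train)
            if i in self.dec_drop:
                u = self.dec_drop[i].forward(u, train)
            h = u
        return self.tanh.forward(h)

    def backward(self, dout):
        d = self.cfg.depth
        du = self.tanh.backward(dout)
        dskip = {}  # gradient flowing into encoder activation e_i via skips
        for i in range(1, d + 1):
            if i in self.dec_drop:
                du = self.dec_drop[i].backward(du)
            if i in self.dec_norm:
                du = self.dec_norm[i].backward(du)
            dh = self.dec[i].backward(du)
            dh = dh * self._relu_masks[i]
            if i < d:
                c = self.ch[i]
                du = dh[:, :c]
                dskip[i] = dh[:, c:]
            else:
                du = dh
        # walk the encoder backwards, merging skip gradients
        de = du  # gradient w.r.t. e_d
        for i in range(d, 0, -1):
            if i in dskip:
                de = de + dskip[i]
            if i in self.enc_norm:
                de = self.enc_norm[i].backward(de)
            da = self.enc[i].backward(de)
            if i > 1:
                m = self._lrelu_masks[i]
                de = np.where(m, da, 0.2 * da)
            else:
                de = da
        return de


def build_generator(cfg: GeneratorConfig, seed: int = 0) -> UNetGenerator:
    return UNetGenerator(cfg, np.random.default_rng(seed))


def generator_forward(generator: UNetGenerator, image, stochastic: bool = False):
    """One forward pass; with ``stochastic`` dropout stays active."""
    x = np.asarray(image, dtype=np.float64)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    y = generator.forward(x, train=stochastic)
    return y[0] if squeeze else y


# --------------------------------------------------------------------------
# patch discriminator

class PatchDiscriminator:
    """Convolutional critic scoring overlapping patches of an image pair.

    Input is the 6-channel concatenation of the current image and the
    candidate future image; output is a 2-D grid of patch logits, one
    per receptive field.
    """

    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator):
        self.cfg = cfg
        layers = []
        c_prev = cfg.in_channels
        for j, (c, s) in enumerate(zip(cfg.layer_channels, cfg.strides)):
            layers.append(nn.Conv2d(c_prev, c, cfg.kernel, s, cfg.pad, rng=rng))
            if 0 < j:
                layers.append(nn.InstanceNorm2d(c))
            layers.append(nn.LeakyReLU(0.2))
            c_prev = c
        layers.append(nn.Conv2d(c_prev, 1, cfg.kernel, 1, cfg.pad, rng=rng))
        self.net = nn.Sequential(*layers)

    def params(self):
        return self.net.params()

    def forward(self, first, second, train=False):
        a = np.asarray(first, dtype=np.float64)
        b = np.asarray(second, dtype=np.float64)
        if a.shape != b.shape:
            raise ValueError(f"image pair shapes differ: {a.shape} vs {b.shape}")
        x = np.concatenate([a, b], axis=1)
        return self.net.forward(x, train=train)[:, 0]

    def backward(self, dout):
        dx = self.net.backward(dout[:, None])
        c = self.cfg.in_channels // 2
        return dx[:, :c], dx[:, c:]


def build_discriminator(cfg: DiscriminatorConfig, seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(cfg, np.random.default_rng(seed))


def discriminator_forward(disc: PatchDiscriminator, first, second) -> np.ndarray:
    """Patch probability map (sigmoid of the patch logits)."""
    a = np.asarray(first, dtype=np.float64)
    squeeze = a.ndim == 3
    if squeeze:
        first = a[None]
        second = np.asarray(second, dtype=np.float64)[None]
    p = nn.sigmoid(disc.forward(first, second))
    return p[0] if squeeze else p


def receptive_field(cfg: DiscriminatorConfig) -> int:
    """Input-pixel receptive field of one output score of the critic.

    Standard recursion over the conv stack (the trailing 1-channel
    scoring convolution included): rf += (k - 1) * jump; jump *= stride.
    """
    rf, jump = 1, 1
    for s in list(cfg.strides) + [1]:
        rf += (cfg.kernel - 1) * jump
        jump *= s
    return rf


# --------------------------------------------------------------------------
# GAN losses

def gan_losses(d_scores_real, d_scores_fake, generated, target,
               lambda_r: float) -> GanLossTerms:
    """Evaluate all terms of the GAN objective from patch probability maps.

    ``d_scores_real``/``d_scores_fake`` are patch maps of probabilities
    (discriminator sigmoid outputs) on a real pair and on a generated
    pair; probabilities are clamped to [1e-7, 1 - 1e-7] inside the logs.
    """
    if lambda_r < 0:
        raise ValueError(f"lambda_r must be non-negative, got {lambda_r}")
    pr = np.clip(np.asarray(d_scores_real, dtype=float), LOG_EPS, 1 - LOG_EPS)
    pf = np.clip(np.asarray(d_scores_fake, dtype=float), LOG_EPS, 1 - LOG_EPS)
    if pr.shape != pf.shape:
        raise ValueError("real and fake score maps must have the same shape")
    g = np.asarray(generated, dtype=float)
    t = np.asarray(target, dtype=float)
    if g.shape != t.shape:
        raise ValueError("generated and target images must have the same shape")
    return GanLossTerms(
        d_real=float(np.mean(np.log(pr))),
        d_fake=float(np.mean(np.log(1.0 - pf))),
        g_adv=float(-np.mean(np.log(pf))),
        g_l1=float(np.mean(np.abs(g - t))),
        lambda_r=float(lambda_r),
    )
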