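"""Scikit-learn-style estimators wrapping the networks and training loops.

``FundusPairClassifier`` grades the current visit's image into the pair
classes (or two classes for plain advanced/not-advanced grading) with a
class-weighted cross-entropy; ``FundusForecaster`` is the conditional
GAN that forecasts the future visit's image.  Both follow sklearn
conventions — constructor hyperparameters, ``fit`` returning self,
trailing-underscore fitted attributes, ``get_params``/``set_params`` —
so they compose with sklearn model selection where useful.

Images everywhere at this interface are channels-last float arrays in
[0, 1]; the channels-first conversion and (for the GAN) the [-1, 1]
rescaling happen internally.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from . import nn
from .evaluation import hand_till_auc
from .models import (ClassifierConfig, DiscriminatorConfig, GeneratorConfig,
                     build_classifier, build_discriminator, build_generator,
                     weighted_ce_grad_logits)
from .pairs import class_histogram, class_weights


def _to_nchw(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 4 or X.shape[3] != 3:
        raise ValueError(f"expected channels-last images (n, H, W, 3), got {X.shape}")
    return X.transpose(0, 3, 1, 2)


def _softplus(z):
    return np.logaddexp(0.0, z)


class FundusPairClassifier(ClassifierMixin, BaseEstimator):
    """CNN grader of fundus images into progression pair classes.

    Training minimizes the inverse-frequency-weighted cross-entropy; the
    model is evaluated on the validation set every ``eval_every_iters``
    optimizer steps and the checkpoint with the lowest validation loss
    is kept (mirroring the training protocol of the study design this
    package implements).

    Parameters
    ----------
    width_scale : channel multiplier of the residual trunk (1.0 is the
        full-size network; small values make CPU-scale models).
    age_fusion : append the (rescaled) age scalar to the pooled features.
    class_weighting : "inverse_freq" or "uniform".
    eval_every_iters : validation cadence in optimizer steps.
    """

    def __init__(self, width_scale=0.25, age_fusion=False, pretrained=False,
                 lr=1e-3, batch_size=32, epochs=20, eval_every_iters=50,
                 class_weighting="inverse_freq", random_state=0):
        self.width_scale = width_scale
        self.age_fusion = age_fusion
        self.pretrained = pretrained
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.eval_every_iters = eval_every_iters
        self.class_weighting = class_weighting
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _encode(self, y):
        y = np.asarray(y)
        idx = np.searchsorted(self.classes_, y)
        if np.any(self.classes_[idx] != y):
            raise ValueError("labels outside the classes seen in fit")
        return idx

    def _val_metrics(self, Xv, yv, agev):
        logits = self._forward_batched(Xv, agev)
        loss, _ = weighted_ce_grad_logits(logits, yv, self.class_weights_)
        proba = nn.softmax(logits)
        try:
            auc = hand_till_auc(yv, proba)
        except ValueError:
            auc = float("nan")
        return loss, auc

    def _forward_batched(self, X, age=None, chunk=256):
        outs = []
        for i in range(0, X.shape[0], chunk):
            a = None if age is None else age[i:i + chunk]
            outs.append(self.net_.forward(X[i:i + chunk], age=a, train=False))
        return np.concatenate(outs, axis=0)

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None, age=None, age_val=None):
        X = _to_nchw(X)
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.n_classes_ = len(self.classes_)
        if self.n_classes_ not in (2, 3):
            raise ValueError(f"need 2 or 3 classes, got {self.n_classes_}")
        yi = self._encode(y)

        if self.class_weighting == "inverse_freq":
            self.class_weights_ = class_weights(
                class_histogram(yi, num_classes=self.n_classes_)).w
        elif self.class_weighting == "uniform":
            self.class_weights_ = np.full(self.n_classes_, 1.0 / self.n_classes_)
        else:
            raise ValueError(f"unknown class_weighting {self.class_weighting!r}")

        cfg = ClassifierConfig(num_classes=self.n_classes_, input_size=X.shape[2],
                               width_scale=self.width_scale,
                               pretrained=self.pretrained,
                               age_fusion=self.age_fusion)
        self.net_ = build_classifier(cfg, seed=self.random_state)
        opt = nn.Adam(self.net_.params(), lr=self.lr)
        rng = np.random.default_rng(self.random_state)

        have_val = X_val is not None and y_val is not None
        if have_val:
            Xv = _to_nchw(X_val)
            yv = self._encode(y_val)
            agev = None if age_val is None else np.asarray(age_val, dtype=float)
        else:  # fall back to checkpointing against the training data
            Xv, yv, agev = X, yi, age

        self.history_ = []
        best = None
        it = 0
        n = X.shape[0]
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                sel = order[start:start + self.batch_size]
                a = None if age is None else np.asarray(age, dtype=float)[sel]
                logits = self.net_.forward(X[sel], age=a, train=True)
                loss, dlogits = weighted_ce_grad_logits(logits, yi[sel],
                                                        self.class_weights_)
                opt.zero_grad()
                self.net_.backward(dlogits)
                opt.step()
                it += 1
                if it % self.eval_every_iters == 0:
                    vloss, vauc = self._val_metrics(Xv, yv, agev)
                    self.history_.append({"iteration": it, "train_loss": loss,
                                          "val_loss": vloss, "val_auc": vauc})
                    if best is None or vloss < best[0]:
                        best = (vloss, vauc, it, nn.get_weights(self.net_))
        # always close with a final evaluation so short runs checkpoint too
        vloss, vauc = self._val_metrics(Xv, yv, agev)
        self.history_.append({"iteration": it, "train_loss": None,
                              "val_loss": vloss, "val_auc": vauc})
        if best is None or vloss < best[0]:
            best = (vloss, vauc, it, nn.get_weights(self.net_))

        self.val_loss_, self.val_auc_, self.best_iteration_, weights = best
        nn.set_weights(self.net_, weights)
        return self

    def predict_proba(self, X, age=None):
        X = _to_nchw(X)
        age = None if age is None else np.asarray(age, dtype=float)
        return nn.softmax(self._forward_batched(X, age))

    def predict(self, X, age=None):
        return self.classes_[np.argmax(self.predict_proba(X, age=age), axis=1)]


class FundusForecaster(TransformerMixin, BaseEstimator):
    """Conditional GAN forecasting the future visit's fundus image.

    The generator is a U-Net conditioned on the current image (dropout
    supplies the stochasticity); the critic is a patch discriminator
    scoring the 6-channel (current, candidate-future) concatenation.
    Training alternates one discriminator and one generator Adam step
    per pair at batch size 1, with the learning rate constant for the
    first ``decay_start_epoch`` epochs and then decayed linearly to 0.
    The generator loss couples the non-saturating adversarial term with
    ``lambda_r`` times the L1 reconstruction error.
    """

    #: the GAN is always trained pair-by-pair
    batch_size = 1

    def __init__(self, input_size=64, depth=6, base_channels=16,
                 dropout_rate=0.5, disc_channels=(64, 128, 256, 512),
                 epochs=200, lr=2e-4, beta1=0.5, beta2=0.999,
                 decay_start_epoch=100, lambda_r=100.0, random_state=0):
        self.input_size = input_size
        self.depth = depth
        self.base_channels = base_channels
        self.dropout_rate = dropout_rate
        self.disc_channels = disc_channels
        self.epochs = epochs
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.decay_start_epoch = decay_start_epoch
        self.lambda_r = lambda_r
        self.random_state = random_state

    def lr_at_epoch(self, epoch: int) -> float:
        """Constant for ``decay_start_epoch`` epochs, then linear to 0."""
        from .training import gan_lr_schedule

        return gan_lr_schedule(epoch, self.epochs, self.decay_start_epoch, self.lr)

    def _val_l1(self, Xv, Yv) -> float:
        out = []
        for i in range(0, Xv.shape[0], 16):
            out.append(np.abs(self.generator_.forward(Xv[i:i + 16], train=False)
                              - Yv[i:i + 16]).mean(axis=(1, 2, 3)))
        return float(np.concatenate(out).mean())

    def fit(self, X, Y, X_val=None, Y_val=None):
        X = _to_nchw(X) * 2.0 - 1.0
        Y = _to_nchw(Y) * 2.0 - 1.0
        if X.shape != Y.shape:
            raise ValueError("input and target image stacks must match in shape")
        if X.shape[2] != X.shape[3] or X.shape[2] != self.input_size:
            raise ValueError(
                f"expected square {self.input_size}px images, got {X.shape[2:]}" )
        if self.lambda_r < 0:
            raise ValueError("lambda_r must be non-negative")

        gcfg = GeneratorConfig(input_size=self.input_size, depth=self.depth,
                               base_channels=self.base_channels,
                               dropout_rate=self.dropout_rate)
        dcfg = DiscriminatorConfig(layer_channels=tuple(self.disc_channels),
                                   strides=(2, 2, 2, 1)[:len(self.disc_channels)])
        self.generator_ = build_generator(gcfg, seed=self.random_state)
        self.discriminator_ = build_discriminator(dcfg, seed=self.random_state + 1)
        g_opt = nn.Adam(self.generator_.params(), lr=self.lr,
                        betas=(self.beta1, self.beta2))
        d_opt = nn.Adam(self.discriminator_.params(), lr=self.lr,
                        betas=(self.beta1, self.beta2))
        rng = np.random.default_rng(self.random_state)

        have_val = X_val is not None and Y_val is not None
        Xv = _to_nchw(X_val) * 2.0 - 1.0 if have_val else X
        Yv = _to_nchw(Y_val) * 2.0 - 1.0 if have_val else Y

        self.val_l1_init_ = self._val_l1(Xv, Yv)
        self.history_ = []
        best = (self.val_l1_init_, 0, nn.get_weights(self.generator_))
        n = X.shape[0]
        for epoch in range(1, self.epochs + 1):
            lr_e = self.lr_at_epoch(epoch)
            g_opt.lr = d_opt.lr = lr_e
            ep = {"d": 0.0, "g_adv": 0.0, "g_l1": 0.0}
            for i in rng.permutation(n):
                x, y = X[i:i + 1], Y[i:i + 1]
                fake = self.generator_.forward(x, train=True)

                # discriminator step: maximize log D(x,y) + log(1 - D(x,fake))
                d_opt.zero_grad()
                zr = self.discriminator_.forward(x, y, train=True)
                npatch = zr[0].size
                self.discriminator_.backward(-(1.0 - nn.sigmoid(zr)) / npatch)
                zf = self.discriminator_.forward(x, fake, train=True)
                self.discriminator_.backward(nn.sigmoid(zf) / npatch)
                d_opt.step()
                ep["d"] += float(np.mean(_softplus(-zr)) + np.mean(_softplus(zf)))

                # generator step: non-saturating adversarial + lambda_r * L1
                zf = self.discriminator_.forward(x, fake, train=True)
                _, dfake = self.discriminator_.backward(
                    -(1.0 - nn.sigmoid(zf)) / npatch)
                dfake = dfake + self.lambda_r * np.sign(fake - y) / fake.size
                g_opt.zero_grad()
                self.generator_.backward(dfake)
                g_opt.step()
                ep["g_adv"] += float(np.mean(_softplus(-zf)))
                ep["g_l1"] += float(np.abs(fake - y).mean())

            val_l1 = self._val_l1(Xv, Yv)
            self.history_.append({"epoch": epoch, "lr": lr_e,
                                  "d_loss": ep["d"] / n,
                                  "g_adv": ep["g_adv"] / n,
                                  "g_l1": ep["g_l1"] / n,
                                  "val_l1": val_l1})
            if val_l1 < best[0]:
                best = (val_l1, epoch, nn.get_weights(self.generator_))
        self.best_val_l1_, self.best_epoch_, self.best_weights_ = best
        self.final_weights_ = nn.get_weights(self.generator_)
        return self

    def use_best(self):
        """Load the best-validation-L1 generator weights (default: final)."""
        nn.set_weights(self.generator_, self.best_weights_)
        return self

    def transform(self, X, stochastic: bool = False) -> np.ndarray:
        """Forecast future images for channels-last [0, 1] inputs."""
        Xn = _to_nchw(X) * 2.0 - 1.0
        out = []
        for i in range(0, Xn.shape[0], 16):
            out.append(self.generator_.forward(Xn[i:i + 16], train=stochastic))
        y = np.concatenate(out, axis=0)
        return ((y + 1.0) / 2.0).clip(0.0, 1.0).transpose(0, 2, 3, 1)

    predict = transform
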