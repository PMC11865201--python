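"""Scikit-learn style estimator wrapping the ECA leaf-disease network.

``LeafDiseaseClassifier`` follows the fit/predict contract: ``X`` is an
array of RGB images shaped (n_samples, H, W, 3) (uint8 or float in
[0, 255]), ``y`` is an array of class labels.  Images are resized to
``image_size`` and scaled to [0, 1] before entering the network.  It
composes with sklearn model selection and pipelines via
``get_params``/``set_params``; fitted state lives in trailing-underscore
attributes (``classes_``, ``network_``, ``loss_curve_``).
"""

from __future__ import annotations

import numpy as np
from PIL import Image
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._layers import Adam, cross_entropy_grad, softmax
from .network import Network, NetworkSpec, build_network


def _prepare(X, image_size: int) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim == 3:
        X = X[None]
    if X.ndim != 4 or X.shape[-1] != 3:
        raise ValueError(f"expected (n, H, W, 3) RGB images, got shape {X.shape}")
    if X.shape[0] == 0:
        raise ValueError("empty image batch")
    if X.shape[1] != image_size or X.shape[2] != image_size:
        resized = np.empty((X.shape[0], image_size, image_size, 3), np.uint8)
        for i, img in enumerate(X):
            pil = Image.fromarray(np.clip(img, 0, 255).astype(np.uint8), "RGB")
            resized[i] = np.asarray(pil.resize((image_size, image_size),
                                               Image.BILINEAR))
        X = resized
    return (X.astype(np.float32) / 255.0).transpose(0, 3, 1, 2)


class LeafDiseaseClassifier(ClassifierMixin, BaseEstimator):
    """Ultra-lightweight ECA-attention CNN classifier for leaf crops.

    Parameters
    ----------
    variant : {"full", "no_eca", "no_dropout"}
        Architecture variant; the ablations drop every attention gate or
        the head dropout stage respectively.
    image_size : int
        Side length images are resized to; 448 is the paper-scale default,
        64 the test scale.  Channel widths and strides are unchanged.
    epochs, batch_size, learning_rate : training hyperparameters
        Cross-entropy loss optimised with Adam.
    dropout_rate : float
        Head dropout probability (ignored by the ``no_dropout`` variant).
    random_state : int
        Seeds initialisation, batching and dropout; fits are reproducible.
    """

    def __init__(self, variant="full", image_size=448, epochs=3, batch_size=32,
                 learning_rate=1e-3, dropout_rate=0.2, random_state=0):
        self.variant = variant
        self.image_size = image_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.dropout_rate = dropout_rate
        self.random_state = random_state

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training data must contain at least two classes")
        spec = NetworkSpec(num_classes=len(self.classes_),
                           dropout_rate=self.dropout_rate,
                           input_size=self.image_size)
        self.network_ = build_network(spec, self.variant, seed=self.random_state)
        Xp = _prepare(X, self.image_size)
        rng = np.random.default_rng(self.random_state)
        opt = Adam(self.network_.params, self.network_.grads,
                   lr=self.learning_rate)
        n = Xp.shape[0]
        self.loss_curve_ = []
        for _ in range(int(self.epochs)):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                if len(idx) < 2:
                    continue  # batch norm needs more than one sample
                logits = self.network_.forward(Xp[idx], training=True)
                loss, grad = cross_entropy_grad(logits, y_idx[idx])
                self.network_.backward(grad)
                opt.step()
                losses.append(loss)
            self.loss_curve_.append(float(np.mean(losses)) if losses else np.nan)
        if self.epochs and n > 1:
            self._recalibrate_batchnorm(Xp)
        self.n_features_in_ = int(np.prod(Xp.shape[1:]))
        return self

    def _recalibrate_batchnorm(self, Xp):
        """Replace the EMA batch-norm statistics with cumulative averages
        computed under the final weights (one pass, no gradients).

        Short runs leave the exponential running estimates dominated by
        early-training activations; inference then sees normalisation
        statistics the final weights were never trained against."""
        from ._layers import BatchNorm2d
        from .network import _iter_layers

        bns = [l for l in _iter_layers(self.network_.stack)
               if isinstance(l, BatchNorm2d)]
        saved = [b.momentum for b in bns]
        for b in bns:
            b.running_mean[...] = 0.0
            b.running_var[...] = 0.0
        n = Xp.shape[0]
        step = 0
        for start in range(0, n, self.batch_size):
            batch = Xp[start:start + self.batch_size]
            if batch.shape[0] < 2:
                continue
            step += 1
            for b in bns:
                b.momentum = 1.0 / step  # cumulative mean of batch statistics
            self.network_.forward(batch, training=True)
        for b, m in zip(bns, saved):
            b.momentum = m

    def decision_function(self, X):
        check_is_fitted(self, "network_")
        Xp = _prepare(X, self.image_size)
        out = []
        for start in range(0, Xp.shape[0], max(self.batch_size, 1)):
            out.append(self.network_.forward(Xp[start:start + self.batch_size],
                                             training=False))
        return np.concatenate(out)

    def predict_proba(self, X):
        return softmax(self.decision_function(X))

    def predict(self, X):
        check_is_fitted(self, "network_")
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    # -- extras ----------------------------------------------------------
    def parameter_count(self) -> int:
        check_is_fitted(self, "network_")
        return self.network_.parameter_count()

    def save(self, path) -> None:
        check_is_fitted(self, "network_")
        self.network_.save(path)
        np.savez(str(path) + ".classes.npz", classes=self.classes_)

    @classmethod
    def load(cls, path) -> "LeafDiseaseClassifier":
        net = Network.load(path)
        est = cls(variant=net.variant, image_size=net.spec.input_size,
                  dropout_rate=net.spec.dropout_rate)
        est.network_ = net
        with np.load(str(path) + ".classes.npz", allow_pickle=True) as d:
            est.classes_ = d["classes"]
        est.loss_curve_ = []
        est.n_features_in_ = 3 * net.spec.input_size**2
        return est
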