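"""Scikit-learn style classifiers wrapping the two network branches.

``SmriClassifier`` consumes multi-view slice tensors (n_subjects, 3, n_slices,
H, W); ``FmriClassifier`` consumes ROI time-series arrays (n_subjects, T, R)
and derives functional-connectivity features internally;
``DualModalClassifier`` consumes a tuple of both and fuses the embeddings.

All three expose ``fit`` / ``predict`` / ``predict_proba`` / ``get_params``
and compose with sklearn model selection.  Training is a seeded Adam
minibatch loop over the focal (or cross-entropy) loss, optionally with Mixup;
given a seed the whole trajectory is deterministic.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .nn import modules as M
from .nn.autodiff import Tensor, no_grad
from .nn.ops import entropy_penalty, softmax
from .nn.temporal import fc_vectorize
from .preprocess.fmri import connectivity
from .train_eval import cross_entropy, focal_loss, mixup

__all__ = ["SmriClassifier", "FmriClassifier", "DualModalClassifier"]


class _BaseNetClassifier(BaseEstimator, ClassifierMixin):
    """Shared seeded training loop; subclasses build the network and map X
    to network inputs."""

    def _more_tags(self):
        return {"binary_only": True}

    # -- subclass hooks ---------------------------------------------------
    def _build_net(self, X, rng) -> M.Module:
        raise NotImplementedError

    def _net_inputs(self, X):
        """Map estimator X to (array_for_mixup, extra_inputs...) tuple."""
        raise NotImplementedError

    def _forward(self, inputs, training, rng):
        raise NotImplementedError

    def _loss(self, logits, z, y_soft):
        if self.loss == "focal":
            base = focal_loss(logits, y_soft, alpha=self.alpha, gamma=self.gamma)
        elif self.loss == "ce":
            base = cross_entropy(logits, y_soft)
        else:
            raise ValueError(f"unknown loss {self.loss!r}")
        lam = getattr(self, "lambda_ent", 0.0)
        if lam:
            base = base + lam * entropy_penalty(z)
        return base

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary classification only")
        y_idx = np.searchsorted(self.classes_, y)
        rng = np.random.default_rng(self.seed)
        inputs = self._net_inputs(X)
        n = len(y_idx)
        if any(len(part) != n for part in inputs):
            raise ValueError("X and y length mismatch")
        self.net_ = self._build_net(X, rng)
        opt = M.Adam(self.net_.parameters(), lr=self.lr)
        self.history_ = []
        onehot = np.eye(2)[y_idx]
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for lo in range(0, n, self.batch_size):
                rows = order[lo : lo + self.batch_size]
                parts = [p[rows] for p in inputs]
                y_soft = onehot[rows]
                if self.mixup:
                    lam = float(rng.beta(self.mixup_alpha, self.mixup_alpha))
                    if len(rows) >= 2:
                        j = rng.permutation(len(rows))
                        parts = [lam * p + (1 - lam) * p[j] for p in parts]
                        y_soft = lam * y_soft + (1 - lam) * y_soft[j]
                logits, z = self._forward(parts, training=True, rng=rng)
                loss = self._loss(logits, z, y_soft)
                self.net_.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            self.history_.append(float(np.mean(losses)))
        self.n_features_in_ = int(np.prod(np.shape(inputs[0])[1:]))
        return self

    def decision_scores(self, X):
        check_is_fitted(self, "net_")
        inputs = self._net_inputs(X)
        n = len(inputs[0])
        outs = []
        with no_grad():
            for lo in range(0, n, max(self.batch_size, 1)):
                parts = [p[lo : lo + self.batch_size] for p in inputs]
                logits, _ = self._forward(parts, training=False, rng=None)
                outs.append(logits.data)
        return np.concatenate(outs, axis=0)

    def predict_proba(self, X):
        logits = self.decision_scores(X)
        return softmax(logits, axis=-1).data

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


class SmriClassifier(_BaseNetClassifier):
    """Multi-view hierarchical 3D convolutional classifier.

    X has shape (n_subjects, 3, n_slices, H, W), the planes ordered
    (axial, coronal, sagittal) as produced by
    :func:`neurofuse.slicing.assemble_multiview`.  The default architecture
    is a reduced desk-scale channel plan; pass ``channels=(32, 64, 128, 256),
    kernels=(3, 5, 3, 5)`` for the full-scale plan.
    """

    def __init__(self, channels=(4, 8), kernels=(3, 3), dilations=(1, 1),
                 strides=(2, 2), spectral_norm=True, channel_attn=True,
                 spatial_attn=True, graph_head=False, lambda_ent=1e-3,
                 loss="focal", alpha=0.25, gamma=2.0, mixup=False,
                 mixup_alpha=0.2, lr=1e-3, batch_size=16, epochs=30, seed=0):
        self.channels = channels
        self.kernels = kernels
        self.dilations = dilations
        self.strides = strides
        self.spectral_norm = spectral_norm
        self.channel_attn = channel_attn
        self.spatial_attn = spatial_attn
        self.graph_head = graph_head
        self.lambda_ent = lambda_ent
        self.loss = loss
        self.alpha = alpha
        self.gamma = gamma
        self.mixup = mixup
        self.mixup_alpha = mixup_alpha
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    def _config(self) -> M.SmriConfig:
        return M.SmriConfig(
            channels=tuple(self.channels), kernels=tuple(self.kernels),
            dilations=tuple(self.dilations), strides=tuple(self.strides),
            spectral_norm=self.spectral_norm, channel_attn=self.channel_attn,
            spatial_attn=self.spatial_attn, graph_head=self.graph_head,
            lambda_ent=self.lambda_ent,
        )

    def _build_net(self, X, rng):
        return M.SmriNet(self._config(), rng)

    def _net_inputs(self, X):
        X = np.asarray(X, float)
        if X.ndim != 5 or X.shape[1] != 3:
            raise ValueError("expected X of shape (n, 3, n_slices, H, W)")
        # standardize per sample for stable optimization
        mu = X.mean(axis=(1, 2, 3, 4), keepdims=True)
        sd = X.std(axis=(1, 2, 3, 4), keepdims=True)
        sd[sd == 0] = 1.0
        return ((X - mu) / sd,)

    def _forward(self, parts, training, rng):
        return self.net_.forward(parts[0], training=training, rng=rng)


class FmriClassifier(_BaseNetClassifier):
    """Temporal fMRI classifier over ROI time series.

    X has shape (n_subjects, T, R); per subject, the Fisher-z functional
    connectivity vector is computed from the series and fused with the
    Bi-LSTM attention embedding.
    """

    def __init__(self, d_h=16, d_f=32, raw_fc_in_concat=True,
                 loss="focal", alpha=0.25, gamma=2.0, mixup=False,
                 mixup_alpha=0.2, lr=1e-3, batch_size=16, epochs=30, seed=0):
        self.d_h = d_h
        self.d_f = d_f
        self.raw_fc_in_concat = raw_fc_in_concat
        self.loss = loss
        self.alpha = alpha
        self.gamma = gamma
        self.mixup = mixup
        self.mixup_alpha = mixup_alpha
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    def _config(self, R) -> M.FmriConfig:
        return M.FmriConfig(n_rois=R, d_h=self.d_h, d_f=self.d_f,
                            raw_fc_in_concat=self.raw_fc_in_concat)

    def _build_net(self, X, rng):
        return M.FmriNet(self._config(np.shape(X)[-1]), rng)

    def _net_inputs(self, X):
        X = np.asarray(X, float)
        if X.ndim != 3:
            raise ValueError("expected X of shape (n, T, R)")
        # per-sample, per-ROI standardization of the series
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        S = (X - mu) / sd
        fc = np.stack([fc_vectorize(connectivity(s).z_mat) for s in X])
        return (S, fc)

    def _forward(self, parts, training, rng):
        return self.net_.forward((parts[0], parts[1]), training=training,
                                 rng=rng)


class DualModalClassifier(_BaseNetClassifier):
    """Fused dual-modality classifier.

    X is a tuple ``(X_smri, X_fmri)`` with the shapes of the two
    single-modality estimators; the modality embeddings are projected to a
    common width and fused as [proj_s, proj_f, proj_s * proj_f].
    """

    def __init__(self, channels=(4, 8), kernels=(3, 3), dilations=(1, 1),
                 strides=(2, 2), d_h=16, d_f=32, common_width=64,
                 lambda_ent=0.0, loss="focal", alpha=0.25, gamma=2.0,
                 mixup=False, mixup_alpha=0.2, lr=1e-3, batch_size=16,
                 epochs=30, seed=0):
        self.channels = channels
        self.kernels = kernels
        self.dilations = dilations
        self.strides = strides
        self.d_h = d_h
        self.d_f = d_f
        self.common_width = common_width
        self.lambda_ent = lambda_ent
        self.loss = loss
        self.alpha = alpha
        self.gamma = gamma
        self.mixup = mixup
        self.mixup_alpha = mixup_alpha
        self.lr = lr
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    def _build_net(self, X, rng):
        smri_cfg = M.SmriConfig(
            channels=tuple(self.channels), kernels=tuple(self.kernels),
            dilations=tuple(self.dilations), strides=tuple(self.strides),
        )
        fmri_cfg = M.FmriConfig(n_rois=np.shape(X[1])[-1], d_h=self.d_h,
                                d_f=self.d_f)
        return M.FusedNet(smri_cfg, fmri_cfg, rng,
                          common_width=self.common_width)

    def _net_inputs(self, X):
        xs, xf = X
        (xs_n,) = SmriClassifier._net_inputs(self, xs)
        xf = np.asarray(xf, float)
        mu = xf.mean(axis=1, keepdims=True)
        sd = xf.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        S = (xf - mu) / sd
        fc = np.stack([fc_vectorize(connectivity(s).z_mat) for s in xf])
        return (xs_n, S, fc)

    def _forward(self, parts, training, rng):
        return self.net_.forward((parts[0], parts[1], parts[2]),
                                 training=training, rng=rng)

    def fit(self, X, y):  # X is a tuple; base fit handles indexable parts
        return super().fit(X, y)
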