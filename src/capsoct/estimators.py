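"""scikit-learn estimator surface.

`CapsNetClassifier` wraps model assembly, the training loop and prediction in
the familiar fit/predict contract so the network composes with sklearn
pipelines and model selection; `ClaheTransform` exposes the CLAHE operator as
a stateless transformer.
"""

from __future__ import annotations

import time
from dataclasses import replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .autodiff import Adam
from .capsule_ops import MarginLossParams, SquashSpec, margin_loss
from .clahe import ClaheParams, clahe_layer
from .model_assembly import PRESETS, CapsNetModel, reconstruction_loss

__all__ = ["CapsNetClassifier", "ClaheTransform"]


class ClaheTransform(BaseEstimator, TransformerMixin):
    """Stateless CLAHE transformer for image batches.

    Accepts (n, H, W, C) arrays (or (n, H*W*C) with ``image_shape`` set) and
    enhances each channel independently; output shape equals input shape.
    """

    def __init__(self, tile_grid=(8, 8), clip_limit=2.0, n_bins=256, image_shape=None):
        self.tile_grid = tile_grid
        self.clip_limit = clip_limit
        self.n_bins = n_bins
        self.image_shape = image_shape

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1:]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        flat = X.ndim == 2
        if flat:
            if self.image_shape is None:
                raise ValueError("flat input requires image_shape")
            X = X.reshape(len(X), *self.image_shape)
        params = ClaheParams(
            tile_grid=tuple(self.tile_grid),
            clip_limit=self.clip_limit,
            n_bins=self.n_bins,
        )
        out = clahe_layer(X, params)
        return out.reshape(len(out), -1) if flat else out


class CapsNetClassifier(BaseEstimator, ClassifierMixin):
    """Capsule-network image classifier with optional CLAHE enhancement layers.

    Parameters mirror the published training recipe: Adam with first-moment
    coefficient ``beta1`` = 0.9, learning rate 1e-4 with per-step decay 1e-6,
    batch size 32, 100 epochs.  ``architecture`` selects the CLAHE-enhanced
    three-convolution capsule network or the original single-convolution
    baseline; ``scale`` = 'tiny' narrows channel widths for CPU-scale runs
    (same kernels, strides and routing).

    Parameters
    ----------
    architecture : 'clahe_capsnet' | 'baseline_capsnet'
    scale : 'full' | 'tiny'
    epochs, batch_size, learning_rate, lr_decay, beta1 : training recipe.
    routing_iters : dynamic-routing iterations (logits reset to 0 per pass).
    coupling_mode : 'sigmoid' | 'softmax' coupling of routing logits.
    squash, squash_exponent : 'power' (with exponent) or 'original' squash.
    recon_weight : weight of the masked-decoder reconstruction loss.
    m_plus, m_minus, loss_lambda : margin-loss hyperparameters.
    input_shape : (H, W, C) the network expects; flat input is reshaped.
    random_state : seeds weight init and batch order.

    Attributes (after fit)
    ----------------------
    classes_ : sorted class labels.
    model_ : the built :class:`~capsoct.model_assembly.CapsNetModel`.
    shape_trace_ : audited per-layer shapes / parameter counts.
    history_ : per-epoch train (and validation) loss and accuracy.
    """

    def __init__(
        self,
        architecture="clahe_capsnet",
        scale="full",
        epochs=100,
        batch_size=32,
        learning_rate=1e-4,
        lr_decay=1e-6,
        beta1=0.9,
        routing_iters=3,
        coupling_mode=None,
        squash=None,
        squash_exponent=3.0,
        recon_weight=0.0005,
        m_plus=0.9,
        m_minus=0.1,
        loss_lambda=0.5,
        input_shape=(48, 48, 3),
        random_state=0,
        verbose=0,
        config=None,
    ):
        self.architecture = architecture
        self.scale = scale
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.beta1 = beta1
        self.routing_iters = routing_iters
        self.coupling_mode = coupling_mode
        self.squash = squash
        self.squash_exponent = squash_exponent
        self.recon_weight = recon_weight
        self.m_plus = m_plus
        self.m_minus = m_minus
        self.loss_lambda = loss_lambda
        self.input_shape = input_shape
        self.random_state = random_state
        self.verbose = verbose
        self.config = config

    # -- config resolution -------------------------------------------------
    def _resolve_config(self, n_classes):
        if self.config is not None:
            cfg = self.config
        else:
            key = self.architecture + ("_tiny" if self.scale == "tiny" else "")
            if key not in PRESETS:
                raise ValueError(f"unknown architecture/scale: {key}")
            cfg = PRESETS[key](n_classes=n_classes,
                               input_shape=tuple(self.input_shape))
        updates = {"routing_iters": self.routing_iters,
                   "recon_weight": self.recon_weight}
        if self.coupling_mode is not None:
            updates["coupling_mode"] = self.coupling_mode
        if self.squash is not None:
            updates["squash"] = SquashSpec(self.squash, self.squash_exponent)
        if cfg.n_classes != n_classes:
            updates["n_classes"] = n_classes
        return replace(cfg, **updates)

    def _as_images(self, X, cfg):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X.reshape(len(X), *cfg.input_shape)
        if X.shape[1:] != tuple(cfg.input_shape):
            raise ValueError(
                f"input images {X.shape[1:]} != expected {cfg.input_shape}"
            )
        return X

    # -- training ----------------------------------------------------------
    def fit(self, X, y, validation_data=None):
        """Train with margin loss plus masked reconstruction regulariser.

        validation_data : optional (X_val, y_val); when given, per-epoch
        validation metrics are logged and the weights of the best
        validation-accuracy epoch are restored at the end.
        """
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        cfg = self._resolve_config(len(self.classes_))
        X = self._as_images(X, cfg)
        self.n_features_in_ = int(np.prod(X.shape[1:]))

        seed = int(self.random_state) % (2**31)
        model = CapsNetModel(cfg, seed=seed)
        opt = Adam(model.params, lr=self.learning_rate, beta1=self.beta1,
                   decay=self.lr_decay)
        mparams = MarginLossParams(self.m_plus, self.m_minus, self.loss_lambda)
        rng = np.random.default_rng(seed + 1)

        if validation_data is not None:
            Xv = self._as_images(validation_data[0], cfg)
            yv_idx = np.searchsorted(self.classes_, np.asarray(validation_data[1]))

        # the input enhancement layer is deterministic: apply it once
        Xp = model.preprocess_input(X)

        history = {"epoch": [], "train_loss": [], "train_acc": [],
                   "val_loss": [], "val_acc": []}
        best = (-np.inf, None)
        t0 = time.time()
        n = len(X)
        for epoch in range(int(self.epochs)):
            order = rng.permutation(n)
            tot_loss = tot_correct = 0.0
            for start in range(0, n, int(self.batch_size)):
                idx = order[start : start + int(self.batch_size)]
                xb, yb = Xp[idx], y_idx[idx]
                out = model.forward(xb, labels=yb, skip_input_clahe=True)
                onehot = np.eye(len(self.classes_), dtype=np.float32)[yb]
                loss = margin_loss(out["lengths"], onehot, mparams)
                if cfg.recon_weight > 0:
                    # decoder redraws the raw (pre-enhancement) input
                    loss = loss + reconstruction_loss(
                        out["recon"], X[idx].reshape(len(idx), -1), cfg.recon_weight
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                tot_loss += float(loss.data) * len(idx)
                tot_correct += float(
                    np.sum(np.argmax(out["lengths"].data, axis=1) == yb)
                )
            history["epoch"].append(epoch)
            history["train_loss"].append(tot_loss / n)
            history["train_acc"].append(tot_correct / n)
            if validation_data is not None:
                vl, va = self._eval_split(model, Xv, yv_idx, mparams, cfg)
                history["val_loss"].append(vl)
                history["val_acc"].append(va)
                if va > best[0]:
                    best = (va, model.get_weights())
            if self.verbose:
                msg = (f"epoch {epoch + 1}/{self.epochs} "
                       f"loss {history['train_loss'][-1]:.4f} "
                       f"acc {history['train_acc'][-1]:.3f}")
                if validation_data is not None:
                    msg += f" val_acc {history['val_acc'][-1]:.3f}"
                print(msg)
        if validation_data is not None and best[1] is not None:
            model.set_weights(best[1])
        history["wall_clock_s"] = time.time() - t0
        self.model_ = model
        self.config_ = cfg
        self.shape_trace_ = model.trace
        self.history_ = history
        return self

    @staticmethod
    def _eval_split(model, X, y_idx, mparams, cfg, batch_size=256):
        scores = model.predict_scores(X, batch_size=batch_size)
        onehot = np.eye(cfg.n_classes, dtype=np.float64)[y_idx]
        loss = float(margin_loss(scores, onehot, mparams))
        acc = float(np.mean(np.argmax(scores, axis=1) == y_idx))
        return loss, acc

    # -- inference ---------------------------------------------------------
    def decision_function(self, X):
        """Class-capsule lengths, shape (n, k); argmax is the prediction."""
        check_is_fitted(self, "model_")
        X = self._as_images(X, self.config_)
        return self.model_.predict_scores(X)

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]
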