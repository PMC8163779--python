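"""Compact convolutional gesture classifier over 4x8 activation frames.

:class:`GridConvNetClassifier` is a scikit-learn style estimator (``fit`` /
``predict`` / ``get_params`` / ``set_params``) around a small NumPy CNN.
Its parameters are explicitly partitioned into *feature layers* (two 3x3
convolutions and one hidden dense layer) and a *classifier head* (the
final dense layer); the two-phase transfer-learning protocol in
:mod:`myogrid.transfer` relies on that partition — session fine-tuning
updates the head only and leaves the feature layers bit-identical.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from . import nn
from .synthetic import GRID_SHAPE, N_CHANNELS


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/validation/test fractions (default 70/15/15)."""

    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15

    def __post_init__(self) -> None:
        total = self.train_frac + self.val_frac + self.test_frac
        if not np.isclose(total, 1.0):
            raise ValueError("split fractions must sum to 1")
        if min(self.train_frac, self.val_frac, self.test_frac) <= 0:
            raise ValueError("split fractions must be positive")


def split_dataset(X, y, spec: SplitSpec = SplitSpec(), seed: int = 0):
    """Stratified 70/15/15 split; per-label proportions within one sample.

    Returns ``(X_train, y_train), (X_val, y_val), (X_test, y_test)``.
    Rejects degenerate inputs (any label with fewer than 3 samples cannot
    appear in all three splits).
    """
    X = np.asarray(X)
    y = np.asarray(y)
    labels, counts = np.unique(y, return_counts=True)
    if labels.size < 1:
        raise ValueError("empty dataset")
    if counts.min() < 3:
        scarce = labels[counts < 3].tolist()
        raise ValueError(f"labels {scarce} have fewer than 3 samples; cannot stratify")
    holdout = spec.val_frac + spec.test_frac
    X_tr, X_rest, y_tr, y_rest = train_test_split(
        X, y, test_size=holdout, stratify=y, random_state=seed
    )
    X_val, X_te, y_val, y_te = train_test_split(
        X_rest,
        y_rest,
        test_size=spec.test_frac / holdout,
        stratify=y_rest,
        random_state=seed,
    )
    return (X_tr, y_tr), (X_val, y_val), (X_te, y_te)


def _as_batch(X) -> np.ndarray:
    """Coerce frames to (N, 1, 4, 8) float32, validating shape and values."""
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 2 and X.shape == GRID_SHAPE:  # a single frame
        X = X[None]
    if X.ndim == 2 and X.shape[1] == N_CHANNELS:
        X = X.reshape(-1, *GRID_SHAPE)
    if X.ndim != 3 or X.shape[1:] != GRID_SHAPE:
        raise ValueError(
            f"frames must be (N, {GRID_SHAPE[0]}, {GRID_SHAPE[1]}) or (N, {N_CHANNELS}); "
            f"got {X.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("frames contain non-finite values")
    return X[:, None, :, :]


class GridConvNetClassifier(BaseEstimator, ClassifierMixin):
    """Small CNN classifier for HD-EMG activation maps.

    Parameters
    ----------
    n_filters1, n_filters2 : int
        Channels of the two 3x3 convolution layers (same padding keeps the
        4x8 grid, preserving translational structure).
    hidden_units : int
        Width of the dense layer feeding the head.
    trainable : {"all", "head"}
        Which parameter partition gradient updates may touch.  ``"head"``
        freezes the feature layers bit-for-bit.
    warm_start : bool
        Continue from the previously fitted parameters instead of
        re-initializing (used for user adaptation and session fine-tuning).
    val_fraction : float
        Internal stratified hold-out used for early stopping.
    scale : float or None
        Fixed input amplitude scale; ``None`` estimates it from the
        training data (mean per-frame peak amplitude).
    amp_jitter : tuple or None
        Log-uniform range of random per-frame amplitude scaling applied to
        non-neutral training frames each epoch.  Contraction intensity is
        effort-dependent and uncontrolled in real use, and during gesture
        transitions the activation pattern passes through scaled-down
        versions of itself; the augmentation teaches the classifier that a
        gesture's spatial pattern, not its absolute amplitude, carries the
        label.  ``None`` disables it.

    Attributes
    ----------
    params_ : dict of ndarray
        Network parameters, keyed by layer name.
    classes_ : ndarray
        Sorted class labels seen at the first fit.
    scale_ : float
        Amplitude normalization divisor.
    training_log_ : list of dict
        Per-epoch loss and validation accuracy, appended across fits.
    """

    def __init__(
        self,
        n_filters1: int = 8,
        n_filters2: int = 16,
        hidden_units: int = 32,
        learning_rate: float = 1e-3,
        batch_size: int = 256,
        max_epochs: int = 30,
        patience: int = 5,
        val_fraction: float = 0.15,
        trainable: str = "all",
        warm_start: bool = False,
        scale: float = None,
        amp_jitter: tuple = (0.25, 2.0),
        random_state: int = None,
    ):
        self.n_filters1 = n_filters1
        self.n_filters2 = n_filters2
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.trainable = trainable
        self.warm_start = warm_start
        self.scale = scale
        self.amp_jitter = amp_jitter
        self.random_state = random_state

    # -- partition introspection -------------------------------------------------
    @staticmethod
    def layer_partition() -> dict:
        """Explicit feature/head parameter name partition."""
        return {"feature_layers": list(nn.FEATURE_PARAMS), "classifier_head": list(nn.HEAD_PARAMS)}

    def feature_parameters(self) -> dict:
        check_is_fitted(self, "params_")
        return {k: self.params_[k] for k in nn.FEATURE_PARAMS}

    def head_parameters(self) -> dict:
        check_is_fitted(self, "params_")
        return {k: self.params_[k] for k in nn.HEAD_PARAMS}

    # -- training ------------------------------------------------------------------
    def _trainable_names(self):
        if self.trainable == "all":
            return nn.ALL_PARAMS
        if self.trainable == "head":
            return nn.HEAD_PARAMS
        raise ValueError("trainable must be 'all' or 'head'")

    def fit(self, X, y):
        Xb = _as_batch(X)
        y = np.asarray(y)
        if Xb.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if Xb.shape[0] == 0:
            raise ValueError("empty training set")
        trainable = self._trainable_names()
        rng = np.random.default_rng(self.random_state)

        resume = self.warm_start and hasattr(self, "params_")
        if resume:
            unknown = set(np.unique(y)) - set(self.classes_)
            if unknown:
                raise ValueError(f"warm-start labels {sorted(unknown)} not in classes_")
        else:
            self.classes_ = np.unique(y)
            self.params_ = nn.init_params(
                rng, self.n_filters1, self.n_filters2, self.hidden_units, len(self.classes_)
            )
            est_scale = float(np.mean(Xb.max(axis=(1, 2, 3))))
            self.scale_ = self.scale if self.scale is not None else (est_scale or 1.0)
            self.training_log_ = []
        self.n_features_in_ = N_CHANNELS

        class_index = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([class_index[c] for c in y])
        Xn = Xb / self.scale_

        if self.max_epochs == 0:
            return self

        # internal stratified hold-out for early stopping
        if self.val_fraction > 0 and np.min(np.bincount(y_idx)) >= 2:
            X_tr, X_val, y_tr, y_val = train_test_split(
                Xn,
                y_idx,
                test_size=self.val_fraction,
                stratify=y_idx,
                random_state=int(rng.integers(2**31)),
            )
        else:
            X_tr, X_val, y_tr, y_val = Xn, Xn, y_idx, y_idx

        opt = nn.Adam(trainable, lr=self.learning_rate)
        best_acc, best_snapshot, since_best = -np.inf, None, 0
        n = X_tr.shape[0]
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = X_tr[idx]
                if self.amp_jitter is not None:
                    lo, hi = self.amp_jitter
                    s = np.exp(rng.uniform(np.log(lo), np.log(hi), xb.shape[0]))
                    xb = xb * s[:, None, None, None].astype(xb.dtype)
                logits, cache = nn.forward(self.params_, xb)
                loss, dlogits = nn.softmax_xent(logits, y_tr[idx])
                grads = nn.backward(self.params_, cache, dlogits)
                opt.step(self.params_, grads)
                losses.append(loss)
            val_acc = float(np.mean(self._predict_idx(X_val) == y_val))
            self.training_log_.append(
                {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_acc": val_acc}
            )
            if val_acc > best_acc:
                best_acc = val_acc
                best_snapshot = {k: self.params_[k].copy() for k in trainable}
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        if best_snapshot is not None:
            self.params_.update(best_snapshot)
        return self

    # -- inference -----------------------------------------------------------------
    def _predict_idx(self, Xn: np.ndarray) -> np.ndarray:
        out = np.empty(Xn.shape[0], dtype=np.int64)
        step = 8192
        for s in range(0, Xn.shape[0], step):
            logits, _ = nn.forward(self.params_, Xn[s : s + step])
            out[s : s + step] = logits.argmax(axis=1)
        return out

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        Xn = _as_batch(X) / self.scale_
        probs = []
        for s in range(0, Xn.shape[0], 8192):
            logits, _ = nn.forward(self.params_, Xn[s : s + 8192])
            probs.append(nn.softmax(logits))
        return np.concatenate(probs)

    def predict(self, X):
        check_is_fitted(self, "params_")
        Xn = _as_batch(X) / self.scale_
        return self.classes_[self._predict_idx(Xn)]

    def predict_frame(self, frame) -> int:
        """Label for one 4x8 frame (convenience for streaming loops)."""
        return int(self.predict(np.asarray(frame)[None])[0])

    def copy_fitted(self) -> "GridConvNetClassifier":
        """Deep copy carrying over fitted parameters (for adaptation)."""
        check_is_fitted(self, "params_")
        new = copy.deepcopy(self)
        return new
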