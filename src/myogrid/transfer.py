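"""Two-phase transfer-learning protocol.

Phase 1 (:func:`pretrain`): train the network on a multi-subject dataset
that must exclude the end user (leakage guard).  Phase 2a
(:func:`adapt_new_user`): one-time training of *all* layers on the user's
initial-protocol recording.  Phase 2b (:func:`finetune_session`): on each
subsequent session, retrain only the classifier head on the reduced
protocol recording — the feature layers stay bit-identical.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .model import GridConvNetClassifier


def _stack(datasets: dict):
    Xs, ys = [], []
    for sid in sorted(datasets):
        X, y = datasets[sid]
        Xs.append(np.asarray(X))
        ys.append(np.asarray(y))
    return np.concatenate(Xs), np.concatenate(ys)


def pretrain(
    datasets: dict,
    exclude_subject=None,
    random_state: int = 0,
    **clf_params,
) -> GridConvNetClassifier:
    """Pre-train a fresh classifier on a multi-subject frame collection.

    ``datasets`` maps subject id -> ``(frames, labels)``.  Raises if fewer
    than two subjects are given or if ``exclude_subject`` (the end user the
    network will later be adapted to) appears in the collection.
    """
    if exclude_subject is not None and exclude_subject in datasets:
        raise ValueError(
            f"leakage guard: target subject {exclude_subject!r} present in pretraining data"
        )
    if len(datasets) < 2:
        raise ValueError("pretraining requires at least 2 subjects")
    X, y = _stack(datasets)
    clf = GridConvNetClassifier(random_state=random_state, **clf_params)
    clf.fit(X, y)
    return clf


def adapt_new_user(
    state: GridConvNetClassifier, X, y, random_state: int = 0, **fit_params
) -> GridConvNetClassifier:
    """One-time all-layer adaptation of a pretrained network to a new user.

    Returns a new fitted classifier; ``state`` is left untouched.  With
    ``max_epochs=0`` the parameters are returned unchanged (zero-epoch
    adaptation).
    """
    new = state.copy_fitted()
    new.set_params(warm_start=True, trainable="all", random_state=random_state, **fit_params)
    new.fit(X, y)
    return new


def finetune_session(
    state: GridConvNetClassifier, X, y, random_state: int = 0, **fit_params
) -> GridConvNetClassifier:
    """Session fine-tuning: train the classifier head only.

    The feature-layer parameters of the result are bit-identical to those
    of ``state`` (asserted before returning).  Raises on an empty dataset.
    """
    X = np.asarray(X)
    if X.shape[0] == 0:
        raise ValueError("empty session dataset")
    if "trainable" in fit_params and fit_params["trainable"] != "head":
        raise ValueError("finetune_session trains the head only; feature layers are frozen")
    fit_params.pop("trainable", None)
    new = state.copy_fitted()
    new.set_params(warm_start=True, trainable="head", random_state=random_state, **fit_params)
    new.fit(X, y)
    for name in nn.FEATURE_PARAMS:
        if not np.array_equal(state.params_[name], new.params_[name]):  # pragma: no cover
            raise AssertionError(f"frozen feature layer {name} changed during fine-tuning")
    return new
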