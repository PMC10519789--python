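"""A scikit-learn-style estimator facade over the model family.

``FCAEfficientNetClassifier`` exposes the standard fit/predict/score
surface with ``get_params``/``set_params``, so it composes with scikit-learn
model selection (``clone``, ``cross_val_score``) without this package
depending on scikit-learn at run time.  Inputs are image batches, either
(N, H, W, 3) uint8 or standardised (N, 3, H, W) float32.
"""

from __future__ import annotations

import numpy as np

from .architecture import ArchitectureSpec, build_model
from .autograd import softmax
from .datapipe import to_model_input
from .training import TrainConfig, train


class FCAEfficientNetClassifier:
    """Image classifier with a scikit-learn estimator interface.

    Parameters mirror the architecture spec (attention/norm/activation,
    fusion node, deep-stage layer triple, input resolution) and the training
    recipe (epochs, warmup, learning rate, decay, batch size).  Fitted
    attributes carry the trailing underscore: ``classes_``, ``model_``,
    ``history_``, ``best_epoch_``.
    """

    def __init__(self, attention: str = "fca", norm: str = "ln",
                 activation: str = "gelu", af_node: str = "node2",
                 layers_567: tuple[int, int, int] = (2, 3, 2),
                 input_resolution: int = 64,
                 epochs: int = 20, warmup_epochs: int = 2,
                 base_lr: float = 1e-3, gamma: float = 0.99,
                 batch_size: int = 16, validation_fraction: float = 0.0,
                 random_state: int = 0):
        self.attention = attention
        self.norm = norm
        self.activation = activation
        self.af_node = af_node
        self.layers_567 = layers_567
        self.input_resolution = input_resolution
        self.epochs = epochs
        self.warmup_epochs = warmup_epochs
        self.base_lr = base_lr
        self.gamma = gamma
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- sklearn protocol ----------------------------------------------------
    _param_names = ("attention", "norm", "activation", "af_node", "layers_567",
                    "input_resolution", "epochs", "warmup_epochs", "base_lr",
                    "gamma", "batch_size", "validation_fraction", "random_state")

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "FCAEfficientNetClassifier":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"invalid parameter {k!r} for "
                                 f"{type(self).__name__}")
            setattr(self, k, v)
        return self

    # -- internals -----------------------------------------------------------
    def _as_inputs(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 4:
            raise ValueError("expected a 4-D image batch")
        if X.shape[-1] == 3 and X.dtype == np.uint8:
            X = to_model_input(X)
        elif X.shape[1] != 3:
            raise ValueError("expected (N, H, W, 3) uint8 or (N, 3, H, W) float")
        X = X.astype(np.float32, copy=False)
        if X.shape[2] != self.input_resolution:
            raise ValueError(f"images are {X.shape[2]}px but the estimator was "
                             f"configured for {self.input_resolution}px")
        return X

    # -- estimator surface ---------------------------------------------------
    def fit(self, X, y) -> "FCAEfficientNetClassifier":
        X = self._as_inputs(X)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        spec = ArchitectureSpec(
            attention=self.attention, norm=self.norm,
            activation=self.activation, af_node=self.af_node,
            layers_567=tuple(self.layers_567),
            num_classes=len(self.classes_),
            input_resolution=self.input_resolution)
        cfg = TrainConfig(base_lr=self.base_lr, epochs=self.epochs,
                          warmup_epochs=self.warmup_epochs, gamma=self.gamma,
                          batch_size=self.batch_size, seed=self.random_state)
        self.model_ = build_model(spec, seed=self.random_state)
        if self.validation_fraction > 0.0:
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(len(y_enc))
            n_val = max(1, int(round(self.validation_fraction * len(y_enc))))
            va, tr = order[:n_val], order[n_val:]
        else:
            tr = va = np.arange(len(y_enc))   # monitor on the training data
        history, best = train(self.model_, (X[tr], y_enc[tr]),
                              (X[va], y_enc[va]), cfg)
        self.model_.load_state_dict(best["state"])
        self.model_.eval()
        self.history_ = history
        self.best_epoch_ = best["epoch"]
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def decision_function(self, X) -> np.ndarray:
        self._check_fitted()
        return self.model_.predict_logits(self._as_inputs(X),
                                          batch_size=self.batch_size)

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[scores.argmax(axis=1)]

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this estimator is not fitted yet; call fit first")
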