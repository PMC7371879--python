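"""scikit-learn style estimator facade over the recurrent network.

``RLLGMNClassifier`` consumes a stack of equal-length multichannel sequences
(shape ``(n_sequences, T, d)``, or a list of ``(T, d)`` arrays with possibly
different T) and exposes the usual ``fit`` / ``predict`` / ``predict_proba``
surface, so it composes with sklearn model selection and pipelines that pass
3-D inputs through.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .core import ModelShape, posterior_sequence
from .exceptions import InvalidParameterError
from .preprocess import FeatureSequence
from .training import TrainingConfig, train

__all__ = ["RLLGMNClassifier"]


class RLLGMNClassifier(ClassifierMixin, BaseEstimator):
    """Recurrent log-linearised Gaussian mixture network classifier.

    Parameters
    ----------
    n_states : hidden states per class (K).
    n_components : Gaussian components per state (M).
    learning_rate, max_epochs, tol : gradient-descent loop controls.
    n_restarts : independent random initialisations; lowest final loss wins.
    init_range : initial weights drawn uniformly from [-init_range, init_range].
    pin_unit : pin one redundant unit at zero (gauge fixing; optional).
    random_state : seed for all randomness.

    Attributes (after fit)
    ----------------------
    classes_ : sorted unique labels; the second one is the "event" class
        whose final-step posterior is the decision score.
    shape_ : the fitted :class:`ModelShape`.
    weights_ : the fitted coefficient tensor.
    training_result_ : per-restart loss trajectories and bookkeeping.
    """

    def __init__(
        self,
        n_states: int = 3,
        n_components: int = 3,
        learning_rate: float = 0.05,
        max_epochs: int = 1000,
        tol: float = 1e-6,
        n_restarts: int = 5,
        init_range: float = 0.1,
        pin_unit: bool = False,
        random_state: int | None = None,
    ):
        self.n_states = n_states
        self.n_components = n_components
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.tol = tol
        self.n_restarts = n_restarts
        self.init_range = init_range
        self.pin_unit = pin_unit
        self.random_state = random_state

    def _coerce_X(self, X) -> list[np.ndarray]:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return [X[i] for i in range(X.shape[0])]
        seqs = [np.atleast_2d(np.asarray(x, dtype=float)) for x in X]
        if not seqs:
            raise InvalidParameterError("X must contain at least one sequence")
        d = seqs[0].shape[1]
        if any(s.shape[1] != d for s in seqs):
            raise InvalidParameterError("all sequences must share the channel count")
        return seqs

    def fit(self, X, y):
        seqs = self._coerce_X(X)
        y = np.asarray(y)
        if len(y) != len(seqs):
            raise InvalidParameterError("X and y length mismatch")
        self.classes_ = np.unique(y)
        C = len(self.classes_)
        if C < 2:
            raise InvalidParameterError("need at least two classes")
        d = seqs[0].shape[1]
        self.n_features_in_ = d
        dataset = []
        for x, label in zip(seqs, y):
            idx = int(np.searchsorted(self.classes_, label)) + 1
            teacher = np.zeros(C)
            teacher[idx - 1] = 1.0
            dataset.append(FeatureSequence(x=x, label=idx, teacher=teacher))
        self.shape_ = ModelShape(C, self.n_states, self.n_components, d)
        cfg = TrainingConfig(
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            tol=self.tol,
            restarts=self.n_restarts,
            init_range=self.init_range,
            seed=0 if self.random_state is None else int(self.random_state),
            pin_unit=self.pin_unit,
        )
        self.training_result_ = train(dataset, self.shape_, cfg)
        self.weights_ = self.training_result_.weights
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Final-step class posteriors, (n_sequences, n_classes)."""
        check_is_fitted(self, "weights_")
        seqs = self._coerce_X(X)
        return np.vstack(
            [posterior_sequence(s, self.weights_)[-1] for s in seqs]
        )

    def predict_proba_sequence(self, x) -> np.ndarray:
        """Per-step posteriors (T, C) of one sequence, for trajectory plots."""
        check_is_fitted(self, "weights_")
        return posterior_sequence(np.atleast_2d(np.asarray(x, float)), self.weights_)

    def decision_function(self, X) -> np.ndarray:
        """Event-class (second class) posterior score of each sequence."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]
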