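"""scikit-learn estimators wrapping the secure and plaintext trainers.

``SecureLogisticRegression`` runs the whole simulated pipeline inside
``fit``: the caller's plaintext (X, y) plays the role of the input party,
every cell is additively shared to the configured computation parties, the
Newton loop runs entirely on shares, and only the final coefficient vector
is reconstructed.  Prediction then uses the revealed model in plaintext.

``NewtonLogisticRegression`` is the ordinary (non-MPC) reference with the
same update formulas; it is the oracle the secure runs are compared to.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .ledger import CommLedger
from .shares import SharedMatrix
from .sigmoid import sigmoid
from .train import (
    TrainConfig,
    TrainingData,
    train,
    train_plaintext_baseline,
)


class _LogisticBase(ClassifierMixin, BaseEstimator):
    """Shared prediction surface: decision_function / predict_proba / predict."""

    def _validate_fit_inputs(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"binary targets required, got {len(self.classes_)} classes"
            )
        y01 = (y == self.classes_[1]).astype(float)
        self.n_features_in_ = X.shape[1]
        return X, y01

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        p1 = sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) >= 0).astype(int)]


class NewtonLogisticRegression(_LogisticBase):
    """Plaintext Newton-Raphson logistic regression (the OLR baseline).

    Parameters
    ----------
    variant : 'full_newton' recomputes the Hessian X^T W X each iteration;
        'fixed_hessian' uses the constant Böhning bound -1/4 X^T X.
    sigmoid_mode : 'exact' or a polynomial approximation 'g3'/'g5'/'g7'.
    """

    def __init__(self, variant="full_newton", n_iter=10, sigmoid_mode="exact",
                 add_intercept=True, clip=False):
        self.variant = variant
        self.n_iter = n_iter
        self.sigmoid_mode = sigmoid_mode
        self.add_intercept = add_intercept
        self.clip = clip

    def fit(self, X, y):
        X, y01 = self._validate_fit_inputs(X, y)
        design = np.hstack([np.ones((X.shape[0], 1)), X]) if self.add_intercept else X
        model = train_plaintext_baseline(
            design, y01, variant=self.variant, n_iter=self.n_iter,
            sigmoid_mode=self.sigmoid_mode, clip=self.clip,
        )
        beta = model.beta
        if self.add_intercept:
            self.intercept_, self.coef_ = beta[0], beta[1:]
        else:
            self.intercept_, self.coef_ = 0.0, beta
        self.model_ = model
        return self


class SecureLogisticRegression(_LogisticBase):
    """Privacy-preserving logistic regression over additive secret shares.

    Parameters mirror :class:`mpclogit.train.TrainConfig`:

    setting : 'honest3' (3 computation parties, Bogdanov-style
        multiplication with re-sharing) or 'dishonest2' (2 parties plus a
        trusted initializer dealing Beaver triples).
    algorithm : 'accurate' (exact secure sigmoid) or 'approx'
        (least-squares sigmoid polynomial).
    sigmoid_mode : None for the per-algorithm default, else 'exact' or
        'g3'/'g5'/'g7'.
    backend : None for the per-algorithm default, else 'real' or 'field'.
    random_state : master seed; derives all party random streams.

    Fitted attributes: ``coef_``, ``intercept_``, ``classes_``,
    ``ledger_`` (communication snapshot), ``model_`` (full run record).
    """

    def __init__(self, setting="honest3", algorithm="accurate",
                 sigmoid_mode=None, n_iter=10, nardi_steps=30, recip_steps=40,
                 z_bound=12.0, backend=None, frac_bits=20, mask_width=16.0,
                 add_intercept=True, random_state=0):
        self.setting = setting
        self.algorithm = algorithm
        self.sigmoid_mode = sigmoid_mode
        self.n_iter = n_iter
        self.nardi_steps = nardi_steps
        self.recip_steps = recip_steps
        self.z_bound = z_bound
        self.backend = backend
        self.frac_bits = frac_bits
        self.mask_width = mask_width
        self.add_intercept = add_intercept
        self.random_state = random_state

    def _make_config(self) -> TrainConfig:
        return TrainConfig(
            setting=self.setting, algorithm=self.algorithm,
            sigmoid=self.sigmoid_mode, n_iter=self.n_iter,
            nardi_steps=self.nardi_steps, recip_steps=self.recip_steps,
            z_bound=self.z_bound, seed=self.random_state,
            backend=self.backend, frac_bits=self.frac_bits,
            mask_width=self.mask_width, add_intercept=self.add_intercept,
        )

    def fit(self, X, y):
        X, y01 = self._validate_fit_inputs(X, y)
        config = self._make_config()
        backend = config.resolve_backend()
        rngs = config.rng_streams()
        design = np.hstack([np.ones((X.shape[0], 1)), X]) if self.add_intercept else X
        data = TrainingData(
            X=SharedMatrix.share(design, config.n_compute_parties, backend,
                                 rngs["sharing"]),
            y=SharedMatrix.share(y01.reshape(-1, 1), config.n_compute_parties,
                                 backend, rngs["sharing"]),
        )
        ledger = CommLedger()
        model = train(data, config, ledger=ledger)
        beta = model.beta
        if self.add_intercept:
            self.intercept_, self.coef_ = beta[0], beta[1:]
        else:
            self.intercept_, self.coef_ = 0.0, beta
        self.ledger_ = model.ledger
        self.model_ = model
        return self


def fit_secure_logreg(X, y, **params) -> SecureLogisticRegression:
    """Functional convenience wrapper over SecureLogisticRegression."""
    return SecureLogisticRegression(**params).fit(X, y)
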