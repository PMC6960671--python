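"""Bayesian linear discriminant analysis (BLDA) by evidence maximization.

The discriminant is the posterior mean of a Bayesian linear regression of
class targets on the features, with an isotropic Gaussian prior of
precision ``alpha`` on the weights (the bias is left unpenalized) and
Gaussian observation noise of precision ``beta``.  Both hyperparameters are
learned from the training data by MacKay-style evidence (type-II maximum
likelihood) updates using the effective-number-of-parameters formulation,
which makes the classifier an automatically tuned ridge regression -- the
regularization guards against overfitting the high-dimensional, noisy
feature vectors typical of single-trial ERP decoding.

Class targets follow the class-balanced coding (+N/N+ for the positive
class, -N/N- for the negative), so the decision surface is not biased by
unequal class counts; plain +-1 coding is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import INSTABILITY, REST

logger = logging.getLogger(__name__)


@dataclass
class BLDAModel:
    """Fitted linear discriminant: weights (bias last), hyperparameters, threshold."""

    weights: np.ndarray  # (n_features + 1,), bias is the last entry
    alpha: float
    beta: float
    threshold: float = np.nan
    n_iterations_used: int = 0
    converged: bool = True

    @property
    def n_features(self) -> int:
        return self.weights.size - 1


def encode_labels(labels) -> np.ndarray:
    """Map rest/instability (or +-1) labels to a +-1 integer vector."""
    labels = np.asarray(labels)
    if labels.dtype.kind in "if":
        vals = labels.astype(int)
        if not set(np.unique(vals)) <= {-1, 1}:
            raise ValueError("numeric labels must be -1/+1")
        return vals
    out = np.empty(labels.size, dtype=int)
    for i, lab in enumerate(labels.ravel()):
        if lab == INSTABILITY:
            out[i] = 1
        elif lab == REST:
            out[i] = -1
        else:
            raise ValueError(f"unknown label {lab!r}")
    return out


def fit_blda(
    features: np.ndarray,
    labels,
    max_iter: int = 100,
    tol: float = 1e-4,
    alpha: float | None = None,
    beta: float | None = None,
    balanced_targets: bool = True,
    penalize_bias: bool = False,
) -> BLDAModel:
    """Fit the BLDA discriminant.

    With ``alpha`` and ``beta`` given, the evidence iteration is skipped and
    the posterior mean is returned for those fixed hyperparameters (the
    ridge-regression closed form).  Otherwise both are iterated until the
    relative change falls below ``tol`` or ``max_iter`` is reached; failure
    to converge is flagged, not raised.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be 2-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    y_cls = encode_labels(labels)
    if y_cls.size != x.shape[0]:
        raise ValueError("labels length must match feature rows")
    n_pos = int((y_cls == 1).sum())
    n_neg = int((y_cls == -1).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 examples of each class")

    n, d = x.shape
    if balanced_targets:
        y = np.where(y_cls == 1, n / n_pos, -n / n_neg).astype(float)
    else:
        y = y_cls.astype(float)

    xa = np.hstack([x, np.ones((n, 1))])  # bias column last
    d1 = d + 1
    xtx = xa.T @ xa
    xty = xa.T @ y
    # prior-precision pattern: 1 on the penalized weights, 0 on the bias
    prior_mask = np.ones(d1)
    if not penalize_bias:
        prior_mask[-1] = 0.0
    n_pen = float(prior_mask.sum())

    def posterior(a: float, b: float) -> tuple[np.ndarray, np.ndarray]:
        prec = b * xtx + np.diag(a * prior_mask)
        cov = np.linalg.inv(prec)
        mean = b * cov @ xty
        return mean, cov

    if alpha is not None and beta is not None:
        if alpha <= 0 or beta <= 0:
            raise ValueError("alpha and beta must be positive")
        m, _ = posterior(alpha, beta)
        return BLDAModel(weights=m, alpha=alpha, beta=beta, n_iterations_used=0)

    a = 1.0
    b = 1.0 / max(np.var(y), 1e-12)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        m, cov = posterior(a, b)
        # effective number of well-determined (penalized) parameters
        gamma_pen = n_pen - a * float(np.sum(np.diag(cov) * prior_mask))
        dof_total = gamma_pen + (d1 - n_pen)
        sse = float(np.sum((y - xa @ m) ** 2))
        a_new = gamma_pen / max(float(np.sum(prior_mask * m**2)), 1e-300)
        b_new = max(n - dof_total, 1e-12) / max(sse, 1e-300)
        if abs(a_new - a) <= tol * a and abs(b_new - b) <= tol * b:
            a, b = a_new, b_new
            converged = True
            break
        a, b = a_new, b_new
    if not converged:
        logger.warning("BLDA evidence iteration did not converge in %d steps", max_iter)
    m, _ = posterior(a, b)
    return BLDAModel(
        weights=m, alpha=a, beta=b, n_iterations_used=it, converged=converged
    )


def decision_values(model: BLDAModel, features: np.ndarray) -> np.ndarray:
    """Linear readout: features . weights + bias."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.n_features:
        raise ValueError(
            f"features must be (n, {model.n_features}); got {x.shape}"
        )
    return x @ model.weights[:-1] + model.weights[-1]


def set_threshold(model: BLDAModel, train_scores: np.ndarray) -> BLDAModel:
    """Decision threshold = median of the pooled training scores.

    With the balanced 20/20 per-trial augmentation the pooled median sits
    between the class clusters, balancing sensitivity and specificity.
    Windows are classified instability iff score > threshold.
    """
    scores = np.asarray(train_scores, dtype=float)
    if scores.size < 1:
        raise ValueError("need at least one training score")
    model.threshold = float(np.median(scores))
    return model


def classify(model: BLDAModel, features: np.ndarray) -> np.ndarray:
    """Boolean instability decisions at the model's threshold."""
    if not np.isfinite(model.threshold):
        raise ValueError("threshold has not been set")
    return decision_values(model, features) > model.threshold
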