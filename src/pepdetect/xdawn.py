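"""xDAWN spatial filtering for evoked-response enhancement.

xDAWN seeks channel-weight vectors ``w`` maximizing the generalized
Rayleigh quotient

    rho(w) = (w' Sigma_s w) / (w' Sigma_x w),

where ``Sigma_s`` is the covariance of the least-squares estimate of the
time-locked evoked response (obtained through the 0/1 Toeplitz design
matrix of the event onsets) and ``Sigma_x`` the covariance of the whole
signal.  The optimal filters are the leading generalized eigenvectors of
``(Sigma_s, Sigma_x)``.  A single component is retained by default,
projecting the multichannel epochs onto a one-dimensional evoked-response
time course.

Feature standardization (z-scoring with train-derived parameters) lives
here too, since its parameters are part of the fitted spatial model and
must never be re-estimated on test data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .preprocess import EpochSet
from .simulate import Recording

logger = logging.getLogger(__name__)


@dataclass
class SpatialFilterModel:
    """Fitted xDAWN filters, evoked estimate, and train-set normalization."""

    filters: np.ndarray  # (n_channels, n_components), unit-norm columns
    evoked_estimate: np.ndarray  # (n_channels, window), uV
    component_scores: np.ndarray  # (n_components,), generalized eigenvalues, descending
    window: int
    norm_mean: np.ndarray | None = field(default=None)
    norm_sd: np.ndarray | None = field(default=None)

    @property
    def n_components(self) -> int:
        return self.filters.shape[1]

    @property
    def n_channels(self) -> int:
        return self.filters.shape[0]


def _build_design(onsets: np.ndarray, n_samples: int, window: int) -> np.ndarray:
    """0/1 Toeplitz design matrix D with D[onset + j, j] = 1 for each onset."""
    d = np.zeros((n_samples, window))
    for onset in onsets:
        stop = min(window, n_samples - onset)
        idx = onset + np.arange(stop)
        d[idx, np.arange(stop)] += 1.0
    return d


def fit_xdawn(
    continuous: Recording,
    onsets,
    window: int,
    n_components: int = 1,
) -> SpatialFilterModel:
    """Fit xDAWN filters on a continuous recording with known event onsets.

    The evoked response is estimated by least squares through the onset
    design matrix; filters are the leading generalized eigenvectors of the
    (evoked, total) covariance pair.  Each filter is unit-norm and signed so
    that the filtered evoked estimate has a negative extremum, matching the
    N1 polarity, which keeps features comparable across fits.
    """
    onsets = np.asarray(onsets, dtype=int)
    if onsets.size < 2:
        raise ValueError("xDAWN needs at least 2 event onsets")
    if window <= 0:
        raise ValueError("window must be positive")
    if onsets.max() + window > continuous.n_samples:
        raise ValueError("recording shorter than last onset + window")
    if n_components < 1 or n_components > continuous.n_channels:
        raise ValueError("n_components must be in [1, n_channels]")

    x = continuous.data.T  # (n_samples, n_channels)
    n = x.shape[0]
    d = _build_design(onsets, n, window)
    gram = d.T @ d
    a_hat, *_ = np.linalg.lstsq(gram, d.T @ x, rcond=None)  # (window, channels)
    s_hat = d @ a_hat

    sigma_s = (s_hat.T @ s_hat) / n
    sigma_x = (x.T @ x) / n

    eps = 1e-8 * np.trace(sigma_x) / continuous.n_channels
    try:
        min_eig = linalg.eigvalsh(sigma_x, subset_by_index=[0, 0])[0]
    except linalg.LinAlgError:  # pragma: no cover
        min_eig = 0.0
    if min_eig <= eps:
        logger.warning(
            "total covariance is (near-)rank-deficient; regularizing with %.3g * I", eps
        )
        sigma_x = sigma_x + eps * np.eye(continuous.n_channels)

    eigvals, eigvecs = linalg.eigh(sigma_s, sigma_x)
    order = np.argsort(eigvals)[::-1][:n_components]
    filters = eigvecs[:, order]
    scores = eigvals[order]

    filters = filters / np.linalg.norm(filters, axis=0, keepdims=True)
    evoked = a_hat.T  # (channels, window)
    for k in range(filters.shape[1]):
        course = filters[:, k] @ evoked
        if abs(course.max()) > abs(course.min()):
            filters[:, k] = -filters[:, k]
    return SpatialFilterModel(
        filters=filters,
        evoked_estimate=evoked,
        component_scores=scores,
        window=window,
    )


def apply_xdawn(model: SpatialFilterModel, epochs: EpochSet) -> np.ndarray:
    """Project epochs through the filters; one flattened row per epoch.

    Returns (n_epochs, n_components * n_samples): each epoch's spatially
    filtered time course(s), concatenated component-major.
    """
    if epochs.n_channels != model.n_channels:
        raise ValueError(
            f"epoch channel count {epochs.n_channels} != filter rows {model.n_channels}"
        )
    projected = np.einsum("ck,ncs->nks", model.filters, epochs.epochs)
    return projected.reshape(len(epochs), -1)


def fit_normalizer(model: SpatialFilterModel, features: np.ndarray) -> SpatialFilterModel:
    """Learn per-feature z-score parameters from training features (in place).

    Constant features get a unit standard deviation (with a warning) so that
    they map to zero instead of NaN.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("need at least 2 training feature vectors")
    mean = features.mean(axis=0)
    sd = features.std(axis=0, ddof=0)
    bad = sd <= 0
    if bad.any():
        logger.warning("%d constant feature(s); using unit sd for them", int(bad.sum()))
        sd = np.where(bad, 1.0, sd)
    model.norm_mean = mean
    model.norm_sd = sd
    return model


def apply_normalizer(model: SpatialFilterModel, features: np.ndarray) -> np.ndarray:
    """Z-score features with the train-derived parameters stored on the model."""
    if model.norm_mean is None or model.norm_sd is None:
        raise ValueError("normalizer has not been fitted")
    return (np.asarray(features, dtype=float) - model.norm_mean) / model.norm_sd


def rayleigh_quotient(w: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Generalized Rayleigh quotient w'Aw / w'Bw (used by oracle checks)."""
    w = np.asarray(w, dtype=float)
    return float((w @ a @ w) / (w @ b @ w))
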