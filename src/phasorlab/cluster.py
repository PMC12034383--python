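"""Gaussian-mixture clustering of phasor distributions.

Pixels are clustered on their phasor coordinates — a 2-D feature per
harmonic, optionally concatenated over harmonics — with a full-covariance
Gaussian mixture fitted by expectation–maximization.  The posterior gives
soft (probability) segmentation; each component is rendered as a
confidence ellipse, by default at the 88% level.

The EM loop is written out here rather than delegated so that (i) the
per-iteration log-likelihood trace is recorded and its monotonicity can be
asserted, and (ii) user-supplied initial cluster points are honored
exactly.  ``sklearn.mixture.GaussianMixture`` is used in the test suite as
an independent cross-check of the fitted parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, DensityMixin
from sklearn.cluster import kmeans_plusplus
from sklearn.utils import check_random_state

from .exceptions import ValidationError
from .field import PhasorField

#: Display confidence level used for cluster ellipses.
DEFAULT_ELLIPSE_LEVEL = 0.88


def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of N(mean, cov) at rows of X via Cholesky."""
    d = X.shape[1]
    chol = np.linalg.cholesky(cov)
    z = solve_triangular(chol, (X - mean).T, lower=True)
    maha = (z**2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


class PhasorGMM(BaseEstimator, DensityMixin):
    """Full-covariance Gaussian mixture fitted by EM.

    Parameters
    ----------
    n_components : int
        Number of clusters K.
    feature_harmonics : tuple of int
        Harmonics whose (G, S) coordinates form the feature space when
        fitting from a :class:`PhasorField` (2 dims per harmonic).
    init_means : array-like (K, d), optional
        User-defined initial cluster points; otherwise k-means++ seeding
        with ``random_state``.
    tol : float
        Relative log-likelihood change below which EM stops.
    max_iter : int
        Iteration cap.
    reg_covar : float
        Floor added to covariance diagonals each M-step.
    random_state : int or None
        Seed for k-means++ initialization; recorded on the model.
    colors : list of RGB tuples, optional
        Display colors per cluster.

    Attributes
    ----------
    weights_ : ndarray (K,)
    means_ : ndarray (K, d)
    covariances_ : ndarray (K, d, d)
    log_likelihood_trace_ : ndarray
        Total log-likelihood after every EM iteration (non-decreasing).
    n_iter_, converged_
    """

    def __init__(
        self,
        n_components: int = 1,
        feature_harmonics: tuple[int, ...] = (1,),
        init_means=None,
        tol: float = 1e-7,
        max_iter: int = 500,
        reg_covar: float = 1e-8,
        random_state=None,
        colors=None,
    ):
        self.n_components = n_components
        self.feature_harmonics = feature_harmonics
        self.init_means = init_means
        self.tol = tol
        self.max_iter = max_iter
        self.reg_covar = reg_covar
        self.random_state = random_state
        self.colors = colors

    # -- fitting -----------------------------------------------------------

    def _initial_parameters(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        K, d = self.n_components, X.shape[1]
        scale = X.var(axis=0).mean()
        if scale <= 0:
            scale = 1e-6
        if self.init_means is not None:
            means = np.asarray(self.init_means, dtype=float)
            if means.shape != (K, d):
                raise ValidationError(
                    f"init_means must have shape ({K}, {d}); got {means.shape}"
                )
        else:
            rs = check_random_state(self.random_state)
            means, _ = kmeans_plusplus(X, K, random_state=rs)
        covs = np.tile(scale * np.eye(d), (K, 1, 1))
        weights = np.full(K, 1.0 / K)
        return weights, means, covs

    def _estimate_log_resp(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        logw = np.log(self.weights_)
        logp = np.column_stack(
            [
                _log_gaussian(X, self.means_[k], self.covariances_[k]) + logw[k]
                for k in range(self.n_components)
            ]
        )
        norm = logsumexp(logp, axis=1)
        return logp - norm[:, None], norm

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (n_samples, n_features)")
        K = int(self.n_components)
        if K < 1:
            raise ValidationError("n_components must be >= 1")
        if X.shape[0] < K:
            raise ValidationError(
                f"need at least n_components={K} samples; got {X.shape[0]}"
            )
        self.weights_, self.means_, self.covariances_ = self._initial_parameters(X)

        trace = []
        prev = -np.inf
        self.converged_ = False
        for it in range(1, int(self.max_iter) + 1):
            log_resp, norm = self._estimate_log_resp(X)
            ll = float(norm.sum())
            trace.append(ll)
            resp = np.exp(log_resp)
            nk = resp.sum(axis=0) + 10.0 * np.finfo(float).tiny
            self.weights_ = nk / nk.sum()
            self.means_ = (resp.T @ X) / nk[:, None]
            d = X.shape[1]
            covs = np.empty((K, d, d))
            for k in range(K):
                diff = X - self.means_[k]
                covs[k] = (resp[:, k, None] * diff).T @ diff / nk[k]
                covs[k].flat[:: d + 1] += self.reg_covar
            self.covariances_ = covs
            if np.isfinite(prev) and abs(ll - prev) <= self.tol * abs(prev):
                self.converged_ = True
                break
            prev = ll
        # likelihood after the final M-step
        _, norm = self._estimate_log_resp(X)
        trace.append(float(norm.sum()))
        self.log_likelihood_trace_ = np.asarray(trace)
        self.log_likelihood_ = trace[-1]
        self.n_iter_ = it
        return self

    def fit_field(self, field: PhasorField) -> "PhasorGMM":
        """Fit on the valid-pixel phasor coordinates of a field."""
        X, _ = field.features(tuple(self.feature_harmonics))
        return self.fit(X)

    # -- inference ---------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "means_"):
            raise ValidationError("PhasorGMM is not fitted")

    def score_samples(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        _, norm = self._estimate_log_resp(X)
        return norm

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        log_resp, _ = self._estimate_log_resp(X)
        return np.exp(log_resp)

    def predict(self, X) -> np.ndarray:
        # argmax breaks ties toward the lowest cluster index
        return np.argmax(self.predict_proba(X), axis=1)

    # -- persistence -------------------------------------------------------

    def to_json(self, path) -> None:
        self._check_fitted()
        payload = {
            "n_components": int(self.n_components),
            "feature_harmonics": list(self.feature_harmonics),
            "weights": self.weights_.tolist(),
            "means": self.means_.tolist(),
            "covariances": self.covariances_.tolist(),
            "colors": [list(c) for c in self.colors] if self.colors else None,
            "random_state": self.random_state,
            "log_likelihood": self.log_likelihood_,
            "n_iter": int(self.n_iter_),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PhasorGMM":
        with open(path) as fh:
            payload = json.load(fh)
        model = cls(
            n_components=payload["n_components"],
            feature_harmonics=tuple(payload["feature_harmonics"]),
            random_state=payload.get("random_state"),
            colors=[tuple(c) for c in payload["colors"]] if payload.get("colors") else None,
        )
        model.weights_ = np.asarray(payload["weights"])
        model.means_ = np.asarray(payload["means"])
        model.covariances_ = np.asarray(payload["covariances"])
        model.log_likelihood_ = payload.get("log_likelihood")
        model.n_iter_ = payload.get("n_iter", 0)
        model.converged_ = True
        model.log_likelihood_trace_ = np.asarray(
            [payload.get("log_likelihood")] if payload.get("log_likelihood") is not None else []
        )
        return model


def apply_gmm(model: PhasorGMM, field: PhasorField) -> tuple[np.ndarray, np.ndarray]:
    """Posterior images and hard labels for a phasor field.

    Returns ``(posteriors, labels)`` where ``posteriors`` has shape
    ``(K, H, W)`` (zeros at invalid pixels, summing to 1 at valid ones) and
    ``labels`` is the argmax cluster index per pixel, ``-1`` where invalid.
    """
    missing = [n for n in model.feature_harmonics if n not in field.harmonics]
    if missing:
        raise ValidationError(f"field lacks harmonics {missing} required by the model")
    X, idx = field.features(tuple(model.feature_harmonics))
    K = model.n_components
    post = np.zeros((K,) + field.shape)
    labels = np.full(field.shape, -1, dtype=np.int32)
    if idx.size:
        p = model.predict_proba(X)
        flat = post.reshape(K, -1)
        flat[:, idx] = p.T
        labels.ravel()[idx] = np.argmax(p, axis=1)
    return post, labels


@dataclass
class ClusterEllipse:
    """Constant-probability ellipse of one Gaussian component.

    ``axes`` are the semi-axis lengths at coverage ``level``; ``angle`` is
    the orientation of the leading axis in radians.
    """

    center: np.ndarray
    axes: np.ndarray
    angle: float
    level: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership of (N, 2) points."""
        pts = np.asarray(points, dtype=float) - self.center
        c, s = np.cos(self.angle), np.sin(self.angle)
        u = pts @ np.array([[c, -s], [s, c]])  # rotate into ellipse frame
        return (u[:, 0] / self.axes[0]) ** 2 + (u[:, 1] / self.axes[1]) ** 2 <= 1.0


def cluster_ellipse(
    model: PhasorGMM,
    component: int = 0,
    level: float = DEFAULT_ELLIPSE_LEVEL,
    harmonic: int | None = None,
) -> ClusterEllipse:
    """Coverage ellipse of one mixture component.

    For a 2-D Gaussian the Mahalanobis radius enclosing a fraction
    ``level`` of the mass is ``r = sqrt(-2 * ln(1 - level))`` (the
    chi-square(2) quantile); semi-axes are ``r * sqrt(eigenvalues)`` of the
    covariance.  For models fitted on several harmonics, ``harmonic``
    selects which (G, S) pair to display.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must be in (0, 1); got {level}")
    model._check_fitted()
    mean = model.means_[component]
    cov = model.covariances_[component]
    if mean.shape[0] != 2:
        if harmonic is None:
            raise ValidationError(
                "model is not 2-D; pass `harmonic` to choose a display plane"
            )
        h = tuple(model.feature_harmonics).index(harmonic)
        sl = slice(2 * h, 2 * h + 2)
        mean = mean[sl]
        cov = cov[sl, sl]
    r = np.sqrt(-2.0 * np.log1p(-level))
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return ClusterEllipse(
        center=mean.copy(), axes=r * np.sqrt(evals), angle=angle, level=float(level)
    )
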