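"""Multivariate information quantities from Gaussianization.

Total correlation T, joint differential entropy h, mutual information I and
Kullback-Leibler divergence are all reduced to univariate entropy estimates
through the iterative Gaussianizer:

* ``T(x)``   — cumulative per-iteration drop while Gaussianizing x.
* ``h(x)``   — ``-T(x) + sum_j h(x_j)``.
* ``I(x,y)`` — ``T([G_x(x), G_y(y)])``: the total correlation left between
  the separately Gaussianized blocks.
* ``KLD(x|y)`` — Gaussianize y with the transform learnt on x; what remains
  is ``T(z) + sum_j KLD(z_j || N(0,1))``.

Kozachenko-Leonenko nearest-neighbor estimates of h (and derived T, I) are
provided as an independent cross-check, and closed-form Gaussian oracles
support validation on fixtures with known answers.  All quantities in bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import stats
from scipy.special import digamma, gammaln, ndtr
from sklearn.neighbors import NearestNeighbors

from .colorset import ParameterError, UsageError
from .gaussianize import (LOG2_2PIE, GaussianizerModel, rbig_fit,
                          univariate_entropy)

LN2 = np.log(2.0)


@dataclass
class InfoEstimate:
    """An information quantity in bits with spread over repeated estimates."""

    value: float
    spread: float = 0.0
    n_repeats: int = 1
    estimator: str = "rbig"
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spread < 0:
            raise ParameterError("spread must be >= 0")
        if self.n_repeats < 1:
            raise ParameterError("n_repeats must be >= 1")

    def __format__(self, spec: str) -> str:
        return f"{self.value:{spec or '.3f'}} ± {self.spread:{spec or '.3f'}}"


@dataclass
class EstimatorConfig:
    """Knobs of the Gaussianization estimators.

    ``mi_fit_split=True`` fits the two Gaussianizers on a held-out half of
    the pairs and measures T on the other half, quantifying the (small)
    overfitting bias of the default same-sample protocol.
    """

    rotation_kind: str = "pca"
    max_iterations: int = 200
    tolerance: float = 0.01
    patience: int = 5
    seed: int | None = 0
    entropy_method: str = "vasicek"
    mi_fit_split: bool = False
    kld_smoothing: float = 0.5
    knn_k: int = 5

    def fit(self, samples: np.ndarray) -> GaussianizerModel:
        return rbig_fit(samples, rotation_kind=self.rotation_kind,
                        max_iterations=self.max_iterations,
                        tolerance=self.tolerance, patience=self.patience,
                        seed=self.seed)


def _as_matrix(samples: np.ndarray, min_n: int = 1000) -> np.ndarray:
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    if x.shape[0] < min_n:
        raise ParameterError(
            f"information estimates need n >= {min_n}, got {x.shape[0]}")
    return x


# ------------------------------------------------------------ RBIG estimators

def total_correlation(samples: np.ndarray,
                      config: EstimatorConfig | None = None) -> InfoEstimate:
    """Total correlation (multi-information) in bits; 0 iff dimensions are
    independent."""
    config = config or EstimatorConfig()
    x = _as_matrix(samples)
    model = config.fit(x)
    return InfoEstimate(model.total_correlation_bits, estimator="rbig",
                        diagnostics={"iterations": model.n_iterations,
                                     "converged": model.converged,
                                     "n": x.shape[0]})


def joint_entropy(samples: np.ndarray,
                  config: EstimatorConfig | None = None) -> InfoEstimate:
    """Joint differential entropy h = -T + sum of marginal entropies, bits."""
    config = config or EstimatorConfig()
    x = _as_matrix(samples)
    t = total_correlation(x, config)
    h_marg = sum(univariate_entropy(x[:, j], config.entropy_method)
                 for j in range(x.shape[1]))
    return InfoEstimate(float(h_marg) - t.value, estimator="rbig",
                        diagnostics={**t.diagnostics, "T": t.value})


def mutual_information(x: np.ndarray, y: np.ndarray,
                       config: EstimatorConfig | None = None) -> InfoEstimate:
    """Mutual information between paired multidimensional samples, bits."""
    config = config or EstimatorConfig()
    x = _as_matrix(x)
    y = _as_matrix(y)
    if x.shape[0] != y.shape[0]:
        raise UsageError("mutual information needs paired samples (same n)")
    if config.mi_fit_split:
        half = x.shape[0] // 2
        gx = config.fit(x[:half]).trimmed(config.tolerance)
        gy = config.fit(y[:half]).trimmed(config.tolerance)
        stacked = np.hstack([gx.transform(x[half:]), gy.transform(y[half:])])
    else:
        gx = config.fit(x).trimmed(config.tolerance)
        gy = config.fit(y).trimmed(config.tolerance)
        stacked = np.hstack([gx.transform(x), gy.transform(y)])
    t = total_correlation(stacked, config)
    return InfoEstimate(t.value, estimator="rbig",
                        diagnostics={**t.diagnostics,
                                     "fit_split": config.mi_fit_split})


def _binned_kld_vs_standard_normal(z: np.ndarray, smoothing: float) -> float:
    """Univariate KLD of a sample against N(0,1) via shared-support binned
    densities with additive smoothing, in bits."""
    n = z.size
    n_bins = max(int(np.ceil(2.0 * n ** (1.0 / 3.0))), 8)  # Rice rule
    lo = min(z.min(), -4.0)
    hi = max(z.max(), 4.0)
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(z, bins=edges)
    # overflow bins pick up the normal tail mass outside the sample range
    cdf = ndtr(edges)
    q = np.concatenate([[cdf[0]], np.diff(cdf), [1.0 - cdf[-1]]])
    p = np.concatenate([[0.0], counts, [0.0]]) + smoothing
    p /= p.sum()
    q = np.maximum(q, 1e-300)
    q += smoothing / n
    q /= q.sum()
    return float(np.sum(p * np.log2(p / q)))


def kld(x: np.ndarray, y: np.ndarray,
        config: EstimatorConfig | None = None) -> InfoEstimate:
    """KLD(x|y): Gaussianize y through the transform learnt on x; the
    divergence is the residual structure T(z) plus the per-dimension
    divergences of z's marginals from N(0,1).  Asymmetric by construction."""
    config = config or EstimatorConfig()
    x = _as_matrix(x)
    y = _as_matrix(y)
    if x.shape[1] != y.shape[1]:
        raise UsageError("KLD needs equal dimensionality")
    # the full (untrimmed) model is needed here: the final iterations are the
    # ones that standardize per-dimension scales, which the marginal
    # divergence against N(0,1) relies on
    gx = config.fit(x)
    z = gx.transform(y)
    t = total_correlation(z, config)
    marg = sum(_binned_kld_vs_standard_normal(z[:, j], config.kld_smoothing)
               for j in range(z.shape[1]))
    return InfoEstimate(t.value + float(marg), estimator="rbig",
                        diagnostics={**t.diagnostics, "T_z": t.value,
                                     "marginal_kld": float(marg)})


# --------------------------------------------------- Kozachenko-Leonenko knn

def _kl_entropy_bits(samples: np.ndarray, k: int) -> float:
    n, d = samples.shape
    if not 1 <= k < n:
        raise ParameterError("need 1 <= k < n")
    # whiten first: the estimator is affine-covariant (h = h_white +
    # (1/2)log2 det cov), and on isotropic clouds its bias is far smaller
    # than on elongated ones
    if d > 1:
        cov = np.cov(samples, rowvar=False)
        try:
            chol = np.linalg.cholesky(cov)
            centered = samples - samples.mean(axis=0)
            samples = np.linalg.solve(chol, centered.T).T
            log_det_bits = float(np.log2(np.linalg.det(cov))) / 2.0
        except np.linalg.LinAlgError:
            log_det_bits = 0.0
    else:
        log_det_bits = 0.0
    nn = NearestNeighbors(n_neighbors=k + 1).fit(samples)
    dist, _ = nn.kneighbors(samples)
    eps = dist[:, k]
    if np.any(eps == 0):  # duplicate points: jitter and flag via warning
        rng = np.random.default_rng(0)
        jittered = samples + rng.normal(scale=1e-10, size=samples.shape)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(jittered)
        eps = nn.kneighbors(jittered)[0][:, k]
    log_ball = (d / 2.0) * np.log(np.pi) - gammaln(d / 2.0 + 1.0)
    h_nats = (digamma(n) - digamma(k) + log_ball
              + d * float(np.mean(np.log(eps))))
    return h_nats / LN2 + log_det_bits


def knn_entropy(samples: np.ndarray, k: int = 5) -> InfoEstimate:
    """Kozachenko-Leonenko nearest-neighbor differential entropy, bits."""
    x = _as_matrix(samples)
    return InfoEstimate(_kl_entropy_bits(x, k), estimator="knn",
                        diagnostics={"k": k, "n": x.shape[0]})


def knn_total_correlation(samples: np.ndarray, k: int = 5) -> InfoEstimate:
    """T from nearest-neighbor entropies: sum of marginal h minus joint h."""
    x = _as_matrix(samples)
    h_marg = sum(_kl_entropy_bits(x[:, j:j + 1], k) for j in range(x.shape[1]))
    return InfoEstimate(h_marg - _kl_entropy_bits(x, k), estimator="knn",
                        diagnostics={"k": k, "n": x.shape[0]})


def knn_mutual_information(x: np.ndarray, y: np.ndarray,
                           k: int = 5) -> InfoEstimate:
    """Nearest-neighbor mutual information (KSG estimator, bits).

    The Kraskov-Stogbauer-Grassberger form derived from the
    Kozachenko-Leonenko entropy: neighbor counts within the joint-space
    k-th-neighbor radius replace explicit entropy sums, which keeps the
    estimator usable for strongly dependent (near-deterministic) pairs where
    a difference of three entropy estimates loses several bits.
    """
    x = _as_matrix(x)
    y = _as_matrix(y)
    n = x.shape[0]
    if y.shape[0] != n:
        raise UsageError("mutual information needs paired samples (same n)")
    if not 1 <= k < n:
        raise ParameterError("need 1 <= k < n")
    from scipy.spatial import cKDTree
    joint = np.hstack([x, y])
    nn = NearestNeighbors(n_neighbors=k + 1, metric="chebyshev").fit(joint)
    eps = nn.kneighbors(joint)[0][:, k]
    radius = eps * (1.0 - 1e-12)  # strictly inside the k-th neighbor ball
    counts = []
    for block in (x, y):
        tree = cKDTree(block)
        counts.append(np.asarray(tree.query_ball_point(
            block, radius, p=np.inf, return_length=True)) - 1)
    nats = (digamma(k) + digamma(n)
            - np.mean(digamma(counts[0] + 1) + digamma(counts[1] + 1)))
    return InfoEstimate(float(max(nats, 0.0)) / LN2, estimator="knn",
                        diagnostics={"k": k})


# ------------------------------------------------------------ Gaussian oracles

def _check_psd(cov: np.ndarray) -> np.ndarray:
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ParameterError("covariance must be symmetric")
    if np.min(np.linalg.eigvalsh(cov)) < -1e-10:
        raise ParameterError("covariance must be positive semi-definite")
    return cov


def gaussian_oracle_T(cov: np.ndarray) -> float:
    """Closed-form Gaussian total correlation: -1/2 log2 det(correlation)."""
    cov = _check_psd(cov)
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    return float(-0.5 * np.log2(np.linalg.det(corr)))


def gaussian_oracle_h(cov: np.ndarray) -> float:
    """Closed-form Gaussian joint entropy: 1/2 log2((2*pi*e)^d det cov)."""
    cov = _check_psd(cov)
    d = cov.shape[0]
    return float(d * LOG2_2PIE + 0.5 * np.log2(np.linalg.det(cov)))


def gaussian_oracle_I(cov_x: np.ndarray, cov_noise: np.ndarray) -> float:
    """Closed-form I(x, x + n) for the additive Gaussian channel:
    1/2 log2(det(cov_x + cov_noise) / det(cov_noise))."""
    cov_x = _check_psd(cov_x)
    cov_noise = _check_psd(cov_noise)
    num = np.linalg.det(cov_x + cov_noise)
    den = np.linalg.det(cov_noise)
    return float(0.5 * np.log2(num / den))


def gaussian_oracle_kld(mean1: np.ndarray, cov1: np.ndarray,
                        mean2: np.ndarray, cov2: np.ndarray) -> float:
    """Closed-form KLD(N1 || N2) in bits."""
    mean1 = np.asarray(mean1, dtype=float).ravel()
    mean2 = np.asarray(mean2, dtype=float).ravel()
    cov1 = _check_psd(cov1)
    cov2 = _check_psd(cov2)
    d = mean1.size
    inv2 = np.linalg.inv(cov2)
    dm = mean2 - mean1
    nats = 0.5 * (np.trace(inv2 @ cov1) + dm @ inv2 @ dm - d
                  + np.log(np.linalg.det(cov2) / np.linalg.det(cov1)))
    return float(nats / LN2)


def pooled_spread(a: InfoEstimate, b: InfoEstimate) -> float:
    """Quadrature-pooled spread of two estimates (for cross-agreement checks)."""
    return float(np.hypot(a.spread, b.spread))
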