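"""Monotone per-dimension maps.

The same container serves two roles: the saturating opponent-channel
nonlinearity of color networks (PDF equalization, either as the exact
empirical equalizer or as a fitted saturating exponential) and the marginal
Gaussianization stage of the iterative Gaussianizer.  Every map is strictly
monotone increasing on its fit domain and invertible there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.special import ndtri

from .colorset import DegenerateInputError, ParameterError

KINDS = ("empirical_cdf", "exponential_fit", "identity", "gauss_quantile")

def _tail_slopes(xk: np.ndarray, yk: np.ndarray) -> tuple[float, float]:
    """Boundary slopes for linear extrapolation, averaged over enough outer
    knots to be robust: consecutive order statistics can be nearly tied, and
    a two-point slope there degenerates to near-vertical."""
    m = min(max(10, len(xk) // 20), len(xk) - 1)
    lo = (yk[m] - yk[0]) / max(xk[m] - xk[0], 1e-300)
    hi = (yk[-1] - yk[-1 - m]) / max(xk[-1] - xk[-1 - m], 1e-300)
    return max(lo, 1e-12), max(hi, 1e-12)


def _interp_monotone(v: np.ndarray, xk: np.ndarray, yk: np.ndarray,
                     extrapolation: str) -> np.ndarray:
    out = np.interp(v, xk, yk)
    if extrapolation == "linear":
        slo, shi = _tail_slopes(xk, yk)
        below = v < xk[0]
        above = v > xk[-1]
        if np.any(below):
            out[below] = yk[0] + (v[below] - xk[0]) * slo
        if np.any(above):
            out[above] = yk[-1] + (v[above] - xk[-1]) * shi
    # "clamp": np.interp already clips to boundary values
    return out


@dataclass
class MarginalMap:
    """A stack of d strictly monotone univariate maps.

    ``x_knots[j] -> y_knots[j]`` define dimension ``j`` by linear
    interpolation; outside the fit domain values are either linearly
    extrapolated (Gaussianization) or clamped to the boundary
    (equalizers applied to unseen test extremes).
    """

    kind: str
    x_knots: list[np.ndarray]
    y_knots: list[np.ndarray]
    extrapolation: str = "clamp"
    space: str | None = None
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ParameterError(f"unknown marginal-map kind {self.kind!r}")
        for xk, yk in zip(self.x_knots, self.y_knots):
            if len(xk) != len(yk) or len(xk) < 2:
                raise ParameterError("each dimension needs >= 2 knots")

    @property
    def d(self) -> int:
        return len(self.x_knots)

    @property
    def domain(self) -> np.ndarray:
        """(2, d) array of per-dimension fit-domain (min, max)."""
        return np.array([[xk[0] for xk in self.x_knots],
                         [xk[-1] for xk in self.x_knots]])

    def forward(self, samples: np.ndarray) -> np.ndarray:
        samples = np.atleast_2d(np.asarray(samples, dtype=float))
        if samples.shape[1] != self.d:
            raise ParameterError(
                f"map has d={self.d}, samples have d={samples.shape[1]}")
        out = np.empty_like(samples)
        for j in range(self.d):
            out[:, j] = _interp_monotone(samples[:, j], self.x_knots[j],
                                         self.y_knots[j], self.extrapolation)
        return out

    def inverse(self, samples: np.ndarray) -> np.ndarray:
        samples = np.atleast_2d(np.asarray(samples, dtype=float))
        out = np.empty_like(samples)
        for j in range(self.d):
            out[:, j] = _interp_monotone(samples[:, j], self.y_knots[j],
                                         self.x_knots[j], self.extrapolation)
        return out

    def out_of_domain(self, samples: np.ndarray) -> np.ndarray:
        """Boolean mask of rows with at least one coordinate outside the
        fit domain (these are clamped/extrapolated and should be flagged)."""
        samples = np.atleast_2d(np.asarray(samples, dtype=float))
        lo, hi = self.domain
        return np.any((samples < lo) | (samples > hi), axis=1)

    @classmethod
    def identity(cls, d: int, lo: float = 0.0, hi: float = 1.0) -> "MarginalMap":
        xk = np.array([lo, hi])
        return cls("identity", [xk.copy() for _ in range(d)],
                   [xk.copy() for _ in range(d)], extrapolation="linear")


def _unique_knots(values: np.ndarray, targets: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Collapse tied sorted values to single knots (mean target per tie group)
    so the interpolant is strictly monotone."""
    xu, start = np.unique(values, return_index=True)
    if len(xu) == len(values):
        return values, targets
    if len(xu) < 2:
        raise DegenerateInputError("constant dimension: cannot fit monotone map")
    sums = np.add.reduceat(targets, start)
    counts = np.diff(np.append(start, len(values)))
    return xu, sums / counts


def empirical_cdf_map(train: np.ndarray, space: str | None = None) -> MarginalMap:
    """Per-dimension empirical CDF: maps training marginals to ~uniform [0, 1].

    The rank offset 1/(2n) keeps outputs strictly inside (0, 1).
    """
    train = np.atleast_2d(np.asarray(train, dtype=float))
    n, d = train.shape
    q = (np.arange(1, n + 1) - 0.5) / n
    xs, ys = [], []
    for j in range(d):
        if np.ptp(train[:, j]) == 0:
            raise DegenerateInputError(f"dimension {j} is constant")
        xk, yk = _unique_knots(np.sort(train[:, j]), q)
        xs.append(xk)
        ys.append(yk)
    return MarginalMap("empirical_cdf", xs, ys, extrapolation="clamp",
                       space=space)


def _block_average(xs: np.ndarray, targets: np.ndarray, n_blocks: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Average sorted values and their quantile targets over equal-count
    blocks, with much finer blocks in the outermost block-width on each side.

    Bulk averaging suppresses the high-frequency rank noise of the raw
    empirical quantile function (which otherwise acts as added channel noise
    when two fitted maps are compared).  Full-width averaging would truncate
    the extreme quantiles to the outer block's mean — for short-tailed
    inputs that truncation leaves residual non-Gaussianity after the map —
    so the tails keep fine sub-blocks: enough reach to map the extremes,
    enough averaging to control the (large) rank noise of tail order
    statistics.
    """
    n = len(xs)
    w = max(1, n // n_blocks)  # bulk block width = tail region width
    if n <= 4 * w:
        return xs, targets
    w_tail = max(1, w // 8)

    def region_edges(start: int, stop: int, width: int) -> np.ndarray:
        k = max(1, round((stop - start) / width))
        return np.linspace(start, stop, k + 1).astype(int)

    edges = np.unique(np.concatenate([
        region_edges(0, w, w_tail),
        region_edges(w, n - w, w),
        region_edges(n - w, n, w_tail),
    ]))
    sums_x = np.add.reduceat(xs, edges[:-1])
    sums_y = np.add.reduceat(targets, edges[:-1])
    counts = np.diff(edges)
    return sums_x / counts, sums_y / counts


def gauss_quantile_map(train: np.ndarray, n_blocks: int | None = None
                       ) -> MarginalMap:
    """Marginal Gaussianization: standard-normal quantile of the smoothed
    empirical CDF, with linear tail extrapolation beyond the observed range.

    ``n_blocks`` controls the knot resolution of the fitted quantile map
    (default ``2 * sqrt(n)``, capped at n); knots are block means of order
    statistics, which keeps the map monotone and smooth.
    """
    train = np.atleast_2d(np.asarray(train, dtype=float))
    n, d = train.shape
    if n < 100:
        raise ParameterError("marginal Gaussianization needs n >= 100")
    if n_blocks is None:
        n_blocks = int(min(n, max(100, 2 * np.sqrt(n))))
    targets = ndtri((np.arange(1, n + 1) - 0.5) / n)
    xs, ys = [], []
    for j in range(d):
        if np.ptp(train[:, j]) == 0:
            raise DegenerateInputError(f"dimension {j} is constant")
        xk, yk = _block_average(np.sort(train[:, j]), targets, n_blocks)
        xk, yk = _unique_knots(xk, yk)
        xs.append(xk)
        ys.append(yk)
    return MarginalMap("gauss_quantile", xs, ys, extrapolation="linear")
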