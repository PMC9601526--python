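"""Color-vision network layers.

The networks are cascades of two linear+nonlinear layers acting on linear
LMS cone responses:

    LMS -> (chromatic adaptation) -> (opponent recombination) -> (saturation)

* adaptation: von Kries (channel-wise division by the white point) or the
  Webster-Clifford moment-matching map (align mean and covariance with a
  reference manifold);
* opponency: an invertible 3x3 recombination into achromatic / red-green /
  yellow-blue channels;
* saturation: dimension-wise PDF equalization ("pleistochrome"), either the
  exact empirical equalizer or a fitted saturating exponential.

The CIE L*a*b* appearance model and a PCA + marginal-equalization statistical
benchmark are provided as alternative network families.  All data-dependent
parameters (white points, moments, equalizers, rotations) are fitted on
training data only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import optimize

from .colorset import (ColorSet, DegenerateInputError, ParameterError,
                       UsageError)
from .marginal import MarginalMap, empirical_cdf_map

# ---------------------------------------------------------------- constants

#: Opponent recombination (achromatic V, red-green, yellow-blue) in terms of
#: LMS cone responses.  The paper-era Jameson-Hurvich opponent stage does not
#: come with canonical coefficients; these are the widely used Ingling & Tsou
#: (1977) suprathreshold opponent weights.
OPPONENT_ATD = np.array([
    [0.600, 0.400, 0.000],
    [1.200, -1.600, 0.400],
    [0.240, 0.105, -0.700],
])

#: LMS -> XYZ: inverse of the Hunt-Pointer-Estevez (D65-normalized) matrix.
HPE_XYZ_TO_LMS = np.array([
    [0.40024, 0.70760, -0.08081],
    [-0.22630, 1.16532, 0.04570],
    [0.00000, 0.00000, 0.91822],
])
LMS_TO_XYZ = np.linalg.inv(HPE_XYZ_TO_LMS)

ADAPTATIONS = ("none", "von_kries", "webster_clifford")
NONLINEARITIES = ("pleistochrome_empirical", "pleistochrome_exponential", "none")
MODEL_FAMILIES = ("physiological", "cielab", "benchmark")


@dataclass
class AffineMap:
    """Invertible affine stage ``x -> matrix @ x + offset``."""

    matrix: np.ndarray
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.offset = np.asarray(self.offset, dtype=float).ravel()
        if self.matrix.shape != (3, 3) or self.offset.size != 3:
            raise ParameterError("AffineMap needs a 3x3 matrix and 3-offset")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ParameterError("AffineMap matrix must be invertible")

    def __call__(self, samples: np.ndarray) -> np.ndarray:
        return samples @ self.matrix.T + self.offset

    def inverse(self) -> "AffineMap":
        inv = np.linalg.inv(self.matrix)
        return AffineMap(inv, -inv @ self.offset)


@dataclass
class NetworkSpec:
    """One configured model variant.

    ``adaptation_reference`` (Webster-Clifford only) holds the target
    ``(mean, covariance)``; when absent the training moments are used, making
    the map a self-alignment within the training frame.
    """

    adaptation: str = "von_kries"
    opponent_matrix: AffineMap = field(
        default_factory=lambda: AffineMap(OPPONENT_ATD))
    nonlinearity: str = "pleistochrome_exponential"
    model_family: str = "physiological"
    adaptation_reference: tuple[np.ndarray, np.ndarray] | None = None
    lms_to_xyz: AffineMap = field(default_factory=lambda: AffineMap(LMS_TO_XYZ))

    def __post_init__(self) -> None:
        if self.adaptation not in ADAPTATIONS:
            raise ParameterError(f"unknown adaptation {self.adaptation!r}")
        if self.nonlinearity not in NONLINEARITIES:
            raise ParameterError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.model_family not in MODEL_FAMILIES:
            raise ParameterError(f"unknown model_family {self.model_family!r}")


# -------------------------------------------------------------- adaptation

def von_kries(colors: ColorSet, white) -> ColorSet:
    """Channel-wise normalization by the white point (the tristimulus
    response to what is considered white; here the training sample mean)."""
    white = np.asarray(white, dtype=float).ravel()
    if white.size != 3 or np.any(white <= 0):
        raise ParameterError("white point must be 3 positive values")
    if colors.space != "LMS_linear":
        raise UsageError("von Kries applies to LMS_linear responses")
    return colors.with_samples(colors.samples / white, space="LMS_adapted",
                               white=white)


def _sym_sqrt(mat: np.ndarray, inverse: bool = False) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() <= 0:
        raise DegenerateInputError("covariance not positive definite")
    power = -0.5 if inverse else 0.5
    return (vecs * vals ** power) @ vecs.T


def webster_clifford(colors: ColorSet, ref_mean, ref_cov) -> ColorSet:
    """Moment-matching adaptation: affine map taking the sample mean and
    covariance exactly onto the reference moments.

    Among the many affine maps equalizing second moments the rotation-free
    (symmetric square root) choice ``A = ref_cov^{1/2} sample_cov^{-1/2}``
    is used: it is unique and does not add an arbitrary rotation.
    """
    ref_mean = np.asarray(ref_mean, dtype=float).ravel()
    ref_cov = np.atleast_2d(np.asarray(ref_cov, dtype=float))
    sample_mean = colors.samples.mean(axis=0)
    sample_cov = np.cov(colors.samples, rowvar=False)
    if np.linalg.matrix_rank(sample_cov, tol=1e-12) < 3:
        raise DegenerateInputError("sample covariance is singular")
    a = _sym_sqrt(ref_cov) @ _sym_sqrt(sample_cov, inverse=True)
    mapped = (colors.samples - sample_mean) @ a.T + ref_mean
    return colors.with_samples(mapped, space="LMS_adapted",
                               wc_reference_mean=ref_mean,
                               wc_reference_cov=ref_cov)


# ---------------------------------------------------------------- opponency

def opponent_transform(colors: ColorSet, opponent: AffineMap | None = None
                       ) -> ColorSet:
    """Linear recombination of (adapted) LMS into opponent ATD channels."""
    if colors.space not in ("LMS_linear", "LMS_adapted"):
        raise UsageError("opponent recombination expects an LMS representation")
    opponent = opponent or AffineMap(OPPONENT_ATD)
    return colors.with_samples(opponent(colors.samples), space="ATD_linear",
                               opponent_matrix=opponent.matrix)


# --------------------------------------------------------------- saturation

def _exp_equalizer(x: np.ndarray, a: float, x0: float, tau: float) -> np.ndarray:
    return a * (1.0 - np.exp(-(x - x0) / tau))


def _fit_exponential_equalizer(values: np.ndarray) -> tuple[float, float, float]:
    """Least-squares fit of the saturating form a*(1 - exp(-(x-x0)/tau)) to
    the empirical equalizer (x_(i), (i-1/2)/n).

    The fit is restricted to the bulk quantile range [0.5%, 99.5%]: sample
    extremes of heavy-tailed channels fluctuate wildly between training
    draws, and a fit anchored on them produces maps that are inconsistent
    across illuminant conditions.
    """
    xs = np.sort(values)
    n = xs.size
    u = (np.arange(1, n + 1) - 0.5) / n
    trim = int(np.ceil(0.005 * n))
    if n - 2 * trim > 100:
        xs, u = xs[trim:n - trim], u[trim:n - trim]
        n = xs.size
    # subsample the fit points: the equalizer is smooth and n can be large
    if n > 2000:
        idx = np.linspace(0, n - 1, 2000).astype(int)
        xs, u = xs[idx], u[idx]
    x_min = xs[0]
    scale = max(float(np.mean(xs) - x_min), 1e-12)
    # the empirical equalizer is a CDF, so its asymptote is pinned near 1 and
    # its foot near the sample minimum; loose bounds let the optimizer run to
    # degenerate near-linear solutions that are unstable across training draws
    p0 = (1.0, x_min, scale)
    bounds = ([0.5, x_min - 0.5 * scale, 1e-9 * scale],
              [1.5, x_min + 0.25 * scale, 1e3 * scale])
    try:
        popt, _ = optimize.curve_fit(_exp_equalizer, xs, u, p0=p0,
                                     bounds=bounds, maxfev=5000)
    except RuntimeError:  # fall back to the initial guess on non-convergence
        popt = p0
    return tuple(float(v) for v in popt)


def fit_pleistochrome(train: ColorSet, kind: str = "exponential_fit"
                      ) -> MarginalMap:
    """Fit the dimension-wise saturating nonlinearity of opponent channels.

    ``empirical_cdf`` is the exact PDF equalizer (training marginals map to
    uniform on [0, 1]); ``exponential_fit`` approximates it with a saturating
    exponential ``a * (1 - exp(-(x - x0)/tau))`` per dimension, fitted to the
    empirical equalizer after centering each dimension to a non-negative
    range (subtracting the training minimum).
    """
    if kind not in ("empirical_cdf", "exponential_fit"):
        raise ParameterError(f"unknown pleistochrome kind {kind!r}")
    if train.n < 1000:
        raise ParameterError("pleistochrome fit needs >= 1000 samples")
    data = train.samples
    if np.any(np.ptp(data, axis=0) == 0):
        raise DegenerateInputError("constant dimension cannot be equalized")
    mins = data.min(axis=0)
    centered = data - mins
    if kind == "empirical_cdf":
        fitted = empirical_cdf_map(centered, space=train.space)
        # knots in original units: undo the centering in the x knots
        fitted.x_knots = [xk + m for xk, m in zip(fitted.x_knots, mins)]
        fitted.params = {"mins": mins}
        return fitted
    xs, ys, params = [], [], []
    for j in range(3):
        a, x0, tau = _fit_exponential_equalizer(centered[:, j])
        lo, hi = centered[:, j].min(), centered[:, j].max()
        grid = np.linspace(lo, hi, 512)
        xs.append(grid + mins[j])
        ys.append(_exp_equalizer(grid, a, x0, tau))
        params.append({"a": a, "x0": x0, "tau": tau})
    return MarginalMap("exponential_fit", xs, ys, extrapolation="clamp",
                       space=train.space, params={"mins": mins,
                                                  "per_dim": params})


def apply_marginal_maps(colors: ColorSet, maps: MarginalMap) -> ColorSet:
    """Dimension-wise application of fitted monotone maps.

    Out-of-domain test values are clamped to the map boundary and the number
    of affected rows is recorded in ``meta`` (keeps the maps monotone and
    bounded on unseen extremes).
    """
    if maps.space is not None and maps.space != colors.space:
        raise UsageError(
            f"maps fitted on {maps.space!r}, applied to {colors.space!r}")
    space_out = {"ATD_linear": "ATD_nonlinear",
                 "BENCHMARK": "BENCHMARK"}.get(colors.space, colors.space)
    n_clamped = int(maps.out_of_domain(colors.samples).sum())
    return colors.with_samples(maps.forward(colors.samples), space=space_out,
                               clamped_rows=n_clamped)


# ------------------------------------------------------------------- CIELAB

_LAB_DELTA = 6.0 / 29.0


def _lab_f(t: np.ndarray) -> np.ndarray:
    """Cube-root compression with the standard linear toe (the toe's linear
    branch also covers t < 0 so the map stays monotone everywhere)."""
    t = np.asarray(t, dtype=float)
    linear = t / (3.0 * _LAB_DELTA ** 2) + 4.0 / 29.0
    return np.where(t > _LAB_DELTA ** 3, np.cbrt(np.maximum(t, 0.0)), linear)


def cielab(colors: ColorSet, white, lms_to_xyz: AffineMap | None = None,
           return_stages: bool = False):
    """CIE L*a*b* responses from linear LMS.

    LMS is taken to XYZ through ``lms_to_xyz``, normalized by the white point
    (itself converted from LMS), compressed by the standard cube-root/linear
    toe, and recombined into (L*, a*, b*).  A sample equal to the white maps
    to (100, 0, 0); multiples of the white map onto the achromatic axis.
    """
    white = np.asarray(white, dtype=float).ravel()
    if white.size != 3 or np.any(white <= 0):
        raise ParameterError("white point must be 3 positive values")
    if colors.space != "LMS_linear":
        raise UsageError("CIELAB conversion starts from LMS_linear")
    lms_to_xyz = lms_to_xyz or AffineMap(LMS_TO_XYZ)
    xyz = lms_to_xyz(colors.samples)
    white_xyz = lms_to_xyz(white[None, :])[0]
    f = _lab_f(xyz / white_xyz)
    lab = np.column_stack([
        116.0 * f[:, 1] - 16.0,
        500.0 * (f[:, 0] - f[:, 1]),
        200.0 * (f[:, 1] - f[:, 2]),
    ])
    out = colors.with_samples(lab, space="LAB", white=white)
    if return_stages:
        stage = colors.with_samples(f, space="LMS_adapted", white=white)
        return out, stage
    return out


# ---------------------------------------------------------------- benchmark

@dataclass
class BenchmarkModel:
    """PCA rotation + per-component empirical equalizers, fitted on train."""

    rotation: np.ndarray
    center: np.ndarray
    equalizers: MarginalMap

    def __call__(self, colors: ColorSet) -> ColorSet:
        rotated = (colors.samples - self.center) @ self.rotation.T
        rotated_set = colors.with_samples(rotated, space="BENCHMARK")
        return apply_marginal_maps(rotated_set, self.equalizers)


def fit_statistical_benchmark(train: ColorSet) -> BenchmarkModel:
    """Statistical reference network: decorrelate by the training PCA
    rotation, then equalize each component with its empirical CDF."""
    center = train.samples.mean(axis=0)
    cov = np.cov(train.samples, rowvar=False)
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]
    signs = np.sign(vecs[np.argmax(np.abs(vecs), axis=0), np.arange(3)])
    signs[signs == 0] = 1.0
    rotation = (vecs * signs).T
    rotated = (train.samples - center) @ rotation.T
    eq = empirical_cdf_map(rotated, space="BENCHMARK")
    return BenchmarkModel(rotation, center, eq)


def statistical_benchmark(train: ColorSet, test: ColorSet) -> ColorSet:
    """Transform test by the train-fitted benchmark (PCA + equalization)."""
    if train.space != test.space:
        raise UsageError("train and test must share a space tag")
    return fit_statistical_benchmark(train)(test)


# ------------------------------------------------------------- full network

@dataclass
class FittedNetwork:
    """Train-fitted parameters of one network variant, applicable to any
    test set from the same space."""

    spec: NetworkSpec
    white: np.ndarray
    wc_reference: tuple[np.ndarray, np.ndarray] | None = None
    pleistochrome: MarginalMap | None = None
    benchmark: BenchmarkModel | None = None

    def adapt(self, test: ColorSet) -> ColorSet:
        """The first nonlinear stage: chromatic adaptation of linear LMS."""
        if self.spec.adaptation == "none":
            return test.with_samples(test.samples, space="LMS_adapted")
        if self.spec.adaptation == "von_kries":
            return von_kries(test, self.white)
        ref_mean, ref_cov = self.wc_reference
        return webster_clifford(test, ref_mean, ref_cov)

    def responses(self, test: ColorSet) -> dict[str, ColorSet]:
        """Ordered layer responses (r1, x1, r2, x2)."""
        spec = self.spec
        r1 = test
        x1 = self.adapt(test)
        if spec.model_family == "cielab":
            lab, stage = cielab(test, self.white, spec.lms_to_xyz,
                                return_stages=True)
            x2 = lab.with_samples(lab.samples, space="ATD_nonlinear")
            return {"r1": r1, "x1": stage,
                    "r2": lab.with_samples(lab.samples, space="ATD_linear"),
                    "x2": x2}
        if spec.model_family == "benchmark":
            x2 = self.benchmark(x1.with_samples(x1.samples))
            rotated = (x1.samples - self.benchmark.center) @ self.benchmark.rotation.T
            r2 = x1.with_samples(rotated, space="ATD_linear")
            return {"r1": r1, "x1": x1, "r2": r2, "x2": x2}
        r2 = opponent_transform(x1, spec.opponent_matrix)
        if spec.nonlinearity == "none" or self.pleistochrome is None:
            x2 = r2.with_samples(r2.samples, space="ATD_nonlinear")
        else:
            x2 = apply_marginal_maps(r2, self.pleistochrome)
        return {"r1": r1, "x1": x1, "r2": r2, "x2": x2}


def fit_network(train: ColorSet, spec: NetworkSpec) -> FittedNetwork:
    """Fit every data-dependent parameter of a network variant on training
    colors only (white point = training sample mean, Webster-Clifford
    reference moments, equalizer knots, benchmark rotation)."""
    if train.space != "LMS_linear":
        raise UsageError("networks are fitted on LMS_linear training colors")
    white = train.samples.mean(axis=0)
    fitted = FittedNetwork(spec=spec, white=white)
    if spec.adaptation == "webster_clifford":
        if spec.adaptation_reference is not None:
            fitted.wc_reference = (
                np.asarray(spec.adaptation_reference[0], dtype=float),
                np.atleast_2d(np.asarray(spec.adaptation_reference[1],
                                         dtype=float)))
        else:
            fitted.wc_reference = (white, np.cov(train.samples, rowvar=False))
    # the training data goes through the fitted early stages to fit the later
    # ones, exactly as the test data will
    if spec.model_family == "physiological" and spec.nonlinearity != "none":
        r2_train = opponent_transform(fitted.adapt(train), spec.opponent_matrix)
        kind = ("empirical_cdf" if spec.nonlinearity == "pleistochrome_empirical"
                else "exponential_fit")
        fitted.pleistochrome = fit_pleistochrome(r2_train, kind)
    if spec.model_family == "benchmark":
        fitted.benchmark = fit_statistical_benchmark(fitted.adapt(train))
    return fitted


def fit_networks_shared(trains: dict[str, ColorSet], spec: NetworkSpec
                        ) -> dict[str, FittedNetwork]:
    """Fit one network per illumination condition with shared later stages.

    Only the adaptation parameters (white point; moment targets) are
    condition-specific; the trainable stages after adaptation (pleistochrome
    equalizers, benchmark rotation + equalizers) are fitted once on the
    pooled adapted training responses of all conditions, so every condition
    passes through the *same* nonlinearity.
    """
    nets = {}
    adapted = []
    for label, train in trains.items():
        if train.space != "LMS_linear":
            raise UsageError("networks are fitted on LMS_linear training colors")
        white = train.samples.mean(axis=0)
        net = FittedNetwork(spec=spec, white=white)
        if spec.adaptation == "webster_clifford":
            if spec.adaptation_reference is not None:
                net.wc_reference = spec.adaptation_reference
            else:
                net.wc_reference = (white, np.cov(train.samples, rowvar=False))
        nets[label] = net
        adapted.append(net.adapt(train))
    pooled = adapted[0].with_samples(
        np.vstack([a.samples for a in adapted]))
    if spec.model_family == "physiological" and spec.nonlinearity != "none":
        r2_pooled = opponent_transform(pooled, spec.opponent_matrix)
        kind = ("empirical_cdf" if spec.nonlinearity == "pleistochrome_empirical"
                else "exponential_fit")
        shared_pleisto = fit_pleistochrome(r2_pooled, kind)
        for net in nets.values():
            net.pleistochrome = shared_pleisto
    if spec.model_family == "benchmark":
        shared_benchmark = fit_statistical_benchmark(pooled)
        for net in nets.values():
            net.benchmark = shared_benchmark
    return nets


def run_network(train: ColorSet, test: ColorSet, spec: NetworkSpec
                ) -> dict[str, ColorSet]:
    """Fit on train, respond to test: returns the layer sequence
    ``{"r1", "x1", "r2", "x2"}`` (input, adapted, linear opponent, nonlinear
    opponent), each a ColorSet with its space tag."""
    if train.space != "LMS_linear" or test.space != "LMS_linear":
        raise UsageError("run_network expects LMS_linear train and test")
    return fit_network(train, spec).responses(test)
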