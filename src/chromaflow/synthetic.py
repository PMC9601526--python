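"""Synthetic color-sample generators with known ground truth.

Two kinds of fixtures:

* exact multivariate-normal sets, for which every information quantity has a
  closed form (validation oracles for the Gaussianization estimators);
* "natural-like" LMS cone-response manifolds under a configurable illuminant:
  all-positive, strongly correlated triplets elongated along the achromatic
  diagonal, with an illuminant change modeled as a per-channel multiplicative
  gain.  In this von-Kries world the diagonal gain is the exact ground-truth
  adaptation, so perfect color compensation (KLD -> 0) is achievable and
  testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colorset import ColorSet, ParameterError

# Natural-like generator defaults: chosen to give the qualitative shape of
# natural cone-response manifolds — a heavy-tailed luminance spread covering
# roughly two orders of magnitude (so the linear-response PDF is strongly
# nonuniform, the regime dimension-wise equalization exploits), pairwise LMS
# correlations around 0.95-0.99 from overlapping spectral sensitivities, and
# strong elongation along the achromatic diagonal.
DEFAULT_INTENSITY_LOG_SD = 1.0   # sd of ln(intensity)
DEFAULT_CHROMA_SD = 0.15         # sd of per-channel log perturbation
DEFAULT_MIXING_OVERLAP = 0.45    # off-diagonal mass of the mixing matrix


@dataclass(frozen=True)
class IlluminantSpec:
    """An illumination condition as per-channel multiplicative LMS gains.

    Stands in for a full illuminant spectrum: changing the light multiplies
    each cone channel's response by a positive factor.
    """

    label: str
    gains: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.gains) != 3 or any(g <= 0 for g in self.gains):
            raise ParameterError("illuminant gains must be 3 positive factors")


#: Neutral (daylight-like) reference condition.
D65LIKE = IlluminantSpec("D65like", (1.0, 1.0, 1.0))
#: Warm (incandescent-like) condition: more long-wave, less short-wave power.
ALIKE = IlluminantSpec("Alike", (1.2, 1.0, 0.6))


def split_seed(seed: int, n_children: int) -> list[np.random.Generator]:
    """Deterministically derive independent generators from one global seed."""
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n_children)]


def generate_gaussian_set(n: int, mean, covariance, seed: int,
                          space: str = "ATD_linear") -> ColorSet:
    """Exact multivariate-normal fixture (closed-form oracle available).

    Same (parameters, seed) give bitwise-identical samples.
    """
    if n < 2:
        raise ParameterError("need n >= 2")
    mean = np.asarray(mean, dtype=float).ravel()
    covariance = np.atleast_2d(np.asarray(covariance, dtype=float))
    if mean.size != 3 or covariance.shape != (3, 3):
        raise ParameterError("mean must be a 3-vector and covariance 3x3")
    if not np.allclose(covariance, covariance.T, atol=1e-10):
        raise ParameterError("covariance must be symmetric")
    eigvals = np.linalg.eigvalsh(covariance)
    if eigvals.min() < -1e-10:
        raise ParameterError("covariance must be positive semi-definite")
    rng = np.random.default_rng(seed)
    samples = rng.multivariate_normal(mean, covariance, size=n,
                                      method="cholesky" if eigvals.min() > 1e-12
                                      else "eigh")
    return ColorSet(samples, space=space, illuminant="none",
                    meta={"generator": "gaussian", "seed": seed,
                          "mean": mean, "covariance": covariance})


def mixing_matrix(overlap: float) -> np.ndarray:
    """Row-stochastic channel-mixing matrix: diagonal ``1 - overlap``,
    off-diagonal mass ``overlap`` split evenly (emulates overlapping cone
    spectral sensitivities)."""
    if not 0 <= overlap < 1:
        raise ParameterError("mixing_overlap must be in [0, 1)")
    m = np.full((3, 3), overlap / 2.0)
    np.fill_diagonal(m, 1.0 - overlap)
    return m


def generate_natural_like(n: int, illuminant: IlluminantSpec = D65LIKE,
                          intensity_log_sd: float = DEFAULT_INTENSITY_LOG_SD,
                          chroma_sd: float = DEFAULT_CHROMA_SD,
                          mixing_overlap: float = DEFAULT_MIXING_OVERLAP,
                          seed: int = 0) -> ColorSet:
    """Natural-like LMS manifold under one illuminant.

    Construction: a log-normal scalar intensity shared by all channels,
    independent per-channel chromatic perturbations (added in the log domain,
    so the output stays strictly positive), channel mixing by a
    row-stochastic matrix emulating overlapping cone sensitivities, then the
    illuminant's per-channel gains.  Pairwise correlations increase with
    ``mixing_overlap``; ``chroma_sd = 0`` with ``mixing_overlap = 0`` reduces
    to three channels proportional to the intensity.
    """
    if n < 2:
        raise ParameterError("need n >= 2")
    if intensity_log_sd < 0 or chroma_sd < 0:
        raise ParameterError("spread parameters must be >= 0")
    rng_int, rng_chroma = split_seed(seed, 2)
    log_intensity = rng_int.normal(0.0, intensity_log_sd, size=n)
    log_chroma = rng_chroma.normal(0.0, chroma_sd, size=(n, 3))
    channels = np.exp(log_intensity[:, None] + log_chroma)
    mixed = channels @ mixing_matrix(mixing_overlap).T
    samples = mixed * np.asarray(illuminant.gains)
    return ColorSet(samples, space="LMS_linear", illuminant=illuminant.label,
                    meta={"generator": "natural_like", "seed": seed,
                          "intensity_log_sd": intensity_log_sd,
                          "chroma_sd": chroma_sd,
                          "mixing_overlap": mixing_overlap,
                          "gains": list(illuminant.gains)})


def generate_condition_pair(n_train: int, n_test: int, seed: int,
                            illuminants: tuple[IlluminantSpec, IlluminantSpec]
                            = (D65LIKE, ALIKE),
                            **params) -> dict[str, dict[str, ColorSet]]:
    """Train/test sets for two illumination conditions of the same scene
    statistics.

    Each (split, illuminant) cell is an independent reflectance draw; the two
    conditions differ *in distribution* exactly by the illuminant gain ratio
    (the ground-truth adaptation).  Draws are kept independent rather than
    scene-paired: with paired draws a near-exact adaptation would collapse
    the two conditions onto duplicated points, a degenerate union density no
    continuous estimator should be fed.
    """
    s_train, s_test = np.random.SeedSequence(seed).spawn(2)
    out: dict[str, dict[str, ColorSet]] = {}
    for split, ss, n in (("train", s_train, n_train), ("test", s_test, n_test)):
        children = ss.spawn(len(illuminants))
        out[split] = {
            ill.label: generate_natural_like(
                n, ill, seed=int(child.generate_state(1)[0] % (2 ** 31)),
                **params)
            for ill, child in zip(illuminants, children)
        }
    return out
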