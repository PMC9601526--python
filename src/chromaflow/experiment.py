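"""The information-flow measurement protocol.

For each network variant the protocol measures, at every layer:

* T   — redundancy among the channels (noiseless responses);
* h   — differential entropy after linear rescaling into a common cube of
        side S (so values are comparable across representations; the
        uniform bound is d*log2(S));
* I   — mutual information between the noiseless input and the layer's
        response corrupted by Gaussian sensor noise (sd = 5% of the
        response deviation), compared to the reference
        I(input, input + negligible 0.05% noise);
* KLD — divergence between the two illuminant-conditioned response sets
        (0 = perfect chromatic compensation).

Each quantity is estimated repeatedly on random subsets of the test set and
reported as mean +/- standard deviation.  Layer-to-layer differences of I
attribute the information gain to retinal adaptation, opponency, and the
saturating nonlinearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .colorset import ColorSet, DegenerateInputError, ParameterError, UsageError
from .info import (EstimatorConfig, InfoEstimate, joint_entropy, kld,
                   knn_entropy, knn_mutual_information, knn_total_correlation,
                   mutual_information, total_correlation)
from .networks import NetworkSpec, fit_networks_shared
from .synthetic import ALIKE, D65LIKE, IlluminantSpec, generate_condition_pair

NOISY_RELATIVE_SD = 0.05        # sensor noise: 5% of the response deviation
NEGLIGIBLE_RELATIVE_SD = 0.0005  # reference-noise level: 0.05%
CUBE_SIZE = 10.0


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian sensor noise, sd expressed as a fraction of the signal
    deviation (per dimension, or pooled over dimensions)."""

    relative_sd: float
    seed: int = 0
    mode: str = "per_dimension"

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ParameterError("relative_sd must be >= 0")
        if self.mode not in ("per_dimension", "pooled"):
            raise ParameterError(f"unknown noise mode {self.mode!r}")


def add_sensor_noise(colors: ColorSet, noise: NoiseSpec) -> ColorSet:
    """Add zero-mean Gaussian noise scaled to the set's own deviation."""
    if noise.relative_sd == 0:
        return colors.with_samples(colors.samples, noise_relative_sd=0.0)
    if noise.mode == "per_dimension":
        sd = colors.samples.std(axis=0)
    else:
        sd = np.full(3, np.sqrt(colors.samples.var(axis=0).sum()))
    rng = np.random.default_rng(noise.seed)
    noisy = colors.samples + rng.normal(size=colors.samples.shape) * (
        noise.relative_sd * sd)
    space = colors.space if colors.space != "LMS_linear" else "LMS_adapted"
    out = replace(colors, samples=noisy, space=space)
    out.meta = {**colors.meta, "noise_relative_sd": noise.relative_sd,
                "noise_mode": noise.mode, "noise_seed": noise.seed}
    return out


def rescale_to_cube(colors: ColorSet, size: float = CUBE_SIZE) -> ColorSet:
    """Per-dimension affine map of [min, max] onto [0, size] (entropy values
    then live on a common support; scale factors recorded in meta)."""
    if size <= 0:
        raise ParameterError("cube size must be positive")
    lo = colors.samples.min(axis=0)
    rng_ = np.ptp(colors.samples, axis=0)
    if np.any(rng_ == 0):
        raise DegenerateInputError("zero range: cannot rescale to cube")
    scaled = (colors.samples - lo) * (size / rng_)
    return colors.with_samples(scaled, space="RESCALED",
                               cube_size=size, cube_scale=(size / rng_))


# ------------------------------------------------------- repeated estimation

_RBIG_QUANTITY = {
    "T": lambda inputs, cfg: total_correlation(inputs[0], cfg),
    "h": lambda inputs, cfg: joint_entropy(inputs[0], cfg),
    "I": lambda inputs, cfg: mutual_information(inputs[0], inputs[1], cfg),
    "KLD": lambda inputs, cfg: kld(inputs[0], inputs[1], cfg),
}
_KNN_QUANTITY = {
    "T": lambda inputs, cfg: knn_total_correlation(inputs[0], cfg.knn_k),
    "h": lambda inputs, cfg: knn_entropy(inputs[0], cfg.knn_k),
    "I": lambda inputs, cfg: knn_mutual_information(inputs[0], inputs[1],
                                                    cfg.knn_k),
}

#: quantities whose two inputs are paired rows (subsampled together)
_PAIRED = {"I"}


def repeated_estimate(quantity: str, inputs, n_repeats: int = 10,
                      subsample_fraction: float = 0.8, seed: int = 0,
                      config: EstimatorConfig | None = None,
                      estimator: str = "rbig") -> InfoEstimate:
    """Mean +/- sd of an information quantity over repeated estimations on
    random subsets (without replacement) of the inputs.

    ``inputs`` is a tuple of sample matrices (or ColorSets): one for T/h,
    two for I (paired rows: subsampled together) and KLD (independent sets:
    subsampled separately).
    """
    table = _RBIG_QUANTITY if estimator == "rbig" else _KNN_QUANTITY
    if quantity not in table:
        raise ParameterError(
            f"unknown quantity {quantity!r} for estimator {estimator!r}")
    if not 0 < subsample_fraction <= 1:
        raise ParameterError("subsample_fraction must be in (0, 1]")
    if n_repeats < 1:
        raise ParameterError("n_repeats must be >= 1")
    config = config or EstimatorConfig()
    mats = [m.samples if isinstance(m, ColorSet) else np.asarray(m, dtype=float)
            for m in (inputs if isinstance(inputs, (tuple, list)) else (inputs,))]
    if int(mats[0].shape[0] * subsample_fraction) < 1000:
        raise ParameterError("subsample too small for information estimation")
    rng = np.random.default_rng(seed)

    def draw(n: int) -> np.ndarray:
        if subsample_fraction == 1:
            return np.arange(n)  # full set, deterministic
        return rng.choice(n, size=int(n * subsample_fraction), replace=False)

    values = []
    for _ in range(n_repeats):
        if quantity in _PAIRED:
            idx = draw(mats[0].shape[0])
            subs = [m[idx] for m in mats]
        else:
            subs = [m[draw(m.shape[0])] for m in mats]
        values.append(table[quantity](subs, config).value)
    values = np.asarray(values)
    return InfoEstimate(float(values.mean()),
                        float(values.std()) if n_repeats > 1 else 0.0,
                        n_repeats=n_repeats, estimator=estimator,
                        diagnostics={"quantity": quantity,
                                     "subsample_fraction": subsample_fraction,
                                     "seed": seed})


def reference_information(test: ColorSet,
                          negligible: NoiseSpec | None = None,
                          noisy: NoiseSpec | None = None,
                          config: EstimatorConfig | None = None,
                          n_repeats: int = 10,
                          subsample_fraction: float = 0.8,
                          seed: int = 0) -> InfoEstimate:
    """Upper reference bound: I between the noiseless input and the input
    under negligible (0.05%) noise.  Every noisier layer shares less."""
    negligible = negligible or NoiseSpec(NEGLIGIBLE_RELATIVE_SD, seed=seed + 1)
    near_clean = add_sensor_noise(test, negligible)
    return repeated_estimate("I", (test, near_clean), n_repeats,
                             subsample_fraction, seed, config)


# --------------------------------------------------------------- the tables

LAYERS_PHYSIOLOGICAL = ("lms_input", "linear_atd", "nonlinear_atd")
LAYERS_APPEARANCE = ("lms_nonlinear", "atd_nonlinear")
_LAYER_TO_RESPONSE = {
    "lms_input": "x1",       # (adapted) linear LMS: the input representation
    "linear_atd": "r2",
    "nonlinear_atd": "x2",
    "lms_nonlinear": "x1",
    "atd_nonlinear": "x2",
    "benchmark": "x2",
}


@dataclass
class ExperimentConfig:
    """Declarative description of one full information-flow experiment."""

    n_train: int = 100_000
    n_test: int = 10_000
    seed: int = 0
    illuminants: tuple[IlluminantSpec, IlluminantSpec] = (D65LIKE, ALIKE)
    generator_params: dict[str, float] = field(default_factory=dict)
    cube_size: float = CUBE_SIZE
    noisy_sd: float = NOISY_RELATIVE_SD
    negligible_sd: float = NEGLIGIBLE_RELATIVE_SD
    n_repeats: int = 10
    subsample_fraction: float = 0.8
    adaptations: tuple[str, ...] = ("none", "von_kries", "webster_clifford")
    families: tuple[str, ...] = ("physiological", "cielab", "benchmark")
    nonlinearity: str = "pleistochrome_exponential"
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)

    def snapshot(self) -> dict[str, Any]:
        return {
            "n_train": self.n_train, "n_test": self.n_test, "seed": self.seed,
            "illuminants": [(i.label, list(i.gains)) for i in self.illuminants],
            "generator_params": dict(self.generator_params),
            "cube_size": self.cube_size, "noisy_sd": self.noisy_sd,
            "negligible_sd": self.negligible_sd, "n_repeats": self.n_repeats,
            "subsample_fraction": self.subsample_fraction,
            "adaptations": list(self.adaptations),
            "families": list(self.families),
            "nonlinearity": self.nonlinearity,
        }


Key = tuple[str, str, str]  # (model_family, adaptation, layer)


@dataclass
class ExperimentReport:
    """Per-layer/per-model tables of T, h, I, KLD and the derived gains."""

    T_table: dict[Key, InfoEstimate] = field(default_factory=dict)
    h_table: dict[Key, InfoEstimate] = field(default_factory=dict)
    I_table: dict[Key, InfoEstimate] = field(default_factory=dict)
    kld_table: dict[Key, InfoEstimate] = field(default_factory=dict)
    gains_table: dict[tuple[str, str], InfoEstimate] = field(default_factory=dict)
    reference: InfoEstimate | None = None
    config: dict[str, Any] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def frame(self, which: str) -> pd.DataFrame:
        """One table as a tidy DataFrame (model, adaptation, layer, value,
        spread, n_repeats, estimator)."""
        table: Mapping = getattr(self, f"{which}_table")
        rows = []
        for key, est in table.items():
            rec = dict(zip(("model", "adaptation", "layer"), key)) \
                if len(key) == 3 else {"model": key[0], "feature": key[1]}
            rows.append({**rec, "value": est.value, "spread": est.spread,
                         "n_repeats": est.n_repeats, "estimator": est.estimator})
        return pd.DataFrame(rows)


def information_gains(I_table: Mapping[tuple[str, str], InfoEstimate]
                      ) -> dict[str, InfoEstimate]:
    """Attribute information gains to network features from an I table keyed
    by ``(adaptation, layer)`` for one model family.

    * retinal_adaptation: mean over adapted conditions of
      I(lms_input | adapted) - I(lms_input | none)
    * opponency: mean over adaptation conditions of
      I(linear_atd) - I(lms_input)
    * saturation: mean over adaptation conditions of
      I(nonlinear_atd) - I(linear_atd)

    Spreads propagate in quadrature.
    """
    def cell(adaptation: str, layer: str) -> InfoEstimate:
        try:
            return I_table[(adaptation, layer)]
        except KeyError:
            raise UsageError(f"I table is missing cell ({adaptation!r}, "
                             f"{layer!r})") from None

    def mean_diff(pairs: list[tuple[InfoEstimate, InfoEstimate]]) -> InfoEstimate:
        diffs = [a.value - b.value for a, b in pairs]
        var = sum(a.spread ** 2 + b.spread ** 2 for a, b in pairs)
        return InfoEstimate(float(np.mean(diffs)),
                            float(np.sqrt(var) / len(pairs)),
                            n_repeats=len(pairs), estimator="derived")

    adaptations = sorted({a for a, _ in I_table})
    adapted = [a for a in adaptations if a != "none"]
    gains = {}
    if adapted and "none" in adaptations:
        gains["retinal_adaptation"] = mean_diff(
            [(cell(a, "lms_input"), cell("none", "lms_input")) for a in adapted])
    gains["opponency"] = mean_diff(
        [(cell(a, "linear_atd"), cell(a, "lms_input")) for a in adaptations])
    gains["saturation"] = mean_diff(
        [(cell(a, "nonlinear_atd"), cell(a, "linear_atd")) for a in adaptations])
    return gains


def _family_layers(family: str) -> tuple[str, ...]:
    if family == "physiological":
        return LAYERS_PHYSIOLOGICAL
    if family == "cielab":
        return LAYERS_APPEARANCE
    return ("benchmark",)


def run_information_flow_experiment(config: ExperimentConfig
                                    ) -> ExperimentReport:
    """Full protocol: synthesize two illuminant conditions, push them through
    every configured network variant, and tabulate T, h, I, KLD per layer
    plus the feature-attributed information gains."""
    ss = np.random.SeedSequence(config.seed)
    seed_data, seed_noise, seed_est = (int(s.generate_state(1)[0] % (2 ** 31))
                                       for s in ss.spawn(3))
    data = generate_condition_pair(config.n_train, config.n_test, seed_data,
                                   config.illuminants,
                                   **config.generator_params)
    labels = [ill.label for ill in config.illuminants]
    ref_label = labels[0]

    report = ExperimentReport(config=config.snapshot())
    est_kwargs = dict(n_repeats=config.n_repeats,
                      subsample_fraction=config.subsample_fraction,
                      config=config.estimator)

    # noiseless linear input (union over conditions) and the reference bound
    input_union = np.vstack([data["test"][lab].samples for lab in labels])
    input_set = ColorSet(input_union, space="LMS_linear", illuminant="union")
    report.reference = reference_information(
        input_set, NoiseSpec(config.negligible_sd, seed=seed_noise + 1),
        seed=seed_est, **est_kwargs)

    for family in config.families:
        adaptations = config.adaptations if family != "cielab" else ("none",)
        for adaptation in adaptations:
            # Webster-Clifford aligns both conditions to the reference
            # condition's training moments
            ref_train = data["train"][ref_label]
            ref_moments = (ref_train.samples.mean(axis=0),
                           np.cov(ref_train.samples, rowvar=False))
            spec = NetworkSpec(
                adaptation=adaptation if family != "cielab" else "none",
                nonlinearity=config.nonlinearity,
                model_family=family,
                adaptation_reference=(ref_moments
                                      if adaptation == "webster_clifford"
                                      else None),
            )
            nets = fit_networks_shared({lab: data["train"][lab]
                                        for lab in labels}, spec)
            responses = {lab: nets[lab].responses(data["test"][lab])
                         for lab in labels}

            for layer in _family_layers(family):
                key = (family, adaptation, layer)
                resp = _LAYER_TO_RESPONSE[layer]
                union = np.vstack([responses[lab][resp].samples
                                   for lab in labels])
                union_set = ColorSet(union,
                                     space=responses[labels[0]][resp].space,
                                     illuminant="union")
                try:
                    report.T_table[key] = repeated_estimate(
                        "T", (union,), seed=seed_est, **est_kwargs)
                    # h is compared across representations on a common support
                    cube = rescale_to_cube(union_set, config.cube_size)
                    report.h_table[key] = repeated_estimate(
                        "h", (cube.samples,), seed=seed_est, **est_kwargs)
                    # noise is injected in the layer's native response domain
                    noisy = add_sensor_noise(
                        union_set, NoiseSpec(config.noisy_sd, seed=seed_noise))
                    report.I_table[key] = repeated_estimate(
                        "I", (input_union, noisy.samples), seed=seed_est,
                        **est_kwargs)
                    report.kld_table[key] = repeated_estimate(
                        "KLD", (responses[labels[0]][resp].samples,
                                responses[labels[1]][resp].samples),
                        seed=seed_est, **est_kwargs)
                except (ParameterError, DegenerateInputError) as exc:
                    report.flags.append(f"{key}: {exc}")

        if family == "physiological":
            fam_I = {(a, layer): report.I_table[(family, a, layer)]
                     for a in adaptations for layer in _family_layers(family)
                     if (family, a, layer) in report.I_table}
            try:
                gains = information_gains(fam_I)
                for feature, est in gains.items():
                    report.gains_table[(family, feature)] = est
            except UsageError as exc:
                report.flags.append(f"gains[{family}]: {exc}")
        elif family == "cielab":
            # appearance models expose only the two nonlinear stages, so
            # opponency and saturation are attributed jointly
            a_key = ("cielab", "none", "atd_nonlinear")
            l_key = ("cielab", "none", "lms_nonlinear")
            if a_key in report.I_table and l_key in report.I_table:
                hi, lo = report.I_table[a_key], report.I_table[l_key]
                report.gains_table[(family, "opponency_plus_saturation")] = \
                    InfoEstimate(hi.value - lo.value,
                                 float(np.hypot(hi.spread, lo.spread)),
                                 n_repeats=1, estimator="derived")
    return report
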