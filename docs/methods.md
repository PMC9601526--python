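# Methods

## The measurement problem

Given color samples at successive stages of a color-vision network, we need
multivariate information quantities — total correlation T, differential
entropy h, mutual information I, Kullback–Leibler divergence — for
3- and 6-dimensional continuous variables at sample sizes of order 10⁴.
Direct density estimation in several dimensions is badly biased at these
sizes; every quantity is therefore reduced to univariate estimation through
iterative Gaussianization.

## The Gaussianizer

`rbig_fit` alternates two steps: each dimension is mapped through the
standard-normal quantile of its smoothed empirical CDF (Ψ), then the vector
is rotated (R; PCA of the current samples by default, random rotations as an
option). Marginal maps leave T unchanged; a rotation of marginally Gaussian
but dependent coordinates re-exposes dependence as marginal
non-Gaussianity. The drop in total correlation achieved by layer n is

    ΔT(n) = (d/2)·log₂(2πe) − Σⱼ ĥ(xⱼ⁽ⁿ⁾),

evaluated on the marginals right after layer n (before the next Ψ); the sum
of drops converges to T of the input as the output approaches N(0, I).

Convergence is declared when the raw ΔT stays below 0.01 bits for 5
consecutive iterations (hard cap 200). PCA rotations converge in ~6
iterations on Gaussian-like data; random rotations also converge, a few
iterations later, and the two agree on T within estimator spread — a useful
robustness check.

### Numerical choices that matter

These choices were set by validating against closed-form Gaussian oracles
and a null process (independent standard normals, where T = 0 exactly);
each removes a specific, measured bias:

* **Univariate entropy** — Vasicek spacing estimator
  (`scipy.stats.differential_entropy`), bias-calibrated by a cached,
  seeded Monte-Carlo offset: the estimator's mean error on standard-normal
  samples of the same size. Spacing estimators are affine-exact, so the
  offset is valid at any Gaussian scale. Uncorrected, the ~+0.005-bit
  per-call bias accumulates across 3 dimensions × ~6 iterations into a
  ~−0.05-bit T bias.
* **Null calibration of ΔT** — the mean per-iteration drop reported on
  independent standard-normal input (truth: 0) is measured once per
  (n, d), cached, and subtracted from every recorded drop. This absorbs
  the residual bias of the spacing estimator on the fitter's internal
  marginals. Convergence and model trimming use the *raw* drops so that
  stopping behavior is not randomized by the correction.
* **Quantile-map smoothing** — Ψ's knots are block means of order
  statistics (about 2√n knots). The raw empirical quantile function
  carries rank noise that acts as an extra ~0.01-sd noise source when two
  independently fitted maps are compared; on a 5%-noise channel
  (I ≈ 13 bits) that noise cost ~0.5 bits of measured I. The outermost
  block-width on each side uses 8× finer sub-blocks: full-width averaging
  truncates the extreme quantiles, which leaves measurable residual
  non-Gaussianity (~0.13 bits of spurious T) for short-tailed inputs such
  as equalized (uniform) channels. Outside the observed range the map is
  extrapolated linearly with a slope averaged over enough outer knots to
  avoid near-tied order statistics.
* **Transform trimming** — when a fitted Gaussianizer is used as a
  transform inside the I estimator, trailing layers whose drop stayed
  below tolerance are removed: each such layer injects small independent
  map distortions (~0.05 bits of pair dependence lost per layer) while
  removing no structure. The KLD path keeps the full model, because its
  trailing layers perform the per-dimension standardization that the
  marginal divergence term against N(0,1) relies on.
* **Univariate KLD** (inside the divergence estimator) — shared-support
  binned densities, Rice-rule bin count, additive smoothing 0.5, with
  overflow bins carrying the reference-normal tail mass.

The estimators reproduce closed forms on 3-D Gaussian fixtures at n = 10⁴
within ≈ 0.1 bits for T, h, I and KLD across correlations 0–0.9, and return
|T| ≲ 0.03 and |KLD| ≲ 0.03 bits on the zero-truth references.

### Nearest-neighbor cross-check

Kozachenko–Leonenko entropies (samples whitened first; the estimator is
affine-covariant and much less biased on isotropic clouds) provide T and h
independently of the Gaussianization route; mutual information uses the KSG
(Kraskov–Stögbauer–Grassberger) neighbor-count form. A known operating
limit: k-NN mutual-information estimators need a sample size roughly
exponential in the MI itself, so on a near-deterministic 5%-noise channel
(~13 bits) they undershoot by 2–4 bits at n = 10⁴ regardless of k. The
cross-check is therefore meaningful for T, h and for moderate-MI channels,
and a dedicated test documents the high-MI limit. The nearest-neighbor
family provides no KLD.

## The networks

* **von Kries** — channel-wise division by the white point, computed as the
  sample mean of the training colors of each illuminant condition.
* **Webster–Clifford** — the affine map taking the sample mean/covariance
  exactly onto a reference (here: the neutral condition's training
  moments). Among the affine maps that equalize second moments, the
  symmetric-square-root choice `A = Σ_ref^{1/2} Σ_sample^{−1/2}` is used:
  it is unique and adds no arbitrary rotation. Note that even in a
  von-Kries world it is not the exact compensator (the exact one is the
  diagonal gain), so a small residual divergence survives it — visible in
  the KLD tables, and consistent with moment matching being only a
  second-order alignment.
* **Opponent stage** — a configurable invertible 3×3 matrix; the shipped
  default is the Ingling & Tsou (1977) opponent weights (achromatic V,
  red–green, yellow–blue), a documented stand-in for the classical
  opponent recombination whose coefficients are not standardized. Every
  report records the matrix used.
* **Pleistochrome** — dimension-wise PDF equalization of the opponent
  channels after centering each dimension to a non-negative range. The
  exact equalizer is the empirical CDF; the default approximates it with
  a saturating exponential `a·(1 − exp(−(x − x₀)/τ))` least-squares
  fitted to the empirical equalizer over its bulk (0.5–99.5% quantile)
  range, with the asymptote bounded near 1 — a CDF's asymptote.
  Unconstrained fits anchored on heavy-tail extremes are ridge-unstable
  across training draws. Fitted maps clamp out-of-domain test values to
  the boundary and flag the affected rows.
* **CIE L\*a\*b\*** — standard formulas (cube-root with linear toe,
  published constants); LMS→XYZ defaults to the inverse
  Hunt–Pointer–Estévez matrix, configurable. The linear toe is extended
  below zero so the map stays monotone on any real input.
* **Statistical benchmark** — PCA rotation + per-component empirical
  equalization, fitted on training data: a transparent stand-in for
  nonlinear infomax methods, marking what a purely statistical,
  rotation-plus-marginal-equalization code achieves.

Training protocol: white points and moment targets are per-illuminant; the
trainable stages after adaptation (equalizers, benchmark rotation) are
fitted once on the pooled adapted training responses of both conditions, so
every condition passes through the same nonlinearity. With per-condition
fits, the two conditions' responses diverge by the difference of the fitted
maps, inflating KLD with an artifact of training variance.

## The synthetic color world

`generate_natural_like` draws a log-normal scalar intensity (ln-sd 1.0,
about two orders of magnitude of luminance — the standard natural-scene
figure, and the regime in which the linear-response PDF is nonuniform
enough for equalization to pay off), adds per-channel log-domain chromatic
perturbations (sd 0.15), mixes channels with a row-stochastic matrix
(off-diagonal mass 0.45, emulating overlapping cone sensitivities; pairwise
LMS correlations ≈ 0.99), and applies per-channel illuminant gains
(neutral (1, 1, 1) vs warm (1.2, 1.0, 0.6)).

What this emulates: all-positive LMS triplets elongated along the
achromatic diagonal, heavy-tailed intensity, and an illuminant change that
is exactly a diagonal gain — making von Kries the oracle-perfect adaptation
and KLD → 0 an achievable ground truth. What it does not emulate: spatial
structure, real illuminant spectra and surface-reflectance statistics,
multimodality of scene content. Passing tests therefore validate the
estimators and the relative ordering of network features, not the paper-
world's absolute table values, which depend on a calibrated scene database.
The two illuminant conditions are independent reflectance draws, matched in
distribution: scene-paired draws would, after near-exact adaptation,
collapse onto duplicated points — a degenerate density that a continuous
estimator should never be fed.

## The experiment protocol

For each network variant: T on the noiseless responses, h after rescaling
the responses into the common cube (S = 10), I between the noiseless linear
input and the response with 5%-of-deviation Gaussian noise (the reference
bound uses 0.05% noise on the input itself), KLD between the two
illuminant-conditioned response sets (neutral condition as the Gaussianizer
reference; the direction is recorded). T, h and I are computed on the union
of the two conditions — the reading under which adaptation changes even the
input-layer statistics, as the published tables show. "Deviation" for noise
scaling is the per-dimension sample sd (a pooled mode exists for
sensitivity analysis). Noise is injected in each layer's native response
domain; cube rescaling applies only to the h table.

Every tabulated value is the mean ± sd of 10 estimates on random 80%
subsets of the test set. Gains: retinal adaptation is the mean over adapted
conditions of I(input | adapted) − I(input | none); opponency and
saturation are the mean layer-to-layer I differences over all adaptation
conditions; spreads propagate in quadrature. These difference formulas
reproduce the published gains table from the published per-layer table to
printed precision.

Default problem sizes are 10⁵ training / 10⁴ test samples with 10 repeats;
the packaged tests and the acceptance script run the same protocol at
2–3×10⁴ training / 3–4×10³ test samples with 3–10 repeats, which keeps every
qualitative ordering stable while completing in minutes on one CPU.

## Known limitations

* Absolute T/h/I/KLD values on synthetic data are not comparable to values
  measured on real calibrated scenes; only the structure of the tables
  (orderings, invariances, bounds, gain arithmetic) transfers.
* The Gaussianization I estimator loses a few hundredths of a bit per
  fitted map on near-deterministic channels (quantile-map noise); at
  n = 10⁴ its ceiling is ~0.1 bits below truth on a 13-bit channel.
* The k-NN mutual-information cross-check is sample-limited on high-MI
  channels (see above).
* The exponential pleistochrome is a poor approximation for nearly
  symmetric channel distributions (its target — the empirical equalizer —
  is then sigmoid, not saturating); the empirical-CDF equalizer is the
  drop-in exact alternative.
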