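# chromaflow

Information flow through biological color-vision networks, measured with
Gaussianization-based estimators of multivariate information quantities.

Color appearance models are cascades of two linear+nonlinear layers acting on
the linear LMS cone responses:

    x0 --spectral integration--> r1 --adaptation--> x1
       --opponent recombination--> r2 --saturation--> x2

where adaptation is von Kries white-point normalization or Webster–Clifford
moment matching, the opponent stage is an invertible 3×3 recombination into
achromatic / red–green / yellow–blue channels, and the saturating
nonlinearity equalizes each opponent channel's distribution. The efficient
coding hypothesis predicts that these psychophysically motivated stages
should also be good information-transmission stages. `chromaflow` quantifies
that claim on synthetic natural-like color manifolds by measuring, at every
layer:

* **T** — total correlation (redundancy), `T(x) = Σⱼ h(xⱼ) − h(x)`;
* **h** — differential entropy after rescaling into a common cube of side
  `S = 10` (uniform bound `3·log₂10 ≈ 9.97` bits);
* **I** — mutual information between the noiseless input and the layer
  response under Gaussian sensor noise (sd = 5% of the response deviation);
* **KLD** — divergence between the response sets acquired under two
  illuminants (0 = perfect chromatic compensation).

All four reduce to univariate entropy estimates through rotation-based
iterative Gaussianization (RBIG): alternating marginal Gaussianization Ψ and
rotation R converge any density to N(0, I), and the per-iteration drop
`ΔT(n) = (d/2)·log₂(2πe) − Σⱼ ĥ(xⱼ⁽ⁿ⁾)` telescopes to T. Then
`h = −T + Σⱼ h(xⱼ)`, `I(x,y) = T([G_x(x), G_y(y)])`, and
`KLD(x|y) = T(z) + Σⱼ KLD(z_j ‖ N(0,1))` with `z = G_x(y)`.
Kozachenko–Leonenko nearest-neighbor estimates provide an independent
cross-check for T, h and I, and closed-form Gaussian oracles validate
everything on fixtures with known answers.

## Worked example

Run a physiological-network experiment on synthetic two-illuminant color
manifolds (a neutral "D65like" condition and a warm "Alike" condition whose
LMS gains are (1.2, 1.0, 0.6)):

```sh
cat > exp.yaml <<CFG
n_train: 20000
n_test: 3000
n_repeats: 3
seed: 7
families: [physiological]
CFG
chromaflow experiment --config exp.yaml --out run/
```

which prints

```
information gain ranking (physiological network):
  opponency            +1.68 ± 0.10 bits
  saturation           +0.14 ± 0.10 bits
  retinal_adaptation   -0.90 ± 0.16 bits
wrote 5 tables to run
```

and writes the five tables (`T`, `h`, `I`, `kld`, `gains`) as CSV. In this
run the opponent recombination is by far the most valuable stage for
information transmission (+1.68 bits of input information made available at
fixed sensor noise), the saturating nonlinearity adds a small further gain,
and retinal adaptation by itself *costs* transmitted information — its job
is manifold alignment, not channel capacity. That is exactly what the KLD
table shows: without adaptation the two illuminant conditions diverge by
~18–31 bits at every layer, while von Kries adaptation collapses the
divergence to ≈ 0 (0.02 ± 0.01 bits at the input layer) because the
synthetic illuminant change is a pure per-channel gain, for which von Kries
is the exact compensator. The redundancy table shows the decorrelation
claim: T drops from 6.8 bits at the (unadapted) LMS input to 1.8 bits in the
linear opponent channels, and stays there through the dimension-wise
nonlinearity, which cannot change T.

The same quantities are available as a library:

```python
from chromaflow import generate_natural_like, total_correlation
colors = generate_natural_like(10_000, seed=0)
print(total_correlation(colors.samples))   # ~6 bits of LMS redundancy
```

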