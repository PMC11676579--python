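# eriwsta

Entropy-regularized iterative weighted shrinkage-thresholding for linear
inverse problems in imaging.

Deblurring and denoising an image `x` from measurements `b = Ax + ε` is
classically done with ISTA: a gradient step on `½‖Ax − b‖²` followed by
soft-thresholding, solving L1-regularized least squares. Weighted variants
give every pixel its own threshold `β·t·wᵢ`, but the classical reweighting
rules (IRL1, WLQ, IRW) produce weights with no common scale — they neither
sum to one nor stay in [0, 1]. This package implements the
entropy-regularized alternative (ERIWSTA): the weights minimize

    Σᵢ wᵢ|xᵢ| + γ Σᵢ wᵢ ln wᵢ   over the probability simplex,

whose closed-form solution is the softmax `wᵢ ∝ exp(−|xᵢ|/γ)` — weights are
probabilities, interpretable as each coordinate's contribution, and the
temperature `γ` tunes how sharply the shrinkage concentrates on
small-magnitude (background) pixels. The package provides:

- matrix-free blur operators with exact adjoints (zero / symmetric /
  circular boundaries), explicit-matrix operators, certified Lipschitz
  bounds, a Shepp-Logan phantom generator and a seeded degradation
  simulator (`eriwsta.linops`);
- the entropy weight update and the ISTA/IRL1/WLQ/IRW rules
  (`eriwsta.weights`);
- one alternating solver loop covering ERIWSTA and the whole weighted-ISTA
  family, plus a two-step (TwIST-style) baseline (`eriwsta.solvers`);
- MAE/profile evaluation, hyperparameter grid search and a self-contained
  benchmark harness (`eriwsta.evaluation`);
- a `click` CLI: `eriwsta simulate | solve | grid | report` (`eriwsta.cli`).

## Worked example

```python
import numpy as np
from eriwsta import BenchmarkConfig, entropy_weights, run_benchmark

# the entropy weights: probabilities concentrating on small magnitudes
print(np.round(entropy_weights(np.array([4.0, 1.0, 5.0]), gamma=0.5), 4))
# [2.500e-03 9.972e-01 3.000e-04]
print(entropy_weights(np.array([4.0, 1.0, 5.0]), gamma=1e-8))
# [0. 1. 0.]   <- zero-temperature limit: one-hot on min{4, 1, 5}

# small end-to-end benchmark: 64x64 phantom, 5x5 uniform blur,
# Gaussian noise of variance 1e-2, 30 iterations of each algorithm
report = run_benchmark(BenchmarkConfig(
    phantom_size=64, noise_variances=(1e-2,), iterations=30,
    seed=0, profile_index=32))
print(report.mae_table[["algorithm", "beta", "gamma", "mae"]]
      .sort_values("mae").to_string(index=False))
```

```
algorithm      beta  gamma      mae
  eriwsta 100.00000   0.01 0.096801
     irl1   0.00001    NaN 0.156355
     ista   0.00100    NaN 0.161185
      wlq   0.00001    NaN 0.171570
      irw   0.00001    NaN 0.171909
    twist   0.00001    NaN 0.379721
```

Lower mean absolute error (MAE, intensity units on the [0, 1] phantom
scale) is better: on this instance the entropy-weighted solver reconstructs
the phantom with ~40% lower error than plain ISTA at the same iteration
budget, because background pixels receive nearly all the weight (hence
strong shrinkage) while edges and bright structures are left untouched. The
objective Φ is monotonically nonincreasing along the iterations
(`report.traces[1e-2]["eriwsta"].objective`: 26.482 → 9.033 here).

The same experiment from the shell:

```sh
eriwsta simulate -c config.yaml -o out/   # phantom + degraded images
eriwsta solve    -c config.yaml -o out/   # traces, images, MAE table, profiles
eriwsta grid     -c config.yaml -o out/   # MAE surfaces over beta (x gamma)
eriwsta report   -c config.yaml -o out/   # plots from the solve outputs
```

See `docs/methods.md` for the model, parameter meanings and numerical
conventions.

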