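# Methods

## Problem and model

The package solves ill-posed linear inverse problems in imaging: recover an
image `x ∈ R^n` from measurements `b = A x + ε`, where `A` is a known linear
forward operator (here: spatial blur) and `ε` is zero-mean Gaussian noise.
Reconstruction minimizes the weighted L1-regularized least-squares objective

    Φ(x, w) = ½‖Ax − b‖² + β ( Σᵢ wᵢ|xᵢ| + γ Σᵢ wᵢ ln wᵢ ),
    subject to wᵢ ≥ 0, Σᵢ wᵢ = 1,

alternating exact minimization in `w` with a majorization-minimization (MM)
step in `x`. The negative-entropy term `γ Σ wᵢ ln wᵢ` regularizes the weight
distribution: without it the optimal `w` is a one-hot vector on the
smallest-magnitude coordinate; with it the minimizer over the simplex is the
closed-form softmax

    wᵢ = exp(−|xᵢ|/γ) / Σₗ exp(−|xₗ|/γ).

The temperature `γ` interpolates between one-hot weights (γ → 0, ties split
equally) and uniform weights `1/n` (γ → ∞). Coordinates with small current
magnitude — in the benchmark, background pixels — receive large weight and
hence a large shrinkage threshold; strong coordinates are barely shrunk.

The `x`-step majorizes the data term `F(x) = ½‖Ax − b‖²` by its second-order
expansion with the Hessian replaced by `L·I`, where `L ≥ λ_max(AᵀA)`. The
surrogate separates per coordinate and its exact minimizer is the
soft-threshold update

    x⁺ᵢ = soft(rᵢ, β t wᵢ),   r = x − t·∇F(x),   t = 1/L,

with `soft(v, θ) = sign(v)·max(|v| − θ, 0)`, the proximal operator of
`θ|·|`. Because the `w`-step is an exact minimizer and the `x`-step is MM
with a true bound `L`, the objective is monotonically nonincreasing — this
is asserted numerically by the test-suite on dense and blur instances.

With constant weights `w ≡ 1` the loop is plain ISTA. The classical
reweighting rules are available under the same loop: IRL1
(`w = 1/(|x|+δ)`), WLQ (`w = 1/(|x|+δ)^{1−p}`) and IRW
(`w = 1/(1+(|x|+δ)^{p+1})`; this closed form was chosen to match the
published range bounds (0, 1] and the decreasing-in-|x| intent of the
scheme, whose printed formula is corrupted in the source literature). A
two-step (TwIST-style) baseline with the same shrinkage denoiser, the
recommended parameters `ρ = (1−√ξm)/(1+√ξm)`, `α = ρ²+1`,
`β₂ = 2α/(1+ξm)` and the monotone safeguard (retreat to the plain IST step
whenever the objective increases) completes the comparison set.

### Gradient-scale convention

Some published forms of the ISTA update write the gradient of `½‖Ax − b‖²`
with an extra factor 2. Both conventions are provided: `step_scale="half"`
(default; `∇F = Aᵀ(Ax−b)`, consistent with the MM bound, descent
guaranteed) and `step_scale="paper"` (`2Aᵀ(Ax−b)`, i.e. an effective step
`2/L`, which can overshoot the majorization and is provided for literal
fidelity to that convention). Which convention produced the original
benchmark numbers is not determinable; all shipped defaults use `"half"`.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| β | regularization strength | table below | trades data fit vs. sparsity |
| γ | entropy temperature (ERIWSTA) | 1e-2 | simplex weights ⇒ per-pixel threshold scale ≈ β·t/n, hence the large optimal β = 1e2 |
| δ | stabilizer for IRL1/WLQ/IRW | 1e-3 | caps the weight at 1/δ (IRL1) |
| p | exponent for WLQ/IRW, in (0, 1] | 0.5 | not recoverable from the source study; fixed once |
| t = 1/L | gradient step | computed | L from the cached operator bound or power iteration |
| max_iter | iteration budget | 100 (grid), 30 (reconstructions) | fixed counts; relative-change stop available (`tol`, default off) |
| x0 | initial iterate | zeros | back-projected start `Aᵀb` selectable |
| ξm | TwIST eigenvalue floor | 0.04 | reference rule of thumb for mildly ill-conditioned operators |

Benchmark per-algorithm hyperparameters (selected by final-MAE grid search
in the original study): ISTA β=1e-3; WLQ/IRW/IRL1 β=1e-5, δ=1e-3;
TwIST β=1e-5; ERIWSTA β=1e2, γ=1e-2.

## Forward model and synthetic benchmark

The benchmark emulates a simulated-CT restoration task that is, concretely,
image deblurring/denoising (no tomographic projection is involved):

- **Phantom.** The standard ten-ellipse Shepp-Logan head phantom rasterized
  at `size × size` from the published ellipse table (high-contrast
  intensities by default; the classic low-contrast variant is selectable
  and rescaled by its maximum), clipped to [0, 1]. Pixel centres lie at
  `linspace(−1, 1, size)`; rendering is deterministic.
- **Blur.** Same-size 2-D correlation with the k×k uniform kernel
  (entries 1/k², default k=5). Boundary handling defaults to zero padding,
  with symmetric and circular selectable; the adjoint is constructed from
  the exact transpose of the padding and correlation steps, so
  forward/adjoint pairs pass randomized dot-product tests to machine
  precision under every mode. For this symmetric kernel correlation equals
  convolution; the correlation convention is fixed for generality.
- **Noise.** I.i.d. zero-mean Gaussian with absolute variance σ² ∈
  {1e-2, 1e-3} on the [0, 1] intensity scale, drawn from a PCG64 generator
  with a per-stage seed derived from one master seed, so all artifacts are
  bit-reproducible.
- **Lipschitz bound.** Blur operators cache the certified Hölder/Schur
  bound `‖A‖₁‖A‖∞ ≥ λ_max(AᵀA)` (equal to 1 for zero/circular boundaries);
  power iteration on blur operators is unreliable because the top of the
  spectrum is nearly degenerate. Generic operators use seeded power
  iteration with a 1.01 safety inflation so the returned value remains a
  true upper bound at finite iteration count, or exact dense
  eigendecomposition for small problems.

Images flatten to vectors in row-major (C) order everywhere.

What the generator does **not** emulate: tomographic physics (Radon
projections, beam hardening), Poisson/mixed noise of real CT or PET
detectors, and real anatomical texture. Passing the benchmark shows correct
optimization behaviour (descent, fixed points, ranking under the stated
degradation), not clinical reconstruction quality.

## Evaluation

Reconstruction quality is the mean absolute error
`MAE = (1/N)‖x − x̂‖₁` over all N pixels (an MSE diagnostic is provided
separately but never called MAE). Central profiles extract one row/column
(1-based index; index 128 on a 256² image is the central profile).
Hyperparameter grids are decade-spaced, 10⁻¹⁰…10¹⁰ by default (21 points
per axis); each cell is an independent solver run from the same degraded
input, diverged cells are recorded as missing, and the argmin cell is
reported. γ-free schemes sweep β only.

A caution on final-MAE ranking at these noise levels: deblurring iterations
semiconverge — MAE first falls, then rises as high-frequency noise is
progressively fit even while the objective decreases. At a fixed iteration
budget the ranking between algorithms therefore depends strongly on the
noise-to-signal scale and on each scheme's effective threshold; the
test-suite checks the scaled-down grid ordering (entropy scheme's best MAE
≤ ISTA's best) and documents the full-scale comparison rather than
promising any particular printed digit.

## Numerical choices

- Softmax weights are computed after subtracting min|xᵢ| (the ratio is
  shift-invariant), so the update never overflows; for tiny γ non-minimal
  coordinates underflow to exact 0 and ties at the minimum split equally.
- `0·ln 0 = 0` in the entropy term; simplex membership is validated (1e-8
  tolerance) whenever the entropy term is active.
- The relative change `‖x⁺−x‖/‖x‖` is defined as 0 when the iterate does
  not move and ∞ for a jump away from an all-zero iterate.
- Non-finite iterates raise an explicit divergence error naming the
  iteration; grid search records such cells as missing.
- Update order within an iteration: weights from the current iterate, then
  the gradient/shrinkage step; the weight trace stored with iteration k is
  the one used to produce iterate k.

## Problem sizes used by the test-suite

Unit and property tests run on 8²–32² images and dense matrices up to
20×40. The end-to-end benchmark check runs the full 256² phantom at both
noise levels for 100 iterations; the grid-search check runs a 32² instance
over a 5×5 decade grid at 30 iterations. These sizes were chosen so the
whole suite completes in a few minutes while exercising the same code paths
as larger runs.

## Known limitations

- The entropy weights live on the simplex, so thresholds scale like β/n;
  β must grow with image size for a comparable shrinkage strength (this is
  why the benchmark's ERIWSTA uses β = 1e2 while ISTA uses 1e-3).
- No acceleration (FISTA-style momentum), backtracking line search, or
  positivity constraints.
- The TwIST baseline's parameters are set by a rule of thumb, not tuned per
  instance; it is included for completeness of the comparison set.
- Real-detector noise models and tomographic operators are out of scope.
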