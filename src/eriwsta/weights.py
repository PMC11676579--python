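"""Per-coordinate weight updates for weighted shrinkage-thresholding.

The entropy-regularized scheme minimizes, over the probability simplex,

    sum_i w_i |x_i|  +  gamma * sum_i w_i ln w_i,

whose closed-form solution is a softmax of ``-|x|/gamma``: coordinates with
small magnitude receive large weight (and hence a large threshold), while the
temperature ``gamma`` interpolates between one-hot weights on the smallest
|x_i| (gamma -> 0) and uniform weights 1/n (gamma -> inf). The classical
reweighting rules (IRL1, WLQ, IRW) and the unit weights of plain ISTA are
provided for comparison; those do not live on the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "WeightSchemeParams",
    "baseline_weights",
    "entropy_term",
    "entropy_weights",
    "update_weights",
]

SCHEMES = ("entropy", "constant", "irl1", "wlq", "irw")


@dataclass(frozen=True)
class WeightSchemeParams:
    """Selects a reweighting rule and its parameters.

    gamma : entropy temperature (> 0, entropy scheme only)
    delta : stabilizer added to |x_i| (> 0, irl1/wlq/irw)
    p     : exponent in (0, 1] (wlq/irw)
    """

    scheme: Literal["entropy", "constant", "irl1", "wlq", "irw"]
    gamma: float | None = None
    delta: float = 1e-3
    p: float = 0.5

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.scheme == "entropy":
            if self.gamma is None or self.gamma <= 0:
                raise ValueError(f"entropy scheme requires gamma > 0, got {self.gamma}")
        if self.scheme in ("irl1", "wlq", "irw") and self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if self.scheme in ("wlq", "irw") and not (0 < self.p <= 1):
            raise ValueError(f"p must lie in (0, 1], got {self.p}")


def entropy_weights(x: np.ndarray, gamma: float) -> np.ndarray:
    """Closed-form entropy-regularized weights: softmax of ``-|x|/gamma``.

    Returns ``w_i = exp(-|x_i|/gamma) / sum_l exp(-|x_l|/gamma)``. The
    minimum magnitude is subtracted before exponentiation — the ratio is
    invariant to this shift — so the computation never overflows; for very
    small gamma the non-minimal coordinates underflow to exact 0 and ties at
    the minimum split the mass equally.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    mag = np.abs(x)
    z = np.exp(-(mag - mag.min()) / gamma)
    return z / z.sum()


def entropy_term(w: np.ndarray, gamma: float) -> float:
    """Negative-entropy penalty ``gamma * sum_i w_i ln w_i`` (0*ln 0 := 0).

    For simplex weights the value lies in ``[-gamma ln n, 0]``.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    pos = w > 0
    return float(gamma * np.sum(w[pos] * np.log(w[pos])))


def baseline_weights(x: np.ndarray, params: WeightSchemeParams) -> np.ndarray:
    """Weights for the non-entropy reweighting rules.

    constant : all ones (plain ISTA; deliberately not normalized)
    irl1     : 1 / (|x_i| + delta)
    wlq      : 1 / (|x_i| + delta)^(1 - p)
    irw      : 1 / (1 + (|x_i| + delta)^(p + 1)), decreasing in |x_i| with
               range (0, 1]
    """
    x = np.asarray(x, dtype=float)
    mag = np.abs(x)
    if params.scheme == "constant":
        return np.ones_like(mag)
    if params.scheme == "irl1":
        return 1.0 / (mag + params.delta)
    if params.scheme == "wlq":
        return 1.0 / (mag + params.delta) ** (1.0 - params.p)
    if params.scheme == "irw":
        return 1.0 / (1.0 + (mag + params.delta) ** (params.p + 1.0))
    raise ValueError(f"unknown scheme {params.scheme!r}")


def update_weights(x: np.ndarray, params: WeightSchemeParams) -> np.ndarray:
    """Dispatch to the configured weight rule."""
    if params.scheme == "entropy":
        return entropy_weights(x, params.gamma)
    return baseline_weights(x, params)
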