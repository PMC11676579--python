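"""Forward models for image deblurring and their spectral bounds.

This module provides the linear forward operators ``A`` appearing in the
measurement model ``b = A x + eps``: explicit dense matrices and matrix-free
2-D blur operators with exact adjoints, together with Lipschitz-constant
estimation for ``A^T A``, a Shepp-Logan phantom generator, and the
degradation simulator (blur + additive Gaussian noise) used by the benchmark.

Conventions
-----------
Images are 2-D ``float64`` arrays. Whenever an image is exchanged with a
solver it is flattened to a 1-D vector in **row-major (C) order** and
reshaped back the same way; this convention is fixed throughout the package.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy import signal

__all__ = [
    "BOUNDARY_MODES",
    "ConvergenceError",
    "DegradationSpec",
    "LinearOperator",
    "degrade",
    "image_to_vector",
    "lipschitz_bound",
    "matrix_operator",
    "shepp_logan_phantom",
    "stage_seed",
    "uniform_blur_operator",
    "vector_to_image",
]

BOUNDARY_MODES = ("zero", "symmetric", "circular")

# np.pad mode implementing each boundary convention
_PAD_MODE = {"zero": "constant", "symmetric": "symmetric", "circular": "wrap"}


class ConvergenceError(RuntimeError):
    """Iterative estimation failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_estimate: float | None = None):
        super().__init__(message)
        self.last_estimate = last_estimate


def image_to_vector(image: np.ndarray) -> np.ndarray:
    """Flatten a 2-D image to a vector (row-major)."""
    return np.asarray(image, dtype=float).ravel(order="C")


def vector_to_image(vec: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Reshape a flat vector back to an image (row-major)."""
    return np.asarray(vec, dtype=float).reshape(shape, order="C")


def stage_seed(master_seed: int, label: str) -> int:
    """Derive a per-stage seed from one master seed and a stage label.

    The derivation is a fixed hash so that a single experiment seed fans out
    deterministically to every stochastic stage (noise draw, power iteration,
    random starts). Result is always in ``[0, 2**31)``.
    """
    return (int(master_seed) * 1000003 + zlib.crc32(label.encode())) % (2**31)


class LinearOperator:
    """A forward/adjoint pair with shape metadata and a cached Lipschitz bound.

    Parameters
    ----------
    forward, adjoint
        Callables mapping flat vectors to flat vectors: ``x -> A x`` and
        ``y -> A^T y``. They must be exact transposes of each other; this is
        checked probabilistically by the test-suite via random dot-product
        probes ``<Ax, y> == <x, A^T y>``.
    domain_shape, range_shape
        Shapes of the (possibly 2-D) domain and range; sizes ``n`` and ``m``.
    lipschitz
        Optional cached upper bound on the largest eigenvalue of ``A^T A``.
    """

    def __init__(
        self,
        forward: Callable[[np.ndarray], np.ndarray],
        adjoint: Callable[[np.ndarray], np.ndarray],
        domain_shape: tuple[int, ...],
        range_shape: tuple[int, ...],
        lipschitz: float | None = None,
    ):
        self._forward = forward
        self._adjoint = adjoint
        self.domain_shape = tuple(int(s) for s in domain_shape)
        self.range_shape = tuple(int(s) for s in range_shape)
        self.lipschitz = lipschitz

    @property
    def domain_size(self) -> int:
        return int(np.prod(self.domain_shape))

    @property
    def range_size(self) -> int:
        return int(np.prod(self.range_shape))

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel(order="C")
        if x.size != self.domain_size:
            raise ValueError(
                f"forward: expected vector of size {self.domain_size}, got {x.size}"
            )
        return self._forward(x)

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float).ravel(order="C")
        if y.size != self.range_size:
            raise ValueError(
                f"adjoint: expected vector of size {self.range_size}, got {y.size}"
            )
        return self._adjoint(y)

    def normal(self, x: np.ndarray) -> np.ndarray:
        """Apply ``A^T A``."""
        return self.adjoint(self.forward(x))

    def as_matrix(self) -> np.ndarray:
        """Assemble the dense matrix column-by-column from unit impulses.

        Only sensible for small operators; used by tests and the exact
        Lipschitz mode.
        """
        n = self.domain_size
        cols = np.empty((self.range_size, n))
        e = np.zeros(n)
        for j in range(n):
            e[j] = 1.0
            cols[:, j] = self.forward(e)
            e[j] = 0.0
        return cols


@dataclass(frozen=True)
class DegradationSpec:
    """Degradation model: k x k uniform blur plus zero-mean Gaussian noise.

    ``noise_variance`` is the absolute variance on the image intensity scale
    (the benchmark phantom lives in [0, 1]); ``boundary`` fixes how the blur
    treats pixels outside the image.
    """

    kernel_size: int = 5
    kernel_kind: Literal["uniform"] = "uniform"
    noise_variance: float = 1e-2
    seed: int = 0
    boundary: Literal["zero", "symmetric", "circular"] = "zero"

    def __post_init__(self):
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd and positive, got {self.kernel_size}")
        if self.kernel_kind != "uniform":
            raise ValueError(f"unknown kernel_kind {self.kernel_kind!r}")
        if self.noise_variance < 0:
            raise ValueError(f"noise_variance must be >= 0, got {self.noise_variance}")
        if self.boundary not in BOUNDARY_MODES:
            raise ValueError(f"boundary must be one of {BOUNDARY_MODES}, got {self.boundary!r}")


# Shepp-Logan ellipse table: (intensity, a, b, x0, y0, phi_degrees).
# a is the semi-axis along the ellipse's own x-axis after rotating by phi
# (counter-clockwise); centres live in the [-1, 1]^2 head coordinate frame.
_SHEPP_LOGAN_GEOMETRY = [
    # a       b       x0     y0      phi
    (0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.0230, 0.0460, 0.06, -0.6050, 0.0),
]
# High-contrast ("modified") intensities, already within [0, 1].
_MODIFIED_INTENSITIES = (1.0, -0.8, -0.2, -0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1)
# Classic low-contrast intensities; the rendered image is rescaled by its
# maximum (2.0 in the skull) so both variants share the [0, 1] convention.
_ORIGINAL_INTENSITIES = (2.0, -0.98, -0.02, -0.02, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01)


def shepp_logan_phantom(size: int, variant: str = "modified") -> np.ndarray:
    """Render the Shepp-Logan head phantom at ``size x size`` pixels.

    The phantom is the sum of ten ellipses on the square [-1, 1]^2 with pixel
    centres at ``linspace(-1, 1, size)`` on each axis (row index increasing
    downwards, i.e. decreasing y). ``variant="modified"`` uses the
    high-contrast intensity set; ``variant="original"`` uses the classic
    values rescaled so the maximum is 1. Output is clipped to [0, 1] and is
    deterministic for fixed arguments.
    """
    size = int(size)
    if size < 16:
        raise ValueError(f"size must be >= 16, got {size}")
    if variant == "modified":
        intensities = _MODIFIED_INTENSITIES
    elif variant == "original":
        intensities = _ORIGINAL_INTENSITIES
    else:
        raise ValueError(f"variant must be 'modified' or 'original', got {variant!r}")

    axis = np.linspace(-1.0, 1.0, size)
    xx, yy = np.meshgrid(axis, -axis)  # y decreases with row index
    img = np.zeros((size, size))
    for value, (a, b, x0, y0, phi) in zip(intensities, _SHEPP_LOGAN_GEOMETRY):
        theta = np.deg2rad(phi)
        c, s = np.cos(theta), np.sin(theta)
        xr = (xx - x0) * c + (yy - y0) * s
        yr = -(xx - x0) * s + (yy - y0) * c
        img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += value
    if variant == "original":
        img /= max(np.max(img), 1.0)
    return np.clip(img, 0.0, 1.0)


def matrix_operator(M: np.ndarray) -> LinearOperator:
    """Wrap a dense ``m x n`` matrix as a :class:`LinearOperator`."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got ndim={M.ndim}")
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix entries must be finite")
    return LinearOperator(
        forward=lambda x: M @ x,
        adjoint=lambda y: M.T @ y,
        domain_shape=(M.shape[1],),
        range_shape=(M.shape[0],),
    )


def _pad_index_map(shape: tuple[int, int], pad: int, boundary: str) -> np.ndarray:
    """Map each padded pixel to the flat source index it copies (-1 = zero)."""
    idx = np.arange(np.prod(shape), dtype=np.int64).reshape(shape)
    if boundary == "zero":
        return np.pad(idx, pad, mode="constant", constant_values=-1)
    return np.pad(idx, pad, mode=_PAD_MODE[boundary])


def uniform_blur_operator(image_shape: tuple[int, int], spec: DegradationSpec) -> LinearOperator:
    """Matrix-free same-size 2-D correlation with the k x k averaging kernel.

    The forward map pads the image according to ``spec.boundary``, then takes
    the *valid* cross-correlation with the kernel of constant entries
    ``1/k**2`` (for this symmetric kernel, correlation and convolution
    coincide). The adjoint is built from the exact transpose of the padding
    and correlation steps, so the operator pair passes dot-product tests to
    machine precision under every boundary mode.
    """
    H, W = (int(s) for s in image_shape)
    k = spec.kernel_size
    if k % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {k}")
    if k > min(H, W):
        raise ValueError(f"kernel size {k} exceeds image dimensions {image_shape}")
    kernel = np.full((k, k), 1.0 / k**2)
    pad = k // 2
    pad_map = _pad_index_map((H, W), pad, spec.boundary).ravel()
    inside = pad_map >= 0
    n = H * W

    def forward(x: np.ndarray) -> np.ndarray:
        padded = np.zeros((H + 2 * pad, W + 2 * pad))
        padded.ravel()[inside] = x[pad_map[inside]]
        out = signal.correlate(padded, kernel, mode="valid", method="direct")
        return out.ravel(order="C")

    def adjoint(y: np.ndarray) -> np.ndarray:
        # transpose of valid correlation = full convolution with the kernel,
        # then the transpose of padding folds border pixels onto their sources
        g = signal.convolve(y.reshape(H, W), kernel, mode="full", method="direct")
        out = np.zeros(n)
        np.add.at(out, pad_map[inside], g.ravel()[inside])
        return out

    if pad == 0:  # k = 1: identity
        return LinearOperator(lambda x: x.copy(), lambda y: y.copy(), (H, W), (H, W), lipschitz=1.0)
    op = LinearOperator(forward, adjoint, (H, W), (H, W))
    # For a matrix with nonnegative entries, lambda_max(A^T A) <= ||A||_1 * ||A||_inf
    # (Holder/Schur bound) = max row sum times max column sum, both obtained by
    # applying the operator pair to a ones vector. This certified bound avoids
    # power iteration, whose tiny spectral gap on blur operators makes it slow;
    # for zero/circular boundaries it equals 1 exactly.
    ones = np.ones(n)
    op.lipschitz = float(np.max(forward(ones)) * np.max(adjoint(ones)))
    return op


def degrade(image: np.ndarray, op: LinearOperator, spec: DegradationSpec) -> np.ndarray:
    """Simulate a measurement ``b = A x + eps`` as a flat vector.

    ``eps`` is i.i.d. zero-mean Gaussian with variance ``spec.noise_variance``,
    drawn from ``numpy``'s PCG64 generator seeded with ``spec.seed``, so the
    output is bit-reproducible for a fixed spec.
    """
    x = image_to_vector(image)
    if x.size != op.domain_size:
        raise ValueError(
            f"image size {x.size} does not match operator domain {op.domain_size}"
        )
    b = op.forward(x)
    if spec.noise_variance > 0:
        rng = np.random.default_rng(spec.seed)
        b = b + rng.normal(0.0, np.sqrt(spec.noise_variance), size=b.size)
    return b


def lipschitz_bound(
    op: LinearOperator,
    method: Literal["power", "exact"] = "power",
    tol: float = 1e-10,
    max_iter: int = 1000,
    seed: int = 0,
    safety: float = 1.01,
) -> float:
    """Upper bound ``L`` on the largest eigenvalue of ``A^T A``.

    ``method="exact"`` assembles the dense matrix and takes the top eigenvalue
    (small operators only). ``method="power"`` runs seeded power iteration on
    ``A^T A`` until the Rayleigh quotient stabilises to relative ``tol``, then
    inflates the estimate by ``safety`` (default 1.01) so that the returned
    value is a true upper bound despite finite iteration — required for the
    majorization step of the solvers to guarantee descent.
    """
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    if method == "exact":
        M = op.as_matrix()
        return float(np.linalg.eigvalsh(M.T @ M)[-1])
    if method != "power":
        raise ValueError(f"method must be 'power' or 'exact', got {method!r}")

    rng = np.random.default_rng(seed)
    v = rng.standard_normal(op.domain_size)
    v /= np.linalg.norm(v)
    estimate = 0.0
    for _ in range(max_iter):
        u = op.normal(v)
        new_estimate = float(v @ u)  # Rayleigh quotient (||v|| = 1)
        norm_u = np.linalg.norm(u)
        if norm_u == 0.0:  # A^T A v = 0: operator is (numerically) zero on v
            return 0.0
        v = u / norm_u
        if abs(new_estimate - estimate) <= tol * max(abs(new_estimate), 1e-300):
            return new_estimate * safety
        estimate = new_estimate
    raise ConvergenceError(
        f"power iteration did not converge in {max_iter} iterations",
        last_estimate=estimate * safety,
    )
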