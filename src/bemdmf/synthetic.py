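"""Synthetic texture generators with known multifractal structure.

The estimators in :mod:`bemdmf.multifractal` are validated against textures
whose singularity spectrum is known in closed form.  The workhorse is the
base-2 multiplicative cascade on the unit square: a mass of 1 is split into
four subcells with fixed fractions ``w_0..w_3``, recursively, ``depth``
times.  Its Legendre spectrum has the exact form

    alpha(q) = -sum_j nu_j(q) log2 w_j,
    f(q)     = -sum_j nu_j(q) log2 nu_j(q),   nu_j(q) = w_j^q / sum_k w_k^q,

which serves as the analytic oracle.  Also provided: a fractional-Brownian
control surface (narrow spectrum), a separable slow/fast oscillation demo
signal used to exercise the mode decomposition, and a labeled two-class
dataset standing in for a healthy/pathological region-of-interest study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "CascadeSpec",
    "FbmSpec",
    "TwoClassDatasetSpec",
    "SyntheticSample",
    "generate_binomial_cascade",
    "cascade_analytic_spectrum",
    "generate_slow_fast_signal",
    "generate_fbm_surface",
    "generate_two_class_dataset",
]


def _validate_weights(weights: Sequence[float]) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (4,):
        raise ValueError("cascade needs exactly 4 subcell weights")
    if np.any(w < 0):
        raise ValueError("cascade weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-12:
        raise ValueError("cascade weights must sum to 1 (got %r)" % (w.sum(),))
    return w


@dataclass(frozen=True)
class CascadeSpec:
    """Base-2, four-subcell multiplicative cascade on a 2^depth square grid.

    ``randomize_placement`` shuffles the weight-to-subcell assignment
    independently in every cell; the realized measure is then spatially
    heterogeneous while its multifractal spectrum is unchanged (the spectrum
    depends only on the weight multiset).
    """

    weights: tuple[float, float, float, float]
    depth: int
    randomize_placement: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        _validate_weights(self.weights)
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


@dataclass(frozen=True)
class FbmSpec:
    """Fractional-Brownian surface: monofractal control with Hurst index."""

    hurst: float
    side: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.hurst < 1.0):
            raise ValueError("hurst must lie strictly in (0, 1)")
        if self.side < 8:
            raise ValueError("side must be >= 8")


@dataclass(frozen=True)
class TwoClassDatasetSpec:
    """Two texture populations built from cascades with different weights.

    Each image is a cascade realization (rescaled to mean 1 so the additive
    terms are on a comparable scale), plus a smooth polynomial background
    bump, plus white Gaussian noise.  Per-image seeds are derived from the
    master seed with ``numpy.random.SeedSequence(seed).spawn`` so any single
    image can be regenerated in isolation.
    """

    n_per_class: int = 40
    class_a: CascadeSpec = field(
        default_factory=lambda: CascadeSpec((0.4, 0.3, 0.2, 0.1), depth=7)
    )
    class_b: CascadeSpec = field(
        default_factory=lambda: CascadeSpec((0.7, 0.1, 0.1, 0.1), depth=7)
    )
    background_amplitude: float = 0.5
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2 (cross-validation impossible)")
        if tuple(self.class_a.weights) == tuple(self.class_b.weights):
            raise ValueError(
                "class_a and class_b weights are identical; the classes would "
                "be indistinguishable by construction"
            )
        if self.background_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("background_amplitude and noise_sd must be >= 0")


class SyntheticSample(NamedTuple):
    image: np.ndarray
    label: int
    seed_key: tuple[int, int]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_binomial_cascade(spec: CascadeSpec) -> np.ndarray:
    """Realize the cascade measure as pixel masses (total mass 1).

    Each refinement replaces every cell of mass ``m`` by a 2x2 block with
    masses ``m * w_perm`` where ``w_perm`` is the (optionally per-cell
    shuffled) weight vector.  Subcell order without shuffling is row-major:
    ``w0 -> (0,0), w1 -> (0,1), w2 -> (1,0), w3 -> (1,1)``.
    """
    w = _validate_weights(spec.weights)
    rng = np.random.default_rng(spec.seed)
    arr = np.ones((1, 1), dtype=float)
    for _ in range(spec.depth):
        m = arr.shape[0]
        tile = np.broadcast_to(w, (m, m, 4))
        if spec.randomize_placement:
            tile = rng.permuted(tile, axis=2)
        quad = arr[:, :, None] * tile
        nxt = np.empty((2 * m, 2 * m), dtype=float)
        nxt[0::2, 0::2] = quad[..., 0]
        nxt[0::2, 1::2] = quad[..., 1]
        nxt[1::2, 0::2] = quad[..., 2]
        nxt[1::2, 1::2] = quad[..., 3]
        arr = nxt
    return arr


def cascade_analytic_spectrum(
    weights: Sequence[float], q_grid: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form Legendre spectrum (alpha(q), f(q)) of the cascade.

    Zero weights carry no mass: they contribute nothing for q > 0 and are
    excluded from the weighted sums for q <= 0 (where w^q would diverge).
    """
    w = _validate_weights(weights)
    w = w[w > 0]
    if w.size == 0:
        raise ValueError("all-zero weight vector")
    q = np.asarray(q_grid, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("q grid must be finite")
    # nu_j(q) via a log-space softmax for numerical safety at large |q|
    logw = np.log2(w)
    z = q[:, None] * logw[None, :]
    z -= z.max(axis=1, keepdims=True)
    nu = np.exp2(z)
    nu /= nu.sum(axis=1, keepdims=True)
    alpha = -(nu * logw[None, :]).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lognu = np.where(nu > 0, np.log2(np.where(nu > 0, nu, 1.0)), 0.0)
    f = -(nu * lognu).sum(axis=1)
    return alpha, f


def generate_slow_fast_signal(
    side: int,
    domain_halfwidth: float = float(np.pi),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Demo signal: Gaussian bump (slow) + cos/sin oscillation (fast) + noise.

    S(x, y) = exp(-(x^2 + y^2)) + cos(2y) + sin(3x) + N(0, noise_sd^2),
    evaluated on a uniform ``side x side`` grid over [-h, h]^2.

    Returns ``(image, slow, fast)`` where ``slow = exp(-(x^2+y^2))`` and
    ``fast = cos(2y) + sin(3x)`` are the noise-free components, kept for
    ground-truth comparisons against the extracted modes.
    """
    if side < 8:
        raise ValueError("side must be >= 8")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    h = float(domain_halfwidth)
    coords = np.linspace(-h, h, side)
    x = coords[None, :]  # column -> x
    y = coords[:, None]  # row -> y
    slow = np.exp(-(x**2 + y**2)) * np.ones((side, side))
    fast = np.cos(2 * y) + np.sin(3 * x)
    image = slow + fast
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    return image, slow, fast


def generate_fbm_surface(spec: FbmSpec) -> np.ndarray:
    """Fractional-Brownian surface by spectral synthesis.

    Fourier amplitudes are shaped so the power spectrum falls off as
    ``frequency^-(2H + 2)``; the result is standardized to zero mean, unit
    variance.  Serves only as a narrow-spectrum (monofractal) control, so
    the exactness of increments is not pursued.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.side
    fx = np.fft.fftfreq(n)[None, :]
    fy = np.fft.fftfreq(n)[:, None]
    freq = np.sqrt(fx**2 + fy**2)
    amp = np.zeros_like(freq)
    nz = freq > 0
    amp[nz] = freq[nz] ** (-(spec.hurst + 1.0))
    white = np.fft.fft2(rng.standard_normal((n, n)))
    surf = np.real(np.fft.ifft2(white * amp))
    surf -= surf.mean()
    sd = surf.std()
    if sd == 0:  # pragma: no cover - cannot happen for side >= 8
        raise RuntimeError("degenerate fBm realization")
    return surf / sd


def _background_bump(side: int) -> np.ndarray:
    """Separable low-order polynomial bump on [0,1]^2, peak value 1."""
    t = (np.arange(side) + 0.5) / side
    b = 4.0 * t * (1.0 - t)
    return np.outer(b, b)


def generate_two_class_dataset(spec: TwoClassDatasetSpec) -> list[SyntheticSample]:
    """Balanced labeled dataset of cascade-textured images.

    Label 0 uses ``class_a`` weights, label 1 ``class_b``.  The cascade
    realization is rescaled to mean 1 (an affine gain that leaves box
    probabilities untouched) before the background bump and noise are added.
    """
    samples: list[SyntheticSample] = []
    children = np.random.SeedSequence(spec.seed).spawn(2 * spec.n_per_class)
    idx = 0
    for label, template in ((0, spec.class_a), (1, spec.class_b)):
        side = 2**template.depth
        bump = spec.background_amplitude * _background_bump(side)
        for i in range(spec.n_per_class):
            child = children[idx]
            # cascade seed must be a plain int for CascadeSpec reproducibility
            sub_seed = int(child.generate_state(1, dtype=np.uint32)[0])
            cascade = generate_binomial_cascade(
                CascadeSpec(
                    weights=template.weights,
                    depth=template.depth,
                    randomize_placement=template.randomize_placement,
                    seed=sub_seed,
                )
            )
            img = cascade * cascade.size + bump
            if spec.noise_sd > 0:
                noise_rng = np.random.default_rng(child)
                img = img + noise_rng.normal(0.0, spec.noise_sd, size=img.shape)
            samples.append(SyntheticSample(img, label, (spec.seed, idx)))
            idx += 1
    return samples
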