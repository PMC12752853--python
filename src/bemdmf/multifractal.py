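"""Moment-method (box-counting) multifractal spectrum estimation.

The image is read as a mass distribution: the measure of a box is the sum
of (offset-corrected) gray levels inside it.  For a grid of box sizes ``s``
and a grid of moment orders ``q``:

    P_i(s)      box probability, box mass / total mass (empty boxes dropped)
    mu_i(q, s)  = P_i^q / sum_j P_j^q          (normalized q-measure)
    alpha(q)    = slope of  sum_i mu_i log P_i  vs  log s
    f(q)        = slope of  sum_i mu_i log mu_i vs  log s
    D(q)        = slope of  log sum_i P_i^q     vs  log s, divided by (q-1);
                  at q = 1 the information-dimension limit sum mu log mu is
                  used instead.

The singularity spectrum is the curve (alpha(q), f(q)); its width
``delta_alpha = alpha_max - alpha_min`` measures the degree of
multifractality and ``delta_f = f(alpha_max) - f(alpha_min)`` its
asymmetry.  ``q`` acts as a microscope: q > 0 emphasizes mass
concentrations (strong singularities), q < 0 the sparse regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "BoxCountingConfig",
    "BoxMeasure",
    "MultifractalSpectrum",
    "HolderMap",
    "DegenerateMeasureError",
    "box_probabilities",
    "normalized_measure",
    "alpha_of_q",
    "f_of_q",
    "generalized_dimensions",
    "legendre_spectrum",
    "select_box_range",
    "holder_exponent_map",
]


class DegenerateMeasureError(ValueError):
    """The image carries no usable mass (all-zero after offsetting)."""


def _default_q_grid() -> tuple[float, ...]:
    # open interval (-4, 4), step 0.1; endpoints excluded
    return tuple(np.round(np.arange(-39, 40) * 0.1, 10))


@dataclass(frozen=True)
class BoxCountingConfig:
    """Box sizes, moment grid and offset policy for the estimators.

    Defaults follow the study conditions: box sizes 2..64 in steps of 2 and
    q in the open interval (-4, 4) with step 0.1.  ``offset_mode`` controls
    how signed surfaces (BIMFs) are made nonnegative before mass counting:
    ``shift_min`` subtracts the global minimum (plus a tiny epsilon so no
    box mass collapses to exactly zero) only when the minimum is negative;
    ``rescale_unit`` maps the full range onto [eps, 1].
    """

    box_sizes: tuple[int, ...] = tuple(range(2, 65, 2))
    q_grid: tuple[float, ...] = field(default_factory=_default_q_grid)
    min_r2: float = 0.95
    offset_mode: str = "shift_min"

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.box_sizes)
        if len(sizes) == 0 or any(s < 2 for s in sizes):
            raise ValueError("box sizes must be integers >= 2")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("box sizes must be strictly increasing")
        if not np.all(np.isfinite(self.q_grid)):
            raise ValueError("q grid must be finite")
        if not (0 < self.min_r2 <= 1):
            raise ValueError("min_r2 must lie in (0, 1]")
        if self.offset_mode not in ("shift_min", "rescale_unit"):
            raise ValueError("unknown offset_mode %r" % (self.offset_mode,))


@dataclass
class BoxMeasure:
    size: int
    probabilities: np.ndarray  # nonempty boxes only, sums to 1
    n_boxes_total: int
    n_boxes_nonempty: int

    @property
    def log_probabilities(self) -> np.ndarray:
        return np.log(self.probabilities)


@dataclass
class MultifractalSpectrum:
    q_grid: np.ndarray
    alpha_q: np.ndarray
    f_q: np.ndarray
    d_q: np.ndarray
    r2_alpha: np.ndarray
    r2_f: np.ndarray
    alpha_min: float
    alpha_max: float
    f_at_alpha_min: float
    f_at_alpha_max: float
    delta_alpha: float
    delta_f: float
    box_sizes_used: tuple[int, ...]

    def feature(self, name: str) -> float:
        """Scalar summaries used as classifier features.

        ``alpha0``/``f0`` are the spectrum apex coordinates alpha(q=0),
        f(q=0) (q=0 weighs all occupied boxes equally, so the apex sits at
        the capacity dimension of the support).
        """
        if name in ("alpha0", "f0"):
            i = int(np.argmin(np.abs(self.q_grid)))
            return float(self.alpha_q[i] if name == "alpha0" else self.f_q[i])
        if name == "delta_alpha":
            return self.delta_alpha
        if name == "delta_f":
            return self.delta_f
        raise KeyError(name)


@dataclass
class HolderMap:
    alpha_xy: np.ndarray
    window_radii: tuple[int, ...]
    r2_xy: np.ndarray


# ---------------------------------------------------------------------------
# measures
# ---------------------------------------------------------------------------

def _offset_image(image: np.ndarray, offset_mode: str) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    lo = img.min()
    rng = img.max() - lo
    if offset_mode == "shift_min":
        if lo < 0:
            img = img - lo + 1e-9 * rng
    elif offset_mode == "rescale_unit":
        if rng > 0:
            img = (img - lo) / rng
            img = img * (1.0 - 1e-9) + 1e-9
        elif lo > 0:
            img = np.ones_like(img)
    else:
        raise ValueError("unknown offset_mode %r" % (offset_mode,))
    if img.sum() <= 0:
        raise DegenerateMeasureError("image has no mass after offsetting")
    return img


def _box_sums(img: np.ndarray, size: int) -> np.ndarray:
    h, w = img.shape
    nh, nw = h // size, w // size
    if nh == 0 or nw == 0:
        raise ValueError("box size %d exceeds image extent %r" % (size, img.shape))
    crop = img[: nh * size, : nw * size]
    return crop.reshape(nh, size, nw, size).sum(axis=(1, 3)).ravel()


def box_probabilities(
    image: np.ndarray, size: int, offset_mode: str = "shift_min"
) -> BoxMeasure:
    """Box masses of an ``size x size`` grid anchored at the top-left corner.

    Trailing partial boxes are discarded; boxes with zero mass are excluded
    from the probability vector.
    """
    img = _offset_image(image, offset_mode)
    sums = _box_sums(img, int(size))
    total = sums.sum()
    if total <= 0:
        raise DegenerateMeasureError("all retained boxes are empty")
    nonempty = sums[sums > 0]
    return BoxMeasure(
        size=int(size),
        probabilities=nonempty / total,
        n_boxes_total=sums.size,
        n_boxes_nonempty=nonempty.size,
    )


def normalized_measure(measure: BoxMeasure, q: float) -> np.ndarray:
    """mu_i(q) = P_i^q / sum P_j^q, computed in log space for large |q|."""
    logp = measure.log_probabilities
    z = q * logp
    z = z - z.max()
    mu = np.exp(z)
    return mu / mu.sum()


# ---------------------------------------------------------------------------
# regressions over box sizes
# ---------------------------------------------------------------------------

def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and R^2; a flat response is flagged with r2 = 0."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    yhat = ym + slope * (x - xm)
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - ym) ** 2).sum()
    if ss_tot == 0:
        return float(slope), 0.0
    return float(slope), float(1.0 - ss_res / ss_tot)


def _moment_numerators(
    image: np.ndarray, q_values: np.ndarray, config: BoxCountingConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per (q, size): A = sum mu log P, F = sum mu log mu, logZ = log sum P^q.

    Returns (log_sizes, A, F, logZ) with A, F, logZ of shape (n_q, n_sizes).
    """
    sizes = config.box_sizes
    nq, ns = len(q_values), len(sizes)
    A = np.empty((nq, ns))
    F = np.empty((nq, ns))
    logZ = np.empty((nq, ns))
    img = _offset_image(image, config.offset_mode)
    for j, s in enumerate(sizes):
        sums = _box_sums(img, s)
        sums = sums[sums > 0]
        logp = np.log(sums / sums.sum())
        z = q_values[:, None] * logp[None, :]  # (nq, nboxes)
        zmax = z.max(axis=1, keepdims=True)
        w = np.exp(z - zmax)
        wsum = w.sum(axis=1, keepdims=True)
        mu = w / wsum
        A[:, j] = (mu * logp[None, :]).sum(axis=1)
        logmu = (z - zmax) - np.log(wsum)
        F[:, j] = (mu * logmu).sum(axis=1)
        logZ[:, j] = (zmax + np.log(wsum))[:, 0]
    return np.log(np.asarray(sizes, float)), A, F, logZ


def _check_sizes(image: np.ndarray, config: BoxCountingConfig) -> None:
    if len(config.box_sizes) < 3:
        raise ValueError("need at least 3 box sizes for the scaling regression")
    if max(config.box_sizes) > min(np.asarray(image).shape):
        raise ValueError("largest box size exceeds the image extent")


def alpha_of_q(
    image: np.ndarray, q: float, config: BoxCountingConfig | None = None
) -> tuple[float, float]:
    """Hölder exponent alpha(q): slope of sum mu log P versus log s."""
    config = config or BoxCountingConfig()
    _check_sizes(image, config)
    logs, A, _, _ = _moment_numerators(image, np.array([float(q)]), config)
    return _linfit(logs, A[0])


def f_of_q(
    image: np.ndarray, q: float, config: BoxCountingConfig | None = None
) -> tuple[float, float]:
    """Spectrum value f(q): slope of sum mu log mu versus log s."""
    config = config or BoxCountingConfig()
    _check_sizes(image, config)
    logs, _, F, _ = _moment_numerators(image, np.array([float(q)]), config)
    return _linfit(logs, F[0])


def generalized_dimensions(
    image: np.ndarray, q: float, config: BoxCountingConfig | None = None
) -> float:
    """D(q) from the partition-sum scaling; q = 1 uses the limit form."""
    config = config or BoxCountingConfig()
    _check_sizes(image, config)
    if abs(q - 1.0) < 1e-9:
        return f_of_q(image, 1.0, config)[0]
    logs, _, _, logZ = _moment_numerators(image, np.array([float(q)]), config)
    slope, _ = _linfit(logs, logZ[0])
    return slope / (q - 1.0)


def legendre_spectrum(
    image: np.ndarray, config: BoxCountingConfig | None = None
) -> MultifractalSpectrum:
    """Evaluate alpha(q), f(q), D(q) over the whole q grid and summarize.

    ``delta_f`` follows the convention f(alpha_max) - f(alpha_min); since
    alpha(q) is non-increasing, alpha_max is reached at the most negative q.
    A monotonicity violation of alpha(q) beyond 1e-6 is logged, never
    silently accepted.
    """
    config = config or BoxCountingConfig()
    _check_sizes(image, config)
    q = np.asarray(config.q_grid, dtype=float)
    logs, A, F, logZ = _moment_numerators(image, q, config)
    nq = len(q)
    alpha = np.empty(nq)
    f = np.empty(nq)
    d = np.empty(nq)
    r2a = np.empty(nq)
    r2f = np.empty(nq)
    for i in range(nq):
        alpha[i], r2a[i] = _linfit(logs, A[i])
        f[i], r2f[i] = _linfit(logs, F[i])
        if abs(q[i] - 1.0) < 1e-9:
            d[i] = f[i]
        else:
            d[i] = _linfit(logs, logZ[i])[0] / (q[i] - 1.0)
    diffs = np.diff(alpha)
    if np.any(diffs > 1e-6):
        logger.warning(
            "alpha(q) not non-increasing: max violation %.3g", float(diffs.max())
        )
    i_min = int(np.argmin(alpha))
    i_max = int(np.argmax(alpha))
    return MultifractalSpectrum(
        q_grid=q,
        alpha_q=alpha,
        f_q=f,
        d_q=d,
        r2_alpha=r2a,
        r2_f=r2f,
        alpha_min=float(alpha[i_min]),
        alpha_max=float(alpha[i_max]),
        f_at_alpha_min=float(f[i_min]),
        f_at_alpha_max=float(f[i_max]),
        delta_alpha=float(alpha[i_max] - alpha[i_min]),
        delta_f=float(f[i_max] - f[i_min]),
        box_sizes_used=tuple(config.box_sizes),
    )


def select_box_range(
    image: np.ndarray,
    candidate_ranges: Sequence[tuple[int, int]],
    config: BoxCountingConfig | None = None,
) -> tuple[tuple[int, int], float]:
    """Pick the (s_min, s_max) window whose q=0 scaling regression is best.

    Candidates are scored by the R^2 of the alpha(q=0) regression restricted
    to the box sizes inside the window; ties go to the widest window, then
    to the smallest s_min.
    """
    config = config or BoxCountingConfig()
    if len(candidate_ranges) == 0:
        raise ValueError("need at least one candidate range")
    best: tuple[float, int, int, tuple[int, int]] | None = None
    for s_min, s_max in candidate_ranges:
        sizes = tuple(s for s in config.box_sizes if s_min <= s <= s_max)
        if len(sizes) < 3:
            raise ValueError(
                "candidate range (%d, %d) keeps fewer than 3 box sizes" % (s_min, s_max)
            )
        sub = BoxCountingConfig(
            box_sizes=sizes,
            q_grid=(0.0,),
            min_r2=config.min_r2,
            offset_mode=config.offset_mode,
        )
        _, r2 = alpha_of_q(image, 0.0, sub)
        key = (r2, s_max - s_min, -s_min, (s_min, s_max))
        if best is None or key[:3] > best[:3]:
            best = key
    assert best is not None
    return best[3], best[0]


# ---------------------------------------------------------------------------
# pointwise diagnostic
# ---------------------------------------------------------------------------

def holder_exponent_map(
    image: np.ndarray, window_radii: Sequence[int], offset_mode: str = "shift_min"
) -> HolderMap:
    """Pointwise Hölder exponent: per-pixel slope of log window-mass vs log size.

    The mass of the ``(2w+1) x (2w+1)`` window centered on each pixel
    (mirror-padded at the border) is regressed against the window side over
    the given radii.  Pixels whose window mass vanishes at some radius are
    flagged non-finite.
    """
    radii = tuple(int(w) for w in window_radii)
    if len(radii) < 2 or any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("need >= 2 strictly increasing window radii")
    img = _offset_image(image, offset_mode)
    logs = np.log([2 * w + 1 for w in radii])
    masses = np.empty((len(radii),) + img.shape)
    for i, w in enumerate(radii):
        side = 2 * w + 1
        masses[i] = ndimage.uniform_filter(img, size=side, mode="reflect") * side**2
    with np.errstate(divide="ignore"):
        y = np.log(masses)
    # closed-form per-pixel OLS across the radius axis
    xm = logs.mean()
    xc = logs - xm
    sxx = (xc**2).sum()
    ym = y.mean(axis=0)
    slope = np.tensordot(xc, y - ym, axes=(0, 0)) / sxx
    yhat = ym[None] + xc[:, None, None] * slope[None]
    ss_res = ((y - yhat) ** 2).sum(axis=0)
    ss_tot = ((y - ym[None]) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    bad = ~np.isfinite(y).all(axis=0)
    if np.any(bad):
        logger.warning("%d pixels have zero-mass windows", int(bad.sum()))
        slope = slope.copy()
        slope[bad] = np.nan
        r2[bad] = np.nan
    return HolderMap(alpha_xy=slope, window_radii=radii, r2_xy=r2)
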