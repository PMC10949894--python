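"""Neighborhood contrast stretching of the intensity channel.

The transform rescales each pixel by the ratio of the global mean to the
local standard deviation, so flat low-contrast regions are stretched hard
while already-busy regions are left mostly alone:

    f(m, n) = (delta * mu / (sigma_p(m, n) + beta)) * (I(m, n) - gamma * mu_p(m, n))
              + mu_p(m, n) ** alpha

with mu the global mean intensity, mu_p / sigma_p the mean and standard
deviation over the p x p window centred at (m, n), and output clipped to
[0, 1].  beta > 0 keeps the stretch finite on constant windows; the final
mu_p ** alpha term restores local brightness.  alpha, beta, gamma, delta are
the decision variables tuned by differential evolution (see
:mod:`hemopipe.de`) to maximize an edge-and-entropy objective

    F(I*) = log(log(G(I*) + e)) * n_e(I*) * H(I*) / (M * N)

where G is the summed Sobel gradient magnitude, n_e the number of edge
pixels (magnitude above a threshold), and H the Shannon entropy of the
intensity histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PARAM_BOUNDS",
    "EnhancementParams",
    "LocalStats",
    "ObjectiveBreakdown",
    "EnhancementConfig",
    "local_window_stats",
    "apply_enhancement",
    "image_entropy",
    "sobel_measures",
    "enhancement_objective",
]

#: Box constraints for the decision vector (alpha, beta, gamma, delta).
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.0, 1.6),
    "beta": (0.0, 0.5),
    "gamma": (0.0, 0.8),
    "delta": (0.5, 1.5),
}

_SIGMA_EPS = 1e-9  # guards sigma_p + beta when beta = 0 on a constant window


def _check_intensity(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError(f"expected a non-empty 2-D intensity image, got shape {img.shape}")
    if img.min() < 0 or img.max() > 1:
        raise ValueError("intensity values must lie in [0, 1]")
    return img


@dataclass(frozen=True)
class EnhancementParams:
    """Decision vector (alpha, beta, gamma, delta) of the transform.

    The optimizer keeps its population inside :data:`PARAM_BOUNDS`; the
    record itself accepts any values so identity-like configurations
    (e.g. gamma = 1, which cancels the stretch term on constant regions)
    can be evaluated directly.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float

    def within_bounds(self, bounds: dict[str, tuple[float, float]] | None = None) -> bool:
        bounds = bounds or PARAM_BOUNDS
        return all(
            bounds[name][0] <= getattr(self, name) <= bounds[name][1]
            for name in ("alpha", "beta", "gamma", "delta")
        )

    @classmethod
    def from_vector(cls, vec) -> "EnhancementParams":
        a, b, g, d = (float(x) for x in vec)
        return cls(a, b, g, d)

    def to_vector(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma, self.delta])


@dataclass(frozen=True)
class LocalStats:
    """Per-pixel window statistics feeding the transform."""

    mu_local: np.ndarray
    sigma_local: np.ndarray
    window: int
    mu_global: float


@dataclass(frozen=True)
class ObjectiveBreakdown:
    """Components of the enhancement objective F."""

    gradient_sum: float
    edge_count: int
    entropy: float
    objective: float
    degenerate: bool = False


@dataclass(frozen=True)
class EnhancementConfig:
    """Tunables of the enhancement stage.

    window: odd neighbourhood side p (3 keeps the stretch maximally local).
    edge_threshold: Sobel magnitude above which a pixel counts as edge,
        on the [0, 1] intensity scale.
    entropy_bins: histogram bins over [0, 1] for H.
    pop_size / iterations: differential-evolution budget N_p and T.
    crossover_rate: binomial crossover probability CR.
    """

    window: int = 3
    edge_threshold: float = 0.1
    entropy_bins: int = 256
    pop_size: int = 30
    iterations: int = 50
    crossover_rate: float = 0.5
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(PARAM_BOUNDS))

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([self.bounds[k][0] for k in ("alpha", "beta", "gamma", "delta")])
        ub = np.array([self.bounds[k][1] for k in ("alpha", "beta", "gamma", "delta")])
        return lb, ub


def local_window_stats(img: np.ndarray, p: int = 3) -> LocalStats:
    """Mean and standard deviation over the p x p window at every pixel.

    Borders are handled by replicate padding.  ``p`` must be odd so the
    window is centred; ``p = 1`` degenerates to the pixel itself.
    """
    img = _check_intensity(img)
    if p < 1 or p % 2 == 0:
        raise ValueError(f"window size must be a positive odd integer, got {p}")
    mu = ndimage.uniform_filter(img, size=p, mode="nearest")
    musq = ndimage.uniform_filter(img * img, size=p, mode="nearest")
    var = np.maximum(musq - mu * mu, 0.0)
    return LocalStats(mu_local=mu, sigma_local=np.sqrt(var), window=p, mu_global=float(img.mean()))


def apply_enhancement(
    img: np.ndarray, stats: LocalStats, params: EnhancementParams
) -> np.ndarray:
    """Apply the neighborhood stretch to an intensity image, clipping to [0, 1]."""
    img = _check_intensity(img)
    if stats.mu_local.shape != img.shape:
        raise ValueError("window statistics were computed for a different image shape")
    gain = params.delta * stats.mu_global / (stats.sigma_local + params.beta + _SIGMA_EPS)
    out = gain * (img - params.gamma * stats.mu_local) + stats.mu_local ** params.alpha
    return np.clip(out, 0.0, 1.0)


def image_entropy(img: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy (bits) of the intensity histogram over [0, 1]."""
    img = _check_intensity(img)
    if bins < 2:
        raise ValueError("need at least 2 histogram bins")
    counts, _ = np.histogram(img, bins=bins, range=(0.0, 1.0))
    p = counts[counts > 0] / img.size
    return float(-(p * np.log2(p)).sum())


_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_SOBEL_Y = _SOBEL_X.T


def sobel_measures(img: np.ndarray, edge_threshold: float = 0.1) -> tuple[float, int]:
    """Summed Sobel gradient magnitude G and edge-pixel count n_e.

    Magnitude is sqrt(gx^2 + gy^2) from the unnormalized 3x3 Sobel kernels
    with replicate borders; a pixel is an edge when magnitude > threshold.
    """
    img = _check_intensity(img)
    if edge_threshold < 0:
        raise ValueError("edge threshold must be non-negative")
    gx = ndimage.convolve(img, _SOBEL_X, mode="nearest")
    gy = ndimage.convolve(img, _SOBEL_Y, mode="nearest")
    mag = np.hypot(gx, gy)
    return float(mag.sum()), int(np.count_nonzero(mag > edge_threshold))


def enhancement_objective(
    enhanced: np.ndarray, cfg: EnhancementConfig | None = None
) -> ObjectiveBreakdown:
    """Evaluate F = log(log(G + e)) * n_e * H / (M * N) on an enhanced image.

    Euler's number is added inside the inner log so its argument exceeds 1
    for any G >= 0.  Degenerate images (no edge pixels or zero entropy)
    cannot be meaningfully ranked and get a -inf sentinel.
    """
    cfg = cfg or EnhancementConfig()
    enhanced = _check_intensity(enhanced)
    g, n_e = sobel_measures(enhanced, cfg.edge_threshold)
    h = image_entropy(enhanced, cfg.entropy_bins)
    if n_e == 0 or h == 0.0:
        return ObjectiveBreakdown(g, n_e, h, float("-inf"), degenerate=True)
    f = np.log(np.log(g + np.e)) * n_e * h / enhanced.size
    return ObjectiveBreakdown(g, n_e, h, float(f))
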