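"""Pre-attentive feature maps and their conversion to attracting masses.

Eight contrastive features are extracted from a frame: the spatial gradient
of the brightness, of each of the three color channels, and of four oriented
edge-energy maps (0, 45, 90, 135 degrees).  Each feature ``f_i`` is a
per-pixel gradient 2-vector; its attracting mass is ``mu_i = alpha_i *
||f_i||`` (pointwise Euclidean norm) and the total mass is ``mu = sum_i
mu_i``.  With the default ``alpha_i = 1`` all features are weighted equally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .errors import GravscanWarning
from .io import RetinaFrame

FEATURE_NAMES = ("intensity", "color1", "color2", "color3",
                 "orient0", "orient45", "orient90", "orient135")
N_FEATURES = len(FEATURE_NAMES)


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the feature bank.

    wavelength_px / sigma_px set the even-symmetric Gabor bank producing the
    orientation maps; ``opponent_colors`` toggles an rg/by opponent transform
    of the color channels before differentiation (off by default: raw RGB).
    """

    wavelength_px: float = 8.0
    sigma_px: float = 4.0
    opponent_colors: bool = False


@dataclass(frozen=True)
class FeatureStack:
    """The 8 gradient features of a frame; ``maps`` has shape (8, H, W, 2)."""

    maps: np.ndarray
    names: tuple = FEATURE_NAMES

    def __post_init__(self) -> None:
        m = np.asarray(self.maps, dtype=float)
        if m.ndim != 4 or m.shape[0] != len(self.names) or m.shape[3] != 2:
            raise ValueError(f"expected (N, H, W, 2) gradient stack, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("feature maps contain non-finite values")
        object.__setattr__(self, "maps", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps.shape[1:3]

    def magnitudes(self) -> np.ndarray:
        """Pointwise Euclidean norms of the gradient features, shape (N, H, W)."""
        return np.linalg.norm(self.maps, axis=3)


@dataclass(frozen=True)
class MassDistribution:
    """Non-negative per-feature masses and their total.

    ``mu_i`` has shape (N, H, W) with ``mu_i >= 0``; ``mu`` is the pointwise
    sum over features.
    """

    mu_i: np.ndarray
    alphas: np.ndarray
    mu: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        mi = np.atleast_3d(np.asarray(self.mu_i, dtype=float))
        if mi.ndim != 3:
            raise ValueError(f"expected (N, H, W) mass stack, got {mi.shape}")
        if not np.all(np.isfinite(mi)) or mi.min() < 0:
            raise ValueError("masses must be finite and non-negative")
        al = np.asarray(self.alphas, dtype=float).ravel()
        if al.size != mi.shape[0] or np.any(al <= 0):
            raise ValueError("need one positive alpha per feature map")
        object.__setattr__(self, "mu_i", mi)
        object.__setattr__(self, "alphas", al)
        object.__setattr__(self, "mu", mi.sum(axis=0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mu.shape

    def total(self) -> float:
        return float(self.mu.sum())


def _spatial_gradient(grid: np.ndarray) -> np.ndarray:
    """Central-difference gradient with replicate borders, shape (H, W, 2).

    Component order is (d/dx, d/dy).
    """
    g = np.asarray(grid, dtype=float)
    pad = np.pad(g, 1, mode="edge")
    ddx = (pad[1:-1, 2:] - pad[1:-1, :-2]) / 2.0
    ddy = (pad[2:, 1:-1] - pad[:-2, 1:-1]) / 2.0
    return np.stack([ddx, ddy], axis=-1)


def intensity_map(frame: RetinaFrame) -> np.ndarray:
    """Brightness: per-pixel mean of the three channels, in [0, 1]."""
    return frame.pixels.mean(axis=2)


def color_channels(frame: RetinaFrame, config: FeatureConfig | None = None) -> np.ndarray:
    """The three color channels, shape (3, H, W).

    Raw RGB by default; with ``opponent_colors`` the red-green, blue-yellow
    opponent pair plus luminance is returned instead.
    """
    config = config or FeatureConfig()
    px = frame.pixels
    if not config.opponent_colors:
        return np.moveaxis(px, 2, 0)
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    lum = (r + g + b) / 3.0
    return np.stack([r - g, b - (r + g) / 2.0, lum])


def gabor_support_px(config: FeatureConfig) -> int:
    """Spatial support (side length) of the Gabor kernels, in pixels."""
    return 2 * int(np.ceil(3.0 * config.sigma_px)) + 1


def gabor_kernel_even(theta: float, config: FeatureConfig) -> np.ndarray:
    """Zero-DC even (cosine-phase) Gabor kernel at orientation ``theta``.

    The DC component is removed by subtracting an envelope-weighted constant,
    so a uniform image produces exactly zero response while the kernel stays
    spatially localized.
    """
    half = (gabor_support_px(config) - 1) // 2
    ys, xs = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    xr = xs * np.cos(theta) + ys * np.sin(theta)
    envelope = np.exp(-(xs ** 2 + ys ** 2) / (2.0 * config.sigma_px ** 2))
    kernel = envelope * np.cos(2.0 * np.pi * xr / config.wavelength_px)
    kernel -= (kernel.sum() / envelope.sum()) * envelope
    # unit-L1 envelope normalization keeps orientation responses on the same
    # scale as the raw gradient features
    return kernel / (2.0 * np.pi * config.sigma_px ** 2)


def orientation_maps(intensity: np.ndarray, config: FeatureConfig | None = None) -> np.ndarray:
    """Oriented edge energy at 0/45/90/135 degrees, shape (4, H, W).

    Rectified (absolute) responses of an even-symmetric Gabor bank with
    edge-replicated borders; the 0-degree map responds to brightness
    variation along x, i.e. to vertical edges.  Non-negative by construction.
    """
    config = config or FeatureConfig()
    grid = np.asarray(intensity, dtype=float)
    support = gabor_support_px(config)
    if min(grid.shape) < support:
        raise ValueError(
            f"grid {grid.shape} smaller than the Gabor support ({support} px); "
            "reduce sigma_px or use a larger frame")
    half = (support - 1) // 2
    padded = np.pad(grid, half, mode="edge")
    out = []
    for theta in (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4):
        kernel = gabor_kernel_even(theta, config)
        out.append(np.abs(fftconvolve(padded, kernel, mode="valid")))
    return np.stack(out)


def extract_features(frame: RetinaFrame, config: FeatureConfig | None = None) -> FeatureStack:
    """The 8 gradient features of a frame (intensity, colors, orientations)."""
    config = config or FeatureConfig()
    inten = intensity_map(frame)
    grids = [inten, *color_channels(frame, config), *orientation_maps(inten, config)]
    return FeatureStack(np.stack([_spatial_gradient(g) for g in grids]))


def compute_masses(stack: FeatureStack, alphas=None) -> MassDistribution:
    """Masses ``mu_i = alpha_i * ||f_i||`` from a feature stack.

    ``alphas`` defaults to all ones (equal feature weighting).
    """
    n = stack.maps.shape[0]
    alphas = np.ones(n) if alphas is None else np.asarray(alphas, dtype=float).ravel()
    if alphas.size != n:
        raise ValueError(f"expected {n} alphas, got {alphas.size}")
    if np.any(alphas <= 0):
        raise ValueError("alphas must be positive")
    return MassDistribution(alphas[:, None, None] * stack.magnitudes(), alphas)


def saliency_as_mass(saliency: np.ndarray) -> MassDistribution:
    """Use an externally computed saliency map as a single-component mass.

    The map is shifted to minimum 0 (additive-constant invariant); a constant
    map yields zero total mass and a warning.
    """
    s = np.asarray(saliency, dtype=float)
    if s.ndim != 2 or not np.all(np.isfinite(s)):
        raise ValueError("saliency must be a finite H x W grid")
    s = s - s.min()
    if s.max() == 0.0:
        warnings.warn("constant saliency map: total mass is zero",
                      GravscanWarning, stacklevel=2)
    return MassDistribution(s[None], np.ones(1))


def masses_from_frame(frame: RetinaFrame, alphas=None,
                      config: FeatureConfig | None = None) -> MassDistribution:
    """Convenience: frame -> features -> masses in one call."""
    return compute_masses(extract_features(frame, config), alphas)
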