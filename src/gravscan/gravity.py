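"""Gravitational field of a mass distribution and the inhibition-of-return field.

Feature masses attract a unitary focus-of-attention mass through the
two-dimensional Coulomb kernel

    e(z) = z / (2 pi ||z||^2),

so the field of a mass grid ``mu`` at a focus ``a`` is the discrete sum over
pixel centers ``x`` of ``e(x - a) mu(x)``, pointing toward mass
concentrations.  The singularity at ``x = a`` is regularized by a small
``epsilon`` added to the squared norm: the continuum principal value is
finite, but the discrete sum needs guarding when the focus coincides with a
pixel center.

Inhibition of return is a leaky memory of visited locations,

    dI/dt + beta I = beta g(x - a(t)),     g(u) = exp(-||u||^2 / (2 sigma^2)),

relaxing toward a unit-peak Gaussian bump at the current focus.  Because g
has peak value 1, I stays in [0, 1] and the inhibited mass ``mu (1 - I)``
can never go negative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .features import MassDistribution

#: Default squared-distance regularizer at the focus singularity (px^2).
DEFAULT_EPSILON = 0.25


@dataclass(frozen=True)
class GravityKernel:
    """Inverse-square attraction kernel with singularity regularizer."""

    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class InhibitionField:
    """IOR memory I(x, t) in [0, 1] with decay rate beta and bump width sigma."""

    I: np.ndarray
    beta: float = 0.1
    sigma_px: float = 25.6

    def __post_init__(self) -> None:
        grid = np.asarray(self.I, dtype=float)
        if grid.ndim != 2 or not np.all(np.isfinite(grid)):
            raise ValueError("I must be a finite H x W grid")
        if grid.min() < 0.0 or grid.max() > 1.0:
            raise ValueError("I must lie in [0, 1]")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if not self.sigma_px > 0:
            raise ValueError("sigma_px must be positive")
        object.__setattr__(self, "I", grid)

    @classmethod
    def zeros(cls, shape: tuple[int, int], beta: float = 0.1,
              sigma_px: float = 25.6) -> "InhibitionField":
        return cls(np.zeros(shape), beta=beta, sigma_px=sigma_px)


def kernel_eval(z, kernel: GravityKernel = GravityKernel()) -> np.ndarray:
    """The regularized kernel e(z) = z / (2 pi (||z||^2 + eps)); e(0) = 0."""
    z = np.asarray(z, dtype=float)
    r2 = np.sum(z * z, axis=-1, keepdims=True)
    return z / (2.0 * np.pi * (r2 + kernel.epsilon))


def _pixel_coords(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    return xs.ravel().astype(float), ys.ravel().astype(float)


def _as_mass_grid(mass) -> np.ndarray:
    if isinstance(mass, MassDistribution):
        return mass.mu
    return np.asarray(mass, dtype=float)


def field_at(mass, focus, kernel: GravityKernel = GravityKernel()) -> np.ndarray:
    """Gravitational field E at ``focus``: sum over pixels of e(x - a) mu(x).

    Direct summation over the whole grid (the defining formula); O(H W) per
    evaluation, vectorized.  ``mass`` may be a :class:`MassDistribution` or a
    bare H x W grid.  The focus must lie inside the frame rectangle.
    """
    mu = _as_mass_grid(mass)
    a = np.asarray(focus, dtype=float)
    h, w = mu.shape
    if not (0.0 <= a[0] <= w - 1 and 0.0 <= a[1] <= h - 1):
        raise ValueError(f"focus {tuple(a)} outside the {h}x{w} frame rectangle")
    xs, ys = _pixel_coords(mu.shape)
    dx = xs - a[0]
    dy = ys - a[1]
    wgt = mu.ravel() / (2.0 * np.pi * (dx * dx + dy * dy + kernel.epsilon))
    return np.array([np.dot(wgt, dx), np.dot(wgt, dy)])


def potential_at(mass, focus, kernel: GravityKernel = GravityKernel()) -> float:
    """Gravitational potential U with -grad U = E (2-D logarithmic potential).

    U(a) = (4 pi)^-1 sum_x mu(x) ln(||a - x||^2 + eps); negative near mass
    concentrations, so the field rolls the focus downhill into them.
    """
    mu = _as_mass_grid(mass)
    a = np.asarray(focus, dtype=float)
    xs, ys = _pixel_coords(mu.shape)
    dx = xs - a[0]
    dy = ys - a[1]
    r2 = dx * dx + dy * dy + kernel.epsilon
    return float(np.dot(mu.ravel(), np.log(r2)) / (4.0 * np.pi))


def ior_bump(shape: tuple[int, int], focus, sigma_px: float) -> np.ndarray:
    """Unit-peak Gaussian g(x - a) on the grid."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    r2 = (xs - focus[0]) ** 2 + (ys - focus[1]) ** 2
    return np.exp(-r2 / (2.0 * sigma_px ** 2))


def ior_step(field: InhibitionField, focus, dt: float) -> InhibitionField:
    """Advance the IOR field by ``dt`` with the focus frozen at ``focus``.

    Uses the exact solution of the linear relaxation over the step,
    I <- g + (I - g) exp(-beta dt), which is unconditionally stable and
    preserves [0, 1].
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    g = ior_bump(field.I.shape, focus, field.sigma_px)
    decay = np.exp(-field.beta * dt)
    new = g + (field.I - g) * decay
    return replace(field, I=np.clip(new, 0.0, 1.0))


def effective_mass(mass: MassDistribution, field: InhibitionField) -> MassDistribution:
    """Inhibition-discounted masses, mu_i (1 - I) per feature, pointwise."""
    if mass.shape != field.I.shape:
        raise ValueError(f"mass grid {mass.shape} and inhibition grid "
                         f"{field.I.shape} have different shapes")
    return MassDistribution(mass.mu_i * (1.0 - field.I)[None], mass.alphas)
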