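"""Damped Newtonian dynamics of the focus of attention.

The focus is a unitary mass obeying

    a'' + lambda a' - E(a, t) = 0,

with E the gravitational field of the (inhibition-discounted) feature
masses.  The damping term ``lambda a'`` suppresses the orbits typical of
gravitational systems and yields ballistic movements that settle on targets.

Integration is a fixed-step classical Runge-Kutta (RK4) scheme with operator
splitting: within a step the inhibition field is frozen while (a, v) are
advanced, then the inhibition relaxes toward the new focus with its exact
exponential update.  Fixed stepping makes trajectories bit-reproducible
across platforms.

Time bookkeeping: the equation of motion is integrated in dimensionless
model-time units; ``time_scale`` model units correspond to one second of
viewing.  Recorded trajectories are expressed in seconds and px/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import NumericalError
from .features import MassDistribution, masses_from_frame
from .gravity import (DEFAULT_EPSILON, GravityKernel, InhibitionField,
                      field_at, ior_bump, potential_at)
from .io import DEFAULT_PIXELS_PER_DEGREE, RetinaFrame


@dataclass(frozen=True)
class FocusState:
    """Instantaneous focus position (px) and velocity (px per model-time unit)."""

    a: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float).reshape(2)
        v = np.asarray(self.v, dtype=float).reshape(2)
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(v))):
            raise ValueError("focus state must be finite")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "v", v)


@dataclass(frozen=True)
class SimulationParams:
    """All knobs of a simulation run.

    lam               damping coefficient (> 0 suppresses orbits)
    beta              IOR relaxation rate, in (0, 1)
    sigma_ior_deg     IOR bump width, degrees of visual angle
    alphas            per-feature mass weights (None = equal weighting)
    duration          viewing time in seconds
    dt                integrator step in model-time units
    time_scale        model-time units per second of viewing
    mass_density      target mean mass per pixel after normalization; fixes
                      the field strength (hence the saccade time scale)
                      independently of image contrast and resolution
    normalize_mass    set False to integrate over the raw masses
    pixels_per_degree viewing-geometry scale for angular conversions
    epsilon           kernel singularity regularizer (px^2)
    a0, v0            initial state (None = frame center / rest)
    randomize_a0      draw a0 uniformly inside the frame (uses ``seed``)
    ior_enabled       set False to disable inhibition of return entirely
    """

    lam: float = 1.0
    beta: float = 0.1
    sigma_ior_deg: float = 2.0
    alphas: Optional[tuple] = None
    duration: float = 3.0
    dt: float = 0.01
    time_scale: float = 40.0
    mass_density: float = 3.5
    normalize_mass: bool = True
    pixels_per_degree: float = DEFAULT_PIXELS_PER_DEGREE
    epsilon: float = DEFAULT_EPSILON
    a0: Optional[tuple] = None
    v0: tuple = (0.0, 0.0)
    randomize_a0: bool = False
    ior_enabled: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if self.dt <= 0 or self.duration <= 0 or self.time_scale <= 0:
            raise ValueError("dt, duration and time_scale must be positive")
        if not 1.0 <= self.duration <= 30.0:
            raise ValueError("duration must lie in [1, 30] seconds")

    @property
    def sigma_ior_px(self) -> float:
        return self.sigma_ior_deg * self.pixels_per_degree

    def n_steps(self) -> int:
        n = int(round(self.duration * self.time_scale / self.dt))
        if n < 10:
            raise ValueError("duration/dt must yield at least 10 steps")
        return n


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled attention trajectory.

    ``t`` is in seconds, ``a`` in pixels, ``v`` in px/s; samples include the
    initial state, so there are ``n_steps + 1`` rows.
    """

    t: np.ndarray
    a: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        a = np.asarray(self.a, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if not (t.ndim == 1 and a.shape == (t.size, 2) and v.shape == (t.size, 2)):
            raise ValueError("inconsistent trajectory arrays")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "v", v)

    def __len__(self) -> int:
        return self.t.size

    @property
    def dt_s(self) -> float:
        return float(self.t[1] - self.t[0])

    def speeds(self) -> np.ndarray:
        """Speed profile |da/dt| in px/s by central differences on positions."""
        d = np.gradient(self.a, self.t, axis=0)
        return np.linalg.norm(d, axis=1)

    def to_frame(self):
        """Trajectory as a pandas DataFrame with columns t,x,y,vx,vy."""
        import pandas as pd
        return pd.DataFrame({"t": self.t, "x": self.a[:, 0], "y": self.a[:, 1],
                             "vx": self.v[:, 0], "vy": self.v[:, 1]})


def normalize_total_mass(mu: np.ndarray, mass_density: float) -> np.ndarray:
    """Scale a mass grid to a fixed mean mass per pixel.

    Keeps the gravitational time scale independent of image contrast and
    grid resolution; a zero grid is returned unchanged.
    """
    total = mu.sum()
    if total <= 0:
        return mu
    return mu * (mass_density * mu.size / total)


def rhs(state: FocusState, mass_eff, lam: float,
        kernel: GravityKernel = GravityKernel()) -> tuple[np.ndarray, np.ndarray]:
    """First-order form of the equation of motion: da = v, dv = -lam v + E(a)."""
    dv = -lam * state.v + field_at(mass_eff, state.a, kernel)
    return state.v, dv


def mechanical_energy(state: FocusState, mass,
                      kernel: GravityKernel = GravityKernel()) -> float:
    """Kinetic plus gravitational potential energy of the focus.

    Velocity is in px per model-time unit.  With a static mass and no
    inhibition this is a Lyapunov function: dE/dt = -lam ||v||^2.
    """
    return 0.5 * float(np.dot(state.v, state.v)) + potential_at(mass, state.a, kernel)


def _clamp_state(a: np.ndarray, v: np.ndarray, shape: tuple[int, int]) -> None:
    """Clamp the focus into the frame, zeroing the outward velocity component."""
    h, w = shape
    for i, hi in ((0, w - 1.0), (1, h - 1.0)):
        if a[i] < 0.0:
            a[i] = 0.0
            if v[i] < 0.0:
                v[i] = 0.0
        elif a[i] > hi:
            a[i] = hi
            if v[i] > 0.0:
                v[i] = 0.0


def simulate(frame_or_mass, params: SimulationParams = SimulationParams()
             ) -> tuple[Trajectory, InhibitionField]:
    """Integrate the attention dynamics over a static stimulus.

    ``frame_or_mass`` is a :class:`RetinaFrame` (features and masses are
    extracted with the parameters' alphas) or a ready
    :class:`MassDistribution`.  Per step: the inhibition-discounted mass is
    formed, (a, v) advance by one RK4 step, then the inhibition field relaxes
    toward the new focus.  Deterministic given params; ``seed`` only feeds
    the optional randomization of the initial position.
    """
    if isinstance(frame_or_mass, RetinaFrame):
        mass = masses_from_frame(frame_or_mass, params.alphas)
    else:
        mass = frame_or_mass
    mu = mass.mu if isinstance(mass, MassDistribution) else np.asarray(mass, float)
    h, w = mu.shape
    if params.normalize_mass:
        mu = normalize_total_mass(mu, params.mass_density)
    kernel = GravityKernel(params.epsilon)

    if params.randomize_a0:
        rng = np.random.default_rng(params.seed)
        a = np.array([rng.uniform(0, w - 1), rng.uniform(0, h - 1)])
    elif params.a0 is not None:
        a = np.asarray(params.a0, dtype=float).copy()
    else:
        a = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    v = np.asarray(params.v0, dtype=float).copy()

    n = params.n_steps()
    dt = params.dt
    lam = params.lam
    ior_on = params.ior_enabled
    inhibition = InhibitionField.zeros((h, w), beta=params.beta,
                                       sigma_px=params.sigma_ior_px)
    I = inhibition.I.copy()
    decay = np.exp(-params.beta * dt)

    # flat pixel coordinates, reused by the vectorized field evaluation
    ys, xs = np.mgrid[0:h, 0:w]
    xs = xs.ravel().astype(float)
    ys = ys.ravel().astype(float)
    eps = params.epsilon
    two_pi = 2.0 * np.pi

    def field(mu_flat, ax, ay):
        dx = xs - ax
        dy = ys - ay
        wgt = mu_flat / (two_pi * (dx * dx + dy * dy + eps))
        return np.dot(wgt, dx), np.dot(wgt, dy)

    ta = np.empty((n + 1, 2))
    tv = np.empty((n + 1, 2))
    ta[0] = a
    tv[0] = v

    mu_flat_base = mu.ravel()
    for k in range(n):
        mu_flat = mu_flat_base * (1.0 - I.ravel()) if ior_on else mu_flat_base

        # one classical RK4 step of (a, v) with the mass frozen
        def deriv(ax, ay, vx, vy):
            ex, ey = field(mu_flat, min(max(ax, 0.0), w - 1.0),
                           min(max(ay, 0.0), h - 1.0))
            return vx, vy, -lam * vx + ex, -lam * vy + ey

        k1 = deriv(a[0], a[1], v[0], v[1])
        k2 = deriv(a[0] + 0.5 * dt * k1[0], a[1] + 0.5 * dt * k1[1],
                   v[0] + 0.5 * dt * k1[2], v[1] + 0.5 * dt * k1[3])
        k3 = deriv(a[0] + 0.5 * dt * k2[0], a[1] + 0.5 * dt * k2[1],
                   v[0] + 0.5 * dt * k2[2], v[1] + 0.5 * dt * k2[3])
        k4 = deriv(a[0] + dt * k3[0], a[1] + dt * k3[1],
                   v[0] + dt * k3[2], v[1] + dt * k3[3])
        a = a + (dt / 6.0) * np.array([k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0],
                                       k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]])
        v = v + (dt / 6.0) * np.array([k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2],
                                       k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3]])
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(v))):
            raise NumericalError(f"trajectory diverged at step {k + 1}")
        _clamp_state(a, v, (h, w))

        if ior_on:
            g = ior_bump((h, w), a, params.sigma_ior_px)
            I = g + (I - g) * decay
            np.clip(I, 0.0, 1.0, out=I)

        ta[k + 1] = a
        tv[k + 1] = v

    dt_s = dt / params.time_scale
    traj = Trajectory(t=np.arange(n + 1) * dt_s, a=ta, v=tv * params.time_scale)
    return traj, replace(inhibition, I=I)
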