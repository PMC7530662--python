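"""Winner-take-all scanpath baseline.

The classical selection scheme over a master conspicuity map: the first
fixation is the location of maximum value; after each selection the map is
inhibited within a disk of 2 degrees of visual angle so attention switches
to the next-most-conspicuous location.  The output is discrete — there is no
continuous dynamics and no timing model, so fixation durations are uniform.

The historical "proximity and similarity preference" rules for choosing
among candidate winners are deliberately not implemented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import GravscanWarning
from .features import FeatureStack
from .io import DEFAULT_PIXELS_PER_DEGREE, Scanpath

#: Inhibition radius around a selected location, degrees of visual angle.
DEFAULT_INHIBITION_DEG = 2.0

#: Fixations per second used to pick a scanpath length for a given exposure.
DEFAULT_FIXATION_RATE = 3.0


@dataclass(frozen=True)
class MasterMap:
    """A single conspicuity map driving winner-take-all selection."""

    values: np.ndarray
    inhibition_radius_px: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or not np.all(np.isfinite(v)):
            raise ValueError("master map must be a finite H x W grid")
        if not self.inhibition_radius_px > 0:
            raise ValueError("inhibition radius must be positive")
        object.__setattr__(self, "values", v)


def combine_equal(maps, pixels_per_degree: float = DEFAULT_PIXELS_PER_DEGREE,
                  inhibition_deg: float = DEFAULT_INHIBITION_DEG) -> MasterMap:
    """Equal-weight linear combination (arithmetic mean) of scalar maps.

    Accepts a list of H x W grids or a :class:`FeatureStack` (whose gradient
    magnitudes are used).
    """
    if isinstance(maps, FeatureStack):
        stack = maps.magnitudes()
    else:
        stack = np.stack([np.asarray(m, dtype=float) for m in maps])
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("need at least one H x W map")
    return MasterMap(stack.mean(axis=0), inhibition_deg * pixels_per_degree)


def n_fixations_for(duration_s: float, rate: float = DEFAULT_FIXATION_RATE) -> int:
    """Scanpath length for an exposure, at a typical human fixation rate."""
    return max(1, int(round(rate * duration_s)))


def wta_scanpath(master: MasterMap, n_fixations: int,
                 fixation_duration: float) -> Scanpath:
    """Iterated argmax selection with local inhibition.

    Ties at the maximum break first-in-row-major order.  The inhibition disk
    (pixels within the radius, inclusive) is set to -inf, so any two emitted
    fixations are at least the radius apart.  If the whole map is inhibited
    before ``n_fixations`` are produced the scanpath is truncated with a
    warning.
    """
    if n_fixations < 1:
        raise ValueError("n_fixations must be at least 1")
    values = master.values.astype(float).copy()
    h, w = values.shape
    r = master.inhibition_radius_px
    if r >= min(h, w):
        raise ValueError("inhibition radius exceeds the frame")
    ys, xs = np.mgrid[0:h, 0:w]
    rows = []
    for k in range(n_fixations):
        flat = np.argmax(values)  # first maximum in row-major order
        if not np.isfinite(values.flat[flat]):
            warnings.warn(f"all locations inhibited after {k} fixations; "
                          "truncating WTA scanpath", GravscanWarning, stacklevel=2)
            break
        y, x = np.unravel_index(flat, values.shape)
        rows.append((float(x), float(y), k * fixation_duration, fixation_duration))
        values[(xs - x) ** 2 + (ys - y) ** 2 <= r * r] = -np.inf
    return Scanpath(np.array(rows, dtype=float).reshape(-1, 4), frame_size=(h, w))
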