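"""Image and scanpath input/output.

The retina domain is a regular pixel grid with continuous coordinates
``(x, y)``: ``x`` grows rightward (columns), ``y`` downward (rows), both
0-based, with pixel centers at integer coordinates.  Angular quantities
(inhibition radii, blur widths given in degrees of visual angle) are converted
to pixels through a single ``pixels_per_degree`` scale attached to the frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _skimage_resize

from .errors import FormatError, GravscanWarning

#: Default working resolution (square) for natural-image experiments.
WORKING_RESOLUTION = (224, 224)

#: Default viewing-geometry scale: treats a 224-px frame as ~17.5 deg of
#: visual field, typical of desktop eye-tracking setups.
DEFAULT_PIXELS_PER_DEGREE = 12.8


@dataclass(frozen=True)
class RetinaFrame:
    """A static RGB stimulus on the retina grid, channel values in [0, 1]."""

    pixels: np.ndarray  # H x W x 3 float array
    pixels_per_degree: float = DEFAULT_PIXELS_PER_DEGREE

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 2:
            px = np.repeat(px[:, :, None], 3, axis=2)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 pixel grid, got shape {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"frame must be at least 8 x 8, got {px.shape[:2]}")
        if not np.all(np.isfinite(px)):
            raise ValueError("frame contains non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("frame values must lie in [0, 1]")
        if self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def center(self) -> np.ndarray:
        """Geometric center of the frame in (x, y) pixel coordinates."""
        return np.array([(self.width_px - 1) / 2.0, (self.height_px - 1) / 2.0])


@dataclass(frozen=True)
class Scanpath:
    """An ordered sequence of fixations on a frame.

    ``fixations`` is an (n, 4) array with columns ``x, y, onset, duration``
    (pixels and seconds).  Onsets are strictly increasing, durations positive
    and coordinates lie inside the frame rectangle.
    """

    fixations: np.ndarray
    frame_size: tuple[int, int]  # (H, W)

    def __post_init__(self) -> None:
        fx = np.asarray(self.fixations, dtype=float).reshape(-1, 4)
        h, w = self.frame_size
        if fx.size:
            if not np.all(np.isfinite(fx)):
                raise ValueError("fixations contain non-finite values")
            if np.any(np.diff(fx[:, 2]) <= 0):
                raise ValueError("fixation onsets must be strictly increasing")
            if np.any(fx[:, 3] <= 0):
                raise ValueError("fixation durations must be positive")
            if fx[:, 0].min() < 0 or fx[:, 0].max() >= w or fx[:, 1].min() < 0 or fx[:, 1].max() >= h:
                raise ValueError("fixation coordinates outside the frame rectangle")
        object.__setattr__(self, "fixations", fx)
        object.__setattr__(self, "frame_size", (int(h), int(w)))

    def __len__(self) -> int:
        return self.fixations.shape[0]

    @property
    def xy(self) -> np.ndarray:
        return self.fixations[:, :2]

    @property
    def onsets(self) -> np.ndarray:
        return self.fixations[:, 2]

    @property
    def durations(self) -> np.ndarray:
        return self.fixations[:, 3]


@dataclass(frozen=True)
class ScanpathDialect:
    """Column map for delimited fixation listings.

    ``columns`` maps the canonical field names (``x``, ``y``, and optionally
    ``onset``, ``duration``) to 0-based column indices, so exports from
    different eye-tracking pipelines can be ingested with one parser.  When
    onsets are absent they are synthesized as cumulative durations; when
    durations are absent a constant ``default_duration`` is assumed.
    """

    delimiter: str = ","
    columns: dict = field(default_factory=lambda: {"x": 0, "y": 1, "onset": 2, "duration": 3})
    skip_header: bool = True
    default_duration: float = 0.25


def load_image(path, pixels_per_degree: float = DEFAULT_PIXELS_PER_DEGREE) -> RetinaFrame:
    """Load an 8- or 16-bit raster image into a [0, 1]-valued RGB frame."""
    path = Path(path)
    try:
        with Image.open(path) as img:
            img.load()
            mode = img.mode
            if mode in ("I;16", "I;16B", "I", "I;16L"):
                arr = np.asarray(img, dtype=float) / 65535.0
            else:
                arr = np.asarray(img.convert("RGB"), dtype=float) / 255.0
    except (OSError, SyntaxError, ValueError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    arr = np.clip(arr, 0.0, 1.0)
    return RetinaFrame(arr, pixels_per_degree=pixels_per_degree)


def save_image(frame_or_grid, path) -> None:
    """Write a frame or a scalar grid as an 8-bit PNG (grids are min-max scaled)."""
    if isinstance(frame_or_grid, RetinaFrame):
        arr = frame_or_grid.pixels
    else:
        arr = np.asarray(frame_or_grid, dtype=float)
        lo, hi = arr.min(), arr.max()
        if hi > lo:
            arr = (arr - lo) / (hi - lo)
        else:
            arr = np.zeros_like(arr)
    Image.fromarray(np.round(arr * 255.0).astype(np.uint8)).save(path)


def resize_frame(frame: RetinaFrame, size: tuple[int, int] = WORKING_RESOLUTION) -> RetinaFrame:
    """Bilinear resize to ``size`` = (H, W); values stay in [0, 1].

    ``pixels_per_degree`` is rescaled by the width ratio so that angular
    extents keep their meaning after resampling.
    """
    h, w = int(size[0]), int(size[1])
    if h < 8 or w < 8:
        raise ValueError(f"target size must be at least 8 x 8, got {(h, w)}")
    if (h, w) == frame.shape:
        return frame
    out = _skimage_resize(frame.pixels, (h, w, 3), order=1, mode="edge",
                          anti_aliasing=False, preserve_range=True)
    ppd = frame.pixels_per_degree * w / frame.width_px
    return RetinaFrame(np.clip(out, 0.0, 1.0), pixels_per_degree=ppd)


def read_scanpath(path, dialect: ScanpathDialect | None = None,
                  frame_size: tuple[int, int] | None = None) -> Scanpath:
    """Parse a delimited fixation listing into a :class:`Scanpath`.

    Rows with onsets out of order are sorted by onset (with a warning);
    coordinates outside the frame are clamped inside (with a warning).
    ``frame_size`` defaults to the working resolution.
    """
    dialect = dialect or ScanpathDialect()
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=dialect.delimiter, header=None,
                         skiprows=1 if dialect.skip_header else 0, comment="#")
    except (pd.errors.EmptyDataError, OSError) as exc:
        raise FormatError(f"no parseable fixation rows in {path}: {exc}") from exc
    df = df.apply(pd.to_numeric, errors="coerce").dropna(axis=0, how="all")
    cols = dialect.columns
    try:
        x = df.iloc[:, cols["x"]].to_numpy(float)
        y = df.iloc[:, cols["y"]].to_numpy(float)
    except (IndexError, KeyError) as exc:
        raise FormatError(f"missing x/y columns in {path}") from exc
    keep = np.isfinite(x) & np.isfinite(y)
    if not keep.any():
        raise FormatError(f"no parseable fixation rows in {path}")
    x, y = x[keep], y[keep]
    n = x.size

    if "duration" in cols and cols["duration"] < df.shape[1]:
        dur = df.iloc[:, cols["duration"]].to_numpy(float)[keep]
    else:
        dur = np.full(n, dialect.default_duration)
    dur = np.where(np.isfinite(dur) & (dur > 0), dur, dialect.default_duration)

    if "onset" in cols and cols["onset"] < df.shape[1]:
        onset = df.iloc[:, cols["onset"]].to_numpy(float)[keep]
        if not np.all(np.isfinite(onset)):
            onset = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
    else:
        onset = np.concatenate([[0.0], np.cumsum(dur)[:-1]])

    if np.any(np.diff(onset) <= 0):
        warnings.warn(f"fixation onsets out of order in {path}; sorting by onset",
                      GravscanWarning, stacklevel=2)
        order = np.argsort(onset, kind="stable")
        x, y, onset, dur = x[order], y[order], onset[order], dur[order]
        # collapse exactly tied onsets by nudging, to preserve strict ordering
        for i in range(1, n):
            if onset[i] <= onset[i - 1]:
                onset[i] = onset[i - 1] + 1e-9

    hh, ww = frame_size if frame_size is not None else WORKING_RESOLUTION
    if x.min() < 0 or x.max() >= ww or y.min() < 0 or y.max() >= hh:
        warnings.warn(f"fixation coordinates outside the {hh}x{ww} frame in {path}; clamping",
                      GravscanWarning, stacklevel=2)
        x = np.clip(x, 0.0, ww - 1)
        y = np.clip(y, 0.0, hh - 1)
    return Scanpath(np.column_stack([x, y, onset, dur]), frame_size=(hh, ww))


def write_scanpath(scanpath: Scanpath, path) -> None:
    """Write a scanpath as CSV with header ``x,y,onset,duration`` (6 decimals)."""
    df = pd.DataFrame(scanpath.fixations, columns=["x", "y", "onset", "duration"])
    try:
        df.to_csv(path, index=False, float_format="%.6f")
    except OSError as exc:
        raise OSError(f"cannot write scanpath to {path}: {exc}") from exc


def degrees_to_pixels(degrees: float, pixels_per_degree: float) -> float:
    """Convert an angular extent in degrees of visual angle to pixels."""
    return float(degrees) * float(pixels_per_degree)
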