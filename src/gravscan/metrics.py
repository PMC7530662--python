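"""Scanpath similarity metrics and NSS-based parameter tuning.

Three scanpath comparison measures are provided:

* **SED** (string-edit distance): the frame is divided into ``m x m``
  regions labeled with characters, each fixation is replaced by the label of
  its region, and the Levenshtein distance between the two label strings is
  returned.  Lower is better; the value is an unnormalized edit count.
* **TDE** (time-delay embeddings): every length-k sub-sequence of the
  reference (human) fixation sequence is compared with all length-k
  sub-sequences of the simulated one; the per-fixation-averaged Euclidean
  distance of the best match is averaged over reference windows.  Lower is
  better.
* **STDE** (scaled TDE): TDE with coordinates normalized to [0, 1] by the
  frame size, mapped to a similarity score ``exp(-d)`` in (0, 1].  Higher is
  better.

NSS (normalized scanpath saliency) — the mean z-scored saliency value at
fixation locations — scores a saliency map against fixations and drives the
grid-search tuning of the dynamics parameters.
"""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy.spatial.distance import cdist

from .dynamics import SimulationParams, simulate
from .errors import GravscanWarning, MetricError
from .fixation import detect_fixations_robust
from .io import RetinaFrame, Scanpath

_ALPHABET = string.digits + string.ascii_lowercase + string.ascii_uppercase


@dataclass(frozen=True)
class MetricParams:
    """Hyper-parameters of the scanpath metrics.

    grid_m   number of SED partitions per side (m x m regions)
    embed_k  sub-sequence (window) length of the time-delay embeddings
    """

    grid_m: int = 5
    embed_k: int = 3

    def __post_init__(self) -> None:
        if self.grid_m < 2:
            raise ValueError("grid_m must be at least 2")
        if self.embed_k < 1:
            raise ValueError("embed_k must be at least 1")
        if self.grid_m ** 2 > len(_ALPHABET) ** 2:
            raise ValueError("grid_m^2 exceeds the label alphabet")


def _cell_label(idx: int, n_cells: int) -> str:
    if n_cells <= len(_ALPHABET):
        return _ALPHABET[idx]
    return _ALPHABET[idx // len(_ALPHABET)] + _ALPHABET[idx % len(_ALPHABET)]


def scanpath_to_string(sp: Scanpath, frame_size: tuple[int, int],
                       grid_m: int) -> tuple[str, ...]:
    """Quantize fixations to the labels of their m x m grid cells.

    Cells are half-open ``[lo, hi)`` except the last (closed), labeled
    row-major.  Returns one single- or two-character label per fixation.
    """
    h, w = frame_size
    n_cells = grid_m * grid_m
    xy = sp.xy
    if xy.size and (xy[:, 0].min() < 0 or xy[:, 0].max() >= w
                    or xy[:, 1].min() < 0 or xy[:, 1].max() >= h):
        raise ValueError("fixation outside the frame")
    col = np.minimum((xy[:, 0] * grid_m / w).astype(int), grid_m - 1)
    row = np.minimum((xy[:, 1] * grid_m / h).astype(int), grid_m - 1)
    return tuple(_cell_label(int(r) * grid_m + int(c), n_cells)
                 for r, c in zip(row, col))


def edit_distance(s1, s2) -> int:
    """Levenshtein distance (unit insert/delete/substitute costs) by DP."""
    n1, n2 = len(s1), len(s2)
    if n1 == 0 or n2 == 0:
        return n1 + n2
    prev = np.arange(n2 + 1)
    cur = np.empty(n2 + 1, dtype=np.int64)
    for i in range(1, n1 + 1):
        cur[0] = i
        sub = prev[:-1] + np.array([s1[i - 1] != c for c in s2], dtype=np.int64)
        for j in range(1, n2 + 1):
            cur[j] = min(sub[j - 1], prev[j] + 1, cur[j - 1] + 1)
        prev, cur = cur, prev
    return int(prev[n2])


def sed(sp_a: Scanpath, sp_b: Scanpath, frame_size: tuple[int, int],
        params: MetricParams = MetricParams()) -> float:
    """String-edit distance between grid-quantized scanpaths (lower = closer)."""
    if len(sp_a) == 0 or len(sp_b) == 0:
        raise MetricError("SED is undefined for empty scanpaths")
    return float(edit_distance(scanpath_to_string(sp_a, frame_size, params.grid_m),
                               scanpath_to_string(sp_b, frame_size, params.grid_m)))


def _windows(xy: np.ndarray, k: int) -> np.ndarray:
    """All length-k windows of a fixation sequence as (n-k+1, 2k) vectors."""
    n = xy.shape[0]
    idx = np.arange(k)[None, :] + np.arange(n - k + 1)[:, None]
    return xy[idx].reshape(n - k + 1, 2 * k)


def tde(human: Scanpath, sim: Scanpath, embed_k: int = 3) -> float:
    """Time-delay-embedding distance of ``sim`` from the reference ``human``.

    Mean over human windows of the minimum per-fixation-averaged Euclidean
    distance to any simulated window.  >= 0; 0 iff every human window occurs
    verbatim among the simulated windows.
    """
    if len(human) < embed_k or len(sim) < embed_k:
        raise MetricError(f"scanpaths need at least {embed_k} fixations for TDE")
    wh = _windows(human.xy, embed_k)
    ws = _windows(sim.xy, embed_k)
    d = cdist(wh, ws) / embed_k
    return float(d.min(axis=1).mean())


def stde(human: Scanpath, sim: Scanpath, frame_size: tuple[int, int],
         embed_k: int = 3) -> float:
    """Scaled TDE similarity in (0, 1] (higher = closer).

    Coordinates are normalized per axis by the frame size before the TDE
    distance, which is then mapped through ``exp(-d)``.
    """
    h, w = frame_size
    scale = np.array([w, h], dtype=float)
    if len(human) < embed_k or len(sim) < embed_k:
        raise MetricError(f"scanpaths need at least {embed_k} fixations for STDE")
    wh = _windows(human.xy / scale, embed_k)
    ws = _windows(sim.xy / scale, embed_k)
    d = cdist(wh, ws) / embed_k
    return float(np.exp(-d.min(axis=1).mean()))


def nss(saliency: np.ndarray, fixations: Scanpath) -> float:
    """Normalized scanpath saliency: mean z-scored map value at fixations."""
    s = np.asarray(saliency, dtype=float)
    sd = s.std()
    if sd == 0:
        raise MetricError("NSS is undefined for a constant saliency map")
    if len(fixations) == 0:
        raise MetricError("NSS needs at least one fixation")
    z = (s - s.mean()) / sd
    h, w = s.shape
    cols = np.clip(np.rint(fixations.xy[:, 0]).astype(int), 0, w - 1)
    rows = np.clip(np.rint(fixations.xy[:, 1]).astype(int), 0, h - 1)
    return float(z[rows, cols].mean())


def evaluate_image(sim: Scanpath, humans, frame_size: tuple[int, int],
                   params: MetricParams = MetricParams()) -> dict:
    """Mean SED/TDE/STDE of a simulated scanpath against human observers.

    Pairs failing a metric's preconditions (e.g. fewer fixations than the
    embedding length) are skipped with a warning; if every pair is skipped a
    :class:`MetricError` is raised.
    """
    if not humans:
        raise MetricError("need at least one human scanpath")
    scores = {"sed": [], "tde": [], "stde": []}
    for hum in humans:
        try:
            triple = (sed(sim, hum, frame_size, params),
                      tde(hum, sim, params.embed_k),
                      stde(hum, sim, frame_size, params.embed_k))
        except MetricError as exc:
            warnings.warn(f"skipping one observer: {exc}", GravscanWarning,
                          stacklevel=2)
            continue
        for key, val in zip(("sed", "tde", "stde"), triple):
            scores[key].append(val)
    if not scores["sed"]:
        raise MetricError("all simulated/human pairs were skipped")
    return {k: float(np.mean(v)) for k, v in scores.items()}


def saliency_from_fixations(fixations: Scanpath, frame_size: tuple[int, int],
                            sigma_px: float) -> np.ndarray:
    """Empirical saliency map: a unit Gaussian accumulated at each fixation."""
    h, w = frame_size
    ys, xs = np.mgrid[0:h, 0:w]
    out = np.zeros((h, w))
    for x, y in fixations.xy:
        out += np.exp(-((xs - x) ** 2 + (ys - y) ** 2) / (2.0 * sigma_px ** 2))
    return out


def _pooled(humans) -> Scanpath:
    rows = np.vstack([h.fixations for h in humans])
    order = np.argsort(rows[:, 2], kind="stable")
    rows = rows[order]
    rows[:, 2] = np.arange(rows.shape[0])  # onsets only need to be ordered
    rows[:, 3] = np.maximum(rows[:, 3], 1e-6)
    return Scanpath(rows, frame_size=humans[0].frame_size)


def grid_search_tune(images, humans, grid: dict,
                     base_params: SimulationParams = SimulationParams(),
                     held_out_n: int | None = None,
                     blur_deg: float = 1.0,
                     min_fixations: int = 3) -> tuple[SimulationParams, list]:
    """Grid search of dynamics parameters maximizing mean NSS.

    For each lattice point of ``grid`` (a mapping of
    :class:`~gravscan.dynamics.SimulationParams` field names to candidate
    values), the model is simulated on the first ``held_out_n`` images, a
    simulated saliency map is built by accumulating a Gaussian of one degree
    of visual angle at each detected model fixation, and the mean NSS
    against the corresponding human fixations is recorded.  Returns the
    argmax parameters (ties break first-in-grid) and the full result list of
    ``(params, mean_nss)``.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("parameter grid must be non-empty")
    if held_out_n is None:
        held_out_n = len(images)
    if held_out_n < 1:
        raise ValueError("held_out_n must be at least 1")
    images = list(images)[:held_out_n]

    keys = list(grid.keys())
    results = []
    best = None
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = _dc_replace(base_params, **dict(zip(keys, combo)))
        vals = []
        for i, image in enumerate(images):
            traj, _ = simulate(image, params)
            if isinstance(image, RetinaFrame):
                shape = image.shape
                ppd = image.pixels_per_degree
            else:
                shape = image.mu.shape if hasattr(image, "mu") else np.asarray(image).shape
                ppd = params.pixels_per_degree
            fix = detect_fixations_robust(traj, shape, min_count=min_fixations)
            if len(fix) == 0:
                continue
            smap = saliency_from_fixations(fix, shape, blur_deg * ppd)
            try:
                vals.append(nss(smap, _pooled(humans[i])))
            except MetricError:
                continue
        score = float(np.mean(vals)) if vals else -np.inf
        results.append((params, score))
        if best is None or score > best[1]:
            best = (params, score)
    return best[0], results
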