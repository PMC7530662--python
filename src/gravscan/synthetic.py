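"""Parametric stimuli and synthetic observers with known attractor structure.

These generators make every stage of the pipeline testable without
eye-tracking data: stimuli are gray frames with Gaussian blobs, uniform
squares and optional noise patches, whose attractor geometry (centroids,
high-gradient borders) is known by construction; observers visit a given
attractor sequence with Gaussian positional jitter and lognormal-ish
fixation durations, emulating free-viewing fixation sequences over known
salient locations.

Everything is reproducible bit-for-bit from (parameters, seed).  This is not
a model of human eye-movement statistics: there is no saccadic main
sequence, no center bias, no fixational drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import RetinaFrame, Scanpath, save_image, write_scanpath


@dataclass(frozen=True)
class Blob:
    """An additive Gaussian luminance/color blob.

    With ``texture_sd > 0`` the blob is a Gaussian-enveloped patch of i.i.d.
    luminance noise instead of a smooth bump.  Smooth blobs put all their
    gradient mass on an annulus around the center (the envelope's slope);
    textured blobs carry gradient mass throughout their support, the way a
    patterned object does.
    """

    center: tuple  # (x, y) px
    sigma: float
    amplitude: float = 0.4
    channel: Optional[int] = None  # None = all channels (achromatic)
    texture_sd: float = 0.0


@dataclass(frozen=True)
class Square:
    """A uniform square patch, given by (x0, y0, side)."""

    rect: tuple
    amplitude: float = 0.4
    channel: Optional[int] = None


def make_blob_stimulus(size: tuple[int, int], blobs: Sequence[Blob] = (),
                       squares: Sequence[Square] = (),
                       noise_region: Optional[tuple] = None,
                       noise_sd: float = 0.15,
                       background: float = 0.5,
                       pixels_per_degree: Optional[float] = None,
                       seed: Optional[int] = None) -> RetinaFrame:
    """A gray frame plus Gaussian blobs, uniform squares, and a noise patch.

    ``noise_region`` is an (x0, y0, width, height) rectangle filled with
    i.i.d. Gaussian noise of standard deviation ``noise_sd`` on all
    channels.  ``pixels_per_degree`` defaults to treating the frame width as
    ~17.5 degrees of visual field, matching the working-resolution
    convention.  Deterministic per seed.
    """
    h, w = int(size[0]), int(size[1])
    img = np.full((h, w, 3), float(background))
    ys, xs = np.mgrid[0:h, 0:w]
    rng = np.random.default_rng(seed)
    for blob in blobs:
        cx, cy = blob.center
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError(f"blob center {blob.center} outside the {h}x{w} frame")
        envelope = np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2)
                          / (2.0 * blob.sigma ** 2))
        if blob.texture_sd > 0:
            bump = blob.amplitude * envelope * rng.normal(
                0.0, blob.texture_sd, size=(h, w))
        else:
            bump = blob.amplitude * envelope
        chans = range(3) if blob.channel is None else (blob.channel,)
        for c in chans:
            img[..., c] += bump
    for sq in squares:
        x0, y0, side = sq.rect
        chans = range(3) if sq.channel is None else (sq.channel,)
        for c in chans:
            img[int(y0):int(y0 + side), int(x0):int(x0 + side), c] += sq.amplitude
    if noise_region is not None:
        x0, y0, nw, nh = (int(v) for v in noise_region)
        img[y0:y0 + nh, x0:x0 + nw, :] += rng.normal(
            0.0, noise_sd, size=(nh, nw, 3))
    ppd = pixels_per_degree if pixels_per_degree is not None else w / 17.5
    return RetinaFrame(np.clip(img, 0.0, 1.0), pixels_per_degree=ppd)


def make_synthetic_observers(attractors, n_subjects: int,
                             frame_size: tuple[int, int],
                             jitter_sd: float = 2.5,
                             timing: tuple[float, float] = (0.25, 0.05),
                             seed: Optional[int] = None) -> list[Scanpath]:
    """Observers that visit the attractors in order with Gaussian jitter.

    Fixation durations are lognormal with the requested median and spread
    (approximately ``timing = (median_s, sd_s)``); onsets are cumulative
    with a 30 ms saccade gap.  Coordinates are clipped into the frame.
    Deterministic per seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    attractors = np.asarray(attractors, dtype=float).reshape(-1, 2)
    h, w = frame_size
    med, sd = timing
    rng = np.random.default_rng(seed)
    sigma_log = np.sqrt(np.log1p((sd / med) ** 2))
    observers = []
    for _ in range(n_subjects):
        xy = attractors + rng.normal(0.0, jitter_sd, size=attractors.shape)
        xy[:, 0] = np.clip(xy[:, 0], 0.0, w - 1)
        xy[:, 1] = np.clip(xy[:, 1], 0.0, h - 1)
        dur = med * np.exp(rng.normal(0.0, sigma_log, size=len(attractors))) \
            if sd > 0 else np.full(len(attractors), med)
        onset = np.concatenate([[0.0], np.cumsum(dur[:-1] + 0.03)])
        observers.append(Scanpath(np.column_stack([xy, onset, dur]),
                                  frame_size=(h, w)))
    return observers


def attractor_tour(centers, frame_size: tuple[int, int],
                   n_fixations: int) -> np.ndarray:
    """Order attractors as a free-viewing tour, cycled to ``n_fixations``.

    The tour starts from the attractor nearest the frame center and proceeds
    by nearest-neighbor steps (emulating the short-saccade preference of
    free viewing), then repeats cyclically so observers revisit targets the
    way humans do over a multi-second exposure.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 2)
    h, w = frame_size
    pos = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    remaining = list(range(len(centers)))
    order = []
    while remaining:
        nxt = min(remaining, key=lambda i: np.linalg.norm(centers[i] - pos))
        order.append(nxt)
        pos = centers[nxt]
        remaining.remove(nxt)
    idx = [order[i % len(order)] for i in range(n_fixations)]
    return centers[idx]


def random_blob_scene(size: tuple[int, int], n_blobs: int, rng: np.random.Generator,
                      sigma_range: tuple[float, float] = (3.5, 5.5),
                      amplitude_range: tuple[float, float] = (0.3, 0.45),
                      min_separation: Optional[float] = None,
                      margin: float = 10.0) -> list[Blob]:
    """Blobs at random positions with a minimum pairwise separation."""
    h, w = size
    if min_separation is None:
        min_separation = 0.3 * min(h, w)
    margin = min(margin, 0.2 * min(h, w))
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_blobs:
        cand = np.array([rng.uniform(margin, w - 1 - margin),
                         rng.uniform(margin, h - 1 - margin)])
        if all(np.linalg.norm(cand - c) >= min_separation for c in centers):
            centers.append(cand)
        tries += 1
        if tries > 200:  # infeasible geometry: relax and retry
            min_separation *= 0.9
            centers.clear()
            tries = 0
    return [Blob(center=(float(c[0]), float(c[1])),
                 sigma=float(rng.uniform(*sigma_range)),
                 amplitude=float(rng.uniform(*amplitude_range)))
            for c in centers]


def make_benchmark_scene(rng: np.random.Generator, size: tuple[int, int] = (64, 64),
                         n_distractors: int = 2, amplitude: float = 0.6,
                         texture_sd: float = 0.5, object_sigma: float = 3.8,
                         separation: tuple = (24.0, 30.0),
                         n_fixations: int = 9, n_subjects: int = 10,
                         jitter_sd: float = 2.5) -> tuple:
    """One benchmark stimulus with paired salient objects plus observers.

    The scene contains two equally strong, compact, lightly textured
    objects (attention is expected to alternate between their centroids
    under inhibition of return) and a few weak distractors; synthetic
    observers alternate between the two object centroids with positional
    jitter, emulating the comparison behavior of free-viewing humans on a
    two-object display.  The objects are compact enough that a 2-degree
    inhibition disk covers them whole.

    Returns ``(frame, object_centers, observers)``.
    """
    h, w = size
    margin = 14.0
    while True:
        c_a = (float(rng.uniform(margin, w - 1 - margin)),
               float(rng.uniform(margin, h - 1 - margin)))
        c_b = (float(rng.uniform(margin, w - 1 - margin)),
               float(rng.uniform(margin, h - 1 - margin)))
        if separation[0] < np.hypot(c_a[0] - c_b[0], c_a[1] - c_b[1]) < separation[1]:
            break
    distractors = []
    tries = 0
    while len(distractors) < n_distractors and tries < 1000:
        tries += 1
        c = (float(rng.uniform(5, w - 6)), float(rng.uniform(5, h - 6)))
        if all(np.hypot(c[0] - m[0], c[1] - m[1]) > 14.0
               for m in [c_a, c_b] + distractors):
            distractors.append(c)
    blobs = [Blob(c_a, object_sigma, amplitude=amplitude, texture_sd=texture_sd),
             Blob(c_b, object_sigma, amplitude=amplitude, texture_sd=texture_sd)]
    blobs += [Blob(m, 2.4, amplitude=0.18) for m in distractors]
    frame = make_blob_stimulus(size, blobs, seed=int(rng.integers(2 ** 31)))
    tour = np.array([c_a if k % 2 == 0 else c_b for k in range(n_fixations)])
    observers = make_synthetic_observers(tour, n_subjects, size,
                                         jitter_sd=jitter_sd,
                                         seed=int(rng.integers(2 ** 31)))
    return frame, np.array([c_a, c_b]), observers


def make_demo_dataset(out_dir, n_images: int = 5, n_subjects: int = 5,
                      size: tuple[int, int] = (64, 64), n_blobs: int = 3,
                      jitter_sd: float = 2.5, seed: int = 0) -> dict:
    """Materialize a small eye-tracking-shaped dataset on disk.

    Layout: ``images/img_###.png`` and ``scanpaths/img_###/subject_##.csv``.
    Observers visit the blob centers in order.  Returns the per-image blob
    centers for reference.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    index = {}
    for i in range(n_images):
        name = f"img_{i:03d}"
        blobs = random_blob_scene(size, n_blobs, rng)
        frame = make_blob_stimulus(size, blobs, seed=int(rng.integers(2 ** 31)))
        save_image(frame, out / "images" / f"{name}.png")
        centers = [b.center for b in blobs]
        observers = make_synthetic_observers(
            centers, n_subjects, size, jitter_sd=jitter_sd,
            seed=int(rng.integers(2 ** 31)))
        spdir = out / "scanpaths" / name
        spdir.mkdir(parents=True, exist_ok=True)
        for s, sp in enumerate(observers):
            write_scanpath(sp, spdir / f"subject_{s:02d}.csv")
        index[name] = centers
    return index
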