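"""Velocity-threshold fixation detection (I-VT).

The continuous model trajectory is turned into discrete fixations with the
same style of detector used on human eye-tracking recordings: samples whose
speed falls below a threshold are grouped into maximal runs, runs shorter
than a minimum duration are discarded, and each surviving run becomes one
fixation at the run centroid.
"""

from __future__ import annotations

import warnings

import numpy as np

from .dynamics import Trajectory
from .errors import GravscanWarning
from .io import Scanpath

#: Speed below which a sample counts as fixational, px/s.
DEFAULT_SPEED_THRESHOLD = 50.0

#: Minimum fixation duration, seconds.
DEFAULT_MIN_DURATION = 0.08


def detect_fixations(traj: Trajectory, frame_size: tuple[int, int],
                     speed_threshold: float = DEFAULT_SPEED_THRESHOLD,
                     min_duration: float = DEFAULT_MIN_DURATION) -> Scanpath:
    """I-VT detection on a uniformly sampled trajectory.

    Speeds are estimated by central differences on the positions.  Each
    maximal sub-threshold run of samples longer than ``min_duration`` yields
    a fixation at the run centroid, with onset at the run start and duration
    equal to the run extent (run length x sampling step).
    """
    if speed_threshold <= 0 or min_duration <= 0:
        raise ValueError("thresholds must be positive")
    n = len(traj)
    dt = traj.dt_s
    if n * dt < min_duration:
        warnings.warn("trajectory shorter than the minimum fixation duration",
                      GravscanWarning, stacklevel=2)
        return Scanpath(np.empty((0, 4)), frame_size=frame_size)

    slow = traj.speeds() < speed_threshold
    rows = []
    k = 0
    while k < n:
        if not slow[k]:
            k += 1
            continue
        start = k
        while k < n and slow[k]:
            k += 1
        run_len = k - start
        duration = run_len * dt
        if duration >= min_duration:
            cx, cy = traj.a[start:k].mean(axis=0)
            rows.append((cx, cy, traj.t[start], duration))
    if not rows:
        warnings.warn("no fixation satisfied the duration threshold",
                      GravscanWarning, stacklevel=2)
    return Scanpath(np.array(rows, dtype=float).reshape(-1, 4), frame_size=frame_size)


def detect_fixations_robust(traj: Trajectory, frame_size: tuple[int, int],
                            thresholds=(60.0, 100.0, 150.0, 250.0),
                            min_duration: float = DEFAULT_MIN_DURATION,
                            min_count: int = 1) -> Scanpath:
    """I-VT detection with an escalating speed-threshold ladder.

    The model's dwell drift speeds scale with the time compression of the
    simulation, so a single absolute threshold cannot fit every setting;
    this tries increasing thresholds until at least ``min_count`` fixations
    emerge (returning the last attempt otherwise).
    """
    sp = Scanpath(np.empty((0, 4)), frame_size=frame_size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", GravscanWarning)
        for th in thresholds:
            sp = detect_fixations(traj, frame_size, speed_threshold=th,
                                  min_duration=min_duration)
            if len(sp) >= min_count:
                break
    return sp
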