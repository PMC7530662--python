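"""Scikit-learn-style estimator facades over the attention models.

Both estimators map stimuli to scanpaths through ``predict``; they compose
with :mod:`sklearn` model selection through ``get_params``/``set_params``
and score scanpath ensembles with the STDE similarity (higher is better).

``GravityScanpathModel.fit`` performs the grid-search calibration of the
dynamics parameters: for each candidate parameter set the model is
simulated on the supplied (held-out) stimuli and the parameters maximizing
the NSS saliency score against the human fixations are retained.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .dynamics import SimulationParams, simulate
from .fixation import (DEFAULT_MIN_DURATION, DEFAULT_SPEED_THRESHOLD,
                       detect_fixations_robust)
from .io import RetinaFrame, Scanpath
from .metrics import MetricParams, evaluate_image, grid_search_tune
from .features import extract_features, saliency_as_mass
from .wta import (DEFAULT_FIXATION_RATE, DEFAULT_INHIBITION_DEG, combine_equal,
                  n_fixations_for, wta_scanpath)


def _as_frames(X):
    if isinstance(X, RetinaFrame):
        return [X]
    return list(X)


class GravityScanpathModel(BaseEstimator):
    """Gravitational scanpath simulator with NSS-calibrated dynamics.

    Parameters mirror :class:`~gravscan.dynamics.SimulationParams` plus the
    fixation-detection thresholds.  After ``fit``, the calibrated damping is
    available as ``lam_`` and the full winning parameter set as
    ``best_params_``.
    """

    def __init__(self, lam=1.0, beta=0.1, sigma_ior_deg=2.0, duration=3.0,
                 dt=0.01, time_scale=40.0, epsilon=0.25, alphas=None,
                 ior_enabled=True, speed_threshold=DEFAULT_SPEED_THRESHOLD,
                 min_fix_duration=DEFAULT_MIN_DURATION, random_state=None):
        self.lam = lam
        self.beta = beta
        self.sigma_ior_deg = sigma_ior_deg
        self.duration = duration
        self.dt = dt
        self.time_scale = time_scale
        self.epsilon = epsilon
        self.alphas = alphas
        self.ior_enabled = ior_enabled
        self.speed_threshold = speed_threshold
        self.min_fix_duration = min_fix_duration
        self.random_state = random_state

    def _params_for(self, frame: RetinaFrame, lam=None) -> SimulationParams:
        return SimulationParams(
            lam=self.lam if lam is None else lam, beta=self.beta,
            sigma_ior_deg=self.sigma_ior_deg, alphas=self.alphas,
            duration=self.duration, dt=self.dt, time_scale=self.time_scale,
            pixels_per_degree=frame.pixels_per_degree, epsilon=self.epsilon,
            ior_enabled=self.ior_enabled, seed=self.random_state)

    def fit(self, X, y, param_grid=None, held_out_n=None):
        """Calibrate dynamics parameters by NSS grid search.

        X is a list of :class:`RetinaFrame`; y a list (per image) of lists
        of human :class:`Scanpath`.  ``param_grid`` maps SimulationParams
        field names to candidates (default: a small damping grid).
        """
        frames = _as_frames(X)
        if param_grid is None:
            param_grid = {"lam": [0.3, 1.0, 3.0]}
        base = self._params_for(frames[0])
        best, results = grid_search_tune(frames, y, param_grid, base_params=base,
                                         held_out_n=held_out_n)
        self.best_params_ = best
        self.tuning_results_ = results
        self.lam_ = best.lam
        self.lam = best.lam
        self.n_features_in_ = 8
        return self

    def simulate(self, frame: RetinaFrame, saliency=None):
        """Trajectory and final inhibition field for one stimulus."""
        params = self._params_for(frame)
        if saliency is not None:
            return simulate(saliency_as_mass(np.asarray(saliency)), params)
        return simulate(frame, params)

    def predict(self, X, saliency=None) -> list[Scanpath]:
        """Simulated scanpaths (detected fixations), one per stimulus.

        Fixations are detected with an escalating speed-threshold ladder
        starting at ``speed_threshold``, so a slow-drift trajectory still
        segments into a usable fixation sequence.
        """
        ladder = tuple(sorted({self.speed_threshold, 100.0, 150.0, 250.0}))
        out = []
        for frame in _as_frames(X):
            traj, _ = self.simulate(frame, saliency=saliency)
            out.append(detect_fixations_robust(
                traj, frame.shape, thresholds=ladder,
                min_duration=self.min_fix_duration, min_count=3))
        return out

    def score(self, X, y, metric_params: MetricParams = MetricParams()) -> float:
        """Mean STDE similarity against human observers (higher is better)."""
        frames = _as_frames(X)
        sims = self.predict(frames)
        vals = [evaluate_image(sp, obs, frame.shape, metric_params)["stde"]
                for sp, obs, frame in zip(sims, y, frames)]
        return float(np.mean(vals))


class WinnerTakeAllModel(BaseEstimator):
    """Winner-take-all scanpath baseline over equally weighted feature maps.

    ``fit`` only validates and records bookkeeping: the baseline has no
    tunable dynamics.
    """

    def __init__(self, n_fixations=None, fixation_rate=DEFAULT_FIXATION_RATE,
                 duration=3.0, inhibition_deg=DEFAULT_INHIBITION_DEG,
                 alphas=None):
        self.n_fixations = n_fixations
        self.fixation_rate = fixation_rate
        self.duration = duration
        self.inhibition_deg = inhibition_deg
        self.alphas = alphas

    def fit(self, X=None, y=None):
        self.n_features_in_ = 8
        return self

    def _n_fix(self) -> int:
        if self.n_fixations is not None:
            return int(self.n_fixations)
        return n_fixations_for(self.duration, self.fixation_rate)

    def predict(self, X, saliency=None) -> list[Scanpath]:
        out = []
        n = self._n_fix()
        for frame in _as_frames(X):
            if saliency is not None:
                maps = [np.asarray(saliency, dtype=float)]
                master = combine_equal(maps, frame.pixels_per_degree,
                                       self.inhibition_deg)
            else:
                stack = extract_features(frame)
                mags = stack.magnitudes()
                if self.alphas is not None:
                    mags = np.asarray(self.alphas)[:, None, None] * mags
                master = combine_equal(list(mags), frame.pixels_per_degree,
                                       self.inhibition_deg)
            out.append(wta_scanpath(master, n, self.duration / n))
        return out

    def score(self, X, y, metric_params: MetricParams = MetricParams()) -> float:
        """Mean STDE similarity against human observers (higher is better)."""
        frames = _as_frames(X)
        sims = self.predict(frames)
        vals = [evaluate_image(sp, obs, frame.shape, metric_params)["stde"]
                for sp, obs, frame in zip(sims, y, frames)]
        return float(np.mean(vals))
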