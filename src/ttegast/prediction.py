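"""Survival-curve container, point-time extraction, ensemble median."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _check_curve(times, S):
    times = np.asarray(times, dtype=float)
    S = np.asarray(S, dtype=float)
    if times.shape != S.shape:
        raise ValueError("times and survival values differ in shape")
    if np.any(np.diff(times) <= 0):
        raise ValueError("curve times must be strictly increasing")
    if np.any(np.diff(S) > 1e-12):
        raise ValueError("survival curve must be non-increasing")
    if np.any(S < -1e-12) or np.any(S > 1 + 1e-12):
        raise ValueError("survival values must lie in [0, 1]")
    return times, np.clip(S, 0.0, 1.0)


def extract_point_time(times, S) -> tuple[float, str]:
    """Point time from a survival curve: the interpolated median survival
    time where S crosses 0.5; if S stays above 0.5 over the grid, the
    restricted mean survival time (trapezoid rule on [0, τ_m]) instead.

    A point at t=0, S=1 is prepended if absent. Returns
    ``(t, policy)`` with policy ``"median"`` or ``"rmst"``.
    """
    times, S = _check_curve(times, S)
    if times[0] > 0:
        times = np.concatenate([[0.0], times])
        S = np.concatenate([[1.0], S])
    if S[-1] <= 0.5:
        idx = int(np.argmax(S <= 0.5))
        if S[idx] == 0.5 or idx == 0:
            return float(times[idx]), "median"
        t0, t1 = times[idx - 1], times[idx]
        s0, s1 = S[idx - 1], S[idx]
        return float(t0 + (s0 - 0.5) * (t1 - t0) / (s0 - s1)), "median"
    return float(np.trapezoid(S, times)), "rmst"


def point_times_from_curves(times, S) -> np.ndarray:
    """Vectorised :func:`extract_point_time` over rows of a survival
    matrix ``S`` (n subjects × m grid points)."""
    times = np.asarray(times, dtype=float)
    S = np.asarray(S, dtype=float)
    if times[0] > 0:
        times = np.concatenate([[0.0], times])
        S = np.column_stack([np.ones(S.shape[0]), S])
    out = np.empty(S.shape[0])
    crosses = S[:, -1] <= 0.5
    if np.any(crosses):
        Sc = S[crosses]
        idx = np.argmax(Sc <= 0.5, axis=1)
        rows = np.arange(Sc.shape[0])
        s1 = Sc[rows, idx]
        t1 = times[idx]
        prev = np.maximum(idx - 1, 0)
        s0 = Sc[rows, prev]
        t0 = times[prev]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(s0 > s1, (s0 - 0.5) / (s0 - s1), 0.0)
        out[crosses] = np.where(idx == 0, t1, t0 + frac * (t1 - t0))
    if np.any(~crosses):
        out[~crosses] = np.trapezoid(S[~crosses], times, axis=1)
    return out


@dataclass
class Prediction:
    """One subject's predicted survival curve with derived quantities."""

    times: np.ndarray
    survival: np.ndarray
    point_time_days: float = field(default=None)
    policy: str = field(default=None)

    def __post_init__(self):
        self.times, self.survival = _check_curve(self.times, self.survival)
        if self.point_time_days is None:
            self.point_time_days, self.policy = extract_point_time(self.times, self.survival)

    def p_event_by(self, horizon: float) -> float:
        """P(event by t) = 1 − S(t), monotone linear interpolation; S=1
        before the grid, S(τ_m) beyond it."""
        t = np.concatenate([[0.0], self.times]) if self.times[0] > 0 else self.times
        S = np.concatenate([[1.0], self.survival]) if self.times[0] > 0 else self.survival
        return float(1.0 - np.interp(horizon, t, S))


def ensemble_median(preds: list) -> Prediction:
    """Element-wise median of survival curves across cross-validation
    folds, plus the median of point times. Requires a common grid; the
    element-wise median of non-increasing curves is non-increasing."""
    if not preds:
        raise ValueError("no predictions to ensemble")
    t0 = preds[0].times
    for p in preds[1:]:
        if p.times.shape != t0.shape or not np.allclose(p.times, t0):
            raise ValueError("ensemble requires a common time grid across predictions")
    S = np.median(np.stack([p.survival for p in preds]), axis=0)
    pt = float(np.median([p.point_time_days for p in preds]))
    return Prediction(times=t0.copy(), survival=S, point_time_days=pt, policy="ensemble-median")
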