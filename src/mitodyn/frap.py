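"""FRAP normalization and time-to-recovery.

Raw bleach-spot, whole-cell and background intensity traces are combined by
double normalization — background subtraction and division by the whole-cell
signal corrects acquisition bleaching, then the pre-bleach mean of the ratio
is scaled to 1.  The summary statistic is the time for the normalized signal
to first reach a given fraction (default 90%) of the *recovered plateau*
measured from the bleach floor; partial-recovery curves therefore still
qualify.  No model fit is required; a single-exponential fit is available as
a diagnostic only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator


@dataclass(frozen=True)
class FrapCurve:
    """Double-normalized FRAP curve with a detected bleach event.

    ``time_s`` is the acquisition time axis; ``intensity`` is normalized so
    the pre-bleach mean is 1; ``bleach_index`` is the first post-bleach frame.
    """

    time_s: np.ndarray
    intensity: np.ndarray
    bleach_index: int

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, float)
        if (np.diff(t) <= 0).any():
            raise ValueError("time must be strictly increasing")
        if not 0 < self.bleach_index < len(t):
            raise ValueError("bleach_index out of range")
        pre = np.asarray(self.intensity, float)[: self.bleach_index]
        if abs(pre.mean() - 1.0) > 1e-9:
            raise ValueError("pre-bleach mean must be normalized to 1")

    @property
    def post_bleach(self) -> tuple[np.ndarray, np.ndarray]:
        """(time since bleach, intensity) from the bleach frame onward."""
        i = self.bleach_index
        return (np.asarray(self.time_s)[i:] - self.time_s[i],
                np.asarray(self.intensity)[i:])


def normalize_frap(raw: pd.DataFrame, pre_bleach_frames: int) -> FrapCurve:
    """Double-normalize a raw FRAP table ``time_s, spot, whole_cell, background``.

    I(t) = (spot - background) / (whole_cell - background), scaled so the
    pre-bleach mean is 1.  The bleach frame is the first frame after the
    pre-bleach window and must show a drop exceeding 3 standard deviations of
    the pre-bleach noise; otherwise no bleach event is detectable and the
    input is rejected.
    """
    for c in ("time_s", "spot", "whole_cell", "background"):
        if c not in raw.columns:
            raise ValueError(f"missing column {c!r}")
    if pre_bleach_frames < 3:
        raise ValueError("need >= 3 pre-bleach frames")
    t = raw["time_s"].to_numpy(float)
    spot = raw["spot"].to_numpy(float)
    whole = raw["whole_cell"].to_numpy(float)
    back = raw["background"].to_numpy(float)
    if (whole <= back).any():
        raise ValueError("whole_cell must exceed background throughout")
    ratio = (spot - back) / (whole - back)
    pre = ratio[:pre_bleach_frames]
    drop = pre.mean() - ratio[pre_bleach_frames]
    noise = pre.std(ddof=1)
    if drop <= max(3.0 * noise, 1e-9):
        raise ValueError("no bleach event detectable "
                         "(drop within 3 SD of pre-bleach noise)")
    return FrapCurve(time_s=t, intensity=ratio / pre.mean(),
                     bleach_index=pre_bleach_frames)


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def time_to_recovery(curve: FrapCurve, fraction: float = 0.9,
                     smooth_window: int = 3) -> float:
    """Time (s after bleach) to first reach ``fraction`` of the recovery.

    The plateau is the mean of the final 10% of post-bleach frames (at least
    5); the bleach floor is the first post-bleach point.  The threshold
    ``floor + fraction·(plateau - floor)`` is crossed on a lightly smoothed
    curve with linear interpolation between frames, so the estimate is
    invariant under affine intensity transforms.  A curve that never crosses
    is rejected ("no recovery").
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    t, y = curve.post_bleach
    if len(y) < 10:
        raise ValueError("post-bleach segment needs >= 10 frames")
    n_tail = max(5, int(round(0.1 * len(y))))
    plateau = float(y[-n_tail:].mean())
    floor = float(y[0])
    if plateau <= floor:
        raise ValueError("no recovery: plateau does not exceed the bleach floor")
    threshold = floor + fraction * (plateau - floor)
    ys = _smooth(y, smooth_window)
    ys[0] = y[0]  # keep the floor anchored at the true bleach point
    above = ys >= threshold
    if not above[1:].any():
        raise ValueError("no recovery: curve never crosses the threshold")
    j = int(np.nonzero(above[1:])[0][0] + 1)
    y0, y1 = ys[j - 1], ys[j]
    if y1 == y0:
        return float(t[j])
    frac = (threshold - y0) / (y1 - y0)
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))


def fit_single_exponential(curve: FrapCurve) -> dict:
    """Diagnostic fit I(t) = floor + amp·(1 - exp(-k t)) on the post-bleach segment."""
    t, y = curve.post_bleach
    floor0 = y[0]
    amp0 = max(y[-1] - floor0, 1e-6)
    k0 = 1.0 / max(t[len(t) // 3], 1e-6)

    def resid(x):
        floor, amp, k = x
        return floor + amp * (1 - np.exp(-k * t)) - y

    res = least_squares(resid, [floor0, amp0, k0],
                        bounds=([-1, 0, 1e-6], [2, 2, 1e3]))
    floor, amp, k = res.x
    return {"floor": float(floor), "amplitude": float(amp), "k": float(k),
            "converged": bool(res.success)}


class FrapRecovery(BaseEstimator):
    """Time-to-recovery estimator for FRAP tables.

    ``fit`` accepts a raw table (``time_s, spot, whole_cell, background``) or
    a :class:`FrapCurve`.  Fitted attributes: ``t90_`` (time to reach
    ``fraction`` of the recovery, s), ``plateau_``, ``bleach_floor_``,
    ``curve_``, ``n_frames_``.
    """

    def __init__(self, pre_bleach_frames: int = 10, fraction: float = 0.9,
                 smooth_window: int = 3):
        self.pre_bleach_frames = pre_bleach_frames
        self.fraction = fraction
        self.smooth_window = smooth_window

    def fit(self, X, y=None):
        curve = X if isinstance(X, FrapCurve) else normalize_frap(
            X, self.pre_bleach_frames
        )
        t, yy = curve.post_bleach
        n_tail = max(5, int(round(0.1 * len(yy))))
        self.curve_ = curve
        self.t90_ = time_to_recovery(curve, self.fraction, self.smooth_window)
        self.plateau_ = float(yy[-n_tail:].mean())
        self.bleach_floor_ = float(yy[0])
        self.n_frames_ = len(curve.time_s)
        return self


__all__ = [
    "FrapCurve", "normalize_frap", "time_to_recovery",
    "fit_single_exponential", "FrapRecovery",
]
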