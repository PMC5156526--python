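"""Kinetic and acquisition parameter containers and named presets.

Two-state (bound/free) transcription-factor kinetics are parameterized by a
free and a bound diffusion coefficient, a pseudo-first-order binding rate
``k_on_star`` (the rate at which a free molecule binds, chromatin sites being
in excess), and an unbinding rate ``k_off``.  The stationary bound fraction is
``k_on_star / (k_on_star + k_off)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class KineticParams:
    """Two-state diffusion/binding kinetics plus imaging nuisance rates.

    Parameters
    ----------
    d_free, d_bound : float
        Diffusion coefficients (µm²/s) of the freely diffusing and the
        chromatin-bound state; ``d_free > d_bound``.
    k_on_star : float
        Pseudo-first-order binding rate while free (1/s).
    k_off : float
        Unbinding rate while bound (1/s).
    sigma_loc : float
        1D localization error standard deviation (µm); ~0.035 µm for
        typical single-molecule experiments.
    k_photobleach : float
        Per-second photobleaching rate (1/s); acts identically on bound and
        free molecules (constant illumination).
    """

    d_free: float
    d_bound: float
    k_on_star: float
    k_off: float
    sigma_loc: float = 0.035
    k_photobleach: float = 0.0

    def __post_init__(self) -> None:
        for name in ("d_free", "d_bound", "k_on_star", "k_off", "sigma_loc",
                     "k_photobleach"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.d_free < self.d_bound:
            raise ValueError("d_free must be >= d_bound")

    @property
    def bound_fraction(self) -> float:
        """Stationary bound fraction k_on*/(k_on*+k_off); 0 if both rates 0."""
        tot = self.k_on_star + self.k_off
        return self.k_on_star / tot if tot > 0 else 0.0


@dataclass(frozen=True)
class AcquisitionSettings:
    """Camera/optics settings of a (simulated) SPT acquisition.

    ``slice_half_width`` is half the axial detection slice thickness Δz/2; a
    molecule is localized only while within ±slice_half_width of the focal
    plane.  ``blink_max_gap`` missed frames are tolerated when re-connecting
    detections into one trajectory (tracking "blinking" setting).
    ``cell_half_depth`` bounds the axial random walk (reflecting boundaries).
    """

    frame_interval: float = 0.0045
    n_frames: int = 100
    exposure: float = 0.001
    slice_half_width: float = 0.35
    blink_max_gap: int = 1
    fov: tuple[float, float] = (20.0, 20.0)
    cell_half_depth: float = 4.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.exposure > self.frame_interval:
            raise ValueError("exposure must be <= frame_interval")
        if self.slice_half_width <= 0:
            raise ValueError("slice_half_width must be > 0")
        if self.blink_max_gap < 0:
            raise ValueError("blink_max_gap must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.cell_half_depth < self.slice_half_width:
            raise ValueError("cell_half_depth must be >= slice_half_width")


# Fast-tracking presets.  Bound fractions mirror the reported interphase
# (30.9%) and mitotic (18.3%) values; the mitotic specific off-rate is
# 1/0.54 of the interphase one (mitotic residence time 54% of interphase).
# D_FREE/D_BOUND are plausible defaults (the underlying study does not state
# them); switching rates are slow relative to the ms lag times so the
# quasi-static two-state jump model applies.
_K_OFF_INTERPHASE = 0.05
_K_OFF_MITOSIS = _K_OFF_INTERPHASE / 0.54


def _k_on_for(f_bound: float, k_off: float) -> float:
    return k_off * f_bound / (1.0 - f_bound)


KINETIC_PRESETS: dict[str, KineticParams] = {
    "interphase": KineticParams(
        d_free=2.0, d_bound=0.01,
        k_on_star=_k_on_for(0.309, _K_OFF_INTERPHASE),
        k_off=_K_OFF_INTERPHASE,
        sigma_loc=0.035, k_photobleach=4.0,
    ),
    "mitosis": KineticParams(
        d_free=2.0, d_bound=0.01,
        k_on_star=_k_on_for(0.183, _K_OFF_MITOSIS),
        k_off=_K_OFF_MITOSIS,
        sigma_loc=0.035, k_photobleach=4.0,
    ),
}

# Slow-tracking (residence time) dwell presets: a two-exponential mixture of
# non-specific (fast) and specific (slow) binding, censored by photobleaching.
# Interphase specific off-rate 0.08/s (τ_s = 12.5 s); the mitotic one is
# scaled by 1/0.54 so the mitotic residence time is 54% of interphase.
DWELL_PRESETS: dict[str, dict[str, float]] = {
    "interphase": dict(f_ns=0.7, k_ns=2.0, k_s=0.08, k_photobleach=0.05),
    "mitosis": dict(f_ns=0.7, k_ns=2.0, k_s=0.08 / 0.54, k_photobleach=0.05),
}

SLOW_TRACKING = AcquisitionSettings(
    frame_interval=0.5, n_frames=600, exposure=0.5, slice_half_width=0.35,
)

FAST_TRACKING = AcquisitionSettings(
    frame_interval=0.0045, n_frames=100, exposure=0.001, slice_half_width=0.35,
)


def preset(name: str) -> KineticParams:
    try:
        return KINETIC_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(KINETIC_PRESETS)}"
        ) from None


__all__ = [
    "KineticParams", "AcquisitionSettings", "KINETIC_PRESETS",
    "DWELL_PRESETS", "SLOW_TRACKING", "FAST_TRACKING", "preset",
]
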