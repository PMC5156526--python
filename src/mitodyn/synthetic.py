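"""Synthetic-data generators for every analysis stage.

All generators draw from the statistical models the analysis stages assume,
so each stage can be verified by parameter recovery against known ground
truth:

* two-state (bound/free) Brownian motion with exponential state durations,
  an axial detection slice, localization error, blinking and photobleaching
  (fast-tracking trajectories);
* exponential dwell-time mixtures censored by photobleaching (slow-tracking
  dwell samples);
* saturating-exponential FRAP recovery with acquisition bleaching, background
  and Gaussian noise;
* two-channel cell images (chromosome marker + TF) with a prescribed
  chromosome/cytoplasm intensity ratio and Poisson noise.

State switching is simulated in continuous time (exponential waiting times);
within each frame interval the displacement variance is integrated piecewise
over the time actually spent in each state, which is exact for the lateral
coordinates.  The axial coordinate performs the same random walk and reflects
at ±cell_half_depth; reflection is applied at frame resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import AcquisitionSettings, KineticParams
from .tracks import TrajectorySet


@dataclass(frozen=True)
class DwellSample:
    """Observed binding-event durations from slow tracking.

    ``durations`` are integer multiples of ``frame_interval`` (≥ 1 frame);
    ``censored`` flags events terminated by photobleaching rather than
    unbinding.
    """

    durations: np.ndarray
    censored: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        d = np.asarray(self.durations, float)
        if d.ndim != 1 or len(d) == 0:
            raise ValueError("durations must be a non-empty 1D array")
        if (d < self.frame_interval - 1e-9).any():
            raise ValueError("durations must be >= 1 frame_interval")
        frames = d / self.frame_interval
        if not np.allclose(frames, np.round(frames), atol=1e-6):
            raise ValueError("durations must be integer multiples of frame_interval")

    def __len__(self) -> int:
        return len(self.durations)


@dataclass(frozen=True)
class FrapGroundTruth:
    """Ground truth for a saturating-exponential FRAP recovery.

    The noiseless bleach-spot signal is 1 before the bleach and
    ``1 - bleach_depth * (1 - A * (1 - exp(-k t)))`` after it, so the
    recovered plateau sits ``bleach_depth * A`` above the bleach floor and the
    time to reach a fraction ``q`` of the recovery is ``-ln(1-q)/k``
    independent of depth and plateau.
    """

    k: float
    recovered_fraction: float = 1.0
    bleach_depth: float = 0.9
    noise_sd: float = 0.0
    sampling_rate: float = 1.0
    pre_bleach_frames: int = 10
    duration_s: float = 60.0
    acq_bleach_rate: float = 0.002

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("recovery rate k must be > 0")
        if not 0.0 <= self.recovered_fraction <= 1.0:
            raise ValueError("recovered_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 < self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must be in (0, 1]")
        if self.pre_bleach_frames < 3:
            raise ValueError("need >= 3 pre-bleach frames")
        if self.sampling_rate <= 0 or self.duration_s <= 0:
            raise ValueError("sampling_rate and duration_s must be > 0")


@dataclass(frozen=True)
class CellRenderSpec:
    """Geometry and photometry of a rendered two-channel mitotic cell.

    ``ratio`` is the true mean TF intensity on chromosomes over the mean TF
    intensity in the rest of the cell.  Intensities are scaled by
    ``photon_budget`` (expected photons per pixel at cytoplasm level) before
    Poisson noise.
    """

    shape: tuple[int, int] = (128, 128)
    pixel_size_um: float = 0.16
    cell_center: tuple[float, float] = (64.0, 64.0)
    cell_axes: tuple[float, float] = (50.0, 40.0)
    chrom_center: tuple[float, float] = (64.0, 64.0)
    chrom_axes: tuple[float, float] = (25.0, 20.0)
    ratio: float = 2.5
    photon_budget: float = 1000.0
    background: float = 0.1
    h2b_chrom_level: float = 2.0
    h2b_cyto_level: float = 0.15
    noise: str = "poisson"

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be > 0")
        if self.photon_budget <= 0:
            raise ValueError("photon_budget must be > 0")
        # chromosome ellipse strictly inside the cell ellipse, cell inside image
        th = np.linspace(0, 2 * np.pi, 256)
        cx = self.chrom_center[0] + self.chrom_axes[0] * np.cos(th)
        cy = self.chrom_center[1] + self.chrom_axes[1] * np.sin(th)
        u = (cx - self.cell_center[0]) / self.cell_axes[0]
        v = (cy - self.cell_center[1]) / self.cell_axes[1]
        if (u * u + v * v >= 1.0).any():
            raise ValueError("chromosome region must lie strictly inside the cell")
        for c, a, n in zip(self.cell_center, self.cell_axes, self.shape[::-1]):
            if c - a < 0 or c + a > n - 1:
                raise ValueError("cell region exceeds image bounds")


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    u = (xx - center[0]) / axes[0]
    v = (yy - center[1]) / axes[1]
    return u * u + v * v <= 1.0


# ---------------------------------------------------------------------------
# fast-tracking trajectory simulation
# ---------------------------------------------------------------------------

def _state_path_free_time(rng, m, frame_times, rate_bound, rate_free, p_bound):
    """Continuous-time alternating state paths for m particles.

    Returns ``free_time`` (m, K-1): seconds spent free within each frame
    interval; and ``bound_at_frame`` (m, K): state at each frame time.
    """
    K = len(frame_times)
    T = frame_times[-1]
    s0_bound = rng.random(m) < p_bound
    durs = []
    flags = []
    j = 0
    total = np.zeros(m)
    # draw alternating exponential interval durations until every particle's
    # event sequence extends past the movie (rate 0 -> infinite interval)
    while True:
        bound_now = s0_bound ^ (j % 2 == 1)
        rate = np.where(bound_now, rate_bound, rate_free)
        with np.errstate(divide="ignore"):
            d = np.where(rate > 0, -np.log(rng.random(m)) / np.maximum(rate, 1e-300),
                         np.inf)
        durs.append(d)
        flags.append(~bound_now)  # free flag of interval j
        total = total + d
        j += 1
        if np.min(total) > T or j > 10000:
            break
    dur = np.column_stack(durs)                       # (m, M)
    free = np.column_stack(flags)                     # (m, M)
    e = np.cumsum(dur, axis=1)                        # event times
    e0 = np.concatenate([np.zeros((m, 1)), e], axis=1)
    with np.errstate(invalid="ignore"):
        fc = np.cumsum(np.where(free, dur, 0.0), axis=1)
    fc0 = np.concatenate([np.zeros((m, 1)), fc], axis=1)

    # interval index containing each frame time
    idx = (e[:, :, None] <= frame_times[None, None, :]).sum(axis=1)  # (m, K)
    phi = (np.take_along_axis(fc0, idx, axis=1)
           + (frame_times[None, :] - np.take_along_axis(e0, idx, axis=1))
           * np.take_along_axis(free, np.minimum(idx, free.shape[1] - 1), axis=1))
    free_time = np.diff(phi, axis=1)
    bound_at_frame = ~np.take_along_axis(
        free, np.minimum(idx, free.shape[1] - 1), axis=1
    )
    return free_time, bound_at_frame


def _fold_reflect(z: np.ndarray, half_depth: float) -> np.ndarray:
    """Fold coordinates into [-half_depth, half_depth] (reflecting walls)."""
    period = 4.0 * half_depth
    w = np.mod(z + half_depth, period)
    w = np.minimum(w, period - w)
    return w - half_depth


def simulate_two_state_tracks(
    params: KineticParams,
    acq: AcquisitionSettings,
    n_particles: int,
    seed: int,
    chunk: int = 4096,
) -> TrajectorySet:
    """Simulate fast-tracking trajectories of two-state diffusing molecules.

    Each particle alternates bound/free states with exponential durations
    (rates ``k_off`` / ``k_on_star``), starting from the stationary state
    distribution.  Per frame interval the displacement per axis is Gaussian
    with variance ``2·(D_free·t_free + D_bound·t_bound)`` integrated over the
    continuous-time state path.  The axial coordinate performs the same walk,
    reflecting at ±cell_half_depth; a localization is emitted only while
    |z| ≤ slice_half_width.  Emitted x/y carry independent Gaussian
    localization error.  Photobleaching removes a particle permanently with
    per-frame probability ``1 - exp(-k_photobleach·Δt)``.  Detections
    separated by at most ``blink_max_gap`` missed frames share a
    trajectory id.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    rng = np.random.default_rng(seed)
    dt = acq.frame_interval
    nF = acq.n_frames
    frame_times = np.arange(nF) * dt
    p_bleach = 1.0 - np.exp(-params.k_photobleach * dt)

    frames_all = []
    x_all = []
    y_all = []
    state_all = []
    pid_all = []
    offset = 0
    for start in range(0, n_particles, chunk):
        m = min(chunk, n_particles - start)
        free_t, bound_at = _state_path_free_time(
            rng, m, frame_times, params.k_off, params.k_on_star,
            params.bound_fraction,
        )
        var = 2.0 * (params.d_free * free_t
                     + params.d_bound * np.clip(dt - free_t, 0.0, None))
        sd = np.sqrt(np.clip(var, 0.0, None))
        dx = rng.standard_normal((m, nF - 1)) * sd
        dy = rng.standard_normal((m, nF - 1)) * sd
        dz = rng.standard_normal((m, nF - 1)) * sd
        x0 = rng.uniform(0.0, acq.fov[0], m)
        y0 = rng.uniform(0.0, acq.fov[1], m)
        z0 = rng.uniform(-acq.cell_half_depth, acq.cell_half_depth, m)
        x = np.concatenate([x0[:, None], x0[:, None] + np.cumsum(dx, axis=1)], axis=1)
        y = np.concatenate([y0[:, None], y0[:, None] + np.cumsum(dy, axis=1)], axis=1)
        z = np.concatenate([z0[:, None], z0[:, None] + np.cumsum(dz, axis=1)], axis=1)
        z = _fold_reflect(z, acq.cell_half_depth)

        if p_bleach > 0:
            life = rng.geometric(p_bleach, m)
        else:
            life = np.full(m, nF, dtype=int)
        alive = np.arange(nF)[None, :] < life[:, None]
        detected = alive & (np.abs(z) <= acq.slice_half_width)

        pi, fi = np.nonzero(detected)
        if len(pi):
            xs = x[pi, fi] + rng.standard_normal(len(pi)) * params.sigma_loc
            ys = y[pi, fi] + rng.standard_normal(len(pi)) * params.sigma_loc
            pid_all.append(pi + start)
            frames_all.append(fi)
            x_all.append(xs)
            y_all.append(ys)
            state_all.append(bound_at[pi, fi])
        offset += m

    if not frames_all:
        df = pd.DataFrame(
            columns=["trajectory_id", "frame", "time_s", "x_um", "y_um", "true_state"]
        )
        return TrajectorySet(df=df, frame_interval=dt, source="simulated", seed=seed)

    pid = np.concatenate(pid_all)
    fr = np.concatenate(frames_all)
    # rows are already ordered by (particle, frame); split into trajectories
    # wherever the detection gap exceeds the blinking tolerance
    new = np.ones(len(pid), dtype=bool)
    same = pid[1:] == pid[:-1]
    gap_ok = (fr[1:] - fr[:-1]) <= acq.blink_max_gap + 1
    new[1:] = ~(same & gap_ok)
    traj = np.cumsum(new) - 1

    df = pd.DataFrame({
        "trajectory_id": traj,
        "frame": fr,
        "time_s": fr * dt,
        "x_um": np.concatenate(x_all),
        "y_um": np.concatenate(y_all),
        "true_state": np.where(np.concatenate(state_all), "bound", "free"),
    })
    return TrajectorySet(df=df, frame_interval=dt, source="simulated", seed=seed)


def simulate_jump_dataset(
    params: KineticParams,
    acq: AcquisitionSettings,
    n_jumps: int,
    seed: int,
    batch: int = 20000,
    max_batches: int = 200,
) -> TrajectorySet:
    """Simulate trajectories until at least ``n_jumps`` lag-1 jumps exist.

    Convenience wrapper used to build datasets of a prescribed size (e.g.
    "24 cells × 2000 jumps"); batches share one seed stream.
    """
    rng = np.random.default_rng(seed)
    parts = []
    total = 0
    next_id = 0
    for _ in range(max_batches):
        ts = simulate_two_state_tracks(
            params, acq, batch, int(rng.integers(0, 2**31 - 1))
        )
        df = ts.df.copy()
        df["trajectory_id"] = df["trajectory_id"] + next_id
        next_id = int(df["trajectory_id"].max()) + 1 if len(df) else next_id
        parts.append(df)
        g = df.groupby("trajectory_id")["frame"]
        total += int((g.diff() == 1).sum())
        if total >= n_jumps:
            break
    out = pd.concat(parts, ignore_index=True)
    return TrajectorySet(df=out, frame_interval=acq.frame_interval,
                         source="simulated", seed=seed)


# ---------------------------------------------------------------------------
# slow-tracking dwell samples
# ---------------------------------------------------------------------------

def simulate_slow_tracking_dwells(
    f_ns: float,
    k_ns: float,
    k_s: float,
    k_photobleach: float,
    acq: AcquisitionSettings,
    n_events: int,
    seed: int,
) -> DwellSample:
    """Draw observed dwell times of bound molecules under slow tracking.

    True binding durations follow the mixture
    ``f_ns·Exp(k_ns) + (1-f_ns)·Exp(k_s)`` (non-specific fast component and
    specific slow component); an independent photobleaching time is
    Exp(k_photobleach).  The observed dwell is the minimum of the two,
    floored to whole frames with a minimum of one frame; the censoring flag
    records whether bleaching ended the event.
    """
    if not (k_ns > k_s > 0):
        raise ValueError("component identifiability requires k_ns > k_s > 0")
    if not 0.0 <= f_ns <= 1.0:
        raise ValueError("f_ns must be in [0, 1]")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    dt = acq.frame_interval
    is_ns = rng.random(n_events) < f_ns
    rate = np.where(is_ns, k_ns, k_s)
    t_unbind = rng.exponential(1.0, n_events) / rate
    if k_photobleach > 0:
        t_bleach = rng.exponential(1.0 / k_photobleach, n_events)
    else:
        t_bleach = np.full(n_events, np.inf)
    obs = np.minimum(t_unbind, t_bleach)
    censored = t_bleach < t_unbind
    frames = np.maximum(1, np.floor(obs / dt).astype(int))
    return DwellSample(durations=frames * dt, censored=censored,
                       frame_interval=dt)


# ---------------------------------------------------------------------------
# FRAP curves
# ---------------------------------------------------------------------------

def simulate_frap_curve(gt: FrapGroundTruth, seed: int) -> pd.DataFrame:
    """Simulate a raw FRAP table ``time_s, spot, whole_cell, background``.

    The spot and whole-cell columns share a slow acquisition-bleaching decay
    and a constant camera background, so the standard double normalization
    recovers the underlying recovery curve exactly in the noiseless limit.
    Whole-cell and background traces average many pixels and carry 1/5 of the
    spot noise.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / gt.sampling_rate
    n_post = int(round(gt.duration_s * gt.sampling_rate))
    n = gt.pre_bleach_frames + n_post
    t = np.arange(n) * dt
    t_b = gt.pre_bleach_frames * dt
    rel = np.clip(t - t_b, 0.0, None)
    spot_true = np.where(
        t < t_b,
        1.0,
        1.0 - gt.bleach_depth
        * (1.0 - gt.recovered_fraction * (1.0 - np.exp(-gt.k * rel))),
    )
    i0, bg = 1000.0, 100.0
    decay = np.exp(-gt.acq_bleach_rate * t)
    spot = bg + i0 * decay * spot_true + rng.standard_normal(n) * gt.noise_sd * i0
    whole = bg + i0 * decay + rng.standard_normal(n) * gt.noise_sd * i0 / 5.0
    back = bg + rng.standard_normal(n) * gt.noise_sd * i0 / 5.0
    return pd.DataFrame(
        {"time_s": t, "spot": spot, "whole_cell": whole, "background": back}
    )


# ---------------------------------------------------------------------------
# two-channel cell images
# ---------------------------------------------------------------------------

def render_cell_image_pair(spec: CellRenderSpec, seed: int):
    """Render a two-channel (chromosome marker, TF) cell image with noise.

    Returns ``(pair, masks)`` where ``masks`` holds the ground-truth boolean
    cell and chromosome regions.  The TF channel has mean intensity
    ``spec.ratio``-fold higher inside the chromosome region than in the rest
    of the cell; Poisson noise is applied at ``spec.photon_budget`` expected
    photons per cytoplasm-level pixel.
    """
    from .enrichment import ImagePair  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    cell = _ellipse_mask(spec.shape, spec.cell_center, spec.cell_axes)
    chrom = _ellipse_mask(spec.shape, spec.chrom_center, spec.chrom_axes)

    # additive camera/ambient background everywhere, fluorescence on top
    tf = np.full(spec.shape, spec.background)
    tf[cell] += 1.0
    tf[chrom] += spec.ratio - 1.0
    h2b = np.full(spec.shape, spec.background / 2.0)
    h2b[cell] += spec.h2b_cyto_level
    h2b[chrom] += spec.h2b_chrom_level - spec.h2b_cyto_level

    if spec.noise == "poisson":
        tf_img = rng.poisson(tf * spec.photon_budget).astype(float)
        h2b_img = rng.poisson(h2b * spec.photon_budget).astype(float)
    elif spec.noise == "none":
        tf_img = tf * spec.photon_budget
        h2b_img = h2b * spec.photon_budget
    else:
        raise ValueError(f"unknown noise model {spec.noise!r}")

    pair = ImagePair(h2b=h2b_img, tf=tf_img, pixel_size_um=spec.pixel_size_um)
    return pair, {"cell": cell, "chromosome": chrom}


def true_log2_enrichment(spec: CellRenderSpec) -> float:
    """Ground-truth log2(mean TF on chromosomes / mean TF over whole cell)."""
    cell = _ellipse_mask(spec.shape, spec.cell_center, spec.cell_axes)
    chrom = _ellipse_mask(spec.shape, spec.chrom_center, spec.chrom_axes)
    a = chrom.sum() / cell.sum()
    mean_cell = a * spec.ratio + (1.0 - a) * 1.0
    return float(np.log2(spec.ratio / mean_cell))


__all__ = [
    "DwellSample", "FrapGroundTruth", "CellRenderSpec",
    "simulate_two_state_tracks", "simulate_jump_dataset",
    "simulate_slow_tracking_dwells", "simulate_frap_curve",
    "render_cell_image_pair", "true_log2_enrichment",
]
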