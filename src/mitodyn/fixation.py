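"""Stochastic particle model of the formaldehyde-fixation artifact.

Transcription factors exchange dynamically on mitotic chromosomes with
intrinsic binding (k_on*) and unbinding (k_off) rates.  When a chemical
fixative is added to the medium it diffuses in through the cell membrane and
crosslinks (immobilizes) molecules where it finds them, producing an
inward-moving crosslinking front: the cytoplasmic pool is fixed first, the
chromosome region last.  During that window bound molecules keep unbinding
into a pool that can no longer rebind in kind, so the apparent chromosome
enrichment of a dynamic factor decays before fixation completes — an
artifact, since the live steady state was enriched.

Geometry is two concentric discs (chromosome disc of radius ``r_chromosome``
inside a cell disc of radius ``r_cell``).  The fixative concentration follows
a 1D inward-diffusion profile along the radial depth,
``C(r, t) = C0 · erfc((R_cell - r)/√(4·D_pfa·t))``, and each mobile particle
acquires crosslinks with hazard ``k_x · C`` after which it is frozen at its
position and state forever.  The ``uniform_instant`` mode freezes every
particle simultaneously at t = 0 (the high-pressure-freezing control), which
preserves the initial enrichment exactly.

The reported enrichment is the same statistic the imaging stage computes:
mean particle density inside the chromosome disc over mean density in the
whole cell.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import erfc


@dataclass(frozen=True)
class FixationConfig:
    """Geometry, kinetics and fixation parameters of one simulation.

    ``c0`` is the fixative dose in relative units (1.0 ≡ 1% PFA);
    ``k_x`` the crosslinking rate constant per unit dose (1/s);
    ``d_pfa`` the *effective* diffusivity of the crosslinking front (µm²/s).
    Free formaldehyde diffuses orders of magnitude faster, but it is consumed
    by crosslinking as it enters, so the reactive front advances far more
    slowly than free diffusion; the default (0.2 µm²/s) makes the front cross
    the cytoplasmic depth on the tens-of-seconds timescale observed in
    fixative-addition movies.  The time step must satisfy
    ``dt ≤ 0.1 / max(k_off, k_on_star, k_x·c0)`` for the per-step
    exponential hazards to be accurate.
    """

    r_cell: float = 8.0
    r_chromosome: float = 4.0
    d_free: float = 2.0
    k_on_star: float = 2.0
    k_off: float = 0.5
    c0: float = 1.0
    d_pfa: float = 0.2
    k_x: float = 0.2
    n_particles: int = 2000
    duration_s: float = 70.0
    dt: float = 0.05
    mode: str = "gradient"
    seed: int = 0
    record_every: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.r_chromosome < self.r_cell:
            raise ValueError("require 0 < r_chromosome < r_cell")
        for name in ("d_free", "k_on_star", "k_off", "c0", "d_pfa", "k_x"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mode not in ("gradient", "uniform_instant"):
            raise ValueError("mode must be 'gradient' or 'uniform_instant'")
        if self.n_particles < 1 or self.duration_s <= 0 or self.dt <= 0:
            raise ValueError("n_particles, duration_s, dt must be positive")
        max_rate = max(self.k_off, self.k_on_star, self.k_x * self.c0)
        if max_rate > 0 and self.dt > 0.1 / max_rate:
            raise ValueError(
                f"dt={self.dt} too coarse: require dt <= {0.1 / max_rate:.4g} "
                "(0.1 / fastest rate) for stable per-step hazards"
            )


@dataclass
class FixationTrace:
    """Time course of apparent enrichment during fixation.

    Columns: ``time_s``, ``enrichment`` (density in chromosome disc over
    cell-average density), ``frac_crosslinked``, ``frac_bound`` (among
    non-crosslinked particles; NaN once all are crosslinked).
    """

    frames: pd.DataFrame
    config: FixationConfig

    def __post_init__(self) -> None:
        fx = self.frames["frac_crosslinked"].to_numpy()
        if (np.diff(fx) < -1e-12).any():
            raise ValueError("fraction crosslinked must be non-decreasing")

    def enrichment_at(self, t: float) -> float:
        f = self.frames
        return float(np.interp(t, f["time_s"], f["enrichment"]))


def pfa_concentration(radius_from_center, t: float,
                      cfg: FixationConfig) -> np.ndarray:
    """Fixative dose at radius r and time t (1D inward-diffusion profile).

    ``C = C0 · erfc((R_cell − r) / √(4·D_pfa·t))`` for t > 0; at t = 0 the
    interior is unexposed (C = 0 for r < R_cell, C0 at the membrane).
    """
    r = np.asarray(radius_from_center, float)
    if (r < 0).any() or (r > cfg.r_cell + 1e-9).any():
        raise ValueError("radius must lie in [0, r_cell]")
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0 or cfg.d_pfa == 0:
        return np.where(r >= cfg.r_cell, cfg.c0, 0.0)
    depth = cfg.r_cell - r
    return cfg.c0 * erfc(depth / np.sqrt(4.0 * cfg.d_pfa * t))


def _stationary_init(cfg: FixationConfig, rng: np.random.Generator):
    """Positions/states at the binding-kinetics steady state.

    Free molecules are uniform over the cell; bound molecules sit on top
    inside the chromosome disc with local ratio bound/free = k_on*/k_off.
    """
    a_cell = np.pi * cfg.r_cell**2
    a_chr = np.pi * cfg.r_chromosome**2
    ratio = cfg.k_on_star / cfg.k_off if cfg.k_off > 0 else np.inf
    if np.isinf(ratio):
        p_bound = 1.0
    else:
        p_bound = ratio * a_chr / (a_cell + ratio * a_chr)
    bound = rng.random(cfg.n_particles) < p_bound

    def uniform_disc(n, radius):
        r = radius * np.sqrt(rng.random(n))
        th = rng.uniform(0, 2 * np.pi, n)
        return r * np.cos(th), r * np.sin(th)

    x = np.empty(cfg.n_particles)
    y = np.empty(cfg.n_particles)
    nb = int(bound.sum())
    x[bound], y[bound] = uniform_disc(nb, cfg.r_chromosome)
    x[~bound], y[~bound] = uniform_disc(cfg.n_particles - nb, cfg.r_cell)
    return x, y, bound


def _reflect_disc(x, y, radius):
    r = np.hypot(x, y)
    out = r > radius
    if out.any():
        r_new = 2 * radius - r[out]
        r_new = np.clip(r_new, 0.0, radius)
        scale = r_new / r[out]
        x[out] *= scale
        y[out] *= scale
    return x, y


def _run_fixation(cfg: FixationConfig, on_state=None) -> FixationTrace:
    """Core particle loop; ``on_state(t, x, y, bound, crosslinked)`` is
    called at every recorded time point."""
    rng = np.random.default_rng(cfg.seed)
    x, y, bound = _stationary_init(cfg, rng)
    crosslinked = np.zeros(cfg.n_particles, dtype=bool)
    a_ratio = cfg.r_chromosome**2 / cfg.r_cell**2

    if cfg.mode == "uniform_instant":
        crosslinked[:] = True

    n_steps = int(round(cfg.duration_s / cfg.dt))
    sd = np.sqrt(2.0 * cfg.d_free * cfg.dt)
    p_bind = 1.0 - np.exp(-cfg.k_on_star * cfg.dt)
    p_unbind = 1.0 - np.exp(-cfg.k_off * cfg.dt)

    rows = []

    def record(t):
        in_disc = np.hypot(x, y) <= cfg.r_chromosome
        mobile = ~crosslinked
        fb = float(bound[mobile].mean()) if mobile.any() else np.nan
        rows.append((t, float(in_disc.mean() / a_ratio),
                     float(crosslinked.mean()), fb))
        if on_state is not None:
            on_state(t, x, y, bound, crosslinked)

    record(0.0)
    for step in range(1, n_steps + 1):
        t = step * cfg.dt
        mobile = ~crosslinked
        free = mobile & ~bound
        # diffusion of mobile free particles
        idx = np.nonzero(free)[0]
        if len(idx):
            x[idx] += rng.standard_normal(len(idx)) * sd
            y[idx] += rng.standard_normal(len(idx)) * sd
            x_i, y_i = _reflect_disc(x[idx], y[idx], cfg.r_cell)
            x[idx], y[idx] = x_i, y_i
            # binding while inside the chromosome disc
            inside = np.hypot(x[idx], y[idx]) <= cfg.r_chromosome
            u = rng.random(len(idx))
            bound[idx[inside & (u < p_bind)]] = True
        # unbinding of mobile bound particles
        idx_b = np.nonzero(mobile & bound)[0]
        if len(idx_b):
            u = rng.random(len(idx_b))
            bound[idx_b[u < p_unbind]] = False
        # crosslinking by the advancing fixative front
        if cfg.mode == "gradient" and cfg.k_x > 0 and cfg.c0 > 0:
            idx_m = np.nonzero(mobile)[0]
            if len(idx_m):
                r = np.clip(np.hypot(x[idx_m], y[idx_m]), 0, cfg.r_cell)
                c = pfa_concentration(r, t, cfg)
                p_x = 1.0 - np.exp(-cfg.k_x * c * cfg.dt)
                u = rng.random(len(idx_m))
                crosslinked[idx_m[u < p_x]] = True
        if step % cfg.record_every == 0 or step == n_steps:
            record(t)

    frames = pd.DataFrame(
        rows, columns=["time_s", "enrichment", "frac_crosslinked", "frac_bound"]
    )
    return FixationTrace(frames=frames, config=cfg)


def simulate_fixation(cfg: FixationConfig) -> FixationTrace:
    """Run the fixation particle simulation and record the enrichment trace.

    Fixative addition is at t = 0.  Per step: free particles diffuse
    (reflecting at the cell boundary) and bind with hazard k_on* while inside
    the chromosome disc; bound particles unbind with hazard k_off; every
    non-crosslinked particle crosslinks with hazard k_x·C(r, t) and is then
    immobilized at its current position and state forever.  In
    ``uniform_instant`` mode all particles are immobilized at t = 0.
    """
    return _run_fixation(cfg)


def dose_response(
    cfg: FixationConfig,
    doses: list[float],
    replicates: int = 10,
    query_time_s: float = 60.0,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """Enrichment at ``query_time_s`` after addition across fixative doses.

    Runs ``replicates`` independent simulations per dose (seeds derived
    deterministically from ``base_seed`` or ``cfg.seed``) and reports the
    mean and standard error per dose.
    """
    if len(doses) < 2:
        raise ValueError("need at least 2 doses")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    root = np.random.default_rng(cfg.seed if base_seed is None else base_seed)
    seeds = root.integers(0, 2**31 - 1, size=(len(doses), replicates))
    out = []
    for i, dose in enumerate(doses):
        vals = []
        for j in range(replicates):
            run = replace(cfg, c0=float(dose), seed=int(seeds[i, j]))
            trace = simulate_fixation(run)
            vals.append(trace.enrichment_at(query_time_s))
        vals = np.asarray(vals)
        out.append((dose, vals.mean(), vals.std(ddof=1) / np.sqrt(len(vals))))
    return pd.DataFrame(out, columns=["dose", "enrichment_mean", "enrichment_se"])


def render_snapshot(x, y, cfg: FixationConfig, shape=(128, 128),
                    photon_budget: float = 200.0, seed: int = 0,
                    smooth_px: float = 2.0):
    """Render particle positions as a two-channel image pair.

    The TF channel is the (smoothed) particle density scaled to
    ``photon_budget`` photons per particle-average pixel with Poisson noise;
    the H2B channel marks the chromosome disc.  Used to round-trip the
    simulator output through the imaging quantification.
    """
    from scipy.ndimage import gaussian_filter

    from .enrichment import ImagePair

    rng = np.random.default_rng(seed)
    half = cfg.r_cell
    px = 2 * half / shape[0]
    counts, _, _ = np.histogram2d(
        np.asarray(y), np.asarray(x),
        bins=shape, range=[[-half, half], [-half, half]],
    )
    dens = gaussian_filter(counts, smooth_px)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cx = (xx + 0.5) * px - half
    cy = (yy + 0.5) * px - half
    rr = np.hypot(cx, cy)
    in_cell = rr <= cfg.r_cell
    in_chr = rr <= cfg.r_chromosome
    mean_in_cell = dens[in_cell].mean()
    tf_level = np.where(in_cell, dens / max(mean_in_cell, 1e-12), 0.02)
    h2b_level = np.where(in_chr, 2.0, np.where(in_cell, 0.15, 0.02))
    tf_img = rng.poisson(np.clip(tf_level, 0, None) * photon_budget).astype(float)
    h2b_img = rng.poisson(h2b_level * photon_budget).astype(float)
    return ImagePair(h2b=h2b_img, tf=tf_img, pixel_size_um=px)


def simulate_fixation_with_snapshots(cfg: FixationConfig, snapshot_times,
                                     **render_kwargs):
    """Run the simulation, returning (trace, rendered image pairs).

    Snapshots are rendered at the first recorded time at or after each
    requested time; the images and the trace describe the same realization.
    """
    want = sorted(float(t) for t in snapshot_times)
    snaps: list = []
    render_seed = render_kwargs.pop("seed", cfg.seed + 1)

    def on_state(t, x, y, bound, crosslinked):
        while want and t >= want[0] - cfg.dt / 2:
            pair = render_snapshot(x, y, cfg, seed=render_seed + len(snaps),
                                   **render_kwargs)
            pair.frame_time_s = t
            snaps.append(pair)
            want.pop(0)

    trace = _run_fixation(cfg, on_state=on_state)
    return trace, snaps


__all__ = [
    "FixationConfig", "FixationTrace", "pfa_concentration",
    "simulate_fixation", "dose_response", "render_snapshot",
    "simulate_fixation_with_snapshots",
]
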