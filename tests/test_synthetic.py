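"""Statistical correctness of the synthetic-data generators."""

import numpy as np
import pytest
from scipy import stats

from mitodyn import (
    FAST_TRACKING,
    SLOW_TRACKING,
    AcquisitionSettings,
    KineticParams,
    render_cell_image_pair,
    simulate_frap_curve,
    simulate_slow_tracking_dwells,
    simulate_two_state_tracks,
    true_log2_enrichment,
)
from mitodyn.synthetic import CellRenderSpec, FrapGroundTruth


def lag1_squared_jumps(ts):
    out = []
    for _, sub in ts.groupby():
        fr = sub["frame"].to_numpy()
        ok = np.diff(fr) == 1
        dx = np.diff(sub["x_um"].to_numpy())
        dy = np.diff(sub["y_um"].to_numpy())
        out.append((dx**2 + dy**2)[ok])
    return np.concatenate(out) if out else np.array([])


class TestTwoStateTracks:
    def test_no_motion_no_noise_gives_zero_jumps(self):
        p = KineticParams(d_free=0.0, d_bound=0.0, k_on_star=0.1, k_off=0.1,
                          sigma_loc=0.0)
        ts = simulate_two_state_tracks(p, AcquisitionSettings(n_frames=20),
                                       200, seed=1)
        assert len(ts) > 0
        assert lag1_squared_jumps(ts).max() == 0.0

    def test_stationary_bound_fraction(self):
        # stationary fraction k_on*/(k_on*+k_off) = 0.309 recovered within
        # 3 binomial SE over >= 1e4 particle-frames
        p = KineticParams(d_free=2.0, d_bound=0.01, k_on_star=0.309,
                          k_off=0.691, sigma_loc=0.035)
        ts = simulate_two_state_tracks(p, AcquisitionSettings(n_frames=50),
                                       10000, seed=2)
        frac = (ts.df["true_state"] == "bound").mean()
        n = len(ts)
        assert n >= 10000
        assert abs(frac - 0.309) < 3 * np.sqrt(0.309 * 0.691 / n)

    def test_free_only_mean_squared_jump(self):
        # closed form: E[r^2] = 4 D dt + 4 sigma^2 for a free diffuser
        # (z confined to the slice so no defocus censoring biases the mean)
        p = KineticParams(d_free=2.0, d_bound=0.0, k_on_star=0.0, k_off=1.0,
                          sigma_loc=0.035)
        acq = AcquisitionSettings(n_frames=60, cell_half_depth=0.4,
                                  slice_half_width=0.4)
        ts = simulate_two_state_tracks(p, acq, 5000, seed=3)
        j2 = lag1_squared_jumps(ts)
        assert len(j2) >= 1e5
        expected = 4 * 2.0 * acq.frame_interval + 4 * 0.035**2
        se = j2.std(ddof=1) / np.sqrt(len(j2))
        assert abs(j2.mean() - expected) < 3 * se

    def test_free_only_jumps_match_rayleigh(self):
        # jump lengths of a free-only simulation follow the Rayleigh law with
        # scale^2 = 2 (D dt + sigma^2) (chi-square goodness of fit)
        p = KineticParams(d_free=2.0, d_bound=0.0, k_on_star=0.0, k_off=1.0,
                          sigma_loc=0.035)
        acq = AcquisitionSettings(n_frames=60, cell_half_depth=0.4,
                                  slice_half_width=0.4)
        ts = simulate_two_state_tracks(p, acq, 5000, seed=4)
        r = np.sqrt(lag1_squared_jumps(ts))
        assert len(r) >= 1e5
        scale = np.sqrt(2 * (2.0 * acq.frame_interval + 0.035**2))
        edges = stats.rayleigh.ppf(np.linspace(0.02, 0.98, 25), scale=scale)
        obs, _ = np.histogram(r, bins=edges)
        probs = np.diff(stats.rayleigh.cdf(edges, scale=scale))
        exp = probs / probs.sum() * obs.sum()
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p_val = stats.chi2.sf(chi2, df=len(obs) - 1)
        assert p_val > 0.001

    def test_bleach_survival_is_exponential(self):
        # a never-unbinding, always-in-slice species disappears only by
        # photobleaching: per-frame geometric lifetime ~ Exp(k_pb)
        p = KineticParams(d_free=0.01, d_bound=0.01, k_on_star=1.0, k_off=0.0,
                          sigma_loc=0.0, k_photobleach=2.0)
        acq = AcquisitionSettings(n_frames=3000, frame_interval=0.0045,
                                  cell_half_depth=0.4, slice_half_width=0.4)
        ts = simulate_two_state_tracks(p, acq, 4000, seed=5)
        lengths = ts.track_lengths().to_numpy()
        # geometric with p = 1 - exp(-k dt); KS against the geometric CDF
        prob = 1 - np.exp(-2.0 * acq.frame_interval)
        grid = np.arange(1, lengths.max() + 1)
        emp = (lengths[None, :] >= grid[:, None]).mean(axis=1)
        theo = (1 - prob) ** (grid - 1)
        assert np.max(np.abs(emp - theo)) < 1.5 / np.sqrt(len(lengths))

    def test_blink_gap_never_exceeded_within_trajectory(self, interphase_tracks):
        for _, sub in interphase_tracks.groupby():
            gaps = np.diff(sub["frame"].to_numpy())
            assert (gaps <= FAST_TRACKING.blink_max_gap + 1).all()

    def test_seed_reproducibility_byte_for_byte(self, tmp_path):
        p = KineticParams(d_free=2.0, d_bound=0.01, k_on_star=0.3, k_off=0.7)
        acq = AcquisitionSettings(n_frames=30)
        paths = []
        for i in range(2):
            ts = simulate_two_state_tracks(p, acq, 300, seed=77)
            f = tmp_path / f"run{i}.csv"
            ts.write_csv(f)
            paths.append(f.read_bytes())
        assert paths[0] == paths[1]

    def test_rejects_zero_particles(self):
        p = KineticParams(d_free=1.0, d_bound=0.0, k_on_star=0.1, k_off=0.1)
        with pytest.raises(ValueError, match="n_particles"):
            simulate_two_state_tracks(p, AcquisitionSettings(), 0, seed=0)


class TestDwellGenerator:
    def test_single_exponential_null(self):
        # k_pb=0, f_ns=0: dwell survival matches Exp(k_s) on the frame grid
        dw = simulate_slow_tracking_dwells(0.0, 2.0, 0.2, 0.0, SLOW_TRACKING,
                                           5000, seed=1)
        dt = dw.frame_interval
        frames = np.round(dw.durations / dt).astype(int)
        grid = np.arange(2, 40)
        emp = (frames[None, :] >= grid[:, None]).mean(axis=1)
        theo = np.exp(-0.2 * grid * dt)
        assert np.max(np.abs(emp - theo)) < 1.7 / np.sqrt(len(frames))

    def test_min_of_exponentials(self):
        # competing risks: unbinding Exp(0.2) + bleaching Exp(0.1) -> Exp(0.3)
        dw = simulate_slow_tracking_dwells(0.0, 2.0, 0.2, 0.1, SLOW_TRACKING,
                                           8000, seed=2)
        frames = np.round(dw.durations / dw.frame_interval).astype(int)
        grid = np.arange(2, 30)
        emp = (frames[None, :] >= grid[:, None]).mean(axis=1)
        theo = np.exp(-0.3 * grid * dw.frame_interval)
        assert np.max(np.abs(emp - theo)) < 1.7 / np.sqrt(len(frames))
        # censoring flag frequency ~ k_pb/(k_s+k_pb) = 1/3
        assert abs(dw.censored.mean() - 1 / 3) < 0.03

    def test_durations_are_frame_multiples_with_minimum(self):
        dw = simulate_slow_tracking_dwells(0.7, 2.0, 0.08, 0.05, SLOW_TRACKING,
                                           2000, seed=3)
        frames = dw.durations / dw.frame_interval
        assert np.allclose(frames, np.round(frames))
        assert frames.min() >= 1

    def test_rejects_unidentifiable_components(self):
        with pytest.raises(ValueError, match="identifiability"):
            simulate_slow_tracking_dwells(0.5, 0.1, 0.2, 0.0, SLOW_TRACKING,
                                          10, seed=0)


class TestFrapGenerator:
    def test_noiseless_curve_matches_closed_form(self):
        # sampled at t90 = ln(10)/k, the noiseless curve sits exactly at 90%
        # of the recovery above the bleach floor
        k = np.log(10)  # so t90 = 1.0 s falls exactly on the 1 Hz grid
        gt = FrapGroundTruth(k=k, recovered_fraction=1.0, noise_sd=0.0,
                             acq_bleach_rate=0.0)
        df = simulate_frap_curve(gt, 0)
        norm = (df["spot"] - df["background"]) / (df["whole_cell"] - df["background"])
        t = df["time_s"].to_numpy() - gt.pre_bleach_frames
        rel = np.clip(t, 0, None)
        expected = np.where(t < 0, 1.0,
                            1 - gt.bleach_depth * np.exp(-k * rel))
        np.testing.assert_allclose(norm, expected, atol=1e-9)
        floor = 1 - gt.bleach_depth
        at_t90 = norm[t == 1.0].iloc[0]
        assert at_t90 == pytest.approx(floor + 0.9 * (1.0 - floor), abs=1e-12)

    def test_zero_recovery_flat_at_floor(self):
        gt = FrapGroundTruth(k=0.5, recovered_fraction=0.0, noise_sd=0.0,
                             acq_bleach_rate=0.0)
        df = simulate_frap_curve(gt, 0)
        norm = (df["spot"] - df["background"]) / (df["whole_cell"] - df["background"])
        post = norm[gt.pre_bleach_frames :]
        assert np.allclose(post, 1 - gt.bleach_depth, atol=1e-12)

    def test_reproducible(self):
        gt = FrapGroundTruth(k=0.5, noise_sd=0.02)
        a = simulate_frap_curve(gt, 5)
        b = simulate_frap_curve(gt, 5)
        assert a.equals(b)


class TestImageRenderer:
    def test_uniform_ratio_means_match_inside_and_out(self):
        spec = CellRenderSpec(ratio=1.0, photon_budget=1000)
        pair, masks = render_cell_image_pair(spec, seed=1)
        inside = pair.tf[masks["chromosome"]]
        outside = pair.tf[masks["cell"] & ~masks["chromosome"]]
        se = np.sqrt(inside.var() / len(inside) + outside.var() / len(outside))
        assert abs(inside.mean() - outside.mean()) < 4 * se

    def test_ground_truth_enrichment_arithmetic(self):
        # rho=2.5 over ~25% of the cell area:
        # log2(2.5 / (0.25*2.5 + 0.75)) = log2(1.8182) ~ 0.8625; the
        # rasterized ellipse area deviates from exactly 25% by <1%
        spec = CellRenderSpec(ratio=2.5)
        assert true_log2_enrichment(spec) == pytest.approx(0.8625, abs=0.01)
        from mitodyn.synthetic import _ellipse_mask

        cell = _ellipse_mask(spec.shape, spec.cell_center, spec.cell_axes)
        chrom = _ellipse_mask(spec.shape, spec.chrom_center, spec.chrom_axes)
        a = chrom.sum() / cell.sum()
        exact = np.log2(2.5 / (a * 2.5 + (1 - a)))
        assert true_log2_enrichment(spec) == pytest.approx(exact, abs=1e-12)

    def test_rejects_region_outside_cell(self):
        with pytest.raises(ValueError, match="inside the cell"):
            CellRenderSpec(chrom_axes=(60.0, 20.0))

    def test_reproducible(self):
        spec = CellRenderSpec()
        a, _ = render_cell_image_pair(spec, seed=9)
        b, _ = render_cell_image_pair(spec, seed=9)
        assert np.array_equal(a.tf, b.tf) and np.array_equal(a.h2b, b.h2b)
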