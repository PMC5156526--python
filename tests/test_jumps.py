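"""Two-state jump-length model: Z_CORR, densities, histograms, fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from mitodyn import (
    FAST_TRACKING,
    DetectionSlice,
    KineticParams,
    TwoStateJumpModel,
    corrected_dz,
    fit_two_state,
    jump_histogram,
    simulate_jump_dataset,
    two_state_density,
    z_corr,
)
from mitodyn.jumps import monte_carlo_z_survival
from mitodyn.tracks import TrajectorySet


def toy_tracks(rows, dt=0.0045):
    df = pd.DataFrame(rows, columns=["trajectory_id", "frame", "x_um", "y_um"])
    df["time_s"] = df["frame"] * dt
    return TrajectorySet(df=df, frame_interval=dt)


class TestCorrectedDz:
    def test_printed_constants_at_zero(self):
        assert corrected_dz(0.0) == pytest.approx(0.90811)

    def test_printed_constants_at_four(self):
        assert corrected_dz(4.0) == pytest.approx(1.22243)

    @given(st.floats(min_value=0.0, max_value=20.0),
           st.floats(min_value=0.0, max_value=20.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_d(self, d1, d2):
        lo, hi = sorted([d1, d2])
        assert corrected_dz(lo) <= corrected_dz(hi)


class TestZCorr:
    def test_immobile_molecules_never_defocus(self):
        assert z_corr(0.0, 0.0135) == 1.0

    def test_very_fast_diffusion_escapes(self):
        assert z_corr(1e6, 0.0135) < 0.01

    def test_matches_monte_carlo_oracle(self):
        # independent brute-force Brownian absorption simulation
        val = z_corr(2.0, 0.0135)
        mc = monte_carlo_z_survival(2.0, 0.0135, corrected_dz(2.0),
                                    n_paths=100_000, n_steps=200, seed=1)
        assert val == pytest.approx(mc, rel=0.01)

    def test_bounds_and_monotonicity_grid(self):
        taus = [0.0045, 0.009, 0.0135, 0.0225, 0.0315]
        ds = [0.2, 0.5, 1.0, 2.0, 5.0, 10.0]
        vals = np.array([[z_corr(d, t) for t in taus] for d in ds])
        assert ((vals >= 0) & (vals <= 1)).all()
        assert (np.diff(vals, axis=0) <= 1e-12).all()  # decreasing in D
        assert (np.diff(vals, axis=1) <= 1e-12).all()  # decreasing in tau


class TestDensity:
    def test_zero_at_origin(self):
        assert two_state_density(0.0, 0.0135, 0.3, 2.0, 0.01, 0.035) == 0.0

    def test_argmax_of_pure_bound_component(self):
        dtau, db, sg = 0.0135, 0.01, 0.035
        r = np.linspace(1e-4, 0.3, 20000)
        dens = two_state_density(r, dtau, 1.0, 2.0, db, sg)
        expected = np.sqrt(2 * (db * dtau + sg**2))
        assert r[np.argmax(dens)] == pytest.approx(expected, rel=1e-3)

    def test_unnormalized_mass_is_f_plus_zcorr_terms(self):
        f, df_, db, sg, dtau = 0.3, 2.0, 0.01, 0.035, 0.0135
        total, _ = quad(
            lambda r: two_state_density(r, dtau, f, df_, db, sg), 0, np.inf,
            limit=200,
        )
        zc = z_corr(df_, dtau)
        assert total == pytest.approx(f + zc * (1 - f), abs=1e-6)

    @given(st.floats(0.05, 0.95), st.floats(0.5, 10.0), st.floats(1e-3, 0.09),
           st.floats(0.02, 0.06))
    @settings(max_examples=25, deadline=None)
    def test_normalized_density_integrates_to_one(self, f, df_, db, sg):
        total, _ = quad(
            lambda r: two_state_density(r, 0.0135, f, df_, db, sg,
                                        normalized=True),
            0, np.inf, limit=200,
        )
        assert total == pytest.approx(1.0, abs=1e-6)


class TestJumpHistogram:
    def test_single_pair_lands_in_right_bin(self):
        ts = toy_tracks([(0, 0, 0.0, 0.0), (0, 1, 0.1, 0.0)])
        h = jump_histogram(ts, lags=(1,), bin_width=0.01)
        edges, dens, n = h.lags[0.0045]
        assert n == 1
        bin_idx = int(np.digitize(0.1, edges)) - 1
        assert dens[bin_idx] > 0
        assert (dens > 0).sum() == 1

    def test_static_particles_fill_first_bin(self):
        rows = [(i, f, 1.0 * i, 2.0) for i in range(5) for f in range(10)]
        h = jump_histogram(toy_tracks(rows), lags=(1, 2))
        for tau, (edges, dens, n) in h.lags.items():
            assert dens[0] * (edges[1] - edges[0]) == pytest.approx(1.0)

    def test_pairs_spanning_blink_gaps_skipped(self):
        # frames 0,1,3: lag-2 pair (1,3) spans a missing frame and is skipped
        ts = toy_tracks([(0, 0, 0.0, 0.0), (0, 1, 0.1, 0.0), (0, 3, 0.3, 0.0)])
        with pytest.warns(UserWarning):
            h = jump_histogram(ts, lags=(1, 2))
        assert 0.0045 in h.lags
        assert h.lags[0.0045][2] == 1  # only the (0,1) pair
        assert 0.009 not in h.lags

    def test_empty_lags_rejected(self):
        ts = toy_tracks([(0, 0, 0.0, 0.0)])
        with pytest.raises(ValueError, match="no lag"):
            with pytest.warns(UserWarning):
                jump_histogram(ts, lags=(1,))

    def test_mean_squared_jump_matches_closed_form(self):
        p = KineticParams(d_free=2.0, d_bound=0.0, k_on_star=0.0, k_off=1.0,
                          sigma_loc=0.035)
        from mitodyn.params import AcquisitionSettings

        acq = AcquisitionSettings(n_frames=60, cell_half_depth=0.4,
                                  slice_half_width=0.4)
        from mitodyn.synthetic import simulate_two_state_tracks

        ts = simulate_two_state_tracks(p, acq, 3000, seed=6)
        h = jump_histogram(ts, lags=(1, 2, 3), r_max=2.0, bin_width=0.005)
        for k in (1, 2, 3):
            edges, dens, n = h.lags[k * acq.frame_interval]
            centers = 0.5 * (edges[:-1] + edges[1:])
            m2 = float((dens * centers**2 * np.diff(edges)).sum())
            expected = 4 * (2.0 * k * acq.frame_interval + 0.035**2)
            assert m2 == pytest.approx(expected, rel=0.05)


class TestTwoStateFitting:
    def test_all_bound_recovered_at_boundary(self):
        p = KineticParams(d_free=2.0, d_bound=0.01, k_on_star=1.0, k_off=0.0,
                          sigma_loc=0.035, k_photobleach=4.0)
        ts = simulate_jump_dataset(p, FAST_TRACKING, 20000, seed=8,
                                   batch=3000)
        model = TwoStateJumpModel().fit(ts)
        assert model.converged_
        assert model.f_bound_ >= 0.97

    def test_recovery_on_mixed_population(self, interphase_tracks):
        model = TwoStateJumpModel().fit(interphase_tracks)
        assert model.converged_
        assert model.f_bound_ == pytest.approx(0.309, abs=0.05)
        assert model.d_free_ == pytest.approx(2.0, rel=0.2)

    def test_bin_width_halving_stability(self, interphase_tracks):
        a = TwoStateJumpModel(bin_width=0.01).fit(interphase_tracks)
        b = TwoStateJumpModel(bin_width=0.005).fit(interphase_tracks)
        assert abs(a.f_bound_ - b.f_bound_) <= 0.01

    def test_needs_two_lags(self, interphase_tracks):
        h = jump_histogram(interphase_tracks, lags=(1,))
        with pytest.raises(ValueError, match="2 lags"):
            fit_two_state(h)

    def test_sigma_fit_option_stays_near_truth(self, interphase_tracks):
        model = TwoStateJumpModel(sigma="fit").fit(interphase_tracks)
        assert 0.02 <= model.sigma_ <= 0.06
        assert model.f_bound_ == pytest.approx(0.309, abs=0.06)

    def test_deterministic_given_random_state(self, interphase_tracks):
        a = TwoStateJumpModel(random_state=3).fit(interphase_tracks)
        b = TwoStateJumpModel(random_state=3).fit(interphase_tracks)
        assert a.f_bound_ == b.f_bound_ and a.d_free_ == b.d_free_

    def test_detection_slice_invariants(self):
        with pytest.raises(ValueError):
            DetectionSlice(dz_nominal=-1.0)
        with pytest.raises(ValueError):
            DetectionSlice(quadrature_points=8)
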