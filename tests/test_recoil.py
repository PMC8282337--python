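"""Interface-length series, retraction velocity and the Kelvin-Voigt fit."""

import numpy as np
import pytest

from epimech.recoil import (InterfaceLengthSeries, VertexTrack, analyze_track,
                            fit_kelvin_voigt, grid_search_fit, interface_length,
                            kelvin_voigt_displacement, retraction_velocity)
from epimech.synth import RecoilSimParams, simulate_recoil_track


def make_series(D, tau, L0=2.0, dt=4.0, n_post=9, n_pre=1):
    t = np.arange(-(n_pre - 1) * dt, (n_post + 0.5) * dt, dt)
    L = L0 + kelvin_voigt_displacement(np.clip(t, 0, None), D, tau)
    return InterfaceLengthSeries(t=t, L=L, ablation_index=n_pre - 1)


class TestInterfaceLength:
    def test_static_vertices_give_pythagorean_constant(self):
        n = 10
        tr = VertexTrack(track_id="t", times=np.arange(n) * 4.0,
                         vertex1_xy=np.zeros((n, 2)),
                         vertex2_xy=np.tile([3.0, 4.0], (n, 1)),
                         ablation_frame=0)
        s = interface_length(tr)
        assert np.allclose(s.L, 5.0)
        assert np.allclose(s.t, np.arange(n) * 4.0)

    def test_noiseless_track_matches_closed_form_everywhere(self, noiseless_track):
        s = interface_length(noiseless_track)
        expected = 2.0 + kelvin_voigt_displacement(np.clip(s.t, 0, None), 1.5, 10.0)
        assert np.max(np.abs(s.L - expected)) < 1e-9
        assert abs(s.L[1] - 2.4945199309465407) < 1e-9  # L(4 s)

    def test_time_axis_covers_36s_window(self, noiseless_track):
        s = interface_length(noiseless_track)
        assert np.allclose(s.t, np.arange(0, 37, 4))

    @pytest.mark.parametrize("bad", [
        dict(ablation_frame=8),          # <2 post frames
        dict(ablation_frame=-1),
    ])
    def test_invalid_ablation_frame_rejected(self, bad):
        n = 10
        with pytest.raises(ValueError, match="ablation_frame"):
            VertexTrack(track_id="t", times=np.arange(n) * 4.0,
                        vertex1_xy=np.zeros((n, 2)),
                        vertex2_xy=np.ones((n, 2)), **bad)

    def test_nonuniform_times_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            VertexTrack(track_id="t", times=np.array([0.0, 4.0, 9.0, 12.0]),
                        vertex1_xy=np.zeros((4, 2)),
                        vertex2_xy=np.ones((4, 2)), ablation_frame=0)


class TestRetractionVelocity:
    def test_constant_series_has_zero_velocity(self):
        s = make_series(D=0.0, tau=10.0)
        assert retraction_velocity(s) == 0.0

    def test_noiseless_kv_velocity_closed_form(self):
        s = make_series(D=1.5, tau=10.0, dt=4.0)
        v = retraction_velocity(s)
        assert abs(v - 1.5 * (1 - np.exp(-0.4)) / 4.0) < 1e-9

    def test_two_point_arithmetic(self):
        s = InterfaceLengthSeries(t=np.array([0.0, 4.0, 8.0]),
                                  L=np.array([2.0, 2.6, 2.9]),
                                  ablation_index=0)
        assert abs(retraction_velocity(s) - 0.15) < 1e-12

    def test_velocity_increases_with_amplitude(self):
        vels = [retraction_velocity(make_series(D=d, tau=10.0))
                for d in (0.5, 1.0, 1.5, 2.0)]
        assert np.all(np.diff(vels) > 0)


class TestKelvinVoigtFit:
    @pytest.mark.parametrize("D", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("tau", [5.0, 10.0, 20.0])
    def test_exact_recovery_on_noiseless_series(self, D, tau):
        fit = fit_kelvin_voigt(make_series(D=D, tau=tau))
        assert fit.converged
        assert abs(fit.D - D) / D < 1e-6
        assert abs(fit.tau - tau) / tau < 1e-6

    def test_zero_recoil_flagged_not_raised(self):
        fit = fit_kelvin_voigt(make_series(D=0.0, tau=10.0))
        assert not fit.converged
        assert fit.D == 0.0

    def test_optimizer_beats_grid_oracle_on_noisy_tracks(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            p = RecoilSimParams(L0=4.0, D=float(rng.uniform(0.5, 2.0)),
                                tau=float(rng.uniform(5, 20)), noise_sd=0.05,
                                seed=int(rng.integers(2 ** 31)))
            s = interface_length(simulate_recoil_track(p))
            fit = fit_kelvin_voigt(s)
            post = s.t > 0
            dL = s.L[post] - s.L[s.ablation_index]
            _, _, grid_rss = grid_search_fit(s.t[post], dL)
            assert fit.rss <= grid_rss + 1e-9

    def test_rigid_transform_invariance(self, noiseless_track):
        base = analyze_track(noiseless_track)
        theta = 0.83
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        shift = np.array([13.0, -7.5])
        moved = VertexTrack(
            track_id="moved", times=noiseless_track.times,
            vertex1_xy=noiseless_track.vertex1_xy @ R.T + shift,
            vertex2_xy=noiseless_track.vertex2_xy @ R.T + shift,
            ablation_frame=noiseless_track.ablation_frame)
        res = analyze_track(moved)
        assert abs(res.retraction_velocity - base.retraction_velocity) < 1e-9
        assert abs(res.fit.D - base.fit.D) < 1e-9
        assert abs(res.fit.tau - base.fit.tau) < 1e-9

    def test_monte_carlo_tau_recovery_under_tracking_noise(self):
        # acquisition regime: 4 s frames, 36 s window, 0.05 um jitter
        taus = []
        rng = np.random.default_rng(3)
        for _ in range(100):
            p = RecoilSimParams(L0=4.0, D=1.2, tau=10.0, noise_sd=0.05,
                                seed=int(rng.integers(2 ** 31)))
            fit = analyze_track(simulate_recoil_track(p)).fit
            if fit.converged:
                taus.append(fit.tau)
        assert abs(np.median(taus) - 10.0) / 10.0 < 0.15

    def test_mean_pre_reference_uses_all_pre_frames(self):
        s = make_series(D=1.0, tau=8.0, n_pre=3)
        s.L[0] += 0.2   # perturb an early pre frame
        f_last = fit_kelvin_voigt(s, l_ref_mode="last_pre")
        f_mean = fit_kelvin_voigt(s, l_ref_mode="mean_pre")
        assert f_last.L_ref == s.L[s.ablation_index]
        assert abs(f_mean.L_ref - s.L[:3].mean()) < 1e-12
        assert f_mean.L_ref != f_last.L_ref

    def test_include_t0_adds_anchor_point(self):
        s = make_series(D=1.0, tau=8.0)
        assert fit_kelvin_voigt(s, include_t0=True).n_points == \
            fit_kelvin_voigt(s).n_points + 1

    def test_too_few_post_frames_rejected(self):
        s = InterfaceLengthSeries(t=np.array([0.0, 4.0, 8.0]),
                                  L=np.array([2.0, 2.3, 2.4]), ablation_index=0)
        with pytest.raises(ValueError, match="post-ablation"):
            fit_kelvin_voigt(s)


def test_analyze_track_composes_velocity_and_fit(noiseless_track):
    res = analyze_track(noiseless_track)
    assert abs(res.retraction_velocity - 1.5 * (1 - np.exp(-0.4)) / 4) < 1e-9
    assert abs(res.fit.D - 1.5) < 1e-6 and abs(res.fit.tau - 10.0) < 1e-5
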