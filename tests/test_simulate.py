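"""Generator-level tests: each synthetic assay is checked against an
independent oracle (closed form, fine-step ODE integration, or binomial
sampling theory) plus determinism and degenerate-limit checks."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from polarflux import (ConfigurationError, DataError, compute_track_metrics,
                       match_spots, pearson_coefficient)
from polarflux import simulate as sim


class TestVesicleTracks:
    def test_ballistic_limit_collinear(self, cfg):
        c = cfg.replace(directed_fraction=1.0, jitter_sd_um=0.0,
                        directed_speed_um_s=5.0)
        tracks = sim.gen_vesicle_tracks(c, 5)
        for t in tracks:
            m = compute_track_metrics(t)
            assert m.path_length_um == pytest.approx(5.0 * 118.0)
            assert m.persistence == pytest.approx(1.0)
            assert t.class_label == "directed"

    def test_diffusive_mean_net_displacement_matches_rayleigh(self, cfg):
        """E|r(T)| = sqrt(pi D T) for 2-D Brownian motion."""
        c = cfg.replace(directed_fraction=0.0)
        tracks = sim.gen_vesicle_tracks(c, 5000)
        disp = np.array([
            np.linalg.norm(t.positions[-1] - t.positions[0]) for t in tracks])
        expected = np.sqrt(np.pi * c.diffusion_um2_s * 118.0)
        # SE of the mean of a Rayleigh sample
        se = disp.std(ddof=1) / np.sqrt(disp.size)
        assert abs(disp.mean() - expected) < 4 * se
        assert expected == pytest.approx(4.3, abs=0.05)

    def test_empty_request_rejected(self, cfg):
        with pytest.raises(ConfigurationError):
            sim.gen_vesicle_tracks(cfg, 0)

    def test_track_shape_and_cadence(self, cfg):
        (t,) = sim.gen_vesicle_tracks(cfg, 1)
        assert t.n_points == cfg.n_frames
        np.testing.assert_allclose(np.diff(t.times), cfg.frame_interval_s)


class TestPhotoconversionGenerator:
    def test_no_exchange_is_static(self, cfg):
        c = cfg.replace(k_pf=0, k_pr=0, k_fp=0, k_rp=0, noise_sd=0)
        s = sim.gen_photoconversion_series(c)
        red_p = s.red["perinuclear"]
        i_conv = s.index_of(45.0)
        assert np.ptp(red_p[i_conv:]) == pytest.approx(0.0, abs=1e-12)
        for reg in ("front", "rear"):
            assert np.ptp(s.red[reg]) == pytest.approx(0.0, abs=1e-12)

    def test_absorbing_efflux_closed_form(self, cfg):
        """With no return flux red P decays as exp(-(k_pf+k_pr) dt)."""
        k = 1e-3
        c = cfg.replace(k_pf=k, k_pr=k, k_fp=0, k_rp=0, noise_sd=0)
        s = sim.gen_photoconversion_series(c)
        i_conv = s.index_of(45.0)
        red_p = s.red["perinuclear"] - c.background_level
        dt = s.times_s[i_conv:] - 45.0
        np.testing.assert_allclose(
            red_p[i_conv:], red_p[i_conv] * np.exp(-2 * k * dt), rtol=1e-10)

    def test_red_mass_conserved_after_conversion(self, cfg):
        c = cfg.replace(noise_sd=0.0)
        s = sim.gen_photoconversion_series(c)
        i_conv = s.index_of(45.0)
        total = sum(s.red[r] for r in ("perinuclear", "front", "rear"))
        total = total[i_conv:] - 3 * c.background_level
        assert np.ptp(total) / total[0] < 1e-8

    def test_front_rear_ratio_matches_fine_step_ode(self, cfg):
        """Independent oracle: integrate the exchange ODE with solve_ivp at
        tight tolerance; with k_pf = 2 k_pr the red front gain is twice the
        rear gain."""
        c = cfg.replace(k_pf=2e-3, k_pr=1e-3, k_fp=0, k_rp=0, noise_sd=0)
        s = sim.gen_photoconversion_series(c)
        i_conv = s.index_of(45.0)
        red0 = np.array([s.red[r][i_conv] - c.background_level
                         for r in ("perinuclear", "front", "rear")])

        def rhs(_, y):
            p, f, r = y
            return [-(c.k_pf + c.k_pr) * p + c.k_fp * f + c.k_rp * r,
                    c.k_pf * p - c.k_fp * f,
                    c.k_pr * p - c.k_rp * r]

        sol = solve_ivp(rhs, (45.0, 960.0), red0, t_eval=s.times_s[i_conv:],
                        rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(
            s.red["front"][i_conv:] - c.background_level, sol.y[1], atol=1e-6)
        front_gain = s.red["front"][-1] - s.red["front"][i_conv]
        rear_gain = s.red["rear"][-1] - s.red["rear"][i_conv]
        assert front_gain / rear_gain == pytest.approx(2.0, rel=1e-9)

    def test_flat_green_baseline_before_conversion(self, cfg):
        """Green starts at exchange steady state, so the pre-conversion
        perinuclear trace is flat."""
        s = sim.gen_photoconversion_series(cfg.replace(noise_sd=0.0))
        g = s.green["perinuclear"]
        assert np.ptp(g[: s.index_of(45.0)]) < 1e-9


class TestSpotFields:
    def test_full_overlap_zero_jitter_coincide(self, cfg):
        c = cfg.replace(overlap_fraction=1.0, jitter_sd_um=0.0)
        a, b = sim.gen_spot_fields(c, 50, 50, 40.0)
        d = np.linalg.norm(a.xy - b.xy[a.pair_index], axis=1)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_zero_overlap_yields_zero_cofraction(self, cfg):
        c = cfg.replace(overlap_fraction=0.0, min_separation_um=2.0)
        a, b = sim.gen_spot_fields(c, 100, 100, 60.0)
        res = match_spots(a, b, radius=0.5)
        assert res.frac_A_with_B == 0.0

    def test_measured_fraction_within_binomial_band(self, cfg):
        c = cfg.replace(overlap_fraction=0.7, jitter_sd_um=0.1)
        a, b = sim.gen_spot_fields(c, 200, 200, 40.0)
        res = match_spots(a, b, radius=0.5)
        se = np.sqrt(0.7 * 0.3 / 200)
        assert abs(res.frac_A_with_B - 0.7) < 1.96 * se + 0.02

    def test_unbiased_across_seeds(self):
        """Over many seeds the mean measured co-fraction sits within two
        binomial standard errors of overlap_fraction."""
        from polarflux import SimConfig
        n, p, n_seeds = 150, 0.5, 50
        fracs = []
        for seed in range(n_seeds):
            c = SimConfig(seed=seed, overlap_fraction=p, jitter_sd_um=0.05,
                          min_separation_um=1.5)
            a, b = sim.gen_spot_fields(c, n, n, 60.0)
            fracs.append(match_spots(a, b, radius=0.5).frac_A_with_B)
        se_mean = np.sqrt(p * (1 - p) / n) / np.sqrt(n_seeds)
        assert abs(np.mean(fracs) - p) < 2 * se_mean + 0.01

    def test_field_too_small_raises(self, cfg):
        c = cfg.replace(overlap_fraction=0.0, min_separation_um=5.0)
        with pytest.raises(DataError, match="too small"):
            sim.gen_spot_fields(c, 50, 200, 10.0)


class TestRenderSpotImages:
    def test_single_center_spot_argmax(self, cfg):
        from polarflux.colocalization import SpotField
        f = SpotField(channel="A", xy=[[5.0, 5.0]], field_um=10.0)
        c = cfg.replace(noise_sd=0.0, background_level=1.0)
        img = sim.render_spot_images((f, f), c)
        row, col = np.unravel_index(np.argmax(img[0]), img[0].shape)
        assert abs(col * c.pixel_size_um - 5.0) <= c.pixel_size_um
        assert abs(row * c.pixel_size_um - 5.0) <= c.pixel_size_um

    def test_same_seed_identical_images(self, cfg):
        a, b = sim.gen_spot_fields(cfg, 30, 30, 20.0)
        img1 = sim.render_spot_images((a, b), cfg)
        img2 = sim.render_spot_images((a, b), cfg)
        np.testing.assert_array_equal(img1, img2)

    def test_spot_outside_field_listed(self, cfg):
        from polarflux.colocalization import SpotField
        f = SpotField(channel="A", xy=[[1.0, 1.0], [25.0, 3.0]], field_um=20.0)
        g = SpotField(channel="B", xy=[[2.0, 2.0]], field_um=20.0)
        with pytest.raises(DataError, match=r"\[1\]"):
            sim.render_spot_images((f, g), cfg)

    def test_independent_fields_uncorrelated(self, cfg):
        c1 = cfg.replace(seed=1)
        c2 = cfg.replace(seed=2)
        a1, _ = sim.gen_spot_fields(c1.replace(overlap_fraction=0.0,
                                               min_separation_um=0.0), 80, 1, 30.0)
        a2, _ = sim.gen_spot_fields(c2.replace(overlap_fraction=0.0,
                                               min_separation_um=0.0), 80, 1, 30.0)
        img1 = sim.render_spot_images((a1, a1), c1)
        img2 = sim.render_spot_images((a2, a2), c2)
        assert abs(pearson_coefficient(img1[0], img2[0])) < 0.05


class TestRecyclingGenerator:
    def test_zero_rate_static(self, cfg):
        c = cfg.replace(recycling_rate_per_min=0.0, noise_sd=0.0)
        s = sim.gen_recycling_series(c, [0, 15, 30, 60])
        np.testing.assert_allclose(s.membrane_FI, 0.0)
        np.testing.assert_allclose(s.cytoplasm_FI, c.initial_intensity)

    def test_closed_form_exact_when_noiseless(self, cfg):
        k = 0.0153
        c = cfg.replace(recycling_rate_per_min=k, noise_sd=0.0)
        t = np.array([0.0, 15, 30, 60, 120])
        s = sim.gen_recycling_series(c, t)
        np.testing.assert_allclose(
            s.membrane_FI, c.initial_intensity * (1 - np.exp(-k * t)))
        np.testing.assert_allclose(
            s.cytoplasm_FI, c.initial_intensity * np.exp(-k * t))
        # k = 0.0153/min at 60 min -> ~60% recycled
        assert s.membrane_FI[3] / c.initial_intensity == pytest.approx(
            0.601, abs=0.002)

    def test_long_time_limit_fully_recycled(self, cfg):
        c = cfg.replace(noise_sd=0.0)
        s = sim.gen_recycling_series(c, [0.0, 1e4])
        assert s.membrane_FI[-1] / c.initial_intensity == pytest.approx(1.0)


class TestHaptotaxisGenerator:
    def test_zero_noise_zero_drift_walks_are_straight(self, cfg):
        """With no heading noise and no drift each track is a straight line
        (persistence 1) and |FMI| = |sin(initial heading)| <= 1."""
        from polarflux.haptotaxis import fmi_from_positions
        c = cfg.replace(heading_sd_rad=0.0, drift_fraction=0.0)
        pos = sim.haptotaxis_positions(c, 200, 96)
        vals = fmi_from_positions(pos)
        assert np.all(np.abs(vals) <= 1.0 + 1e-12)
        straightness = np.linalg.norm(pos[:, -1] - pos[:, 0], axis=1) / (
            np.linalg.norm(np.diff(pos, axis=1), axis=2).sum(axis=1))
        np.testing.assert_allclose(straightness, 1.0, rtol=1e-12)

    def test_unbiased_population_mean_fmi_near_zero(self, cfg):
        c = cfg.replace(drift_fraction=0.0)
        pos = sim.haptotaxis_positions(c, 4000, 96)
        from polarflux.haptotaxis import fmi_from_positions
        vals = fmi_from_positions(pos)
        assert abs(vals.mean()) < 3 * vals.std(ddof=1) / np.sqrt(vals.size)

    def test_drift_mean_fmi_matches_geometry(self, cfg):
        """Ensemble-mean FMI ~ drift / sqrt(1 + drift^2) ~ 0.196 at 0.2."""
        c = cfg.replace(drift_fraction=0.2, heading_sd_rad=0.8)
        pos = sim.haptotaxis_positions(c, 4000, 96)
        from polarflux.haptotaxis import fmi_from_positions
        vals = fmi_from_positions(pos)
        predicted = 0.2 / np.sqrt(1 + 0.2**2)
        assert vals.mean() == pytest.approx(predicted, abs=0.03)

    def test_duration_must_divide_step(self, cfg):
        with pytest.raises(ConfigurationError, match="divisible"):
            sim.gen_haptotaxis_tracks(cfg, 5, duration_hr=1.3)

    def test_tracks_origin_anchored(self, cfg):
        tracks = sim.gen_haptotaxis_tracks(cfg, 5)
        for t in tracks:
            np.testing.assert_array_equal(t.positions[0], [0.0, 0.0])
            assert t.n_points == 97


class TestDeterminism:
    """Same seed => bit-identical output for every generator."""

    def test_all_generators(self, cfg):
        t1 = sim.gen_vesicle_tracks(cfg, 10)
        t2 = sim.gen_vesicle_tracks(cfg, 10)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.positions, b.positions)
        s1 = sim.gen_photoconversion_series(cfg)
        s2 = sim.gen_photoconversion_series(cfg)
        np.testing.assert_array_equal(s1.red["front"], s2.red["front"])
        np.testing.assert_array_equal(s1.background, s2.background)
        f1 = sim.gen_spot_fields(cfg, 40, 40, 30.0)
        f2 = sim.gen_spot_fields(cfg, 40, 40, 30.0)
        np.testing.assert_array_equal(f1[0].xy, f2[0].xy)
        r1 = sim.gen_recycling_series(cfg, [0, 30, 60])
        r2 = sim.gen_recycling_series(cfg, [0, 30, 60])
        np.testing.assert_array_equal(r1.membrane_FI, r2.membrane_FI)
        h1 = sim.gen_haptotaxis_tracks(cfg, 8)
        h2 = sim.gen_haptotaxis_tracks(cfg, 8)
        for a, b in zip(h1, h2):
            np.testing.assert_array_equal(a.positions, b.positions)

    def test_different_seeds_differ(self, cfg):
        other = cfg.replace(seed=1)
        a = sim.gen_vesicle_tracks(cfg, 3)[0].positions
        b = sim.gen_vesicle_tracks(other, 3)[0].positions
        assert not np.array_equal(a, b)
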