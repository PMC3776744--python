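"""Generators: analytic pixel values, oracle ground truth, determinism."""

import numpy as np
import pytest
from scipy.integrate import quad

from hypoperf.image import ImageVolume
from hypoperf.phantoms import (
    BolusSpec,
    CurveSpec,
    EffectSpec,
    GridSpec,
    bolus_ground_truth,
    curve_arc_length,
    curve_chord_length,
    default_dti_template,
    default_echo_times,
    ellipse_perimeter,
    gamma_variate,
    generate_bolus_series,
    generate_dti_cohort,
    generate_multiecho_series,
    generate_ring_image,
    generate_vessel_volume,
    helix_for_metrics,
    simulate_longitudinal_metrics,
)


class TestCurves:
    def test_straight_line_arc_equals_chord(self):
        spec = CurveSpec("line", {"start": (0.5, 0.5, 0.5), "end": (1.87, 0.5, 0.5)},
                         radius=0.15)
        assert curve_arc_length(spec) == pytest.approx(1.37, abs=1e-9)
        assert curve_chord_length(spec) == pytest.approx(1.37, abs=1e-9)

    def test_semicircle_arc_and_chord(self):
        r = 1.3
        spec = CurveSpec("arc", {"center": (3, 3, 3), "radius": r,
                                 "basis_u": (1, 0, 0), "basis_v": (0, 1, 0),
                                 "theta0": 0.0, "theta1": np.pi}, radius=0.2)
        assert curve_arc_length(spec) == pytest.approx(np.pi * r, rel=1e-9)
        assert curve_chord_length(spec) == pytest.approx(2 * r, rel=1e-9)

    def test_helix_arc_length_matches_independent_quadrature(self):
        # oracle: adaptive quadrature of |dgamma/dt| from finite differences
        spec = CurveSpec("helix", {"center": (0, 0, 0), "radius": 1.0,
                                   "pitch": 1.0, "turns": 2, "axis": "z"},
                         radius=0.2)

        def speed(t, h=1e-6):
            from hypoperf.phantoms import curve_points

            d = (curve_points(spec, np.array([t + h]))[0]
                 - curve_points(spec, np.array([t - h]))[0]) / (2 * h)
            return np.linalg.norm(d)

        oracle, _ = quad(speed, 1e-5, 1 - 1e-5, limit=200)
        # analytic check of the same quantity
        analytic = 2 * np.hypot(2 * np.pi * 1.0, 1.0)
        assert curve_arc_length(spec) == pytest.approx(analytic, rel=1e-6)
        assert curve_arc_length(spec) == pytest.approx(oracle, rel=1e-4)

    def test_helix_for_metrics_hits_length_and_tortuosity(self):
        spec = helix_for_metrics(15.0, 1.25)
        assert curve_arc_length(spec) == pytest.approx(15.0, rel=1e-9)
        tau = curve_arc_length(spec) / curve_chord_length(spec)
        assert tau == pytest.approx(1.25, rel=1e-9)


class TestVesselVolume:
    def test_bright_tube_on_dark_background(self, iso_grid):
        spec = CurveSpec("line", {"start": (1, 2.7, 2.7), "end": (4, 2.7, 2.7)},
                         radius=0.3)
        vol, truth = generate_vessel_volume(spec, iso_grid, seed=0)
        assert vol.data.max() == 1000.0
        assert vol.data.min() == 0.0
        assert truth.arc_length_mm[0] == pytest.approx(3.0, rel=1e-9)

    def test_curve_exiting_grid_rejected(self, iso_grid):
        spec = CurveSpec("line", {"start": (0, 0, 0), "end": (99, 0, 0)}, radius=0.3)
        with pytest.raises(ValueError, match="exits the grid"):
            generate_vessel_volume(spec, iso_grid, seed=0)

    def test_same_seed_bit_reproducible(self, iso_grid):
        spec = CurveSpec("line", {"start": (1, 2.7, 2.7), "end": (4, 2.7, 2.7)},
                         radius=0.3)
        v1, _ = generate_vessel_volume(spec, iso_grid, background_sd=15, seed=9)
        v2, _ = generate_vessel_volume(spec, iso_grid, background_sd=15, seed=9)
        assert np.array_equal(v1.data, v2.data)


class TestMultiEcho:
    def test_noiseless_signal_follows_exponential(self):
        sp = (1, 1, 1)
        t2 = ImageVolume(np.full((2, 2, 1), 70.0), sp)
        s0 = ImageVolume(np.full((2, 2, 1), 1000.0), sp)
        ser = generate_multiecho_series(t2, s0, [35.0, 70.0])
        assert ser.data[0, 0, 0, 1] == pytest.approx(1000.0 / np.e, rel=1e-12)

    def test_default_echo_ladder_spans_11_to_176(self):
        te = default_echo_times()
        assert len(te) == 16
        assert te[0] == 11.0 and te[-1] == 176.0
        assert np.allclose(np.diff(te), 11.0)

    def test_rician_floor_mean_at_zero_signal(self):
        # Monte-Carlo oracle: E[M | A=0] = sd * sqrt(pi/2)
        sp = (1, 1, 1)
        t2 = ImageVolume(np.full((50, 50, 4), 60.0), sp)
        s0 = ImageVolume(np.zeros((50, 50, 4)), sp)
        ser = generate_multiecho_series(t2, s0, [11.0, 22.0], noise="rician",
                                        noise_sd=10.0, seed=3)
        assert ser.data.mean() == pytest.approx(10.0 * np.sqrt(np.pi / 2), rel=0.02)

    def test_non_increasing_echoes_rejected(self):
        sp = (1, 1, 1)
        t2 = ImageVolume(np.full((2, 2, 1), 70.0), sp)
        s0 = ImageVolume(np.full((2, 2, 1), 1000.0), sp)
        with pytest.raises(ValueError, match="strictly increasing"):
            generate_multiecho_series(t2, s0, [70.0, 35.0])


class TestBolus:
    def test_default_phases_cover_the_protocol(self):
        # 2 min baseline + 20 s injection + 3 min 36 s recovery at 0.16 s
        spec = BolusSpec()
        assert spec.phases == (750, 125, 1350)
        assert sum(spec.phases) * 0.16 == pytest.approx(356.0)

    def test_ttp_is_alpha_beta_and_fwhm_from_root_finding(self):
        spec = BolusSpec(amplitude=200.0, t0=120.0, alpha=3.0, beta=1.5)
        truth = bolus_ground_truth(spec, t_end=336.0)
        assert truth["ttp_s"] == pytest.approx(4.5, abs=1e-9)
        # independent bisection check of the half-maximum crossings
        lo, hi = 120.0, 124.5
        for _ in range(60):
            mid = (lo + hi) / 2
            if gamma_variate(np.array([mid]), 120, 3, 1.5)[0] < 0.5:
                lo = mid
            else:
                hi = mid
        left = (lo + hi) / 2
        lo, hi = 124.5, 140.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if gamma_variate(np.array([mid]), 120, 3, 1.5)[0] > 0.5:
                lo = mid
            else:
                hi = mid
        right = (lo + hi) / 2
        assert truth["fwhm_s"] == pytest.approx(right - left, abs=1e-6)

    def test_zero_amplitude_marks_no_bolus(self):
        truth = bolus_ground_truth(BolusSpec(amplitude=0.0), t_end=336.0)
        assert truth["no_bolus"] and truth["auc"] == 0.0

    def test_amplitude_above_baseline_rejected(self):
        with pytest.raises(ValueError, match="exceeds baseline"):
            BolusSpec(baseline=100.0, amplitude=300.0)

    def test_series_signal_is_baseline_minus_dip(self):
        grid = GridSpec((2, 2, 1), (1, 1, 1), frame_interval=0.16)
        layout = ImageVolume(np.ones((2, 2, 1)), (1, 1, 1))
        spec = BolusSpec(baseline=500.0, amplitude=100.0, t0=121.0)
        ser, truth = generate_bolus_series(layout, {1: spec}, grid, seed=0)
        assert ser.data.shape[-1] == 2225
        assert ser.data[0, 0, 0, 0] == 500.0
        assert ser.data[0, 0, 0].min() == pytest.approx(400.0, abs=0.5)


class TestDtiCohort:
    def test_null_effect_groups_exchangeable(self):
        tmpl = default_dti_template(shape=(10, 10, 5))
        eff = EffectSpec(region_mask=np.zeros((10, 10, 5), bool), effect=0.0,
                         subject_sd=0.03, n_per_group=4, seed=1)
        g1, g2, info = generate_dti_cohort(tmpl, eff)
        assert len(g1) == len(g2) == 4
        pooled1 = np.mean([v.data.mean() for v in g1])
        pooled2 = np.mean([v.data.mean() for v in g2])
        assert pooled1 == pytest.approx(pooled2, abs=0.01)

    def test_effect_added_to_group_two_only(self):
        tmpl = default_dti_template(shape=(10, 10, 5))
        mask = np.zeros((10, 10, 5), bool)
        mask[3:7, 3:7, 1:4] = True
        eff = EffectSpec(region_mask=mask, effect=-0.10, subject_sd=0.001,
                         n_per_group=3, seed=2)
        g1, g2, _ = generate_dti_cohort(tmpl, eff)
        d = g2[0].data - g1[0].data
        assert d[mask].mean() == pytest.approx(-0.10, abs=0.005)
        assert abs(d[~mask].mean()) < 0.005

    def test_single_subject_per_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            EffectSpec(region_mask=np.zeros((4, 4, 2), bool), n_per_group=1)

    def test_fa_clipping_counted(self):
        tmpl = default_dti_template(shape=(8, 8, 4))
        mask = np.ones((8, 8, 4), bool)
        eff = EffectSpec(region_mask=mask, effect=-0.5, subject_sd=0.2,
                         n_per_group=3, seed=0)
        with pytest.warns(UserWarning, match="clipped"):
            _, g2, info = generate_dti_cohort(tmpl, eff)
        assert info["n_clipped"] > 0
        assert all(v.data.min() >= 0 for v in g2)


class TestRings:
    def test_circular_lamina_lengths_are_2_pi_r(self):
        ri = generate_ring_image(10.0, 20.0, pixel_size_um=0.25)
        assert ri.truth["l_i_um"] == pytest.approx(62.8319, abs=1e-3)
        assert ri.truth["l_e_um"] == pytest.approx(125.6637, abs=1e-3)

    def test_zero_nuclei_ground_truth(self):
        ri = generate_ring_image(10.0, 20.0, n_nuclei=0)
        assert ri.truth["n_nuclei"] == 0

    def test_elliptic_perimeter_against_special_function_oracle(self):
        # oracle: complete elliptic integral, P = 4 a E(e^2)
        from scipy.special import ellipe

        a, b = 30.0, 20.0
        oracle = 4 * a * ellipe(1 - (b / a) ** 2)
        assert ellipse_perimeter(a, b) == pytest.approx(oracle, rel=1e-9)
        assert ellipse_perimeter(a, a) == pytest.approx(2 * np.pi * a, rel=1e-9)

    def test_nuclei_overflow_rejected(self):
        with pytest.raises(ValueError, match="nuclei"):
            generate_ring_image(10.0, 13.0, n_nuclei=500, seed=0)

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            generate_ring_image(20.0, 10.0)


class TestLongitudinal:
    def test_sham_trajectories_flat(self):
        _, truth = simulate_longitudinal_metrics(seed=0)
        sham = truth[truth.group == "sham"]
        per_subj = sham.groupby("subject")["length_mm"].nunique()
        assert (per_subj == 1).all()

    def test_paper_schedule_has_seven_timepoints(self):
        _, truth = simulate_longitudinal_metrics(seed=0)
        assert list(truth.timepoint.unique()) == ["pre", "2h", "24h", "10d",
                                                  "3w", "7w", "12w"]

    def test_occluded_growth_reaches_plus_20_percent(self):
        _, truth = simulate_longitudinal_metrics(seed=0)
        for subj, sdf in truth[truth.group == "occluded"].groupby("subject"):
            first = sdf[sdf.timepoint == "pre"]["length_mm"].iloc[0]
            last = sdf[sdf.timepoint == "12w"]["length_mm"].iloc[0]
            assert last / first == pytest.approx(1.20, rel=1e-9)

    def test_shrinking_occluded_multipliers_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            simulate_longitudinal_metrics(
                length_multipliers={
                    "occluded": {tp: 0.9 for tp in
                                 ("pre", "2h", "24h", "10d", "3w", "7w", "12w")},
                    "sham": {tp: 1.0 for tp in
                             ("pre", "2h", "24h", "10d", "3w", "7w", "12w")},
                },
            )
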