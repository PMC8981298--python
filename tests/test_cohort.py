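"""Synthetic cohort generator: duration law, step model, signal model, dataset."""

import numpy as np
import pytest
from scipy.stats import lognorm

from freegait.cohort import (BoutDurationLaw, CohortConfig, GaitProfile,
                             generate_cohort, pendulum_excursion,
                             sample_bout_schedule, synthesize_acceleration,
                             synthesize_step_sequence)


class TestBoutDurationLaw:
    def test_tail_constraints_hold_in_closed_form(self):
        law = BoutDurationLaw.from_tail_probs(0.87, 0.018)
        assert law.cdf(10.0) == pytest.approx(0.87, abs=1e-9)
        assert 1.0 - law.cdf(120.0) == pytest.approx(0.018, abs=1e-9)

    def test_sampled_gt120_fraction_matches_independent_cdf(self):
        """Empirical tail fraction agrees with the shifted-lognormal CDF
        evaluated via scipy's lognorm (independent of the class's cdf)."""
        law = BoutDurationLaw.from_tail_probs(0.87, 0.018)
        expected = float(lognorm.sf(120.0 - law.min_s, law.sigma, scale=np.exp(law.mu)))
        d = law.sample(200_000, np.random.default_rng(3))
        se = np.sqrt(expected * (1 - expected) / len(d))
        assert np.mean(d > 120.0) == pytest.approx(expected, abs=4 * se)

    def test_samples_respect_floor_and_cap(self):
        law = BoutDurationLaw.from_tail_probs(0.85, 0.019, min_s=2.0, cap_s=600.0)
        d = law.sample(50_000, np.random.default_rng(0))
        assert d.min() > 2.0 and d.max() <= 600.0


class TestBoutSchedule:
    def test_short_bout_fraction_near_configured_tail(self, hc_profile):
        prof = GaitProfile(group="PD",
                           bout_duration_law=BoutDurationLaw.from_tail_probs(0.87, 0.018),
                           bout_rate=408)
        days = sample_bout_schedule(prof, 7, rng_seed=1)
        durs = np.array([e - s for day in days for s, e in day])
        assert len(durs) >= 2000
        assert np.mean(durs <= 10.0) == pytest.approx(0.87, abs=0.05)

    def test_zero_rate_gives_empty_schedule(self, hc_profile):
        prof = GaitProfile(group="HC", bout_rate=0.0)
        assert sample_bout_schedule(prof, 3, rng_seed=0) == [[], [], []]

    def test_seed_determinism(self, hc_profile):
        a = sample_bout_schedule(hc_profile, 2, rng_seed=7)
        b = sample_bout_schedule(hc_profile, 2, rng_seed=7)
        assert a == b  # bit-identical floats

    def test_overfull_day_rejected(self):
        prof = GaitProfile(group="HC", bout_rate=20000)
        with pytest.raises(ValueError, match="24 h"):
            sample_bout_schedule(prof, 1, rng_seed=0)

    def test_bouts_disjoint_with_rest_gaps_inside_day(self, hc_profile):
        days = sample_bout_schedule(hc_profile, 2, rng_seed=5)
        for d, day in enumerate(days):
            for (s0, e0), (s1, _) in zip(day, day[1:]):
                assert s1 - e0 >= 1.0 - 1e-9
            for s, e in day:
                assert d * 86400 <= s < e < (d + 1) * 86400


class TestStepSequence:
    def test_degenerate_noise_gives_identical_steps(self, quiet_profile):
        steps = synthesize_step_sequence(quiet_profile, 30.0, 0)
        times = {round(s.step_time, 12) for s in steps}
        assert times == {0.55}

    def test_systematic_asymmetry_recovered_exactly(self):
        prof = GaitProfile(group="HC", mean_step_time=0.55, step_time_sd=0.0,
                           step_length_sd=0.0, asym_step_time=0.02,
                           asym_step_length=0.0)
        steps = synthesize_step_sequence(prof, 60.0, 1)
        left = np.mean([s.step_time for s in steps if s.side == "L"])
        right = np.mean([s.step_time for s in steps if s.side == "R"])
        assert abs(left - right) == pytest.approx(0.02, abs=1e-12)

    def test_step_count_tracks_duration_over_mean_step_time(self, quiet_profile):
        steps = synthesize_step_sequence(quiet_profile, 60.0, 2)
        assert 105 <= len(steps) <= 110  # ~= 60 s / 0.55 s minus bout edges

    def test_velocity_time_length_identity(self, hc_profile):
        steps = synthesize_step_sequence(hc_profile, 45.0, 3)
        for s in steps:
            assert abs(s.step_velocity * s.step_time - s.step_length) < 1e-12

    def test_too_short_duration_raises(self, hc_profile):
        with pytest.raises(ValueError):
            synthesize_step_sequence(hc_profile, 1.0, 0)


class TestAcceleration:
    def test_rest_is_pure_gravity_without_noise(self):
        rec = synthesize_acceleration([], fs=100, sensor_height=1.0, noise_sd=0.0,
                                      tilt_deg=0.0, rng_seed=0, t_end=5.0)
        assert np.allclose(rec.vertical, 1.0, atol=1e-12)
        assert np.allclose(rec.data[:, 1:], 0.0, atol=1e-12)

    def test_double_integration_recovers_pendulum_excursion(self, quiet_profile):
        """For SL=0.6 m and l=1.0 m the CoM excursion must come back as
        h = 1 - sqrt(1 - 0.09) = 0.04606 m (closed form evaluated here
        independently of the generator)."""
        from scipy.integrate import cumulative_trapezoid
        steps = synthesize_step_sequence(quiet_profile, 10.0, 0)
        s = steps[4]
        rec = synthesize_acceleration(steps, fs=100, sensor_height=1.0,
                                      noise_sd=0.0, tilt_deg=0.0, rng_seed=0,
                                      t_end=10.0)
        h_expected = 1.0 - np.sqrt(1.0 - (0.6 / 2) ** 2)
        assert h_expected == pytest.approx(0.04606, abs=5e-5)
        i0 = int(round(s.ic_time * 100))
        i1 = int(round((s.ic_time + s.step_time) * 100))
        a = (rec.vertical[i0:i1] - 1.0) * 9.80665
        v = cumulative_trapezoid(a, dx=0.01, initial=0)
        x = cumulative_trapezoid(v, dx=0.01, initial=0)
        from scipy.signal import detrend
        x = detrend(x)
        assert x.max() - x.min() == pytest.approx(h_expected, rel=0.05)

    def test_values_clipped_to_sensor_range(self, quiet_profile):
        steps = synthesize_step_sequence(quiet_profile, 10.0, 0)
        rec = synthesize_acceleration(steps, fs=100, sensor_height=1.0,
                                      noise_sd=0.0, tilt_deg=0.0, rng_seed=0,
                                      ic_pulse_g=12.0, t_end=10.0)
        assert np.abs(rec.data).max() <= 8.0

    def test_impossible_pendulum_geometry_raises(self):
        with pytest.raises(ValueError):
            pendulum_excursion(2.2, 1.0)


class TestGenerateCohort:
    def test_dataset_layout_and_lab_duration(self, tmp_path):
        cfg = CohortConfig(n_days=1).scaled(bout_rate=20)
        manifest = generate_cohort(2, 2, cfg, master_seed=11, out_dir=tmp_path / "c")
        assert len(manifest) == 4
        for m in manifest:
            assert m["n_sessions"] == 2  # lab + 1 real-world day
        import pandas as pd
        lab = pd.read_csv(tmp_path / "c" / "PD000" / "lab_steps.csv")
        span = lab.ic_time_s.max() - lab.ic_time_s.min()
        assert 117.0 <= span <= 120.0  # 2-min walk within one step of 120 s

    def test_refuses_overwrite_without_force(self, tmp_path):
        cfg = CohortConfig(n_days=1).scaled(bout_rate=5)
        generate_cohort(1, 1, cfg, 0, tmp_path / "d")
        with pytest.raises(FileExistsError):
            generate_cohort(1, 1, cfg, 0, tmp_path / "d")
        generate_cohort(1, 1, cfg, 0, tmp_path / "d", force=True)

    def test_configured_group_effect_direction(self):
        """Profile draws reproduce the configured contrast: HC faster than PD."""
        from freegait.cohort import DEFAULT_GROUPS, participant_rng
        vel = {}
        for g in ("HC", "PD"):
            profs = [DEFAULT_GROUPS[g].draw_profile(participant_rng(123, i, 0))
                     for i in range(20)]
            vel[g] = np.mean([p.mean_step_length / p.mean_step_time for p in profs])
        assert vel["HC"] > vel["PD"]


class TestProfileValidation:
    @pytest.mark.parametrize("kwargs", [
        {"mean_step_time": -0.5}, {"swing_fraction": 1.2},
        {"sensor_height": 0.5}, {"group": "XX"},
    ])
    def test_invalid_profiles_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GaitProfile(**{"group": "HC", **kwargs})

    def test_law_outside_plausible_short_fraction_rejected(self):
        law = BoutDurationLaw.from_tail_probs(0.30, 0.30)
        with pytest.raises(ValueError):
            GaitProfile(group="HC", bout_duration_law=law)
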