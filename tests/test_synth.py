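"""Forward simulator: reporter kinetics, deposition map, rendering."""

import numpy as np
import pytest

from geminirec import profiles, synth
from geminirec.growth import GrowthModel, fit_growth


class TestReporterKinetics:
    def test_zero_before_any_event(self):
        trace = synth.SignalTrace(events=[(5.0, 8.0, 1.0)])
        assert synth.reporter_concentration(trace, 0.0) == 0.0
        assert synth.reporter_concentration(trace, 6.9) == 0.0  # within delay

    def test_instant_rise_limit_is_step_at_delayed_onset(self):
        trace = synth.SignalTrace(events=[(3.0, 50.0, 2.0)], delay=2.0, tau_on=0.0)
        assert synth.reporter_concentration(trace, 4.99) == 0.0
        assert synth.reporter_concentration(trace, 5.0) == pytest.approx(2.0)

    def test_half_rise_time_matches_first_order_solution(self):
        """c(t) = a(1 - e^{-(t-on-delay)/tau}) reaches a/2 at on+delay+tau*ln2."""
        trace = synth.SignalTrace(events=[(1.0, 40.0, 1.0)], delay=2.0, tau_on=0.5)
        t_half = 1.0 + 2.0 + 0.5 * np.log(2.0)
        assert synth.reporter_concentration(trace, t_half) == pytest.approx(0.5, rel=1e-9)

    def test_boost_sets_fast_turnover(self):
        trace = synth.SignalTrace(events=[(0.0, 1.0, 1.0)], boost=True)
        assert trace.tau_on == trace.tau_off == synth.BOOST_TAU

    def test_events_superpose_additively(self):
        e1 = synth.SignalTrace(events=[(0.0, 2.0, 1.0)], delay=0.0)
        e2 = synth.SignalTrace(events=[(1.0, 3.0, 0.5)], delay=0.0)
        both = synth.SignalTrace(events=e1.events + e2.events, delay=0.0)
        t = np.linspace(0, 6, 61)
        np.testing.assert_allclose(
            both.concentration(t), e1.concentration(t) + e2.concentration(t)
        )


@pytest.fixture
def simple_spec():
    return synth.ParticleSpec(
        model=GrowthModel(K=1000.0, A=0.0, units="px"),
        centre=(64.0, 64.0),
        nucleation_time=-8.0,
    )


class TestRadialRecord:
    def test_dark_core_before_first_switch(self, simple_spec):
        schedule = synth.DyeSchedule(switches=[(0.0, "a"), (6.0, "b")])
        rec = synth.compose_radial_record(simple_spec, schedule, end_time=12.0)
        r_first = simple_spec.radius_at(0.0)
        core = rec.ell < r_first - rec.meta["resolution"]
        assert core.sum() > 10
        for ch in ("a", "b"):
            assert np.all(rec.channels[ch][core] == 0.0)

    def test_constant_trace_gives_uniform_signal_shell(self, simple_spec):
        schedule = synth.DyeSchedule(switches=[(0.0, "a")])
        trace = synth.SignalTrace(events=[], basal=3.0)
        rec = synth.compose_radial_record(
            simple_spec, schedule, trace, end_time=12.0, gain=10.0
        )
        np.testing.assert_allclose(rec.channels["signal"], 10.0)

    def test_signal_step_onset_at_deposition_radius(self, simple_spec):
        schedule = synth.DyeSchedule(switches=[(0.0, "a")])
        trace = synth.SignalTrace(events=[(5.0, 50.0, 1.0)], delay=0.0, tau_on=0.0)
        rec = synth.compose_radial_record(
            simple_spec, schedule, trace, end_time=12.0, resolution=0.05, gain=1.0
        )
        sig = rec.channels["signal"]
        onset_ell = rec.ell[np.flatnonzero(sig > 0)[0]]
        assert onset_ell == pytest.approx(simple_spec.radius_at(5.0), abs=0.06)

    def test_pulse_band_is_centred_on_injection_time(self, simple_spec):
        schedule = synth.DyeSchedule(switches=[(0.0, "a")], pulses=[(4.0, 0.5, "p")])
        rec = synth.compose_radial_record(
            simple_spec, schedule, end_time=12.0, resolution=0.02
        )
        band = rec.ell[rec.channels["p"] > 0]
        mid = 0.5 * (band.min() + band.max())
        assert mid == pytest.approx(simple_spec.radius_at(4.0), abs=0.05)

    def test_deposition_conservation(self, simple_spec):
        """Volume-weighted channel content equals its time-domain deposition.

        With layer volume dV proportional to ell^2 d ell, the integral of a
        channel's occupancy over the record equals the integral of its
        occupancy over deposition time weighted by dV/dt = K/3 (both sides
        computed by quadrature).
        """
        schedule = synth.DyeSchedule(switches=[(0.0, "a"), (6.0, "b")])
        rec = synth.compose_radial_record(
            simple_spec, schedule, end_time=12.0, resolution=0.01
        )
        occ = rec.channels["b"]
        lhs = np.trapezoid(occ * 3 * rec.ell**2, rec.ell)
        t = np.linspace(-8.0, 12.0, 20001)
        occupancy_t = ((t >= 6.0) & (t <= 12.0)).astype(float)
        rhs = np.trapezoid(occupancy_t * simple_spec.model.K, t + 8.0)
        assert lhs == pytest.approx(rhs, rel=0.01)


class TestRenderMidplane:
    def test_blur_free_render_inverts_to_the_record(self, step_scene):
        spec, record, _, _ = step_scene
        image = synth.render_midplane([(spec, record)], (256, 256))
        direction = spec.orientation + np.pi / 4
        prof = profiles.extract_radial_profile(
            image.data, spec.centre, direction, width=1, step=0.25,
            layer_scale=np.sqrt(2.0), channel_names=image.channels,
            max_radius=120.0,
        )
        ideal = np.interp(prof.ell, record.ell, record.channels["stamp2"], right=0.0)
        close = np.abs(prof.channels["stamp2"] - ideal) < 0.02 * ideal.max()
        # pixelation only disturbs samples at band edges
        assert close.mean() > 0.9

    def test_rotation_leaves_band_positions_unchanged(self, simple_spec):
        schedule = synth.DyeSchedule(switches=[(0.0, "a"), (6.0, "b")])
        radii = {}
        for theta in (0.0, np.pi / 6):
            spec = synth.ParticleSpec(
                model=simple_spec.model, centre=(64.0, 64.0),
                orientation=theta, nucleation_time=-8.0,
            )
            rec = synth.compose_radial_record(spec, schedule, end_time=12.0)
            img = synth.render_midplane([(spec, rec)], (128, 128))
            d = theta + np.pi / 4
            prof = profiles.extract_radial_profile(
                img.data, spec.centre, d, width=3, step=0.25,
                layer_scale=np.sqrt(2.0), channel_names=img.channels,
                max_radius=60.0,
            )
            radii[theta] = profiles.call_onset(prof, "b").radius
        assert radii[0.0] == pytest.approx(radii[np.pi / 6], abs=1.0)

    def test_seed_determinism_is_bitwise(self, simple_spec):
        schedule = synth.DyeSchedule(switches=[(0.0, "a")])
        rec = synth.compose_radial_record(simple_spec, schedule, end_time=12.0)
        noise = synth.NoiseModel(psf_sigma=1.0, shot_noise=50.0, read_noise_sd=0.1)
        img1 = synth.render_midplane([(simple_spec, rec)], (128, 128), noise=noise, seed=9)
        img2 = synth.render_midplane([(simple_spec, rec)], (128, 128), noise=noise, seed=9)
        assert np.array_equal(img1.data, img2.data)

    def test_stochastic_noise_requires_seed(self, simple_spec):
        schedule = synth.DyeSchedule(switches=[(0.0, "a")])
        rec = synth.compose_radial_record(simple_spec, schedule, end_time=12.0)
        with pytest.raises(ValueError, match="seed"):
            synth.render_midplane(
                [(simple_spec, rec)], (128, 128),
                noise=synth.NoiseModel(shot_noise=10.0),
            )

    def test_overlapping_particles_flagged(self, simple_spec):
        schedule = synth.DyeSchedule(switches=[(0.0, "a")])
        rec = synth.compose_radial_record(simple_spec, schedule, end_time=12.0)
        other = synth.ParticleSpec(
            model=simple_spec.model, centre=(70.0, 64.0), nucleation_time=-8.0
        )
        img = synth.render_midplane([(simple_spec, rec), (other, rec)], (128, 128))
        assert img.meta["overlap"]


class TestTimelapse:
    def test_projected_area_follows_two_thirds_power(self, timelapse_scene):
        specs, times, _, truth = timelapse_scene
        sub = truth[truth["particle_id"] == 0]
        expected = 2.0 * (3000.0 * sub["t_h"]) ** (2 / 3)
        np.testing.assert_allclose(sub["area_px"], expected, rtol=1e-9)

    def test_ground_truth_volume_index_linear_in_time(self, timelapse_scene):
        specs, times, _, truth = timelapse_scene
        sub = truth[truth["particle_id"] == 1]
        from geminirec.growth import GrowthTrajectory

        traj = GrowthTrajectory(
            times=sub["t_h"].to_numpy(), values=sub["area_px"].to_numpy() ** 1.5
        )
        assert fit_growth(traj).r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_particles_full_table(self):
        specs = [
            synth.ParticleSpec(
                model=GrowthModel(K=500.0), centre=(30.0, 30.0), particle_id="a"
            ),
            synth.ParticleSpec(
                model=GrowthModel(K=500.0), centre=(96.0, 96.0), particle_id="b"
            ),
        ]
        times = np.arange(1.0, 6.0)
        _, truth = synth.render_timelapse(specs, times, (128, 128))
        assert len(truth) == 2 * len(times)
        assert set(truth["particle_id"]) == {"a", "b"}


class TestJitteredBands:
    def test_zero_jitter_reproduces_ideal_radii(self):
        df = synth.jittered_band_set(
            [0.0, 11.0], [5.0], n_particles=20, radial_jitter_sd=0.0, seed=1
        )
        np.testing.assert_allclose(df["radius_obs"], df["radius_true"])

    def test_seeded_tables_are_identical(self):
        kw = dict(stamp_times=[0.0, 11.0], event_times=[5.0], n_particles=50,
                  radial_jitter_sd=0.05, seed=123)
        assert synth.jittered_band_set(**kw).equals(synth.jittered_band_set(**kw))

    def test_jitter_calibration_hits_target_sd(self):
        """Decoded s.d. at the window midpoint matches the calibration target."""
        from geminirec.decode import decode_radii

        target = 0.75
        sigma_r = synth.timing_jitter_sigma(0.3, -8.0, (0.0, 11.0), target)
        df = synth.jittered_band_set(
            [0.0, 11.0], [5.5], n_particles=10_000, radial_jitter_sd=sigma_r,
            k_mean=0.3, k_cv=0.0, seed=2,
        )
        decoded = []
        for _, sub in df.groupby("particle"):
            st = sub[sub["role"] == "stamp"]
            ev = sub[sub["role"] == "event"]
            decoded.append(
                decode_radii(
                    st["time"].to_numpy(), st["radius_obs"].to_numpy(),
                    ev["radius_obs"].to_numpy(),
                )[0]
            )
        sd = float(np.std(decoded, ddof=1))
        assert abs(sd - target) / target < 0.15

    def test_late_window_error_follows_cube_root_scaling(self):
        """At fixed radial noise the single-band timing s.d. grows as t^(2/3)."""
        rng = np.random.default_rng(3)
        m = GrowthModel(K=0.3, A=0.0)
        sigma_r = 0.01
        t_early, t_late = 13.5, 66.0
        sds = {}
        for t in (t_early, t_late):
            r = m.radius_at_time(t)
            decoded = m.time_at_radius(r + rng.normal(0, sigma_r, 20_000))
            sds[t] = decoded.std(ddof=1)
        assert sds[t_late] / sds[t_early] == pytest.approx(
            (t_late / t_early) ** (2 / 3), rel=0.05
        )


class TestGrowthTrajectorySimulation:
    def test_shapes_and_determinism(self):
        trajs, truth = synth.simulate_growth_trajectories(
            n_particles=5, duration=10.0, dt=0.5, seed=4
        )
        assert len(trajs) == 5 and len(truth) == 5
        t2, _ = synth.simulate_growth_trajectories(
            n_particles=5, duration=10.0, dt=0.5, seed=4
        )
        np.testing.assert_array_equal(trajs[0].values, t2[0].values)

    def test_noise_free_limit_is_linear(self):
        trajs, truth = synth.simulate_growth_trajectories(
            n_particles=3, duration=20.0, dt=0.5, subunit_volume=1e-9,
            area_noise_sd=0.0, k_cv=0.0, seed=5,
        )
        fit = fit_growth(trajs[0])
        assert fit.r_squared == pytest.approx(1.0, abs=1e-6)
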