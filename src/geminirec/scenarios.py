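"""Canonical benchmark scenarios for the recorder platform.

These functions pin down the standard study conditions — growth-law
characterization, early- and late-window decoding accuracy, rapid-switch
band counting and the dual-event resolution scan — so that tests, the
command line and reproduction scripts all run the same simulations.

Conventions used throughout:

* growth rate ``K`` ~ 0.3 um^3/h with 20% log-normal spread (particles
  reach ~2.4 um radius in 48 h);
* recorder induction 8 h before the first timestamp, so the first stamp
  band sits outside a dark core;
* early window: stamps at 0 and 11 h, signal onsets at 2-8 h;
* late window: recording starts 48 h after induction with a 36 h stamp
  window (stamps at 48 and 84 h on the induction clock), signal onsets at
  6-30 h into the window;
* band-localization jitter calibrated so the total decoded timing s.d.
  at the early-window midpoint is 0.75 h (sub-hour single-particle
  precision), and the SAME radial jitter reused for the late window.
"""

from __future__ import annotations

import numpy as np

from . import decode, profiles, synth
from .growth import GrowthModel, GrowthTrajectory, fit_growth

__all__ = [
    "K_MEAN_UM3_H",
    "K_CV",
    "EARLY_STAMPS",
    "EARLY_GROUPS",
    "LATE_STAMPS",
    "LATE_GROUPS",
    "SIGMA_T_MIDPOINT",
    "growth_fit_summary",
    "early_window_benchmark",
    "late_window_benchmark",
    "rapid_switch_band_count",
    "boost_resolution_scan",
]

K_MEAN_UM3_H = 0.3
K_CV = 0.2
INDUCTION_LEAD_H = 8.0  # growth before the first timestamp (dark core)

EARLY_STAMPS = (0.0, 11.0)
EARLY_GROUPS = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
SIGMA_T_MIDPOINT = 0.75  # hours, total decoded s.d. at the window midpoint

# Late window on the induction clock: recording starts 48 h after
# induction; signals at 6/12/18/24/30 h within the 36 h stamp window.
LATE_STAMPS = (48.0, 84.0)
LATE_GROUPS = (54.0, 60.0, 66.0, 72.0, 78.0)


def growth_fit_summary(seed: int, n_particles: int = 35) -> dict:
    """Growth-law fit quality on simulated timelapse trajectories.

    Simulates ``n_particles`` 48-h trajectories (0.5-h sampling, Poisson
    subunit-count noise plus 2% multiplicative area measurement noise),
    fits the linearized cube-root model per particle and to the
    normalized population-mean volume-index profile, and returns both
    R^2 summaries.
    """
    trajectories, _ = synth.simulate_growth_trajectories(
        n_particles=n_particles,
        duration=48.0,
        dt=0.5,
        k_mean=K_MEAN_UM3_H,
        k_cv=K_CV,
        area_noise_sd=0.02,
        seed=seed,
    )
    fits = [fit_growth(tr) for tr in trajectories]
    individual = np.array([f.r_squared for f in fits])
    normalized = np.array([tr.values / tr.values[-1] for tr in trajectories])
    mean_traj = GrowthTrajectory(
        times=trajectories[0].times,
        values=normalized.mean(axis=0),
        kind="volume_index",
        particle_id="population-mean",
    )
    return {
        "population_r2": float(fit_growth(mean_traj).r_squared),
        "mean_individual_r2": float(individual.mean()),
        "n_particles": n_particles,
    }


def early_window_benchmark(
    seed: int, n_per_group: int = 250
) -> decode.BenchmarkResult:
    """Two-timestamp decoding accuracy in the early recording window."""
    return decode.benchmark_decoding(
        list(EARLY_STAMPS),
        list(EARLY_GROUPS),
        n_per_group,
        sigma_t_target=SIGMA_T_MIDPOINT,
        k_mean=K_MEAN_UM3_H,
        k_cv=K_CV,
        nucleation_time=-INDUCTION_LEAD_H,
        seed=seed,
    )


def late_window_benchmark(
    seed: int, n_per_group: int = 100
) -> decode.BenchmarkResult:
    """Decoding accuracy when recording starts 48 h after induction.

    The radial jitter is the SAME as in the early window (identical
    optics/band-localization error); only the geometry changes — larger
    radii and slower radial growth degrade the time resolution.
    """
    sigma_r = synth.timing_jitter_sigma(
        K_MEAN_UM3_H, -INDUCTION_LEAD_H, EARLY_STAMPS, SIGMA_T_MIDPOINT
    )
    return decode.benchmark_decoding(
        list(LATE_STAMPS),
        list(LATE_GROUPS),
        n_per_group,
        radial_jitter_sd=sigma_r,
        k_mean=K_MEAN_UM3_H,
        k_cv=K_CV,
        nucleation_time=0.0,
        seed=seed,
    )


def rapid_switch_band_count(
    seed: int,
    n_switches: int = 11,
    interval_h: float = 2.0,
    first_switch_h: float = 6.0,
) -> int:
    """Bands recovered from a rapid equal-interval dye-switch particle.

    Renders one particle whose schedule switches between three dyes every
    ``interval_h`` hours (``n_switches`` switches in total, fixation one
    interval after the last), with the PSF sigma set to 20% of the mean
    inter-band spacing and signal-to-noise >= 20, then extracts the
    edge-normal radial profile and counts called peaks across the dye
    channels.
    """
    K = 8000.0  # px^3/h: bands 1.5-3.7 px apart over ages 6-28 h
    dyes = ["dye1", "dye2", "dye3"]
    switch_times = [first_switch_h + interval_h * i for i in range(n_switches)]
    end_time = switch_times[-1] + interval_h
    model = GrowthModel(K=K, A=0.0, units="px")
    spec = synth.ParticleSpec(model=model, centre=(128.0, 128.0), orientation=0.3)
    schedule = synth.DyeSchedule(
        switches=[(t, dyes[i % len(dyes)]) for i, t in enumerate(switch_times)]
    )
    record = synth.compose_radial_record(
        spec, schedule, None, end_time=end_time, resolution=0.25, gain=1.0
    )
    radii = model.radius_at_time(np.array(switch_times + [end_time]))
    psf = 0.2 * float(np.mean(np.diff(radii)))
    noise = synth.NoiseModel(
        psf_sigma=psf, shot_noise=400.0, read_noise_sd=0.01, background=0.1
    )
    image = synth.render_midplane([(spec, record)], (256, 256), noise=noise, seed=seed)
    direction = spec.orientation + np.pi / 4
    profile = profiles.extract_radial_profile(
        image.data,
        spec.centre,
        direction,
        width=5,
        step=0.5,
        max_radius=120.0,
        layer_scale=np.sqrt(2.0),
        channel_names=image.channels,
    )
    conditioned = profiles.condition_profile(profile, cutoff=0.35)
    return sum(len(profiles.call_peaks(conditioned, ch)) for ch in dyes)


def boost_resolution_scan(
    seed: int, separations_min: tuple[float, ...] = (60.0, 45.0, 30.0, 15.0)
) -> tuple[float | None, dict[float, int]]:
    """Smallest resolvable dual-event separation with fast-turnover kinetics.

    Returns the limit in MINUTES plus the per-separation peak counts.
    """
    seps_h = [s / 60.0 for s in separations_min]
    limit_h, counts_h = decode.resolution_limit(seps_h, boost=True, seed=seed)
    counts = {round(k * 60.0, 6): v for k, v in counts_h.items()}
    return (limit_h * 60.0 if limit_h is not None else None), counts
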