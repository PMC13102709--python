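"""Shared fixtures: small rendered scenes used across test modules."""

import numpy as np
import pytest

from geminirec import decode, synth
from geminirec.growth import GrowthModel


@pytest.fixture(scope="session")
def step_scene():
    """Noise-free rendered particle with two switch stamps and a signal step.

    Stamps at 0 and 11 h, a sharp signal step at t = 5 h (no reporter
    delay), induction 8 h before the first stamp, fixation at 22 h.
    Returns (spec, record, image, protocol).
    """
    model = GrowthModel(K=4000.0, A=0.0, units="px")
    spec = synth.ParticleSpec(
        model=model, centre=(128.0, 128.0), orientation=0.25, nucleation_time=-8.0
    )
    schedule = synth.DyeSchedule(switches=[(0.0, "stamp1"), (11.0, "stamp2")])
    trace = synth.SignalTrace(
        events=[(5.0, 22.0, 1.0)], delay=0.0, tau_on=1e-6, tau_off=1.0
    )
    record = synth.compose_radial_record(
        spec, schedule, trace, end_time=22.0, resolution=0.1, gain=100.0
    )
    image = synth.render_midplane(
        [(spec, record)], (256, 256), noise=synth.NoiseModel(psf_sigma=0.5)
    )
    protocol = decode.RecordingProtocol(
        stamps=[decode.Stamp(0.0, "stamp1"), decode.Stamp(11.0, "stamp2")]
    )
    return spec, record, image, protocol


@pytest.fixture(scope="session")
def timelapse_scene():
    """Rendered growing-particle timelapse with one late-nucleating particle."""
    specs = [
        synth.ParticleSpec(
            model=GrowthModel(K=3000.0, A=0.0), centre=(60.0, 70.0),
            orientation=0.2, particle_id=0,
        ),
        synth.ParticleSpec(
            model=GrowthModel(K=4000.0, A=0.0), centre=(190.0, 80.0),
            orientation=0.9, particle_id=1,
        ),
        synth.ParticleSpec(
            model=GrowthModel(K=3500.0, A=0.0), centre=(120.0, 190.0),
            orientation=0.5, nucleation_time=10.0, particle_id=2,
        ),
    ]
    frame_times = np.arange(1.0, 21.0, 1.0)
    noise = synth.NoiseModel(
        psf_sigma=1.0, shot_noise=100.0, read_noise_sd=0.02, background=0.5
    )
    stack, truth = synth.render_timelapse(
        specs, frame_times, (256, 256), intensity=10.0, noise=noise, seed=5
    )
    return specs, frame_times, stack, truth
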